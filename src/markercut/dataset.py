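"""Core data model: patient-level marker data, dichotomization, candidate grids.

All optimizers in this package share the same semantics:

* a *cutoff* ``v`` splits patients into ``low = {marker < v}`` and
  ``high = {marker >= v}``; a value equal to the cutoff belongs to the
  high group, and "high" is the marker-positive reference group in every
  downstream effect size;
* candidate cutoffs are the distinct observed marker values whose split
  leaves at least ``min_group`` patients on each side, so reported
  cutoffs stay interpretable on the marker's own scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Optional, Sequence

import numpy as np

__all__ = [
    "MarkerDataset",
    "CandidateGrid",
    "CutoffResult",
    "NoCutoffError",
    "candidate_cutoffs",
    "dichotomize",
]


class NoCutoffError(ValueError):
    """Raised when the marker admits no valid dichotomization."""


METHOD_TAGS = frozenset(
    {
        "mixture",
        "binary_significance",
        "roc_euclidean",
        "roc_manhattan",
        "min_sensitivity",
        "min_specificity",
        "survival_significance",
        "manual",
    }
)


@dataclass(frozen=True)
class MarkerDataset:
    """Per-patient marker values with optional binary outcome and survival data.

    Parameters
    ----------
    marker
        Metric or ordinal marker value, one per patient; no missing values
        (rows with a missing marker must be dropped before construction,
        see :func:`markercut.io.build_dataset`).
    outcome
        Optional boolean array, ``True`` for the positive outcome level.
    time, event
        Optional right-censored survival pair: non-negative follow-up time
        and event indicator (1 = event observed, 0 = censored).
    ids
        Optional patient identifiers, kept only for reporting.
    """

    marker: np.ndarray
    outcome: Optional[np.ndarray] = None
    time: Optional[np.ndarray] = None
    event: Optional[np.ndarray] = None
    ids: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        marker = np.asarray(self.marker, dtype=float)
        if marker.ndim != 1 or marker.size == 0:
            raise ValueError("marker must be a non-empty 1-D array")
        if not np.all(np.isfinite(marker)):
            raise ValueError("marker contains missing or non-finite values")
        object.__setattr__(self, "marker", marker)

        if self.outcome is not None:
            outcome = np.asarray(self.outcome, dtype=bool)
            if outcome.shape != marker.shape:
                raise ValueError("outcome length does not match marker")
            if np.unique(outcome).size != 2:
                raise ValueError("outcome must have exactly two observed levels")
            object.__setattr__(self, "outcome", outcome)

        if (self.time is None) != (self.event is None):
            raise ValueError("time and event must be given together")
        if self.time is not None:
            time = np.asarray(self.time, dtype=float)
            event = np.asarray(self.event, dtype=int)
            if time.shape != marker.shape or event.shape != marker.shape:
                raise ValueError("time/event length does not match marker")
            if np.any(time < 0) or not np.all(np.isfinite(time)):
                raise ValueError("time must be finite and >= 0")
            if not np.all(np.isin(event, (0, 1))):
                raise ValueError("event must be 0/1")
            object.__setattr__(self, "time", time)
            object.__setattr__(self, "event", event)

        if self.ids is not None:
            ids = np.asarray(self.ids)
            if ids.shape != marker.shape:
                raise ValueError("ids length does not match marker")
            object.__setattr__(self, "ids", ids)

    @property
    def n(self) -> int:
        return self.marker.size

    @property
    def has_outcome(self) -> bool:
        return self.outcome is not None

    @property
    def has_survival(self) -> bool:
        return self.time is not None


@dataclass(frozen=True)
class CandidateGrid:
    """Ascending candidate cutoffs with the group sizes each split yields."""

    cutoffs: np.ndarray
    n_low: np.ndarray
    n_high: np.ndarray

    def __len__(self) -> int:
        return self.cutoffs.size

    @property
    def group_sizes(self) -> list[tuple[int, int]]:
        return list(zip(self.n_low.tolist(), self.n_high.tolist()))


@dataclass
class CutoffResult:
    """A selected cutoff, the method that chose it, and its at-cutoff statistics.

    ``statistics`` is a method-dependent mapping (odds ratio, hazard ratio,
    sensitivity/specificity with Wilson CIs, p-values ...). ``warnings``
    collects non-fatal conditions met while optimizing.
    """

    cutoff: float
    method: str
    statistics: dict[str, Any] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.method not in METHOD_TAGS:
            raise ValueError(f"unknown method tag {self.method!r}")


def dichotomize(data: MarkerDataset | Sequence[float] | np.ndarray, cutoff: float) -> np.ndarray:
    """Boolean high/low labels: ``True`` where ``marker >= cutoff``.

    Monotone in the cutoff: raising the cutoff never moves a patient from
    low to high.
    """
    marker = data.marker if isinstance(data, MarkerDataset) else np.asarray(data, dtype=float)
    return marker >= cutoff


def candidate_cutoffs(data: MarkerDataset, min_group: int = 1) -> CandidateGrid:
    """Enumerate every admissible cutoff over the observed marker values.

    A distinct observed value ``v`` is a candidate when both
    ``{marker < v}`` and ``{marker >= v}`` hold at least ``min_group``
    patients; the global minimum is therefore always excluded (it leaves
    the low group empty).

    Raises
    ------
    NoCutoffError
        If fewer than two distinct marker values exist, or no candidate
        survives the ``min_group`` filter.
    """
    if min_group < 1:
        raise ValueError("min_group must be >= 1")
    marker = data.marker
    values = np.unique(marker)
    if values.size < 2:
        raise NoCutoffError("no cutoff definable: fewer than 2 distinct marker values")
    # n_low(v) counts marker < v; searchsorted on the sorted sample does all
    # candidates at once.
    sorted_marker = np.sort(marker)
    n_low = np.searchsorted(sorted_marker, values, side="left")
    n_high = marker.size - n_low
    keep = (n_low >= min_group) & (n_high >= min_group)
    if not np.any(keep):
        raise NoCutoffError("min_group too large: no candidate cutoff leaves both groups populated")
    return CandidateGrid(cutoffs=values[keep], n_low=n_low[keep], n_high=n_high[keep])
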