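"""Binary-outcome cutoff optimization: minimal Fisher p, ROC distance, constrained
sensitivity/specificity.

The dichotomized marker is cross-tabulated against the outcome; "high
predicts positive" under the default ``high_positive`` orientation. Per
candidate cutoff the scan records the odds ratio with a 95% Wald CI (the
logistic-regression MLE for a single binary predictor is the cross-product
ratio), the two-sided Fisher exact p, and sensitivity/specificity with
Wilson score intervals. Three selection rules operate on the scan:

* ``optimize_binary_significance`` — minimal Fisher p (maximally selected
  2x2 statistic; note the uncorrected minimal p is anti-conservative);
* ``optimize_roc`` — minimal Euclidean or Manhattan distance to the ROC
  ideal point (0, 1); the Manhattan rule maximizes Youden's
  J = sensitivity + specificity - 1;
* ``constrained_cutoff`` — first cutoff whose sensitivity (or specificity)
  exceeds a user threshold, maximizing the complementary measure among
  the qualifying candidates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact, norm
from statsmodels.stats.proportion import proportion_confint

from .dataset import CandidateGrid, CutoffResult, MarkerDataset, dichotomize

__all__ = [
    "ConfusionTable",
    "ROCCurve",
    "BinaryScan",
    "EquivocalZone",
    "confusion_at",
    "fisher_p",
    "odds_ratio",
    "wilson_ci",
    "binary_scan",
    "optimize_binary_significance",
    "roc_curve",
    "optimize_roc",
    "constrained_cutoff",
    "proportion_significant",
    "equivocal_zone",
    "auto_orientation",
]

Orientation = Literal["high_positive", "low_positive"]


@dataclass(frozen=True)
class ConfusionTable:
    """2x2 counts of predicted (high/low) vs observed (positive/negative)."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def sensitivity(self) -> float:
        pos = self.tp + self.fn
        return self.tp / pos if pos else np.nan

    @property
    def specificity(self) -> float:
        neg = self.tn + self.fp
        return self.tn / neg if neg else np.nan


@dataclass(frozen=True)
class ROCCurve:
    """ROC points (1-specificity, sensitivity), one per candidate cutoff.

    ``fpr``/``tpr`` include the trivial endpoints (0,0) and (1,1);
    ``cutoffs`` aligns with the interior points only.
    """

    fpr: np.ndarray
    tpr: np.ndarray
    cutoffs: np.ndarray
    orientation: Orientation

    @property
    def interior(self) -> tuple[np.ndarray, np.ndarray]:
        return self.fpr[1:-1], self.tpr[1:-1]


@dataclass
class BinaryScan:
    """Per-candidate-cutoff odds ratios, Fisher p-values and test accuracy."""

    cutoffs: np.ndarray
    odds_ratio: np.ndarray
    or_low: np.ndarray
    or_high: np.ndarray
    p: np.ndarray
    sensitivity: np.ndarray
    sens_low: np.ndarray
    sens_high: np.ndarray
    specificity: np.ndarray
    spec_low: np.ndarray
    spec_high: np.ndarray
    orientation: Orientation = "high_positive"
    zero_cell_corrected: np.ndarray | None = None

    def __len__(self) -> int:
        return self.cutoffs.size

    def to_frame(self) -> pd.DataFrame:
        cols = {
            "cutoff": self.cutoffs,
            "odds_ratio": self.odds_ratio,
            "or_ci_low": self.or_low,
            "or_ci_high": self.or_high,
            "fisher_p": self.p,
            "sensitivity": self.sensitivity,
            "sens_ci_low": self.sens_low,
            "sens_ci_high": self.sens_high,
            "specificity": self.specificity,
            "spec_ci_low": self.spec_low,
            "spec_ci_high": self.spec_high,
        }
        return pd.DataFrame(cols)


def auto_orientation(data: MarkerDataset) -> Orientation:
    """Orientation under which the marker's empirical AUC is >= 0.5.

    The rank-sum (Mann-Whitney) statistic gives the probability that a
    positive patient's marker exceeds a negative patient's.
    """
    if data.outcome is None:
        raise ValueError("outcome required to orient the marker")
    pos = data.marker[data.outcome]
    neg = data.marker[~data.outcome]
    from scipy.stats import mannwhitneyu

    u = mannwhitneyu(pos, neg, alternative="two-sided").statistic
    auc = u / (pos.size * neg.size)
    return "high_positive" if auc >= 0.5 else "low_positive"


def confusion_at(
    data: MarkerDataset, cutoff: float, orientation: Orientation = "high_positive"
) -> ConfusionTable:
    """Cross-tabulate the dichotomized marker against the outcome."""
    if data.outcome is None:
        raise ValueError("outcome required to build a confusion table")
    if orientation not in ("high_positive", "low_positive"):
        raise ValueError(f"unknown orientation {orientation!r}")
    high = dichotomize(data, cutoff)
    predicted_pos = high if orientation == "high_positive" else ~high
    pos = data.outcome
    return ConfusionTable(
        tp=int(np.sum(predicted_pos & pos)),
        fp=int(np.sum(predicted_pos & ~pos)),
        tn=int(np.sum(~predicted_pos & ~pos)),
        fn=int(np.sum(~predicted_pos & pos)),
    )


def fisher_p(table: ConfusionTable) -> float:
    """Two-sided Fisher exact p (summation of hypergeometric probabilities
    no larger than the observed table's)."""
    return float(fisher_exact([[table.tp, table.fn], [table.fp, table.tn]])[1])


def odds_ratio(table: ConfusionTable, level: float = 0.95) -> tuple[float, float, float, float, bool]:
    """Cross-product odds ratio with Wald CI and Wald p.

    Returns ``(or, ci_low, ci_high, p_wald, corrected)``. The point
    estimate (tp*tn)/(fp*fn) is the logistic MLE for a single binary
    predictor; with any zero cell the Haldane-Anscombe +0.5 correction
    is applied to every cell and flagged via ``corrected``.
    """
    cells = np.array([table.tp, table.fp, table.tn, table.fn], dtype=float)
    corrected = bool(np.any(cells == 0))
    if corrected:
        cells = cells + 0.5
    tp, fp, tn, fn = cells
    log_or = np.log(tp * tn) - np.log(fp * fn)
    se = np.sqrt((1 / cells).sum())
    z = norm.ppf(0.5 + level / 2)
    p_wald = 2 * norm.sf(abs(log_or) / se)
    return (
        float(np.exp(log_or)),
        float(np.exp(log_or - z * se)),
        float(np.exp(log_or + z * se)),
        float(p_wald),
        corrected,
    )


def wilson_ci(successes: int, trials: int, level: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion."""
    if trials < 1:
        raise ValueError("wilson_ci requires at least one trial")
    if not 0 <= successes <= trials:
        raise ValueError("successes must lie in [0, trials]")
    low, high = proportion_confint(successes, trials, alpha=1 - level, method="wilson")
    return float(low), float(high)


def binary_scan(
    data: MarkerDataset, grid: CandidateGrid, orientation: Orientation = "high_positive"
) -> BinaryScan:
    """Evaluate OR/CI, Fisher p and sens/spec with Wilson CIs at every candidate."""
    if data.outcome is None:
        raise ValueError("outcome required for a binary scan")
    m = len(grid)
    out = {k: np.empty(m) for k in (
        "or_", "or_lo", "or_hi", "p", "sens", "sens_lo", "sens_hi", "spec", "spec_lo", "spec_hi")}
    corrected = np.zeros(m, dtype=bool)
    for i, cut in enumerate(grid.cutoffs):
        t = confusion_at(data, cut, orientation)
        out["p"][i] = fisher_p(t)
        out["or_"][i], out["or_lo"][i], out["or_hi"][i], _, corrected[i] = odds_ratio(t)
        out["sens"][i] = t.sensitivity
        out["sens_lo"][i], out["sens_hi"][i] = wilson_ci(t.tp, t.tp + t.fn)
        out["spec"][i] = t.specificity
        out["spec_lo"][i], out["spec_hi"][i] = wilson_ci(t.tn, t.tn + t.fp)
    return BinaryScan(
        cutoffs=np.asarray(grid.cutoffs, dtype=float),
        odds_ratio=out["or_"],
        or_low=out["or_lo"],
        or_high=out["or_hi"],
        p=out["p"],
        sensitivity=out["sens"],
        sens_low=out["sens_lo"],
        sens_high=out["sens_hi"],
        specificity=out["spec"],
        spec_low=out["spec_lo"],
        spec_high=out["spec_hi"],
        orientation=orientation,
        zero_cell_corrected=corrected,
    )


def _at_cutoff_stats(scan: BinaryScan, idx: int) -> dict:
    return {
        "odds_ratio": float(scan.odds_ratio[idx]),
        "or_ci": (float(scan.or_low[idx]), float(scan.or_high[idx])),
        "fisher_p": float(scan.p[idx]),
        "sensitivity": float(scan.sensitivity[idx]),
        "sens_ci": (float(scan.sens_low[idx]), float(scan.sens_high[idx])),
        "specificity": float(scan.specificity[idx]),
        "spec_ci": (float(scan.spec_low[idx]), float(scan.spec_high[idx])),
    }


def optimize_binary_significance(
    data: MarkerDataset, grid: CandidateGrid, orientation: Orientation = "high_positive"
) -> tuple[CutoffResult, BinaryScan]:
    """Cutoff with the most significant (Fisher exact) 2x2 split.

    Ties in the minimal p break toward the lower cutoff. When the outcome
    is independent of the marker every p may equal 1; the minimal-p
    candidate is still returned, with a warning recorded on the result.
    """
    scan = binary_scan(data, grid, orientation)
    idx = int(np.argmin(scan.p))
    result = CutoffResult(
        cutoff=float(scan.cutoffs[idx]),
        method="binary_significance",
        statistics=_at_cutoff_stats(scan, idx),
    )
    if np.all(scan.p >= 1.0):
        result.warnings.append("all candidate splits have p = 1; selection is arbitrary")
    return result, scan


def roc_curve(
    data: MarkerDataset, grid: CandidateGrid, orientation: Orientation = "high_positive"
) -> ROCCurve:
    """ROC points for every candidate cutoff, plus the (0,0)/(1,1) endpoints."""
    if data.outcome is None:
        raise ValueError("outcome required for a ROC curve")
    sens = np.empty(len(grid))
    spec = np.empty(len(grid))
    for i, cut in enumerate(grid.cutoffs):
        t = confusion_at(data, cut, orientation)
        sens[i] = t.sensitivity
        spec[i] = t.specificity
    # order interior points with ascending fpr so the curve runs (0,0)->(1,1)
    order = np.argsort(grid.cutoffs)[:: 1 if orientation == "low_positive" else -1]
    fpr = np.concatenate(([0.0], 1 - spec[order], [1.0]))
    tpr = np.concatenate(([0.0], sens[order], [1.0]))
    return ROCCurve(
        fpr=fpr, tpr=tpr, cutoffs=np.asarray(grid.cutoffs, dtype=float)[order], orientation=orientation
    )


def optimize_roc(
    roc: ROCCurve, metric: Literal["euclidean", "manhattan"] = "euclidean"
) -> CutoffResult:
    """Candidate closest to the ROC ideal point (0, 1).

    ``euclidean`` minimizes sqrt((1-sens)^2 + (1-spec)^2); ``manhattan``
    minimizes (1-sens) + (1-spec), i.e. maximizes Youden's J. Ties break
    toward the lower cutoff.
    """
    fpr, tpr = roc.interior
    if fpr.size == 0:
        raise ValueError("empty ROC curve")
    if metric == "euclidean":
        dist = np.hypot(fpr, 1 - tpr)
    elif metric == "manhattan":
        dist = fpr + (1 - tpr)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    # interior points may be ordered by descending cutoff; break ties on cutoff
    # (1e-12 absolute tolerance: the same distance reached through different
    # float paths differs in the last ulp)
    best = dist.min()
    tied = np.flatnonzero(dist <= best + 1e-12)
    idx = tied[np.argmin(roc.cutoffs[tied])]
    method = "roc_euclidean" if metric == "euclidean" else "roc_manhattan"
    return CutoffResult(
        cutoff=float(roc.cutoffs[idx]),
        method=method,
        statistics={
            "sensitivity": float(tpr[idx]),
            "specificity": float(1 - fpr[idx]),
            "youden_j": float(tpr[idx] - fpr[idx]),
            "distance": float(dist[idx]),
        },
    )


def constrained_cutoff(
    scan: BinaryScan,
    constraint: Literal["sensitivity", "specificity"],
    threshold: float,
) -> CutoffResult:
    """First cutoff whose constrained measure strictly exceeds ``threshold``.

    Among the qualifying candidates the complementary measure is
    maximized; ties in the complementary measure break toward the more
    stringent qualifying cutoff (largest for a sensitivity constraint,
    smallest for a specificity constraint).
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    if constraint == "sensitivity":
        measure, complement = scan.sensitivity, scan.specificity
        method = "min_sensitivity"
    elif constraint == "specificity":
        measure, complement = scan.specificity, scan.sensitivity
        method = "min_specificity"
    else:
        raise ValueError(f"unknown constraint {constraint!r}")
    qualifying = np.flatnonzero(measure > threshold)
    if qualifying.size == 0:
        raise ValueError(f"no cutoff satisfies constraint {constraint} > {threshold}")
    comp = complement[qualifying]
    tied = qualifying[np.isclose(comp, comp.max(), rtol=0, atol=0)]
    idx = int(tied.max() if constraint == "sensitivity" else tied.min())
    stats = _at_cutoff_stats(scan, idx)
    stats["constraint"] = {"measure": constraint, "threshold": threshold}
    return CutoffResult(cutoff=float(scan.cutoffs[idx]), method=method, statistics=stats)


def proportion_significant(scan, alpha: float = 0.05) -> float:
    """Fraction of candidate cutoffs with p below ``alpha``.

    A robustness diagnostic: a dichotomization whose significance holds
    over most of the cutoff range is less likely to be a minimal-p
    artifact. Accepts any scan object with a ``p`` attribute.
    """
    p = np.asarray(scan.p, dtype=float)
    if p.size == 0:
        raise ValueError("empty scan")
    return float(np.mean(p < alpha))


@dataclass
class EquivocalZone:
    """Three-way test from two constrained cutoffs.

    Markers below ``lower`` are negative, at or above ``upper`` positive,
    in between equivocal (no reliable call).
    """

    lower: float
    upper: float
    fraction_equivocal: float
    warnings: list[str] = field(default_factory=list)

    def classify(self, marker: np.ndarray) -> np.ndarray:
        """Per-sample call: 'negative', 'equivocal' or 'positive'."""
        marker = np.asarray(marker, dtype=float)
        out = np.full(marker.shape, "equivocal", dtype=object)
        out[marker < self.lower] = "negative"
        out[marker >= self.upper] = "positive"
        return out


def equivocal_zone(
    data: MarkerDataset,
    grid: CandidateGrid,
    sens_threshold: float = 0.9,
    spec_threshold: float = 0.9,
    orientation: Orientation = "high_positive",
) -> EquivocalZone:
    """Two sequential constrained optimizations yielding an indeterminate band.

    The lower cutoff guarantees sensitivity above ``sens_threshold``, the
    upper guarantees specificity above ``spec_threshold``; samples with
    marker in [lower, upper) are reported as equivocal rather than forced
    into a group.
    """
    scan = binary_scan(data, grid, orientation)
    lower = constrained_cutoff(scan, "sensitivity", sens_threshold).cutoff
    upper = constrained_cutoff(scan, "specificity", spec_threshold).cutoff
    zone = EquivocalZone(lower=lower, upper=upper, fraction_equivocal=0.0)
    if lower > upper:
        msg = "constraints produce an inverted zone (sensitivity cutoff above specificity cutoff)"
        warnings.warn(msg, stacklevel=2)
        zone.warnings.append(msg)
    frac = np.mean((data.marker >= min(lower, upper)) & (data.marker < max(lower, upper)))
    zone.fraction_equivocal = float(frac) if lower < upper else 0.0
    return zone
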