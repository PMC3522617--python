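"""Survival-based cutoff optimization and survival summaries.

Per candidate cutoff the marker is dichotomized and the two arms are
compared by the log-rank test (which drives the selection of the optimal
cutoff), a univariate Cox proportional-hazards fit (hazard ratio of the
high arm vs the low arm, with a 95% Wald CI), and the difference in
restricted mean survival time (RMST). All RMSTs use one uniform horizon:
the maximum observed time in the full dataset, so the areas under the two
Kaplan-Meier curves are comparable across arms and across cutoffs.

Kaplan-Meier estimation and the log-rank test are delegated to lifelines;
the Cox fit uses lifelines' Efron tie handling (switchable to Breslow).
The RMST point estimate and its Greenwood-type asymptotic variance are
computed directly from the product-limit curve:

    Var(RMST) = sum over event times t_i <= tau of
                A_i^2 * d_i / (n_i * (n_i - d_i)),   A_i = int_{t_i}^{tau} S(u) du
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy.stats import norm
from statsmodels.duration.hazard_regression import PHReg

from .dataset import CandidateGrid, CutoffResult, MarkerDataset, dichotomize

__all__ = [
    "KMCurve",
    "CoxHR",
    "SurvivalScan",
    "km_estimate",
    "logrank_p",
    "cox_hr",
    "rmst",
    "rmst_variance",
    "survival_difference_scan",
    "survival_scan",
    "optimize_survival_significance",
]


@dataclass(frozen=True)
class KMCurve:
    """Kaplan-Meier step function.

    ``survival[i]`` is the product-limit estimate just after
    ``event_times[i]``; the curve is 1 before the first event and constant
    between events. ``max_time`` is the largest observed time, event or
    censored.
    """

    event_times: np.ndarray
    survival: np.ndarray
    n_risk: np.ndarray
    n_event: np.ndarray
    max_time: float

    def survival_at(self, t: np.ndarray) -> np.ndarray:
        """Left-continuous step evaluation S(t)."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.event_times, t, side="right")
        s = np.concatenate(([1.0], self.survival))
        return s[idx]


def km_estimate(times, events) -> KMCurve:
    """Product-limit survival estimate S(t) = prod (1 - d_i/n_i)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("empty survival input")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    table = kmf.event_table
    has_event = table["observed"] > 0
    event_times = table.index.to_numpy(dtype=float)[has_event]
    surv = kmf.survival_function_["KM_estimate"].to_numpy()[has_event.to_numpy()]
    return KMCurve(
        event_times=event_times,
        survival=surv,
        n_risk=table["at_risk"].to_numpy()[has_event.to_numpy()],
        n_event=table["observed"].to_numpy()[has_event.to_numpy()],
        max_time=float(times.max()),
    )


def logrank_p(times, events, groups) -> float:
    """Two-group log-rank test p-value (chi-square, 1 df).

    With no events at all the statistic is undefined; p = 1 is returned
    with a warning.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups, dtype=bool)
    if groups.all() or (~groups).all():
        raise ValueError("log-rank test requires two non-empty groups")
    if events.sum() == 0:
        warnings.warn("no events observed; log-rank p set to 1", stacklevel=2)
        return 1.0
    res = logrank_test(times[groups], times[~groups], events[groups], events[~groups])
    return float(res.p_value)


class CoxHR(NamedTuple):
    hr: float
    ci_low: float
    ci_high: float
    p_wald: float
    flagged: bool


def cox_hr(times, events, groups, ties: str = "efron", level: float = 0.95) -> CoxHR:
    """Univariate Cox hazard ratio for a binary group indicator (high vs low).

    When every event falls in one group the partial likelihood is monotone
    in the coefficient; the estimate is returned at the boundary (0 or
    inf) with an infinite CI and ``flagged=True`` instead of iterating to
    a failure.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups, dtype=bool)
    if groups.all() or (~groups).all():
        raise ValueError("Cox fit requires two non-empty groups")
    n_events = events.sum()
    if n_events == 0:
        raise ValueError("Cox fit requires at least one event")
    ev_high = int(events[groups].sum())
    ev_low = int(n_events - ev_high)
    if ev_high == 0 or ev_low == 0:
        return CoxHR(
            hr=0.0 if ev_high == 0 else np.inf,
            ci_low=0.0,
            ci_high=np.inf,
            p_wald=np.nan,
            flagged=True,
        )
    if ties not in ("efron", "breslow"):
        raise ValueError(f"unknown tie method {ties!r}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = PHReg(times, groups.astype(float)[:, None], status=events, ties=ties)
        res = model.fit()
    coef = float(res.params[0])
    se = float(res.bse[0])
    z = norm.ppf(0.5 + level / 2)
    return CoxHR(
        hr=float(np.exp(coef)),
        ci_low=float(np.exp(coef - z * se)),
        ci_high=float(np.exp(coef + z * se)),
        p_wald=float(2 * norm.sf(abs(coef) / se)) if se > 0 else np.nan,
        flagged=False,
    )


def _segment_areas(curve: KMCurve, tau: float) -> tuple[np.ndarray, np.ndarray]:
    """Per-event-time tail areas A_i = int_{t_i}^{tau} S(u) du and the full area."""
    t = curve.event_times
    s = curve.survival
    within = t <= tau
    t_in = t[within]
    s_in = s[within]
    knots = np.concatenate(([0.0], t_in, [tau]))
    heights = np.concatenate(([1.0], s_in))
    widths = np.diff(knots)
    areas = heights * widths
    total = areas.sum()
    # A_i = area to the right of t_i; suffix sums of the segments, segment i
    # starting at event time t_i
    suffix = np.cumsum(areas[::-1])[::-1]
    return suffix[1:], np.array([total])


def rmst(curve: KMCurve, tau: float) -> float:
    """Restricted mean survival time: area under the KM step up to ``tau``.

    With no censoring and ``tau`` = the largest time this equals the
    arithmetic mean of the survival times. For ``tau`` beyond the last
    observed time the curve is held constant and a warning is issued.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    if tau > curve.max_time:
        warnings.warn(
            "tau exceeds the maximum observed time; survival held constant beyond the data",
            stacklevel=2,
        )
    _, total = _segment_areas(curve, tau)
    return float(total[0])


def rmst_variance(curve: KMCurve, tau: float) -> float:
    """Greenwood-type asymptotic variance of the RMST estimate."""
    if tau <= 0:
        raise ValueError("tau must be positive")
    tail, _ = _segment_areas(curve, tau)
    within = curve.event_times <= tau
    d = curve.n_event[within].astype(float)
    n = curve.n_risk[within].astype(float)
    denom = n * (n - d)
    terms = np.where(tail**2 > 0, np.divide(tail**2 * d, denom, out=np.zeros_like(d), where=denom > 0), 0.0)
    return float(terms.sum())


@dataclass
class SurvivalScan:
    """Per-candidate-cutoff hazard ratios, log-rank p and RMST differences."""

    cutoffs: np.ndarray
    hr: np.ndarray
    hr_low: np.ndarray
    hr_high: np.ndarray
    p: np.ndarray
    rmst_diff: np.ndarray
    rmst_diff_low: np.ndarray
    rmst_diff_high: np.ndarray
    hr_flagged: np.ndarray | None = None
    rmst_ci_unreliable: np.ndarray | None = None
    tau: float = np.nan

    def __len__(self) -> int:
        return self.cutoffs.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cutoff": self.cutoffs,
                "hazard_ratio": self.hr,
                "hr_ci_low": self.hr_low,
                "hr_ci_high": self.hr_high,
                "logrank_p": self.p,
                "rmst_diff": self.rmst_diff,
                "rmst_diff_ci_low": self.rmst_diff_low,
                "rmst_diff_ci_high": self.rmst_diff_high,
            }
        )


def survival_difference_scan(data: MarkerDataset, grid: CandidateGrid) -> pd.DataFrame:
    """RMST(high) - RMST(low) at every candidate, uniform tau = max time.

    The CI combines the Greenwood-type variances of the two arms as
    independent; an arm without events yields zero estimated variance and
    the CI is flagged unreliable.
    """
    if not data.has_survival:
        raise ValueError("survival variables required")
    tau = float(data.time.max())
    rows = []
    for cut in grid.cutoffs:
        high = dichotomize(data, cut)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            km_hi = km_estimate(data.time[high], data.event[high])
            km_lo = km_estimate(data.time[~high], data.event[~high])
            r_hi, r_lo = rmst(km_hi, tau), rmst(km_lo, tau)
            var = rmst_variance(km_hi, tau) + rmst_variance(km_lo, tau)
        unreliable = km_hi.event_times.size == 0 or km_lo.event_times.size == 0
        half = 1.959964 * np.sqrt(var)
        rows.append(
            {
                "cutoff": float(cut),
                "rmst_high": r_hi,
                "rmst_low": r_lo,
                "rmst_diff": r_hi - r_lo,
                "rmst_diff_ci_low": r_hi - r_lo - half,
                "rmst_diff_ci_high": r_hi - r_lo + half,
                "ci_unreliable": unreliable,
            }
        )
    return pd.DataFrame(rows)


def survival_scan(
    data: MarkerDataset, grid: CandidateGrid, include_effects: bool = True
) -> SurvivalScan:
    """Log-rank p at every candidate; optionally HR/CI and RMST differences."""
    if not data.has_survival:
        raise ValueError("survival variables required")
    m = len(grid)
    p = np.empty(m)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i, cut in enumerate(grid.cutoffs):
            high = dichotomize(data, cut)
            p[i] = logrank_p(data.time, data.event, high)
    nanarr = np.full(m, np.nan)
    scan = SurvivalScan(
        cutoffs=np.asarray(grid.cutoffs, dtype=float),
        hr=nanarr.copy(),
        hr_low=nanarr.copy(),
        hr_high=nanarr.copy(),
        p=p,
        rmst_diff=nanarr.copy(),
        rmst_diff_low=nanarr.copy(),
        rmst_diff_high=nanarr.copy(),
        hr_flagged=np.zeros(m, dtype=bool),
        rmst_ci_unreliable=np.zeros(m, dtype=bool),
        tau=float(data.time.max()),
    )
    if include_effects:
        for i, cut in enumerate(grid.cutoffs):
            high = dichotomize(data, cut)
            fit = cox_hr(data.time, data.event, high)
            scan.hr[i], scan.hr_low[i], scan.hr_high[i] = fit.hr, fit.ci_low, fit.ci_high
            scan.hr_flagged[i] = fit.flagged
        diff = survival_difference_scan(data, grid)
        scan.rmst_diff = diff["rmst_diff"].to_numpy()
        scan.rmst_diff_low = diff["rmst_diff_ci_low"].to_numpy()
        scan.rmst_diff_high = diff["rmst_diff_ci_high"].to_numpy()
        scan.rmst_ci_unreliable = diff["ci_unreliable"].to_numpy()
    return scan


def optimize_survival_significance(
    data: MarkerDataset, grid: CandidateGrid, include_effects: bool = True
) -> tuple[CutoffResult, SurvivalScan]:
    """Cutoff with the most significant (log-rank) split.

    Ties in the minimal p break toward the lower cutoff. Selection uses
    the log-rank p only; the per-candidate HR/CI and RMST differences are
    reported alongside when ``include_effects`` is set.
    """
    if not data.has_survival:
        raise ValueError("survival variables required")
    if data.event.sum() == 0:
        raise ValueError("no events observed; survival optimization undefined")
    scan = survival_scan(data, grid, include_effects=include_effects)
    idx = int(np.argmin(scan.p))
    stats = {"logrank_p": float(scan.p[idx])}
    if include_effects:
        stats.update(
            hazard_ratio=float(scan.hr[idx]),
            hr_ci=(float(scan.hr_low[idx]), float(scan.hr_high[idx])),
            rmst_diff=float(scan.rmst_diff[idx]),
            rmst_diff_ci=(float(scan.rmst_diff_low[idx]), float(scan.rmst_diff_high[idx])),
        )
    return (
        CutoffResult(cutoff=float(scan.cutoffs[idx]), method="survival_significance", statistics=stats),
        scan,
    )
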