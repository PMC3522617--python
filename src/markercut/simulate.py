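"""Synthetic cohorts with the statistical structure each cutoff method assumes.

The default cohort emulates a microarray-style hormone-receptor marker in
breast cancer: a bimodal log2-scale expression value (two Gaussian
components around 5 and 10, a ~30% low-expressing subpopulation), a binary
gold-standard status tightly linked to the marker (step link at the
component crossing with a small misclassification rate), and right-censored
follow-up in which high expression is protective (proportional hazards,
HR 0.5 at the true cutoff, ~30% censoring), with n = 286 patients.

All draws are reproducible from a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .dataset import MarkerDataset

__all__ = [
    "MixtureSpec",
    "gen_bimodal_marker",
    "gen_binary_outcome",
    "gen_survival",
    "make_cohort",
    "write_cohort_tsv",
    "cohort_dataset",
]


@dataclass(frozen=True)
class MixtureSpec:
    """Two-Gaussian marker distribution; defaults mirror a bimodal log2
    expression profile with a low-expressing minority component."""

    pi1: float = 0.3
    mu1: float = 5.0
    mu2: float = 10.0
    sigma1: float = 1.0
    sigma2: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.pi1 < 1:
            raise ValueError("pi1 must lie strictly in (0, 1)")
        if self.sigma1 <= 0 or self.sigma2 <= 0:
            raise ValueError("component SDs must be positive")

    @property
    def mean(self) -> float:
        return self.pi1 * self.mu1 + (1 - self.pi1) * self.mu2


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    if seed is None:
        raise ValueError("a seed is required for reproducibility")
    return np.random.default_rng(seed)


def gen_bimodal_marker(n: int, spec: MixtureSpec = MixtureSpec(), seed=None) -> np.ndarray:
    """``n`` draws from the two-component Gaussian mixture."""
    rng = _rng(seed)
    comp = rng.random(n) >= spec.pi1  # True -> upper component
    mu = np.where(comp, spec.mu2, spec.mu1)
    sigma = np.where(comp, spec.sigma2, spec.sigma1)
    return rng.normal(mu, sigma)


def gen_binary_outcome(
    marker: np.ndarray,
    link: str = "step",
    changepoint: float = 7.5,
    flip_prob: float = 0.05,
    intercept: float = 0.0,
    slope: float = 0.0,
    seed=None,
) -> np.ndarray:
    """Binary outcome linked to the marker.

    ``step``: positive iff marker >= ``changepoint``, each label flipped
    independently with probability ``flip_prob`` (a noisy gold standard).
    ``logistic``: P(positive) = expit(intercept + slope * marker); a zero
    slope gives an outcome independent of the marker for null simulations.
    """
    rng = _rng(seed)
    marker = np.asarray(marker, dtype=float)
    if link == "step":
        if not 0 <= flip_prob < 0.5:
            raise ValueError("flip_prob must lie in [0, 0.5)")
        truth = marker >= changepoint
        flips = rng.random(marker.size) < flip_prob
        return truth ^ flips
    if link == "logistic":
        return rng.random(marker.size) < expit(intercept + slope * marker)
    raise ValueError(f"unknown link {link!r}")


def _censoring_rate_for_target(p_high: float, lam_low: float, lam_high: float, target: float) -> float:
    """Exponential censoring rate c with P(C < T) = target under the marginal
    two-group exponential event-time mixture (P(cens | rate lam) = c/(c+lam))."""

    def frac(c):
        return (1 - p_high) * c / (c + lam_low) + p_high * c / (c + lam_high) - target

    hi = 1.0
    while frac(hi) < 0:
        hi *= 10
        if hi > 1e12:
            raise ValueError("cannot reach the requested censoring fraction")
    return brentq(frac, 1e-12, hi)


def gen_survival(
    marker: np.ndarray,
    true_cutoff: float = 7.5,
    baseline_rate: float = 0.2,
    hr_high: float = 0.5,
    censoring: float = 0.3,
    seed=None,
) -> tuple[np.ndarray, np.ndarray]:
    """Right-censored survival with a proportional-hazards step effect.

    Event times are exponential with hazard ``baseline_rate`` below the
    true cutoff and ``baseline_rate * hr_high`` at or above it; censoring
    times are independent exponentials with the rate calibrated so the
    expected censored fraction equals ``censoring``.
    """
    rng = _rng(seed)
    marker = np.asarray(marker, dtype=float)
    if baseline_rate <= 0 or hr_high <= 0:
        raise ValueError("rates and hazard ratios must be positive")
    if not 0 <= censoring < 1:
        raise ValueError("censoring fraction must lie in [0, 1)")
    high = marker >= true_cutoff
    lam = np.where(high, baseline_rate * hr_high, baseline_rate)
    t_event = rng.exponential(1 / lam)
    if censoring == 0:
        return t_event, np.ones(marker.size, dtype=int)
    c_rate = _censoring_rate_for_target(
        float(high.mean()), baseline_rate, baseline_rate * hr_high, censoring
    )
    t_cens = rng.exponential(1 / c_rate, size=marker.size)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    return time, event


def make_cohort(
    n: int = 286,
    seed: int = 0,
    spec: MixtureSpec = MixtureSpec(),
    changepoint: float = 7.5,
    flip_prob: float = 0.05,
    hr_high: float = 0.5,
    censoring: float = 0.3,
    baseline_rate: float = 0.2,
) -> pd.DataFrame:
    """Full synthetic cohort: marker + binary status + survival columns.

    The true changepoint defaults to 7.5, midway between the mixture
    components, which for equal component SDs is also near the density
    crossing, so the distribution-based and outcome-based methods target
    the same underlying cutoff.
    """
    rng = _rng(seed)
    marker = gen_bimodal_marker(n, spec, rng)
    outcome = gen_binary_outcome(marker, "step", changepoint, flip_prob, seed=rng)
    time, event = gen_survival(
        marker, changepoint, baseline_rate, hr_high, censoring, seed=rng
    )
    return pd.DataFrame(
        {
            "patient": [f"P{i + 1:04d}" for i in range(n)],
            "marker": marker,
            "status": np.where(outcome, "positive", "negative"),
            "time": time,
            "event": event,
        }
    )


def write_cohort_tsv(path, df: pd.DataFrame) -> None:
    """Write a cohort in the tab-separated input dialect of the loader."""
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def cohort_dataset(df: pd.DataFrame) -> MarkerDataset:
    """Convenience: build a MarkerDataset from a generated cohort frame."""
    return MarkerDataset(
        marker=df["marker"].to_numpy(),
        outcome=(df["status"] == "positive").to_numpy(),
        time=df["time"].to_numpy(),
        event=df["event"].to_numpy(),
        ids=df["patient"].to_numpy(),
    )
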