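"""Distribution-based cutoff: two-component Gaussian mixture density crossing.

The marker is modelled as pi1*N(mu1, sigma1^2) + pi2*N(mu2, sigma2^2),
fitted by maximum likelihood (EM on the raw observations, not on binned
histogram counts). The cutoff is the point where the two weighted
component densities coincide, i.e. the root of

    pi1 * phi(x; mu1, sigma1) = pi2 * phi(x; mu2, sigma2)

lying between the component means. Taking logs this is a quadratic in x
for unequal variances and linear for equal variances, so the crossing is
solved in closed form.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp
from scipy.stats import norm

from .dataset import MarkerDataset

__all__ = ["MixtureFit", "fit_mixture", "mixture_cutoff", "mixture_density"]

# EM stopping rule: relative log-likelihood change below this, or MAX_ITER.
_REL_TOL = 1e-8
_MAX_ITER = 500
# Component SDs are floored at this fraction of the sample SD to prevent
# the likelihood from diverging on a collapsing component.
_SIGMA_FLOOR_FRAC = 1e-4


@dataclass
class MixtureFit:
    """Maximum-likelihood two-Gaussian mixture, components ordered mu1 < mu2."""

    pi1: float
    pi2: float
    mu1: float
    mu2: float
    sigma1: float
    sigma2: float
    loglik: float
    n_iter: int
    converged: bool
    loglik_trace: np.ndarray = field(repr=False, default=None)

    @property
    def params(self) -> tuple[float, float, float, float, float, float]:
        return (self.pi1, self.pi2, self.mu1, self.mu2, self.sigma1, self.sigma2)


def mixture_density(fit: MixtureFit, x: np.ndarray) -> np.ndarray:
    """Mixture pdf evaluated at ``x``."""
    x = np.asarray(x, dtype=float)
    return fit.pi1 * norm.pdf(x, fit.mu1, fit.sigma1) + fit.pi2 * norm.pdf(x, fit.mu2, fit.sigma2)


def _log_component_densities(x, pi, mu, sigma):
    return np.log(pi)[:, None] + norm.logpdf(x[None, :], mu[:, None], sigma[:, None])


def _em(x: np.ndarray, pi, mu, sigma, sigma_floor: float):
    """One EM run from the given start; returns (params, loglik_trace)."""
    pi = np.asarray(pi, dtype=float)
    mu = np.asarray(mu, dtype=float)
    sigma = np.maximum(np.asarray(sigma, dtype=float), sigma_floor)
    trace = []
    loglik = -np.inf
    for _ in range(_MAX_ITER):
        log_dens = _log_component_densities(x, pi, mu, sigma)
        log_total = logsumexp(log_dens, axis=0)
        new_loglik = float(log_total.sum())
        trace.append(new_loglik)
        resp = np.exp(log_dens - log_total[None, :])
        nk = resp.sum(axis=1)
        nk = np.maximum(nk, 1e-300)
        pi = nk / x.size
        mu = resp @ x / nk
        var = (resp * (x[None, :] - mu[:, None]) ** 2).sum(axis=1) / nk
        sigma = np.maximum(np.sqrt(var), sigma_floor)
        if new_loglik - loglik < _REL_TOL * max(1.0, abs(new_loglik)):
            loglik = new_loglik
            break
        loglik = new_loglik
    return (pi, mu, sigma), np.asarray(trace)


def fit_mixture(
    data: MarkerDataset | np.ndarray,
    seed: int | None = 0,
    n_starts: int = 5,
) -> MixtureFit:
    """Fit the two-component Gaussian mixture by EM, best of ``n_starts``.

    The first start splits the sample at its median and uses each half's
    mean/SD as component parameters; the remaining starts draw random
    component means from the data under ``seed``. Components of the
    returned fit are relabelled so ``mu1 < mu2``.

    Raises
    ------
    ValueError
        If fewer than 10 observations or the marker is constant.
    """
    x = data.marker if isinstance(data, MarkerDataset) else np.asarray(data, dtype=float)
    if x.size < 10:
        raise ValueError("mixture fit requires at least 10 observations")
    if np.ptp(x) == 0:
        raise ValueError("marker is constant; mixture fit undefined")
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")

    sd = float(np.std(x))
    sigma_floor = _SIGMA_FLOOR_FRAC * sd
    rng = np.random.default_rng(seed)

    med = float(np.median(x))
    lo, hi = x[x <= med], x[x > med]
    if hi.size == 0:  # heavy ties at the median
        lo, hi = x[x < med], x[x >= med]
    starts = [
        (
            np.array([lo.size, hi.size], dtype=float) / x.size,
            np.array([lo.mean(), hi.mean()]),
            np.array([max(lo.std(), sigma_floor), max(hi.std(), sigma_floor)]),
        )
    ]
    for _ in range(n_starts - 1):
        mu0 = rng.choice(x, size=2, replace=False)
        w = rng.uniform(0.25, 0.75)
        starts.append((np.array([w, 1 - w]), np.sort(mu0), np.array([sd, sd])))

    best = None
    for start in starts:
        (pi, mu, sigma), trace = _em(x, *start, sigma_floor)
        if best is None or trace[-1] > best[1][-1]:
            best = ((pi, mu, sigma), trace)
    (pi, mu, sigma), trace = best
    converged = trace.size < _MAX_ITER or (
        trace.size >= 2 and trace[-1] - trace[-2] < _REL_TOL * max(1.0, abs(trace[-1]))
    )
    order = np.argsort(mu)
    pi, mu, sigma = pi[order], mu[order], sigma[order]
    return MixtureFit(
        pi1=float(pi[0]),
        pi2=float(pi[1]),
        mu1=float(mu[0]),
        mu2=float(mu[1]),
        sigma1=float(sigma[0]),
        sigma2=float(sigma[1]),
        loglik=float(trace[-1]),
        n_iter=int(trace.size),
        converged=bool(converged),
        loglik_trace=trace,
    )


def mixture_cutoff(fit: MixtureFit) -> float:
    """Cutoff where the two weighted component densities coincide.

    Solves ``pi1*phi1(x) = pi2*phi2(x)`` in closed form. With unequal
    variances the log-density difference is quadratic and has two roots;
    the root inside the open interval ``(mu1, mu2)`` is returned. If no
    root falls in that interval (e.g. the fit is effectively unimodal),
    the root closest to the interval is returned with a warning.

    Raises
    ------
    ValueError
        If the fit is flagged non-converged.
    """
    if not fit.converged:
        raise ValueError("mixture fit did not converge; no reliable crossing point")
    pi1, pi2, mu1, mu2, s1, s2 = fit.pi1, fit.pi2, fit.mu1, fit.mu2, fit.sigma1, fit.sigma2
    k = np.log(pi1 * s2) - np.log(pi2 * s1)
    a1, a2 = 1.0 / (2 * s1**2), 1.0 / (2 * s2**2)
    # log pi1 phi1 - log pi2 phi2 = k - a1 (x-mu1)^2 + a2 (x-mu2)^2
    qa = a2 - a1
    qb = 2 * (a1 * mu1 - a2 * mu2)
    qc = a2 * mu2**2 - a1 * mu1**2 + k
    if abs(qa) < 1e-14 * max(a1, a2):
        if abs(qb) < 1e-300:
            raise ValueError("degenerate mixture: identical components have no crossing")
        roots = np.array([-qc / qb])
    else:
        disc = qb**2 - 4 * qa * qc
        if disc < 0:
            raise ValueError("densities never coincide (no real crossing)")
        sq = np.sqrt(disc)
        roots = np.array([(-qb - sq) / (2 * qa), (-qb + sq) / (2 * qa)])
    inside = roots[(roots > mu1) & (roots < mu2)]
    if inside.size:
        return float(inside[0])
    # fall back to the root nearest the (mu1, mu2) interval
    dist = np.where(roots < mu1, mu1 - roots, np.where(roots > mu2, roots - mu2, 0.0))
    warnings.warn(
        "no density crossing between the component means; returning the nearest root "
        "(the fitted mixture may be effectively unimodal)",
        stacklevel=2,
    )
    return float(roots[np.argmin(dist)])
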