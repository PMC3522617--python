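"""Independent reference implementations used only to check the package.

Each oracle recomputes a quantity from first principles (enumeration,
hand product-limit arithmetic, direct likelihood evaluation) without
touching the code paths it validates.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import chi2, hypergeom


def fisher_two_sided(tp: int, fn: int, fp: int, tn: int) -> float:
    """Two-sided Fisher exact p by full hypergeometric enumeration.

    Sums P(k) over all tables with the observed margins whose probability
    does not exceed the observed table's (with the customary 1+1e-7
    relative tolerance for ties).
    """
    row1 = tp + fn
    n = tp + fn + fp + tn
    col1 = tp + fp
    support = np.arange(max(0, col1 - (n - row1)), min(col1, row1) + 1)
    pmf = hypergeom.pmf(support, n, row1, col1)
    p_obs = hypergeom.pmf(tp, n, row1, col1)
    return float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())


def km_by_hand(times, events):
    """Product-limit estimate via an explicit loop over distinct event times.

    Returns (event_times, survival, n_risk, n_event).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    out_t, out_s, out_n, out_d = [], [], [], []
    s = 1.0
    for t in np.unique(times[events == 1]):
        n_risk = int(np.sum(times >= t))
        d = int(np.sum((times == t) & (events == 1)))
        s *= 1 - d / n_risk
        out_t.append(t)
        out_s.append(s)
        out_n.append(n_risk)
        out_d.append(d)
    return (np.array(out_t), np.array(out_s), np.array(out_n), np.array(out_d))


def logrank_by_hand(times, events, groups) -> tuple[float, float]:
    """Two-group log-rank statistic and p from the O-E / hypergeometric
    variance sums, computed with an explicit loop."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups, dtype=bool)
    u = 0.0
    v = 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n = int(at_risk.sum())
        n1 = int((at_risk & groups).sum())
        d = int(((times == t) & (events == 1)).sum())
        d1 = int(((times == t) & (events == 1) & groups).sum())
        u += d1 - d * n1 / n
        if n > 1:
            v += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if v == 0:
        return 0.0, 1.0
    stat = u * u / v
    return stat, float(chi2.sf(stat, df=1))


def efron_log_partial_likelihood(beta: float, times, events, groups) -> float:
    """Efron-tie log partial likelihood of a single binary covariate."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    x = np.asarray(groups, dtype=float)
    eta = np.exp(beta * x)
    ll = 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        dead = (times == t) & (events == 1)
        d = int(dead.sum())
        sum_risk = eta[at_risk].sum()
        sum_dead = eta[dead].sum()
        ll += beta * x[dead].sum()
        for j in range(d):
            ll -= np.log(sum_risk - (j / d) * sum_dead)
    return ll


def cox_beta_by_likelihood(times, events, groups, bound: float = 8.0) -> float:
    """Maximize the Efron partial likelihood over a bounded 1-D search."""
    res = minimize_scalar(
        lambda b: -efron_log_partial_likelihood(b, times, events, groups),
        bounds=(-bound, bound),
        method="bounded",
        options={"xatol": 1e-8},
    )
    return float(res.x)


def rmst_by_hand(times, events, tau) -> float:
    """Area under the hand-computed KM step function up to tau."""
    t, s, _, _ = km_by_hand(times, events)
    area = 0.0
    prev_t, prev_s = 0.0, 1.0
    for ti, si in zip(t, s):
        if ti >= tau:
            break
        area += prev_s * (ti - prev_t)
        prev_t, prev_s = ti, si
    area += prev_s * (tau - prev_t)
    return area


def rmst_greenwood_var_by_hand(times, events, tau) -> float:
    """Greenwood-type RMST variance via explicit loops: for each event time
    t_i <= tau, the squared remaining area times d_i / (n_i (n_i - d_i))."""
    t, s, n_risk, d = km_by_hand(times, events)
    var = 0.0
    for i, ti in enumerate(t):
        if ti > tau:
            break
        # area under S from t_i to tau
        area = 0.0
        prev_t, prev_s = ti, s[i]
        for tj, sj in zip(t[i + 1:], s[i + 1:]):
            if tj >= tau:
                break
            area += prev_s * (tj - prev_t)
            prev_t, prev_s = tj, sj
        area += prev_s * (tau - prev_t)
        denom = n_risk[i] * (n_risk[i] - d[i])
        if denom > 0 and area > 0:
            var += area**2 * d[i] / denom
    return var


def wilson_by_formula(k: int, n: int, z: float = 1.959963984540054) -> tuple[float, float]:
    """Wilson score interval from the closed-form expression."""
    p = k / n
    denom = 1 + z**2 / n
    center = (p + z**2 / (2 * n)) / denom
    half = (z / denom) * np.sqrt(p * (1 - p) / n + z**2 / (4 * n**2))
    return center - half, center + half


def gaussian_crossing_bisect(pi1, mu1, s1, pi2, mu2, s2, lo, hi, tol=1e-12) -> float:
    """Bisection root of pi1*phi1 - pi2*phi2 on (lo, hi)."""
    from scipy.stats import norm

    def f(x):
        return pi1 * norm.pdf(x, mu1, s1) - pi2 * norm.pdf(x, mu2, s2)

    flo = f(lo)
    assert flo * f(hi) < 0, "bisection bracket does not straddle a root"
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if f(mid) * flo <= 0:
            hi = mid
        else:
            lo = mid
            flo = f(lo)
        if hi - lo < tol:
            break
    return 0.5 * (lo + hi)
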