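"""Independent oracles used by the test suite.

Each function recomputes a quantity by brute force or closed form, staying
independent of the package code paths it is used to check.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def brute_force_interval_counts(presence: np.ndarray, i: int) -> dict:
    """Per-taxon scan of a boolean presence matrix (taxa x intervals).

    Returns the 2t/3t/pt/gf and boundary-crosser tallies for interval ``i``
    directly from the definitions, one taxon at a time.
    """
    n_int = presence.shape[1]
    out = dict(two_timer=0, three_timer=0, part_timer=0, gap_filler=0,
               n_bt=0, n_bL=0, sampled=0)
    for row in presence:
        idx = np.flatnonzero(row)
        if idx.size == 0:
            continue
        has = lambda j: bool(0 <= j < n_int and row[j])
        if has(i):
            out["sampled"] += 1
        if has(i - 1) and has(i):
            out["two_timer"] += 1
            if has(i + 1):
                out["three_timer"] += 1
        if has(i - 1) and has(i + 1) and not has(i):
            out["part_timer"] += 1
        if has(i - 1) and has(i + 2) and not has(i + 1):
            out["gap_filler"] += 1
        first, last = idx[0], idx[-1]
        if first < i <= last:
            if last > i:
                out["n_bt"] += 1
            else:
                out["n_bL"] += 1
    return out


def brute_force_rates(counts: dict) -> dict:
    """Rate estimators straight from their formulas, no flooring."""
    q = None
    if counts["n_bt"] > 0:
        q = -np.log(counts["n_bt"] / (counts["n_bt"] + counts["n_bL"]))
    return {"per_capita": q}


def max_gcd_oracle(points: list[tuple[float, float]], radius: float = 6371.0) -> float:
    """All-pairs great-circle maximum via 3D unit vectors and arccos."""
    def unit(lat, lng):
        la, lo = np.radians(lat), np.radians(lng)
        return np.array([np.cos(la) * np.cos(lo), np.cos(la) * np.sin(lo), np.sin(la)])

    best = 0.0
    for a, b in combinations(points, 2):
        cosang = float(np.clip(np.dot(unit(*a), unit(*b)), -1.0, 1.0))
        best = max(best, radius * np.arccos(cosang))
    return best


def exact_mwu_two_sided(x, y) -> tuple[float, float]:
    """Full enumeration of the Mann-Whitney null distribution (no ties).

    Returns (U1, two-sided exact p) with U1 = #{(a, b): a > b} for a in x,
    b in y, and p = min(1, 2 * min(P(U <= u), P(U >= u))).
    """
    x = list(x)
    y = list(y)
    pooled = x + y
    assert len(set(pooled)) == len(pooled), "enumeration oracle assumes no ties"
    u_obs = sum(1 for a in x for b in y if a > b)
    n = len(x)
    us = []
    idxs = list(range(len(pooled)))
    for comb in combinations(idxs, n):
        cs = set(comb)
        xs = [pooled[i] for i in comb]
        ys = [pooled[i] for i in idxs if i not in cs]
        us.append(sum(1 for a in xs for b in ys if a > b))
    us = np.asarray(us)
    p = 2.0 * min((us <= u_obs).mean(), (us >= u_obs).mean())
    return float(u_obs), float(min(1.0, p))


def ols_normal_equations(x, y) -> tuple[float, float, float]:
    """(slope, intercept, r_squared) from the closed-form normal equations."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    sxx = ((x - x.mean()) ** 2).sum()
    sxy = ((x - x.mean()) * (y - y.mean())).sum()
    slope = sxy / sxx
    intercept = y.mean() - slope * x.mean()
    resid = y - intercept - slope * x
    sst = ((y - y.mean()) ** 2).sum()
    return float(slope), float(intercept), float(1.0 - (resid**2).sum() / sst)


def logistic_nll(beta, X, y) -> float:
    """Negative binomial log-likelihood of a logistic model."""
    z = X @ beta
    # log(1 + exp(z)) computed stably
    return float(np.sum(np.logaddexp(0.0, z) - y * z))


def logistic_ml_oracle(X, y, x0=None):
    """Derivative-free maximization of the logistic likelihood (Nelder-Mead)."""
    from scipy.optimize import minimize

    X = np.asarray(X, float)
    y = np.asarray(y, float)
    if x0 is None:
        x0 = np.zeros(X.shape[1])
    res = minimize(
        logistic_nll, x0, args=(X, y), method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000, "maxfev": 20000},
    )
    return res.x, -res.fun
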