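"""Vectorized numerical kernels used by the simulation experiments.

The replicate grids fit tens of thousands of tiny regressions; going through
statsmodels for each would dominate the runtime, so the simple-regression OLS
slope/SE and the two-parameter logistic IRLS are written directly on top of
numpy. The association pipeline proper (assoc.py) uses statsmodels.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


def ols_slope(x: np.ndarray, y: np.ndarray) -> float:
    """Slope of the least-squares regression of ``y`` on ``x`` (with intercept)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xc = x - x.mean()
    sxx = xc @ xc
    if sxx == 0.0:
        raise ValueError("predictor is constant")
    return float((xc @ (y - y.mean())) / sxx)


def ols_slope_se_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Slope, standard error and two-sided t-test p for simple regression."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    xc = x - x.mean()
    yc = y - y.mean()
    sxx = xc @ xc
    if sxx == 0.0:
        raise ValueError("predictor is constant")
    slope = (xc @ yc) / sxx
    rss = yc @ yc - slope * (xc @ yc)
    sigma2 = max(rss, 0.0) / (n - 2)
    se = np.sqrt(sigma2 / sxx)
    if se == 0.0:
        return float(slope), 0.0, 0.0
    t = slope / se
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return float(slope), float(se), float(p)


def signed_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Explained variance of the simple regression, signed by the slope."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    sx = x.std()
    sy = y.std()
    if sx == 0.0 or sy == 0.0:
        return 0.0
    r = float(np.corrcoef(x, y)[0, 1])
    return np.sign(r) * r * r


def logistic_slope(x: np.ndarray, d: np.ndarray, max_iter: int = 50,
                   tol: float = 1e-8) -> tuple[float, float]:
    """(slope, SE) of the logistic regression of binary ``d`` on ``x``.

    Plain Newton/IRLS for the intercept + one-predictor model; returns
    ``(nan, nan)`` when the iteration diverges (e.g. perfect separation).
    """
    x = np.asarray(x, dtype=float)
    d = np.asarray(d, dtype=float)
    n = x.size
    X = np.column_stack([np.ones(n), x])
    beta = np.zeros(2)
    mu_d = d.mean()
    if mu_d <= 0.0 or mu_d >= 1.0:
        raise ValueError("outcome has a single class")
    beta[0] = np.log(mu_d / (1.0 - mu_d))
    for _ in range(max_iter):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30)))
        w = p * (1.0 - p)
        grad = X.T @ (d - p)
        hess = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            return float("nan"), float("nan")
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    if np.max(np.abs(beta)) > 30:
        return float("nan"), float("nan")
    eta = X @ beta
    p = 1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30)))
    w = p * (1.0 - p)
    hess = (X * w[:, None]).T @ X
    try:
        cov = np.linalg.inv(hess)
    except np.linalg.LinAlgError:
        return float(beta[1]), float("nan")
    return float(beta[1]), float(np.sqrt(cov[1, 1]))


def standardize_pop(v: np.ndarray, name: str = "vector") -> np.ndarray:
    """Center/scale with the population (divide-by-n) variance convention."""
    v = np.asarray(v, dtype=float)
    sd = v.std()  # numpy default ddof=0 = population convention
    if sd == 0.0:
        raise ValueError(f"{name} is constant; cannot standardize")
    return (v - v.mean()) / sd


def spawn_rngs(seed: int, n: int) -> list[np.random.Generator]:
    """Derive ``n`` independent generators from one master seed."""
    ss = np.random.SeedSequence(seed)
    return [np.random.default_rng(child) for child in ss.spawn(n)]
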