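"""From-scratch statistical oracles used to cross-check the implementation.

Everything here is deliberately independent of scipy.stats: t densities are
integrated numerically with the trapezoidal rule, the normal CDF uses
math.erf, and quantiles are obtained by bisection.
"""

from __future__ import annotations

import math

import numpy as np


def t_pdf(x: np.ndarray, df: float) -> np.ndarray:
    log_c = (
        math.lgamma((df + 1) / 2.0)
        - math.lgamma(df / 2.0)
        - 0.5 * math.log(df * math.pi)
    )
    return np.exp(log_c - ((df + 1) / 2.0) * np.log1p(np.asarray(x) ** 2 / df))


def t_cdf(x: float, df: float, n_points: int = 400_001) -> float:
    """Central-t CDF by trapezoidal integration of the density over [0, |x|]."""
    if x == 0:
        return 0.5
    grid = np.linspace(0.0, abs(x), n_points)
    area = np.trapezoid(t_pdf(grid, df), grid)
    return 0.5 + area if x > 0 else 0.5 - area


def norm_cdf(z: float) -> float:
    return 0.5 * (1.0 + math.erf(z / math.sqrt(2.0)))


def norm_ppf(p: float, lo: float = -12.0, hi: float = 12.0) -> float:
    """Standard-normal quantile by bisection on the erf-based CDF."""
    for _ in range(200):
        mid = (lo + hi) / 2.0
        if norm_cdf(mid) < p:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def pearson_r(x, y) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xc, yc = x - x.mean(), y - y.mean()
    return float((xc * yc).sum() / math.sqrt((xc**2).sum() * (yc**2).sum()))


def one_tailed_p_from_r(r: float, n: int, direction: str = "positive") -> float:
    r = min(max(r, -1.0), 1.0)
    if abs(r) == 1.0:
        t_obs = math.inf if r > 0 else -math.inf
        upper = 0.0 if r > 0 else 1.0
    else:
        t_obs = r * math.sqrt((n - 2) / (1.0 - r * r))
        upper = 1.0 - t_cdf(t_obs, n - 2)
    return upper if direction == "positive" else 1.0 - upper


def average_ranks(v) -> np.ndarray:
    """Ranks 1..n with ties receiving the average of their positions."""
    v = np.asarray(v, dtype=float)
    order = np.argsort(v, kind="stable")
    ranks = np.empty(len(v))
    i = 0
    while i < len(v):
        j = i
        while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def paired_t(x1, x2) -> tuple[float, int, float]:
    d = np.asarray(x1, dtype=float) - np.asarray(x2, dtype=float)
    n = d.size
    sd = math.sqrt(((d - d.mean()) ** 2).sum() / (n - 1))
    t = d.mean() / (sd / math.sqrt(n))
    p = 2.0 * (1.0 - t_cdf(abs(t), n - 1))
    return t, n - 1, p


def two_sample_t(x1, x2) -> tuple[float, int, float]:
    a, b = np.asarray(x1, dtype=float), np.asarray(x2, dtype=float)
    n1, n2 = a.size, b.size
    df = n1 + n2 - 2
    var_p = (((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()) / df
    t = (a.mean() - b.mean()) / math.sqrt(var_p * (1.0 / n1 + 1.0 / n2))
    p = 2.0 * (1.0 - t_cdf(abs(t), df))
    return t, df, p


def hedges_d(x1, x2) -> float:
    a, b = np.asarray(x1, dtype=float), np.asarray(x2, dtype=float)
    df = a.size + b.size - 2
    var_p = (((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()) / df
    d = (a.mean() - b.mean()) / math.sqrt(var_p)
    return d * (1.0 - 3.0 / (4.0 * df - 1.0))


def gaussian_loglik(x) -> float:
    x = np.asarray(x, dtype=float)
    var = float(((x - x.mean()) ** 2).mean())
    return float(
        -0.5 * x.size * (math.log(2.0 * math.pi) + math.log(var) + 1.0)
    )


def t_to_z(t: float, df: float) -> float:
    return norm_ppf(t_cdf(t, df))
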