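"""Inferential statistics: one-tailed correlations, stepwise regression,
robustness checks, effect sizes, and power-based sample-size calculation.

All correlation p values are one-tailed against a stated direction, matching
an a-priori directional hypothesis; Spearman variants serve as nonparametric
robustness checks for variables that contain outliers (any observation more
than two sample SDs from the mean).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .errors import ValidationError

Direction = str  # "positive" | "negative"


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p_one_tailed: float
    n: int
    direction: Direction
    method: str  # "pearson" | "spearman"


@dataclass(frozen=True)
class StepwiseResult:
    """Forward-selection result with standardized coefficients.

    ``coefficients`` maps every candidate name to (beta, p, selected); for
    unselected candidates beta/p come from refitting the final model with that
    candidate added singly, which is how a single coefficient table can report
    both selected and unselected predictors.
    """

    selected: tuple[str, ...]
    coefficients: dict[str, tuple[float, float, bool]]
    r_squared: Optional[float]
    df: Optional[tuple[int, int]]
    model_p: Optional[float]
    p_enter: float
    p_remove: float


@dataclass(frozen=True)
class EffectSizeResult:
    t: float
    df: int
    p: float
    hedges_d: float
    required_n_per_group: Optional[int] = None


def _as_1d(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValidationError(f"{name} must be one-dimensional")
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"{name} contains non-finite values")
    return arr


def _check_direction(direction: Direction) -> str:
    if direction not in ("positive", "negative"):
        raise ValidationError(f"direction must be 'positive' or 'negative', got {direction!r}")
    return "greater" if direction == "positive" else "less"


def _corr(x, y, direction: Direction, method: str) -> CorrelationResult:
    xv, yv = _as_1d(x, "x"), _as_1d(y, "y")
    if xv.size != yv.size:
        raise ValidationError("x and y must have equal length")
    if xv.size < 3:
        raise ValidationError("correlation requires n >= 3")
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        raise ValidationError("correlation undefined for a constant vector")
    alternative = _check_direction(direction)
    if method == "pearson":
        res = stats.pearsonr(xv, yv, alternative=alternative)
    else:
        res = stats.spearmanr(xv, yv, alternative=alternative)
    return CorrelationResult(
        r=float(res.statistic),
        p_one_tailed=float(res.pvalue),
        n=int(xv.size),
        direction=direction,
        method=method,
    )


def pearson_one_tailed(x, y, direction: Direction = "positive") -> CorrelationResult:
    """Pearson r with a one-tailed p value in the hypothesized direction.

    For ``direction='positive'`` the p value is P(T_{n-2} >= t_obs) with
    t_obs = r * sqrt((n-2)/(1-r^2)).
    """
    return _corr(x, y, direction, "pearson")


def spearman_check(x, y, direction: Direction = "positive") -> CorrelationResult:
    """Spearman rho (average ranks for ties) with a one-tailed p value."""
    return _corr(x, y, direction, "spearman")


def needs_nonparametric(values) -> bool:
    """True iff any value lies more than 2 sample SDs from the sample mean."""
    v = _as_1d(values, "values")
    if v.size < 3:
        raise ValidationError("outlier screening requires n >= 3")
    sd = v.std(ddof=1)
    if sd == 0:
        return False
    return bool(np.any(np.abs(v - v.mean()) > 2 * sd))


def _standardize(v: np.ndarray, name: str) -> np.ndarray:
    sd = v.std(ddof=1)
    if sd == 0:
        raise ValidationError(f"candidate {name!r} is constant")
    return (v - v.mean()) / sd


def stepwise_regress(
    y,
    candidates: dict[str, Sequence[float]],
    p_enter: float = 0.05,
    p_remove: float = 0.10,
) -> StepwiseResult:
    """Forward stepwise selection with backward pruning on standardized data.

    At each step the not-yet-included candidate with the largest |t| is added
    if its coefficient p value (in the model including the already selected
    predictors) is below ``p_enter``; after each addition any included
    predictor whose p value rose above ``p_remove`` is dropped.  Coefficients
    are standardized (all variables z-scored), so with a single selected
    predictor beta equals the Pearson correlation.
    """
    yv = _as_1d(y, "y")
    names = list(candidates)
    if len(names) == 0:
        raise ValidationError("at least one candidate predictor is required")
    X = {}
    for name in names:
        v = _as_1d(candidates[name], name)
        if v.size != yv.size:
            raise ValidationError(f"candidate {name!r} length differs from y")
        X[name] = _standardize(v, name)
    n = yv.size
    if n <= len(names) + 2:
        raise ValidationError(
            f"n = {n} too small for {len(names)} candidates (need n > k + 2)"
        )
    mat = np.column_stack([X[name] for name in names])
    if np.linalg.matrix_rank(mat) < len(names):
        raise ValidationError("candidate design matrix is rank deficient")
    ys = _standardize(yv, "y")

    def fit(sel: list[str]):
        design = sm.add_constant(np.column_stack([X[s] for s in sel]))
        return sm.OLS(ys, design).fit()

    selected: list[str] = []
    seen_states: set[tuple[str, ...]] = set()
    while True:
        state = tuple(selected)
        if state in seen_states:  # guard against add/remove oscillation
            break
        seen_states.add(state)
        changed = False
        # forward step: best |t| among admissible entrants
        best_name, best_t, best_p = None, 0.0, 1.0
        for name in names:
            if name in selected:
                continue
            res = fit(selected + [name])
            tstat = res.tvalues[-1]
            pval = res.pvalues[-1]
            if pval < p_enter and abs(tstat) > abs(best_t):
                best_name, best_t, best_p = name, tstat, pval
        if best_name is not None:
            selected.append(best_name)
            changed = True
        # backward step: drop anything whose p rose above p_remove
        while selected:
            res = fit(selected)
            pvals = dict(zip(selected, res.pvalues[1:]))
            worst = max(selected, key=lambda s: pvals[s])
            if pvals[worst] > p_remove:
                selected.remove(worst)
                changed = True
            else:
                break
        if not changed:
            break

    coefficients: dict[str, tuple[float, float, bool]] = {}
    if selected:
        final = fit(selected)
        for name, beta, pval in zip(selected, final.params[1:], final.pvalues[1:]):
            coefficients[name] = (float(beta), float(pval), True)
        r_squared = float(final.rsquared)
        df = (int(final.df_model), int(final.df_resid))
        model_p = float(final.f_pvalue)
    else:
        r_squared, df, model_p = None, None, None
    for name in names:
        if name in coefficients:
            continue
        res = fit(selected + [name])
        coefficients[name] = (float(res.params[-1]), float(res.pvalues[-1]), False)

    return StepwiseResult(
        selected=tuple(selected),
        coefficients=coefficients,
        r_squared=r_squared,
        df=df,
        model_p=model_p,
        p_enter=p_enter,
        p_remove=p_remove,
    )


def multicollinearity_check(candidates: dict[str, Sequence[float]]):
    """Pairwise Pearson r (two-tailed p) among candidate predictors.

    Returns (r_frame, p_frame) as pandas DataFrames indexed by candidate name.
    """
    import pandas as pd

    names = list(candidates)
    if len(names) < 2:
        raise ValidationError("multicollinearity check requires >= 2 candidates")
    vecs = {}
    for name in names:
        v = _as_1d(candidates[name], name)
        if np.ptp(v) == 0:
            raise ValidationError(f"candidate {name!r} is constant")
        vecs[name] = v
    r = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    p = pd.DataFrame(np.zeros((len(names), len(names))), index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            res = stats.pearsonr(vecs[a], vecs[b])
            r.loc[a, b] = r.loc[b, a] = float(res.statistic)
            p.loc[a, b] = p.loc[b, a] = float(res.pvalue)
    return r, p


def group_compare(x1, x2, compute_required_n: bool = False,
                  alpha: float = 0.05, power: float = 0.80) -> EffectSizeResult:
    """Pooled-variance two-sample t test with Hedge's d.

    hedges_d = cohen_d * J with the small-sample correction
    J = 1 - 3 / (4*df - 1), df = n1 + n2 - 2.
    """
    a, b = _as_1d(x1, "x1"), _as_1d(x2, "x2")
    if a.size < 2 or b.size < 2:
        raise ValidationError("each group needs n >= 2")
    res = stats.ttest_ind(a, b, equal_var=True)
    df = a.size + b.size - 2
    s_pooled = math.sqrt(
        ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / df
    )
    cohen_d = 0.0 if s_pooled == 0 else (a.mean() - b.mean()) / s_pooled
    hedges_d = cohen_d * (1 - 3 / (4 * df - 1))
    required = required_n_per_group(abs(hedges_d), alpha, power) if (
        compute_required_n and hedges_d != 0
    ) else None
    return EffectSizeResult(
        t=float(res.statistic),
        df=df,
        p=float(res.pvalue),
        hedges_d=float(hedges_d),
        required_n_per_group=required,
    )


def required_n_per_group(d: float, alpha: float = 0.05, power: float = 0.80) -> int:
    """Per-group sample size for a two-sample t test (normal approximation).

    n = ceil( 2 * (z_{1-alpha/2} + z_power)^2 / d^2 ).
    """
    if not (d > 0):
        raise ValidationError("effect size d must be positive")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValidationError("alpha and power must lie in (0, 1)")
    z_alpha = stats.norm.isf(alpha / 2)
    z_power = stats.norm.ppf(power)
    return int(math.ceil(2 * (z_alpha + z_power) ** 2 / d**2))
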