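"""Bimodality of per-patient reaction-time distributions.

The two-state account of attentional bias predicts that a patient's pooled
detection times (angry and neutral trials together) form two peaks — one fast
(undermodulatory state) and one slow (overmodulatory state).  The detection
pipeline is:

1. condition-mean normalization: angry and neutral RTs are recentred to the
   pooled grand mean so that an expression main effect cannot masquerade as
   bimodality;
2. Gaussian mixture fits with k = 1 and k = 2 components compared by AIC
   (AIC = 2*n_params - 2*logL; k=1 has 2 parameters, k=2 has 5, so the
   penalty difference is exactly 6).  A difference greater than 2 in favour
   of the two-component model is read as meaningful bimodality;
3. k-means (k = 2) on the normalized RTs gives two peak centres whose
   absolute distance is the per-patient peak-distance statistic;
4. because single-initialization k-means is seed-dependent, the correlation
   between peak distance and the symptom sum is repeated over many fresh
   initializations (default 100) and summarized by the mean and range of r
   and of the one-tailed p.

The k = 2 fit uses expectation-maximization with unconstrained component
variances, multiple random restarts, and one restart always initialized from
the k = 1 solution split at +/- 1 SD; this guarantees the maximized k = 2
log-likelihood is never below the k = 1 log-likelihood.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from sklearn.cluster import KMeans

from .association_stats import CorrelationResult, pearson_one_tailed
from .errors import ValidationError

_LOG_2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class RTSample:
    """Kept RTs of one subject with expression labels, before/after recentring."""

    subject_id: str
    rts: np.ndarray
    expressions: np.ndarray
    normalized_rts: np.ndarray


@dataclass(frozen=True)
class MixtureFit:
    k: int
    weights: tuple[float, ...]
    means: tuple[float, ...]
    variances: tuple[float, ...]
    log_likelihood: float
    n_params: int
    aic: float
    converged: bool
    seed: Optional[int]
    n: int


@dataclass(frozen=True)
class BimodalityResult:
    subject_id: str
    delta_aic: float  # aic(k=1) - aic(k=2)
    preferred: str  # "unimodal" | "bimodal" | "indeterminate"
    centers: tuple[float, float]
    peak_distance: float


@dataclass(frozen=True)
class DistanceCorrelation:
    n_iterations: int
    r_values: tuple[float, ...]
    p_values: tuple[float, ...]
    mean_r: float
    r_range: tuple[float, float]
    mean_p: float
    p_range: tuple[float, float]
    seeds: tuple[int, ...]


def normalize_conditions(rts, expressions, subject_id: str = "") -> RTSample:
    """Recenter each expression condition to the pooled grand mean.

    rt' = rt - mean(condition) + grand mean, so both condition means equal the
    grand mean afterwards and the pooled mean is preserved.
    """
    r = np.asarray(rts, dtype=float)
    e = np.asarray(expressions)
    if r.size == 0:
        raise ValidationError("normalize_conditions: empty RT vector")
    if r.shape != e.shape:
        raise ValidationError("rts and expressions must have equal shape")
    out = r.astype(float).copy()
    grand = r.mean()
    for expr in ("angry", "neutral"):
        mask = e == expr
        if not mask.any():
            raise ValidationError(f"normalize_conditions: no {expr} trials")
        out[mask] += grand - r[mask].mean()
    return RTSample(subject_id=subject_id, rts=r, expressions=e, normalized_rts=out)


def _gaussian_logpdf(x: np.ndarray, mean: float, var: float) -> np.ndarray:
    return -0.5 * (_LOG_2PI + math.log(var) + (x - mean) ** 2 / var)


def _fit_k1(x: np.ndarray) -> tuple[float, float, float]:
    """Closed-form Gaussian MLE: (mean, variance, log-likelihood)."""
    mean = float(x.mean())
    var = float(x.var(ddof=0))
    if var <= 0:
        var = max(var, 1e-12)
    logl = float(_gaussian_logpdf(x, mean, var).sum())
    return mean, var, logl


def _em_2comp_batch(
    x: np.ndarray,
    mu0: np.ndarray,
    var0: np.ndarray,
    w0: np.ndarray,
    tol: float,
    max_iter: int,
    var_floor: float,
):
    """EM for all restarts at once; shapes (R, 2) for parameters.

    Returns (logl (R,), w, mu, var, converged (R,), failed (R,)); a restart
    fails when a component loses all responsibility.
    """
    R = mu0.shape[0]
    mu, var, w = mu0.copy(), np.maximum(var0, var_floor), w0.copy()
    prev = np.full(R, -np.inf)
    conv = np.zeros(R, dtype=bool)
    failed = np.zeros(R, dtype=bool)
    xb = x[None, None, :]
    for _ in range(max_iter):
        log_comp = np.log(w)[:, :, None] - 0.5 * (
            _LOG_2PI + np.log(var)[:, :, None] + (xb - mu[:, :, None]) ** 2 / var[:, :, None]
        )
        m = log_comp.max(axis=1, keepdims=True)
        log_norm = m[:, 0, :] + np.log(np.exp(log_comp - m).sum(axis=1))
        logl = log_norm.sum(axis=1)
        resp = np.exp(log_comp - log_norm[:, None, :])
        nk = resp.sum(axis=2)
        lost = (nk.min(axis=1) < 1e-10) & ~failed & ~conv
        failed |= lost
        active = ~failed & ~conv
        newly = active & (np.abs(logl - prev) < tol)
        conv |= newly
        prev = np.where(~failed | lost, logl, prev)
        active = ~failed & ~conv
        if active.any():
            a = active
            w[a] = nk[a] / x.size
            mu[a] = (resp[a] @ x) / nk[a]
            var_new = (resp[a] * (xb[0] - mu[a][:, :, None]) ** 2).sum(axis=2) / nk[a]
            var[a] = np.maximum(var_new, var_floor)
        else:
            break
    return prev, w, mu, var, conv, failed


def fit_gmm(
    rts,
    k: int,
    seed: Optional[int] = None,
    n_restarts: int = 20,
    tol: float = 1e-6,
    max_iter: int = 500,
    min_n_for_k2: int = 10,
) -> MixtureFit:
    """Fit a one- or two-component Gaussian mixture to a 1-D RT sample.

    k=1 uses the closed-form MLE.  k=2 runs EM with ``n_restarts``
    initializations (the first splits the k=1 solution at +/- 1 SD, the rest
    draw two distinct observations as initial means) and keeps the best
    log-likelihood.  Component variances are unconstrained apart from a
    small scale-aware floor that prevents single-point collapse.
    """
    x = np.asarray(rts, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ValidationError("fit_gmm expects a non-empty 1-D vector")
    if not np.all(np.isfinite(x)):
        raise ValidationError("fit_gmm: non-finite RT values")
    if k == 1:
        mean, var, logl = _fit_k1(x)
        aic = 2 * 2 - 2 * logl
        return MixtureFit(1, (1.0,), (mean,), (var,), logl, 2, aic, True, seed, x.size)
    if k != 2:
        raise ValidationError("only k = 1 or k = 2 mixtures are supported")
    if x.size < min_n_for_k2:
        raise ValidationError(f"k = 2 requires n >= {min_n_for_k2}, got {x.size}")

    mean1, var1, logl1 = _fit_k1(x)
    sd1 = math.sqrt(var1)
    var_floor = max(1e-10, 1e-6 * var1)
    rng = np.random.default_rng(seed)

    mu0 = np.empty((n_restarts, 2))
    mu0[0] = (mean1 - sd1, mean1 + sd1)  # split of the k=1 solution
    for r in range(1, n_restarts):
        mu0[r] = x[0] if np.ptp(x) == 0 else rng.choice(x, size=2, replace=False)
    var0 = np.full((n_restarts, 2), var1)
    w0 = np.full((n_restarts, 2), 0.5)
    logls, ws, mus, vars_, convs, faileds = _em_2comp_batch(
        x, mu0, var0, w0, tol, max_iter, var_floor
    )
    usable = ~faileds if (~faileds).any() else np.ones(n_restarts, dtype=bool)
    best_idx = int(np.argmax(np.where(usable, logls, -np.inf)))
    logl = float(logls[best_idx])
    w, mu, var = ws[best_idx], mus[best_idx], vars_[best_idx]
    any_converged = bool(convs.any())
    if logl < logl1:
        # the k=1 solution, written as two equal components, is itself a
        # valid k=2 parameter point; never report a worse likelihood
        w = np.array([0.5, 0.5])
        mu = np.array([mean1, mean1])
        var = np.array([var1, var1])
        logl = logl1
        any_converged = True
    order = np.argsort(mu)
    w, mu, var = w[order], mu[order], var[order]
    aic = 2 * 5 - 2 * logl
    return MixtureFit(
        k=2,
        weights=tuple(float(v) for v in w),
        means=tuple(float(v) for v in mu),
        variances=tuple(float(v) for v in var),
        log_likelihood=float(logl),
        n_params=5,
        aic=float(aic),
        converged=bool(any_converged),
        seed=seed,
        n=x.size,
    )


def classify_modality(
    fit1: MixtureFit,
    fit2: MixtureFit,
    threshold: float = 2.0,
    centers: tuple[float, float] = (float("nan"), float("nan")),
    peak_distance: float = float("nan"),
    subject_id: str = "",
) -> BimodalityResult:
    """AIC verdict: bimodal iff AIC(k=1) - AIC(k=2) > threshold.

    A smaller-AIC model within the threshold band is not meaningfully better,
    so any delta at or below the threshold is reported as unimodal; a
    non-converged two-component fit yields "indeterminate".
    """
    if fit1.k != 1 or fit2.k != 2:
        raise ValidationError("classify_modality expects a k=1 and a k=2 fit")
    if fit1.n != fit2.n:
        raise ValidationError("fits were computed on different sample sizes")
    delta = fit1.aic - fit2.aic
    if not fit2.converged:
        preferred = "indeterminate"
    elif delta > threshold:
        preferred = "bimodal"
    else:
        preferred = "unimodal"
    return BimodalityResult(
        subject_id=subject_id,
        delta_aic=float(delta),
        preferred=preferred,
        centers=centers,
        peak_distance=peak_distance,
    )


def kmeans_peaks(rts, seed: Optional[int] = None) -> tuple[tuple[float, float], float]:
    """Two-cluster k-means on 1-D RTs: (ascending centers, |distance|).

    A single random initialization is used on purpose so the documented
    seed-to-seed variability exists and can be averaged over.
    """
    x = np.asarray(rts, dtype=float)
    if x.size < 2:
        raise ValidationError("kmeans_peaks requires n >= 2")
    if np.ptp(x) == 0:
        warnings.warn("all RTs identical; degenerate clusters", stacklevel=2)
        return (float(x[0]), float(x[0])), 0.0
    km = KMeans(n_clusters=2, init="random", n_init=1, random_state=seed)
    km.fit(x.reshape(-1, 1))
    centers = np.sort(km.cluster_centers_.ravel())
    return (float(centers[0]), float(centers[1])), float(centers[1] - centers[0])


def distance_symptom_correlation(
    samples: Sequence[RTSample],
    symptom_sums: Sequence[float],
    n_iterations: int = 100,
    seed: Optional[int] = None,
) -> DistanceCorrelation:
    """Iterated correlation between k-means peak distance and symptom sum.

    Each iteration re-runs every patient's k-means with a fresh seed derived
    from the master seed, then Pearson-correlates peak distances with symptom
    sums (one-tailed, positive direction).
    """
    if len(samples) != len(symptom_sums):
        raise ValidationError("one symptom sum per patient is required")
    if len(samples) < 4:
        raise ValidationError("distance correlation requires >= 4 patients")
    ss = np.random.SeedSequence(seed)
    iter_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_iterations)]
    sums = np.asarray(symptom_sums, dtype=float)
    rs, ps = [], []
    for it_seed in iter_seeds:
        sub = np.random.SeedSequence(it_seed)
        patient_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in sub.spawn(len(samples))]
        dists = np.array(
            [
                kmeans_peaks(s.normalized_rts, seed=ks)[1]
                for s, ks in zip(samples, patient_seeds)
            ]
        )
        res = pearson_one_tailed(dists, sums, direction="positive")
        rs.append(res.r)
        ps.append(res.p_one_tailed)
    rs_a, ps_a = np.array(rs), np.array(ps)
    return DistanceCorrelation(
        n_iterations=n_iterations,
        r_values=tuple(rs),
        p_values=tuple(ps),
        mean_r=float(rs_a.mean()),
        r_range=(float(rs_a.min()), float(rs_a.max())),
        mean_p=float(ps_a.mean()),
        p_range=(float(ps_a.min()), float(ps_a.max())),
        seeds=tuple(iter_seeds),
    )


def analyze_subject(
    sample: RTSample,
    seed: Optional[int] = None,
    n_restarts: int = 20,
    tol: float = 1e-6,
    max_iter: int = 500,
    threshold: float = 2.0,
) -> tuple[BimodalityResult, MixtureFit, MixtureFit]:
    """Mixture fits + AIC verdict + k-means peaks for one subject."""
    ss = np.random.SeedSequence(seed)
    em_seed, km_seed = (int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2))
    x = sample.normalized_rts
    fit1 = fit_gmm(x, 1)
    fit2 = fit_gmm(x, 2, seed=em_seed, n_restarts=n_restarts, tol=tol, max_iter=max_iter)
    centers, dist = kmeans_peaks(x, seed=km_seed)
    result = classify_modality(
        fit1, fit2, threshold=threshold, centers=centers, peak_distance=dist,
        subject_id=sample.subject_id,
    )
    return result, fit1, fit2


def plot_density(sample: RTSample, fit1: MixtureFit, fit2: MixtureFit, path) -> None:
    """Histogram of normalized RTs with fitted 1- and 2-component curves."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x = sample.normalized_rts
    grid = np.linspace(x.min() - 3 * x.std(), x.max() + 3 * x.std(), 400)

    def pdf(fit: MixtureFit) -> np.ndarray:
        out = np.zeros_like(grid)
        for w, m, v in zip(fit.weights, fit.means, fit.variances):
            out += w * np.exp(_gaussian_logpdf(grid, m, v))
        return out

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.hist(x, bins=16, density=True, color="0.8", edgecolor="0.5")
    ax.plot(grid, pdf(fit1), color="tab:blue", label=f"unimodal (AIC {fit1.aic:.1f})")
    ax.plot(grid, pdf(fit2), color="tab:red", label=f"bimodal (AIC {fit2.aic:.1f})")
    ax.set_xlabel("normalized reaction time (ms)")
    ax.set_ylabel("density")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
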