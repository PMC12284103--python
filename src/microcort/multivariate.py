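"""Multilinear map prediction, dominance analysis, distance-dependent CV,
PLS correlation with spin significance, and mediation analysis.

Dominance follows the general-dominance (Shapley) scheme: each predictor's
increment to R^2 is averaged within subset size and then across sizes, so
the contributions sum exactly to the full-model unadjusted R^2; shares are
expressed against the full-model adjusted R^2.  PLS is the SVD of the
cross-block covariance of z-scored blocks, with LV1 significance from
spin-permuting the region order of the Y block.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .synthetic_cortex import ParcelGeometry, RegionMap, great_circle_distance
from .spatial_inference import SpinNull, TestResult, _perm_pvalue

__all__ = [
    "DominanceResult",
    "CvResult",
    "PlsResult",
    "MediationResult",
    "multilinear_predict",
    "dominance_analysis",
    "distance_cv",
    "pls_correlation",
    "mediation",
]


def _design(X: list[RegionMap]) -> np.ndarray:
    """Z-scored predictor matrix (regions x p)."""
    cols = [m.zscored().values for m in X]
    return np.column_stack(cols)


def _r2(Xs: np.ndarray, y: np.ndarray) -> float:
    """Unadjusted R^2 of OLS with intercept."""
    A = np.column_stack([np.ones(len(y)), Xs])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    sst = ((y - y.mean()) ** 2).sum()
    return float(1.0 - (resid**2).sum() / sst)


def multilinear_predict(
    X: list[RegionMap],
    y: RegionMap,
    null: SpinNull | None = None,
    alternative: str = "greater",
) -> tuple[TestResult, RegionMap]:
    """OLS prediction of y from z-scored maps; r(fitted, observed) with spin p.

    The spin null re-fits the model on each spun outcome map, so the null
    statistic carries the same optimism as the observed one.
    """
    Z = _design(X)
    n, p = Z.shape
    if p >= n:
        raise ValueError("need more regions than predictors")
    A = np.column_stack([np.ones(n), Z])
    if np.linalg.cond(A) > 1e10:
        raise ValueError("multilinear_predict: collinear predictors")
    H = A @ np.linalg.solve(A.T @ A, A.T)  # hat matrix (refit-under-null)
    yv = y.values
    fitted = H @ yv
    obs = float(np.corrcoef(fitted, yv)[0, 1])

    if null is None:
        return TestResult(obs, float("nan"), alternative), RegionMap(fitted, "fitted")

    Yp = null.apply(yv).T  # (n, n_perm)
    Fp = H @ Yp
    Fz = (Fp - Fp.mean(axis=0)) / Fp.std(axis=0)
    Yz = (Yp - Yp.mean(axis=0)) / Yp.std(axis=0)
    null_r = (Fz * Yz).mean(axis=0)
    p_val = _perm_pvalue(obs, null_r, alternative)
    return (
        TestResult(obs, p_val, alternative, null.n_perm),
        RegionMap(fitted, f"fitted_{y.metric_name}"),
    )


@dataclass
class DominanceResult:
    predictors: list
    contributions: np.ndarray  # average Delta-R^2 per predictor
    shares_pct: np.ndarray  # 100 * contribution / adjusted R^2 of full model
    r2_full: float
    adj_r2_full: float


def dominance_analysis(X: list[RegionMap], y: RegionMap) -> DominanceResult:
    """General dominance over all 2^p predictor subsets."""
    p = len(X)
    if p > 20:
        raise ValueError("dominance_analysis enumerates 2^p subsets; reduce p <= 20")
    Z = _design(X)
    yv = y.values
    n = len(yv)

    r2 = {(): 0.0}
    for size in range(1, p + 1):
        for subset in combinations(range(p), size):
            r2[subset] = _r2(Z[:, subset], yv)

    contributions = np.zeros(p)
    for i in range(p):
        others = [j for j in range(p) if j != i]
        size_means = []
        for size in range(0, p):
            deltas = [
                r2[tuple(sorted(s + (i,)))] - r2[s]
                for s in combinations(others, size)
            ]
            size_means.append(np.mean(deltas))
        contributions[i] = np.mean(size_means)

    r2_full = r2[tuple(range(p))]
    adj = 1.0 - (1.0 - r2_full) * (n - 1) / (n - p - 1)
    shares = 100.0 * contributions / adj
    names = [m.metric_name for m in X]
    return DominanceResult(names, contributions, shares, r2_full, adj)


@dataclass
class CvResult:
    seed_regions: np.ndarray
    train_r: np.ndarray
    test_r: np.ndarray


def distance_cv(
    X: list[RegionMap],
    y: RegionMap,
    geom: ParcelGeometry,
    train_frac: float = 0.75,
    n_reps: int = 100,
    seed: int = 0,
) -> CvResult:
    """Distance-dependent cross-validation.

    Per repetition a seed region is drawn uniformly; the nearest
    ``train_frac`` of regions (by great-circle centroid distance) train the
    model and the farthest remainder test it.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    Z = _design(X)
    yv = y.values
    n, p = Z.shape
    n_train = int(round(train_frac * n))
    if n_train < p + 2:
        raise ValueError("training set smaller than p + 2")
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, n, size=n_reps)
    train_r = np.empty(n_reps)
    test_r = np.empty(n_reps)
    A = np.column_stack([np.ones(n), Z])
    for k, s in enumerate(seeds):
        d = great_circle_distance(geom.parcel_centroid, geom.parcel_centroid[s])
        order = np.argsort(d, kind="stable")
        tr, te = order[:n_train], order[n_train:]
        coef, *_ = np.linalg.lstsq(A[tr], yv[tr], rcond=None)
        train_r[k] = np.corrcoef(A[tr] @ coef, yv[tr])[0, 1]
        test_r[k] = np.corrcoef(A[te] @ coef, yv[te])[0, 1]
    return CvResult(seeds, train_r, test_r)


@dataclass
class PlsResult:
    singular_values: np.ndarray
    x_weights: np.ndarray  # (p, k)
    y_weights: np.ndarray  # (q, k)
    x_scores: np.ndarray  # (n, k)
    y_scores: np.ndarray
    x_loadings: np.ndarray  # correlations of X columns with X scores
    y_loadings: np.ndarray
    covariance_explained: np.ndarray  # s_i^2 / sum s^2
    p_spin_lv1: float | None


def _zscore_cols(M: np.ndarray) -> np.ndarray:
    return (M - M.mean(axis=0)) / M.std(axis=0, ddof=0)


def pls_correlation(
    X: np.ndarray, Y: np.ndarray, null: SpinNull | None = None
) -> PlsResult:
    """PLS correlation: SVD of the cross-block covariance of z-scored blocks.

    LV1 significance spins the region order of Y and compares the null
    share of covariance explained by the first singular value.
    """
    X = _zscore_cols(np.asarray(X, dtype=float))
    Y = _zscore_cols(np.asarray(Y, dtype=float))
    if X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must share the region index")
    n = X.shape[0]
    R = X.T @ Y / (n - 1)
    if not np.any(R):
        raise ValueError("pls_correlation: zero cross-covariance")
    U, s, Vt = np.linalg.svd(R, full_matrices=False)
    V = Vt.T
    x_scores = X @ U
    y_scores = Y @ V
    cov_expl = s**2 / (s**2).sum()

    def _load(block: np.ndarray, scores: np.ndarray) -> np.ndarray:
        out = np.empty((block.shape[1], scores.shape[1]))
        for j in range(scores.shape[1]):
            sc = scores[:, j]
            out[:, j] = block.T @ ((sc - sc.mean()) / sc.std()) / n
        return out

    p_spin = None
    if null is not None:
        obs = cov_expl[0]
        null_stats = np.empty(null.n_perm)
        for k in range(null.n_perm):
            Rp = X.T @ Y[null.permutations[k]] / (n - 1)
            sp = np.linalg.svd(Rp, compute_uv=False)
            null_stats[k] = sp[0] ** 2 / (sp**2).sum()
        p_spin = _perm_pvalue(obs, null_stats, "greater")

    return PlsResult(
        s, U, V, x_scores, y_scores, _load(X, x_scores), _load(Y, y_scores),
        cov_expl, p_spin,
    )


@dataclass
class MediationResult:
    a: float  # x -> m
    b: float  # m -> y given x
    c: float  # total x -> y
    c_prime: float  # direct x -> y given m
    proportion_mediated_pct: float
    flag: str | None = None


def _ols(y: np.ndarray, cols: list[np.ndarray]) -> np.ndarray:
    A = np.column_stack([np.ones(len(y))] + cols)
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    return coef


def mediation(x: RegionMap, m: RegionMap, y: RegionMap) -> MediationResult:
    """Single-mediator OLS mediation with the proportion mediated in percent.

    Paths: m = a x;  y = c x (total);  y = c' x + b m (direct).  Negative
    or >100% proportions are reported as-is and flagged (competitive
    mediation / suppression).
    """
    xv, mv, yv = x.values, m.values, y.values
    uniq = np.unique(xv)
    if not np.array_equal(uniq, uniq.astype(bool).astype(float)) and uniq.size > 2:
        warnings.warn("mediation: x is not a binary indicator", RuntimeWarning,
                      stacklevel=2)
    a = _ols(mv, [xv])[1]
    c = _ols(yv, [xv])[1]
    coef = _ols(yv, [xv, mv])
    c_prime, b = coef[1], coef[2]
    flag = None
    scale = max(np.abs(yv).max(), 1.0)
    if abs(c) < 1e-12 * scale:
        prop = float("nan")
        flag = "undefined: zero total effect"
    else:
        prop = 100.0 * (c - c_prime) / c
        if prop < 0 or prop > 100:
            flag = "competitive mediation or suppression"
    return MediationResult(float(a), float(b), float(c), float(c_prime),
                           float(prop), flag)
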