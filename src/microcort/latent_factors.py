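"""Minimum-residual factor analysis with promax rotation, plus an ICA check.

The metric-by-metric correlation matrix (computed region-wise over group-
average maps) is factored by minres: uniquenesses are optimized so that the
off-diagonal residuals of R - Lambda Lambda' are minimal, with loadings
obtained from the truncated eigendecomposition of R - diag(psi).  Factors
explaining more than the retention threshold (1% of total variance) are
kept, then rotated varimax followed by promax (power 4, oblique).

The ICA cross-check runs FastICA on the z-scored region-by-metric data and
matches components one-to-one to factors by maximal |correlation| of their
region scores, flipping signs to agree.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.optimize import linear_sum_assignment

from .synthetic_cortex import RegionMap

__all__ = [
    "FactorModel",
    "IcaResult",
    "metric_correlations",
    "fit_minres_fa",
    "variance_explained",
    "ica_check",
    "tucker_congruence",
    "varimax",
    "promax",
]


def metric_correlations(maps: list[RegionMap]) -> np.ndarray:
    """Metric-by-metric Pearson correlations across regions."""
    if len(maps) < 2:
        raise ValueError("need >= 2 metric maps")
    n = maps[0].n_parcels
    if n < 3:
        raise ValueError("need >= 3 regions")
    X = np.column_stack([m.values for m in maps])
    if X.shape[0] != n or any(m.n_parcels != n for m in maps):
        raise ValueError("maps must share a common region index")
    sd = X.std(axis=0, ddof=0)
    if (sd == 0).any():
        warnings.warn("metric_correlations: constant metrics give NaN rows",
                      RuntimeWarning, stacklevel=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        Z = (X - X.mean(axis=0)) / sd
        R = Z.T @ Z / n
    np.fill_diagonal(R, np.where(sd == 0, np.nan, 1.0))
    return np.clip(R, -1.0, 1.0)


@dataclass
class FactorModel:
    loadings: np.ndarray  # pattern matrix (metric x factor)
    uniquenesses: np.ndarray
    phi: np.ndarray  # factor correlation matrix
    variance_explained_pct: np.ndarray  # per retained factor
    retain_threshold: float
    metric_names: list = field(default_factory=list)

    @property
    def n_factors(self) -> int:
        return self.loadings.shape[1]

    @property
    def structure(self) -> np.ndarray:
        return self.loadings @ self.phi

    def communalities(self) -> np.ndarray:
        return np.einsum("if,fg,ig->i", self.loadings, self.phi, self.loadings)


def _loadings_for_psi(R: np.ndarray, psi: np.ndarray, k: int) -> np.ndarray:
    vals, vecs = np.linalg.eigh(R - np.diag(psi))
    order = np.argsort(vals)[::-1][:k]
    lam = np.clip(vals[order], 0.0, None)
    return vecs[:, order] * np.sqrt(lam)


def _minres_objective(psi: np.ndarray, R: np.ndarray, k: int) -> float:
    L = _loadings_for_psi(R, psi, k)
    resid = R - L @ L.T
    np.fill_diagonal(resid, 0.0)
    return float((resid**2).sum())


def _extract_minres(R: np.ndarray, k: int, max_iter: int = 1000) -> tuple[np.ndarray, np.ndarray]:
    """Minres extraction: optimize uniquenesses, loadings from eigentruncation."""
    p = R.shape[0]
    # start from squared multiple correlations
    try:
        smc = 1.0 - 1.0 / np.diag(np.linalg.inv(R))
    except np.linalg.LinAlgError:
        smc = np.full(p, 0.5)
    psi0 = np.clip(1.0 - smc, 0.05, 0.95)
    res = minimize(
        _minres_objective,
        psi0,
        args=(R, k),
        method="L-BFGS-B",
        bounds=[(0.005, 1.0)] * p,
        options={"maxiter": max_iter, "ftol": 1e-14, "gtol": 1e-10},
    )
    if not res.success and res.nit >= max_iter:
        raise RuntimeError(
            f"minres did not converge in {max_iter} iterations "
            f"(residual {res.fun:.3e})"
        )
    psi = res.x
    return _loadings_for_psi(R, psi, k), psi


def varimax(loadings: np.ndarray, max_iter: int = 500, tol: float = 1e-10) -> np.ndarray:
    """Kaiser-normalized varimax rotation."""
    L = loadings.copy()
    if L.shape[1] < 2:
        return L
    comm = np.sqrt((L**2).sum(axis=1))
    comm[comm == 0] = 1.0
    L = L / comm[:, None]
    p, k = L.shape
    T = np.eye(k)
    d_old = 0.0
    for _ in range(max_iter):
        Lr = L @ T
        u, s, vt = np.linalg.svd(
            L.T @ (Lr**3 - Lr @ np.diag((Lr**2).sum(axis=0)) / p)
        )
        T = u @ vt
        d = s.sum()
        if d_old != 0 and d / d_old < 1 + tol:
            break
        d_old = d
    return (L @ T) * comm[:, None]


def promax(loadings: np.ndarray, power: int = 4) -> tuple[np.ndarray, np.ndarray]:
    """Promax oblique rotation; returns (pattern, factor correlations)."""
    X = varimax(loadings)
    if X.shape[1] < 2:
        return X, np.eye(X.shape[1])
    Y = X * np.abs(X) ** (power - 1)
    coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
    d = np.diag(np.linalg.inv(coef.T @ coef))
    coef = coef @ np.diag(np.sqrt(d))
    pattern = X @ coef
    coef_inv = np.linalg.inv(coef)
    phi = coef_inv @ coef_inv.T
    return pattern, phi


def fit_minres_fa(
    R: np.ndarray,
    max_factors: int = 8,
    retain_threshold: float = 0.01,
    metric_names: list | None = None,
) -> FactorModel:
    """Minres factor analysis with the >threshold variance retention rule.

    Extraction runs at ``max_factors``; factors whose unrotated variance
    share exceeds ``retain_threshold`` are kept and the model is refit at
    the retained count before promax rotation.
    """
    R = np.asarray(R, dtype=float)
    p = R.shape[0]
    if R.shape != (p, p) or not np.allclose(R, R.T, atol=1e-8):
        raise ValueError("R must be a symmetric correlation matrix")
    if not np.allclose(np.diag(R), 1.0, atol=1e-6):
        raise ValueError("R must have unit diagonal")
    max_factors = min(max_factors, p - 1)

    L, _ = _extract_minres(R, max_factors)
    ve = (L**2).sum(axis=0) / p  # unrotated variance share per factor
    k = int((ve > retain_threshold).sum())
    if k == 0:
        return FactorModel(
            np.zeros((p, 0)), np.ones(p), np.zeros((0, 0)), np.zeros(0),
            retain_threshold, metric_names or [],
        )
    L, psi = _extract_minres(R, k)
    pattern, phi = promax(L)
    model = FactorModel(pattern, psi, phi, np.zeros(k), retain_threshold,
                        metric_names or [])
    model.variance_explained_pct = variance_explained(model)
    return model


def variance_explained(model: FactorModel, convention: str = "structure") -> np.ndarray:
    """Per-factor percent variance: sum of squared loadings over n metrics.

    The default uses structure loadings (pattern times factor
    correlations); with oblique factors the per-factor shares overlap and
    need not sum to the total communality.
    """
    if model.n_factors == 0:
        return np.zeros(0)
    p = model.loadings.shape[0]
    if convention == "structure":
        L = model.structure
    elif convention == "pattern":
        L = model.loadings
    else:
        raise ValueError(f"unknown convention {convention!r}")
    return 100.0 * (L**2).sum(axis=0) / p


def tucker_congruence(a: np.ndarray, b: np.ndarray) -> float:
    """Tucker's congruence coefficient between two loading vectors."""
    return float(np.dot(a, b) / np.sqrt(np.dot(a, a) * np.dot(b, b)))


def factor_scores(data: np.ndarray, R: np.ndarray, model: FactorModel) -> np.ndarray:
    """Thurstone regression scores from z-scored data (region x metric)."""
    weights = np.linalg.solve(R, model.structure)
    return data @ weights


@dataclass
class IcaResult:
    components: np.ndarray  # (metric, k) metric weights, matched order
    sources: np.ndarray  # (region, k) matched+sign-flipped IC scores
    match_correlations: np.ndarray  # |corr| of each IC with its factor
    variance_explained_pct: np.ndarray
    seed_used: int


def ica_check(
    data: np.ndarray,
    k: int,
    model: FactorModel,
    R: np.ndarray,
    seed: int = 0,
    max_restarts: int = 5,
) -> IcaResult:
    """FastICA on z-scored region-by-metric data, matched to the factors.

    Components are reordered by solving the assignment that maximizes the
    total |correlation| between IC scores and factor scores, and signs are
    flipped to make the matched correlations positive.  Per-component
    variance explained is the mean squared correlation of the metrics with
    the IC score, in percent; with non-orthogonal components these may sum
    to more than 100.
    """
    from sklearn.decomposition import FastICA
    from sklearn.exceptions import ConvergenceWarning

    data = np.asarray(data, dtype=float)
    if k > data.shape[1]:
        raise ValueError("more components than metrics")
    Z = (data - data.mean(axis=0)) / data.std(axis=0, ddof=0)
    f_scores = factor_scores(Z, R, model)

    sources = None
    seed_used = seed
    for attempt in range(max_restarts):
        ica = FastICA(n_components=k, fun="logcosh", random_state=seed + attempt,
                      max_iter=2000, tol=1e-6)
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", ConvergenceWarning)
            s = ica.fit_transform(Z)
            converged = not any(
                issubclass(w.category, ConvergenceWarning) for w in caught
            )
        if converged:
            sources = s
            seed_used = seed + attempt
            break
    if sources is None:
        raise RuntimeError(f"FastICA failed to converge in {max_restarts} restarts")

    # match ICs to factors by maximal |correlation| of region scores
    kf = min(k, model.n_factors)
    corr = np.zeros((k, max(kf, 1)))
    for i in range(k):
        for j in range(kf):
            corr[i, j] = np.corrcoef(sources[:, i], f_scores[:, j])[0, 1]
    rows, cols = linear_sum_assignment(-np.abs(corr[:, :kf]))
    order = np.argsort(cols)
    matched = rows[order]
    extra = [i for i in range(k) if i not in set(matched)]
    full_order = list(matched) + extra

    out_sources = sources[:, full_order].copy()
    match_corr = np.zeros(k)
    for j in range(kf):
        c = corr[full_order[j], j]
        if c < 0:
            out_sources[:, j] = -out_sources[:, j]
        match_corr[j] = abs(c)

    comps = np.zeros((Z.shape[1], k))
    ve = np.zeros(k)
    for j in range(k):
        s = out_sources[:, j]
        r = np.array([np.corrcoef(Z[:, m], s)[0, 1] for m in range(Z.shape[1])])
        comps[:, j] = r
        ve[j] = 100.0 * float(np.mean(r**2))
    return IcaResult(comps, out_sources, match_corr, ve, seed_used)
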