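"""Structural covariance networks and Laplacian-embedding gradients.

An SCN is the region-by-region Pearson correlation of subject profiles for
one metric, or of stacked z-scored (subject, metric) observations for the
combined network.  Gradients are eigenvectors of the degree-normalized
(random-walk) graph Laplacian of the nonnegative affinity matrix; the
constant steady-state eigenvector is dropped and the next k eigenvectors,
ordered by ascending eigenvalue, are returned as SG1..SGk.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import eigh
from scipy.sparse.csgraph import connected_components

from .synthetic_cortex import SubjectPanel

__all__ = ["CovNetwork", "GradientEmbedding", "scn", "combined_scn", "laplacian_gradients"]


@dataclass
class CovNetwork:
    matrix: np.ndarray  # (regions, regions) correlations
    source: str

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != self.matrix.shape[1]:
            raise ValueError("covariance network must be square")


@dataclass
class GradientEmbedding:
    eigenvalues: np.ndarray  # ascending, excluding the dropped one
    gradients: np.ndarray  # (regions, k)
    steady_state: np.ndarray  # the dropped constant eigenvector
    steady_state_eigenvalue: float


def _corr_rows(obs: np.ndarray) -> np.ndarray:
    """Pearson correlation between columns of an (observations, regions) array."""
    sd = obs.std(axis=0, ddof=0)
    zero = sd == 0
    if zero.any():
        warnings.warn(
            f"scn: {int(zero.sum())} zero-variance regions produce NaN rows",
            RuntimeWarning, stacklevel=3,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (obs - obs.mean(axis=0)) / sd
        c = (z.T @ z) / obs.shape[0]
    np.fill_diagonal(c, np.where(zero, np.nan, 1.0))
    return np.clip(c, -1.0, 1.0)


def scn(panel: SubjectPanel, metric: str | int | None = None) -> CovNetwork:
    """Region-by-region correlation of subject values for one metric.

    Sessions are averaged within subject before correlating.
    """
    if panel.n_subjects < 3:
        raise ValueError("scn needs >= 3 subjects")
    if metric is None:
        metric = 0
    if isinstance(metric, str):
        name, metric = metric, panel.metric_index(metric)
    else:
        name = panel.metrics[metric]
    obs = panel.values[..., metric].mean(axis=1)  # (subject, region)
    return CovNetwork(_corr_rows(obs), f"metric:{name}")


def combined_scn(panel: SubjectPanel) -> CovNetwork:
    """SCN over all metrics: z-score each metric, stack (subject, metric) rows."""
    x = panel.values.mean(axis=1)  # (subject, region, metric)
    blocks = []
    kept = []
    for m in range(x.shape[2]):
        v = x[..., m]
        sd = v.std()
        if sd == 0:
            warnings.warn(f"combined_scn: metric {panel.metrics[m]!r} is constant, excluded",
                          RuntimeWarning, stacklevel=2)
            continue
        blocks.append((v - v.mean()) / sd)
        kept.append(panel.metrics[m])
    if not blocks:
        raise ValueError("combined_scn: no non-constant metrics")
    obs = np.vstack(blocks)  # (subject*metric, region)
    return CovNetwork(_corr_rows(obs), f"combined:{','.join(kept)}")


def _clip_affinity(matrix: np.ndarray) -> np.ndarray:
    w = np.array(matrix, dtype=float)
    w[w < 0] = 0.0
    np.fill_diagonal(w, 0.0)
    return w


def laplacian_gradients(
    net: CovNetwork, k: int = 2, affinity: str = "clip"
) -> GradientEmbedding:
    """Degree-normalized Laplacian embedding of the affinity graph.

    Solves (D - W) v = lambda D v; the zero-eigenvalue constant vector is
    discarded and the next k eigenvectors are returned.  Eigenvector signs
    are fixed so each gradient's largest-|value| entry is positive.
    """
    if affinity != "clip":
        raise ValueError(f"unknown affinity rule {affinity!r}")
    W = _clip_affinity(net.matrix)
    if np.isnan(W).any():
        raise ValueError("affinity matrix contains NaN (zero-variance regions?)")
    n_comp, labels = connected_components(W > 0, directed=False)
    if n_comp > 1:
        sizes = np.bincount(labels)
        raise ValueError(
            f"affinity graph is disconnected: {n_comp} components with sizes {sizes.tolist()}"
        )
    deg = W.sum(axis=1)
    L = np.diag(deg) - W
    vals, vecs = eigh(L, np.diag(deg))
    order = np.argsort(vals)
    vals, vecs = vals[order], vecs[:, order]

    steady = vecs[:, 0]
    if np.abs(steady - steady.mean()).max() > 1e-8 * max(1.0, np.abs(steady).max()):
        warnings.warn("laplacian_gradients: first eigenvector is not constant",
                      RuntimeWarning, stacklevel=2)
    grads = vecs[:, 1 : 1 + k].copy()
    for j in range(grads.shape[1]):
        anchor = np.argmax(np.abs(grads[:, j]))
        if grads[anchor, j] < 0:
            grads[:, j] = -grads[:, j]
    return GradientEmbedding(vals[1 : 1 + k], grads, steady, float(vals[0]))
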