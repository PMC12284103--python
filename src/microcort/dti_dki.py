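"""Ordinary-least-squares diffusion tensor and kurtosis fitting.

The tensor fit uses only the b <= 1000 s/mm^2 shell; the kurtosis fit uses
all shells.  Both are plain unconstrained OLS on the log signal.  The
kurtosis design absorbs MD^2 into the rank-4 coefficients (columns carry
(b^2/6) times the direction quartics), so noise-free model signals are
recovered exactly in a single joint solve; W is rescaled afterwards by the
fitted MD^2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .synthetic_signals import (
    AcquisitionScheme,
    W_MULTIPLICITY,
    W_UNIQUE_INDICES,
    w_unique_to_full,
)

__all__ = ["TensorFit", "DKIFit", "fit_dti", "dti_scalars", "fit_dki", "dki_scalars"]


@dataclass
class TensorFit:
    S0: float
    D: np.ndarray  # (3, 3) symmetric, mm^2/s
    eigenvalues: np.ndarray  # descending
    eigenvectors: np.ndarray  # columns matching eigenvalues

    @property
    def e1(self) -> np.ndarray:
        return self.eigenvectors[:, 0]

    @property
    def md(self) -> float:
        return float(np.trace(self.D) / 3.0)


@dataclass
class DKIFit:
    S0: float
    D: np.ndarray
    W: np.ndarray  # full (3, 3, 3, 3) symmetric, dimensionless
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray

    @property
    def md(self) -> float:
        return float(np.trace(self.D) / 3.0)


def _d_design(b: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Columns for (Dxx, Dyy, Dzz, Dxy, Dxz, Dyz) in the log-signal model."""
    nx, ny, nz = n[:, 0], n[:, 1], n[:, 2]
    return -b[:, None] * np.column_stack(
        [nx**2, ny**2, nz**2, 2 * nx * ny, 2 * nx * nz, 2 * ny * nz]
    )


def _w_design(b: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Columns for the 15 unique kurtosis-tensor coefficients (times MD^2)."""
    cols = []
    for mult, idx in zip(W_MULTIPLICITY, W_UNIQUE_INDICES):
        cols.append(mult * n[:, idx[0]] * n[:, idx[1]] * n[:, idx[2]] * n[:, idx[3]])
    return (b**2 / 6.0)[:, None] * np.column_stack(cols)


def _d_from_coeffs(c: np.ndarray) -> np.ndarray:
    return np.array(
        [[c[0], c[3], c[4]], [c[3], c[1], c[5]], [c[4], c[5], c[2]]]
    )


def _usable(signal: np.ndarray, mask: np.ndarray, minimum: int, what: str) -> np.ndarray:
    bad = mask & ~(signal > 0)
    if bad.any():
        warnings.warn(
            f"{what}: excluded {int(bad.sum())} non-positive signal volumes",
            RuntimeWarning,
            stacklevel=3,
        )
    usable = mask & (signal > 0)
    if usable.sum() < minimum:
        raise ValueError(f"{what}: only {int(usable.sum())} usable volumes (< {minimum})")
    return usable


def _sorted_eig(D: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    vals, vecs = np.linalg.eigh(D)
    order = np.argsort(vals)[::-1]
    return vals[order], vecs[:, order]


def fit_dti(
    signal: np.ndarray, scheme: AcquisitionScheme, max_b: float = 1000.0
) -> TensorFit:
    """OLS tensor fit on volumes with b <= max_b (plus shell tolerance)."""
    signal = np.asarray(signal, dtype=float)
    mask = scheme.b <= max_b + 50.0
    usable = _usable(signal, mask, 7, "fit_dti")
    b, n, s = scheme.b[usable], scheme.directions[usable], signal[usable]
    X = np.column_stack([np.ones_like(b), _d_design(b, n)])
    coef, _, rank, _ = np.linalg.lstsq(X, np.log(s), rcond=None)
    if rank < X.shape[1]:
        raise ValueError("fit_dti: rank-deficient design (need >= 6 non-collinear directions)")
    D = _d_from_coeffs(coef[1:7])
    vals, vecs = _sorted_eig(D)
    return TensorFit(float(np.exp(coef[0])), D, vals, vecs)


def dti_scalars(fit: TensorFit, prefix: str = "") -> dict[str, float]:
    """FA/AD/RD/MD from sorted eigenvalues."""
    lam = fit.eigenvalues
    out = {
        f"{prefix}AD": float(lam[0]),
        f"{prefix}RD": float((lam[1] + lam[2]) / 2.0),
        f"{prefix}MD": float(lam.mean()),
    }
    norm = np.linalg.norm(lam)
    if norm == 0.0:
        warnings.warn("dti_scalars: zero tensor, FA undefined", RuntimeWarning, stacklevel=2)
        out[f"{prefix}FA"] = float("nan")
    else:
        out[f"{prefix}FA"] = float(
            np.sqrt(1.5) * np.linalg.norm(lam - lam.mean()) / norm
        )
    return out


def fit_dki(signal: np.ndarray, scheme: AcquisitionScheme) -> DKIFit:
    """Joint OLS kurtosis fit over all shells.

    Requires >= 2 nonzero shells and >= 22 usable volumes.  The W columns
    carry no MD factor; the fitted coefficients equal MD^2 * W and are
    rescaled by the fitted tensor's MD^2.
    """
    signal = np.asarray(signal, dtype=float)
    if len(scheme.shells()) < 2:
        raise ValueError("fit_dki requires at least 2 nonzero shells")
    usable = _usable(signal, np.ones_like(scheme.b, dtype=bool), 22, "fit_dki")
    b, n, s = scheme.b[usable], scheme.directions[usable], signal[usable]
    X = np.column_stack([np.ones_like(b), _d_design(b, n), _w_design(b, n)])
    coef, _, rank, _ = np.linalg.lstsq(X, np.log(s), rcond=None)
    if rank < X.shape[1]:
        raise ValueError("fit_dki: rank-deficient design")
    D = _d_from_coeffs(coef[1:7])
    md = np.trace(D) / 3.0
    if md <= 0:
        raise ValueError("fit_dki: non-positive mean diffusivity, cannot scale W")
    W = w_unique_to_full(coef[7:22] / md**2)
    vals, vecs = _sorted_eig(D)
    return DKIFit(float(np.exp(coef[0])), D, W, vals, vecs)


# Fully symmetric isotropic rank-4 tensor: W(n) = 1 for all unit n.
_EYE = np.eye(3)
_I_ISO = (
    np.einsum("ij,kl->ijkl", _EYE, _EYE)
    + np.einsum("ik,jl->ijkl", _EYE, _EYE)
    + np.einsum("il,jk->ijkl", _EYE, _EYE)
) / 3.0


def _apparent_kurtosis(fit: DKIFit, dirs: np.ndarray) -> np.ndarray:
    """K(n) = (MD^2 / D(n)^2) W(n) along the given unit directions."""
    d_app = np.einsum("vi,ij,vj->v", dirs, fit.D, dirs)
    w_app = np.einsum("vi,vj,vk,vl,ijkl->v", dirs, dirs, dirs, dirs, fit.W)
    return (fit.md**2 / d_app**2) * w_app


def dki_scalars(fit: DKIFit, n_dirs_quadrature: int = 300) -> dict[str, float]:
    """DKI diffusivity/anisotropy scalars plus MK, AK, RK, MKT, KFA.

    MK is the spherical average of the apparent kurtosis over a Fibonacci
    quadrature; RK averages over a dense circle perpendicular to the
    principal axis; MKT and KFA come directly from the kurtosis tensor.
    """
    out = dti_scalars(
        TensorFit(fit.S0, fit.D, fit.eigenvalues, fit.eigenvectors), prefix="DKI-"
    )

    # Spherical product quadrature laid out in the tensor eigenframe.  The
    # node set is invariant under per-axis sign flips (Gauss-Legendre in
    # cos(theta), even uniform azimuth), so MK is exactly invariant under
    # joint rotation of (D, W) despite the eigenvector sign ambiguity.
    n_t = max(4, int(round(np.sqrt(n_dirs_quadrature / 2.0))))
    n_phi = 2 * n_t
    t, wt = np.polynomial.legendre.leggauss(n_t)
    phi = 2.0 * np.pi * np.arange(n_phi) / n_phi
    st = np.sqrt(1.0 - t**2)
    nodes = np.stack(
        [
            np.outer(st, np.cos(phi)).ravel(),
            np.outer(st, np.sin(phi)).ravel(),
            np.repeat(t, n_phi),
        ],
        axis=1,
    )
    weights = np.repeat(wt, n_phi) / (2.0 * n_phi)
    dirs = nodes @ fit.eigenvectors.T
    out["MK"] = float(weights @ _apparent_kurtosis(fit, dirs))

    e1 = fit.eigenvectors[:, 0]
    out["AK"] = float(_apparent_kurtosis(fit, e1[None, :])[0])

    u, v = fit.eigenvectors[:, 1], fit.eigenvectors[:, 2]
    theta = np.linspace(0.0, np.pi, 256, endpoint=False)
    circle = np.outer(np.cos(theta), u) + np.outer(np.sin(theta), v)
    out["RK"] = float(np.mean(_apparent_kurtosis(fit, circle)))

    mkt = float(np.einsum("iijj->", fit.W)) / 5.0
    out["MKT"] = mkt
    w_norm = np.linalg.norm(fit.W)
    if w_norm == 0.0:
        warnings.warn("dki_scalars: zero kurtosis tensor, KFA undefined",
                      RuntimeWarning, stacklevel=2)
        out["KFA"] = float("nan")
    else:
        out["KFA"] = float(np.linalg.norm(fit.W - mkt * _I_ISO) / w_norm)
    return out
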