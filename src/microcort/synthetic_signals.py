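"""Multi-shell acquisition schemes and forward dMRI signal models.

Units follow the FSL/dMRI conventions: b in s/mm^2, diffusivities in
mm^2/s, pulse timings in ms, q in 1/mm.  The effective diffusion time is
tau = Delta - delta/3 and b = (2 pi q)^2 tau (tau in seconds).

Forward models: a log-quadratic kurtosis representation (``signal_dki``),
a three-compartment Watson-dispersed stick/zeppelin/ball tissue model
(``signal_watson``), plain Gaussian decay, and Rician noise with its
method-of-moments debiasing.

The Watson orientation average uses a Funk-Hecke decomposition: both the
stick and zeppelin kernels depend on the fibre orientation x only through
(n.x)^2, so E_Watson[f(n.x)] = sum_l a_l(c) p_l(kappa) P_l(n.mu), where
a_l are Legendre coefficients of the kernel and p_l are Legendre moments
of the Watson density.  Both are fixed-order Gauss-Legendre quadratures,
which stay accurate up to the kappa -> infinity stick limit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import eval_legendre

__all__ = [
    "AcquisitionScheme",
    "VoxelTruth",
    "D_PARALLEL",
    "D_ISO",
    "gen_scheme",
    "signal_dki",
    "signal_watson",
    "signal_gaussian",
    "add_rician_noise",
    "rician_debias",
    "watson_legendre_moments",
    "dki_truth_from_mixture",
    "random_dki_truth",
    "w_full_to_unique",
    "w_unique_to_full",
]

# Fixed tissue diffusivities (mm^2/s): gray-matter-adjusted parallel
# diffusivity and free-water isotropic diffusivity.
D_PARALLEL = 1.1e-3
D_ISO = 3.0e-3

_GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))

# Unique elements of a fully symmetric rank-4 tensor and their
# multiplicities under index permutation (sums to 81).
W_UNIQUE_INDICES: list[tuple[int, int, int, int]] = [
    (0, 0, 0, 0), (1, 1, 1, 1), (2, 2, 2, 2),
    (0, 0, 0, 1), (0, 0, 0, 2), (0, 1, 1, 1),
    (1, 1, 1, 2), (0, 2, 2, 2), (1, 2, 2, 2),
    (0, 0, 1, 1), (0, 0, 2, 2), (1, 1, 2, 2),
    (0, 0, 1, 2), (0, 1, 1, 2), (0, 1, 2, 2),
]
W_MULTIPLICITY = np.array([1, 1, 1, 4, 4, 4, 4, 4, 4, 6, 6, 6, 12, 12, 12], dtype=float)


@dataclass(frozen=True)
class AcquisitionScheme:
    """Multi-shell acquisition: b-values, unit directions, pulse timings."""

    b: np.ndarray  # (N,) s/mm^2
    directions: np.ndarray  # (N, 3); zero rows for b = 0 volumes
    delta_ms: float = 10.6
    Delta_ms: float = 43.1

    def __post_init__(self) -> None:
        object.__setattr__(self, "b", np.asarray(self.b, dtype=float))
        object.__setattr__(self, "directions", np.asarray(self.directions, dtype=float))
        if self.b.shape[0] != self.directions.shape[0]:
            raise ValueError("b and directions length mismatch")
        if (self.b < 0).any():
            raise ValueError("b-values must be nonnegative")
        if not (self.b == 0).any():
            raise ValueError("scheme must contain at least one b = 0 volume")
        dwi = self.b > 0
        norms = np.linalg.norm(self.directions[dwi], axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("directions must be unit norm for b > 0 volumes")

    @property
    def n_volumes(self) -> int:
        return self.b.shape[0]

    @property
    def tau_ms(self) -> float:
        """Effective diffusion time Delta - delta/3 (ms)."""
        return self.Delta_ms - self.delta_ms / 3.0

    @property
    def tau_s(self) -> float:
        return self.tau_ms * 1e-3

    @property
    def q(self) -> np.ndarray:
        """q-magnitude per volume (1/mm), from b = (2 pi q)^2 tau."""
        return np.sqrt(self.b / self.tau_s) / (2.0 * np.pi)

    @property
    def b0_mask(self) -> np.ndarray:
        return self.b == 0

    def shells(self, tol: float = 50.0) -> list[tuple[float, int]]:
        """Nonzero shells as (mean b, n directions), grouped at ``tol``."""
        out: list[tuple[float, int]] = []
        bs = np.sort(self.b[self.b > 0])
        if bs.size == 0:
            return out
        group = [bs[0]]
        for v in bs[1:]:
            if v - group[-1] <= tol:
                group.append(v)
            else:
                out.append((float(np.mean(group)), len(group)))
                group = [v]
        out.append((float(np.mean(group)), len(group)))
        return out

    def subset(self, mask: np.ndarray) -> "AcquisitionScheme":
        return AcquisitionScheme(self.b[mask], self.directions[mask],
                                 self.delta_ms, self.Delta_ms)


@dataclass
class VoxelTruth:
    """Ground-truth voxel parameters for one forward model.

    ``model`` is one of {'dki', 'watson', 'gaussian'}.  For 'dki' and
    'gaussian', ``D`` is the 3x3 diffusion tensor (mm^2/s) and ``W`` the
    full (3,3,3,3) dimensionless kurtosis tensor.  For 'watson' the
    compartment parameters (f_ic, f_iso, kappa, mu) apply.
    """

    model: str
    S0: float = 1.0
    D: np.ndarray | None = None
    W: np.ndarray | None = None
    f_ic: float = 0.5
    f_iso: float = 0.0
    kappa: float = 3.0
    mu: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    d_par: float = D_PARALLEL
    d_iso: float = D_ISO

    def __post_init__(self) -> None:
        if self.model not in ("dki", "watson", "gaussian"):
            raise ValueError(f"unknown model {self.model!r}")
        if self.model in ("dki", "gaussian"):
            if self.D is None:
                raise ValueError(f"{self.model} truth requires D")
            self.D = np.asarray(self.D, dtype=float)
            eigs = np.linalg.eigvalsh(self.D)
            if eigs.min() < -1e-15:
                raise ValueError("D must be positive semidefinite")
        if self.model == "dki":
            if self.W is None:
                self.W = np.zeros((3, 3, 3, 3))
            self.W = np.asarray(self.W, dtype=float)
        if self.model == "watson":
            if not (0.0 <= self.f_ic <= 1.0 and 0.0 <= self.f_iso <= 1.0):
                raise ValueError("volume fractions must lie in [0, 1]")
            if self.kappa <= 0:
                raise ValueError("Watson concentration kappa must be positive")
            self.mu = np.asarray(self.mu, dtype=float)
            self.mu = self.mu / np.linalg.norm(self.mu)


def fibonacci_directions(n: int, azimuth_offset: float = 0.0) -> np.ndarray:
    """n quasi-uniform unit vectors on the full sphere."""
    k = np.arange(n)
    z = 1.0 - (2.0 * k + 1.0) / n
    phi = k * _GOLDEN_ANGLE + azimuth_offset
    s = np.sqrt(np.clip(1.0 - z**2, 0.0, None))
    pts = np.column_stack([s * np.cos(phi), s * np.sin(phi), z])
    return pts / np.linalg.norm(pts, axis=1, keepdims=True)


_PROTOCOLS = {
    "hcp_like": {"shells": [(1000.0, 90), (2000.0, 90), (3000.0, 90)], "n_b0": 18},
    "mgh": {"shells": [(1000.0, 64), (3000.0, 64), (5000.0, 128), (10000.0, 256)],
            "n_b0": 10},
}


def gen_scheme(
    protocol: str = "hcp_like",
    shells: list[tuple[float, int]] | None = None,
    n_b0: int | None = None,
    delta_ms: float = 10.6,
    Delta_ms: float = 43.1,
) -> AcquisitionScheme:
    """Build a named or custom multi-shell acquisition scheme.

    Directions are quasi-uniform spherical Fibonacci sets, offset per shell
    so shells do not share directions.  ``protocol='custom'`` requires an
    explicit ``shells`` list of (b, n_directions).
    """
    if protocol == "custom":
        if not shells:
            raise ValueError("custom protocol requires a nonempty shell list")
        spec = {"shells": shells, "n_b0": 10 if n_b0 is None else n_b0}
    elif protocol in _PROTOCOLS:
        spec = dict(_PROTOCOLS[protocol])
        if n_b0 is not None:
            spec["n_b0"] = n_b0
    else:
        raise ValueError(f"unknown protocol {protocol!r}")
    if not spec["shells"]:
        raise ValueError("shell list is empty")

    bs = [np.zeros(spec["n_b0"])]
    dirs = [np.zeros((spec["n_b0"], 3))]
    for i, (bval, ndir) in enumerate(spec["shells"]):
        if bval <= 0 or ndir < 1:
            raise ValueError("shells need positive b and >= 1 direction")
        bs.append(np.full(ndir, float(bval)))
        dirs.append(fibonacci_directions(ndir, azimuth_offset=0.37 * (i + 1)))
    return AcquisitionScheme(np.concatenate(bs), np.vstack(dirs), delta_ms, Delta_ms)


# ---------------------------------------------------------------------------
# Kurtosis representation forward model
# ---------------------------------------------------------------------------

def w_full_to_unique(W: np.ndarray) -> np.ndarray:
    """Extract the 15 unique elements of a symmetric rank-4 tensor."""
    return np.array([W[idx] for idx in W_UNIQUE_INDICES])


def w_unique_to_full(w15: np.ndarray) -> np.ndarray:
    """Expand 15 unique elements into the full symmetric (3,3,3,3) tensor."""
    from itertools import permutations

    W = np.zeros((3, 3, 3, 3))
    for val, idx in zip(w15, W_UNIQUE_INDICES):
        for perm in set(permutations(idx)):
            W[perm] = val
    return W


def signal_dki(truth: VoxelTruth, scheme: AcquisitionScheme) -> np.ndarray:
    """Noise-free kurtosis-representation signal.

    ln S(b, n) = ln S0 - b n'Dn + (b^2/6) MD^2 sum_ijkl n_i n_j n_k n_l W_ijkl.
    """
    if truth.model != "dki":
        raise ValueError("signal_dki requires a 'dki' truth")
    n = scheme.directions
    b = scheme.b
    d_app = np.einsum("vi,ij,vj->v", n, truth.D, n)
    w_app = np.einsum("vi,vj,vk,vl,ijkl->v", n, n, n, n, truth.W)
    md = np.trace(truth.D) / 3.0
    log_s = np.log(truth.S0) - b * d_app + (b**2 / 6.0) * md**2 * w_app
    s = np.exp(log_s)
    if (s > truth.S0 * (1.0 + 1e-9)).any():
        warnings.warn(
            "kurtosis term exceeds S0 at some volumes (non-physical W at this b)",
            RuntimeWarning,
            stacklevel=2,
        )
    return s


def signal_gaussian(truth: VoxelTruth, scheme: AcquisitionScheme) -> np.ndarray:
    """Pure tensor decay S0 * exp(-b n'Dn)."""
    if truth.model not in ("gaussian", "dki"):
        raise ValueError("signal_gaussian requires a 'gaussian' (or 'dki') truth")
    d_app = np.einsum("vi,ij,vj->v", scheme.directions, truth.D, scheme.directions)
    return truth.S0 * np.exp(-scheme.b * d_app)


# ---------------------------------------------------------------------------
# Watson-dispersed stick/zeppelin/ball forward model
# ---------------------------------------------------------------------------

def watson_legendre_moments(kappa: float, lmax: int, n_quad: int = 128) -> np.ndarray:
    """Legendre moments p_l = E_Watson[P_l(mu . x)] for even l <= lmax.

    Computed as 1-D quadratures of the axial profile exp(kappa t^2) on
    t in [0, 1].  For large kappa the mass concentrates at t = 1, so the
    integral is transformed with s = kappa (1 - t), where the integrand
    exp(-2s + s^2/kappa) decays on an O(1) scale.
    """
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    ls = np.arange(0, lmax + 1, 2)
    if kappa <= 30.0:
        t, w = np.polynomial.legendre.leggauss(n_quad)
        t = 0.5 * (t + 1.0)  # map to [0, 1]
        w = 0.5 * w
        dens = np.exp(kappa * (t**2 - 1.0))  # stable: exponent <= 0
    else:
        s_max = min(kappa, 40.0)
        s, w = np.polynomial.legendre.leggauss(n_quad)
        s = 0.5 * s_max * (s + 1.0)
        w = 0.5 * s_max * w
        t = 1.0 - s / kappa
        dens = np.exp(-2.0 * s + s**2 / kappa)
    norm = np.sum(w * dens)
    return np.array([np.sum(w * dens * eval_legendre(l, t)) for l in ls]) / norm


def _kernel_legendre_coeffs(c: float, lmax: int, n_quad: int = 128) -> np.ndarray:
    """Legendre coefficients a_l of exp(c w^2) on [-1, 1], even l <= lmax."""
    ls = np.arange(0, lmax + 1, 2)
    t, w = np.polynomial.legendre.leggauss(n_quad)
    t = 0.5 * (t + 1.0)
    w = 0.5 * w
    f = np.exp(c * t**2)
    # even symmetry: (2l+1)/2 * int_{-1}^{1} = (2l+1) * int_0^1
    return np.array([(2 * l + 1) * np.sum(w * f * eval_legendre(l, t)) for l in ls])


def watson_mean_kernel(
    cos_angles: np.ndarray, c: float, kappa: float, lmax: int = 40, n_quad: int = 128
) -> np.ndarray:
    """E_Watson[exp(c (n.x)^2)] for gradient/fibre-axis cosines ``cos_angles``."""
    a = _kernel_legendre_coeffs(c, lmax, n_quad)
    p = watson_legendre_moments(kappa, lmax, n_quad)
    ls = np.arange(0, lmax + 1, 2)
    P = np.stack([eval_legendre(l, cos_angles) for l in ls], axis=-1)
    return P @ (a * p)


def signal_watson(
    truth: VoxelTruth,
    scheme: AcquisitionScheme,
    lmax: int = 40,
    n_quad: int = 128,
) -> np.ndarray:
    """Three-compartment Watson stick/zeppelin/ball signal.

    S/S0 = (1 - f_iso) [f_ic A_ic + (1 - f_ic) A_ec] + f_iso exp(-b d_iso)
    with tortuosity d_perp = d_par (1 - f_ic) in the extracellular zeppelin.
    """
    if truth.model != "watson":
        raise ValueError("signal_watson requires a 'watson' truth")
    b = scheme.b
    cosang = scheme.directions @ truth.mu
    d_par, d_iso = truth.d_par, truth.d_iso
    d_perp = d_par * (1.0 - truth.f_ic)

    a_ic = np.ones_like(b)
    a_ec = np.ones_like(b)
    for bval in np.unique(b[b > 0]):
        m = b == bval
        a_ic[m] = watson_mean_kernel(cosang[m], -bval * d_par, truth.kappa, lmax, n_quad)
        a_ec[m] = np.exp(-bval * d_perp) * watson_mean_kernel(
            cosang[m], -bval * (d_par - d_perp), truth.kappa, lmax, n_quad
        )
    tissue = truth.f_ic * a_ic + (1.0 - truth.f_ic) * a_ec
    s = (1.0 - truth.f_iso) * tissue + truth.f_iso * np.exp(-b * d_iso)
    return truth.S0 * s


# ---------------------------------------------------------------------------
# Rician noise
# ---------------------------------------------------------------------------

def add_rician_noise(signal: np.ndarray, sigma: float, seed: int) -> np.ndarray:
    """Magnitude signal sqrt((S + e1)^2 + e2^2) with e ~ N(0, sigma^2)."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    signal = np.asarray(signal, dtype=float)
    if sigma == 0:
        return signal.copy()
    rng = np.random.default_rng(seed)
    e1 = rng.normal(0.0, sigma, signal.shape)
    e2 = rng.normal(0.0, sigma, signal.shape)
    return np.sqrt((signal + e1) ** 2 + e2**2)


def rician_debias(signal: np.ndarray, sigma: float) -> np.ndarray:
    """Method-of-moments correction sqrt(max(S^2 - 2 sigma^2, 0))."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    signal = np.asarray(signal, dtype=float)
    return np.sqrt(np.clip(signal**2 - 2.0 * sigma**2, 0.0, None))


# ---------------------------------------------------------------------------
# Ground-truth constructors
# ---------------------------------------------------------------------------

def _sym4(outer: np.ndarray) -> np.ndarray:
    """Fully symmetrize a rank-4 tensor built from rank-2 outer products."""
    from itertools import permutations

    out = np.zeros_like(outer)
    for perm in permutations(range(4)):
        out += np.transpose(outer, perm)
    return out / 24.0


def dki_truth_from_mixture(
    tensors: list[np.ndarray], fractions: np.ndarray, S0: float = 1.0
) -> VoxelTruth:
    """Self-consistent (D, W) from a Gaussian multi-tensor mixture.

    For a mixture, the apparent kurtosis along n is
    3 Var_f(n'D_i n) / Dbar(n)^2, which corresponds to
    W = (3 / MD^2) * sym(E_f[D (x) D] - Dbar (x) Dbar).
    """
    fractions = np.asarray(fractions, dtype=float)
    if not np.isclose(fractions.sum(), 1.0):
        raise ValueError("mixture fractions must sum to 1")
    tensors = [np.asarray(t, dtype=float) for t in tensors]
    dbar = sum(f * t for f, t in zip(fractions, tensors))
    second = sum(
        f * np.einsum("ij,kl->ijkl", t, t) for f, t in zip(fractions, tensors)
    )
    cov = second - np.einsum("ij,kl->ijkl", dbar, dbar)
    md = np.trace(dbar) / 3.0
    W = 3.0 * _sym4(cov) / md**2
    return VoxelTruth("dki", S0=S0, D=dbar, W=W)


def random_dki_truth(rng: np.random.Generator, n_components: int = 3) -> VoxelTruth:
    """Random physically-consistent kurtosis truth from a tensor mixture."""
    tensors = []
    for _ in range(n_components):
        q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        lam = rng.uniform(0.2e-3, 2.5e-3, 3)
        tensors.append(q @ np.diag(lam) @ q.T)
    f = rng.dirichlet(np.ones(n_components))
    return dki_truth_from_mixture(tensors, f, S0=float(rng.uniform(0.5, 2.0)))
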