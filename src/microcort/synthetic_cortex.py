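"""Synthetic two-hemisphere spherical parcellations and parcellated test data.

The cortical sheet is modelled as two mirror-image hemispheres on the unit
sphere (left: x < 0, right: x > 0).  Parcels are Voronoi cells of a
quasi-uniform Fibonacci lattice of centroids; great-circle distance stands
in for geodesic mesh distance.  On top of the geometry, generators produce
spatially autocorrelated region maps, subject/session panels with known
variance components, contiguous class atlases, linear target maps, and
two-block data with a planted shared latent gradient.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ParcelGeometry",
    "RegionMap",
    "SubjectPanel",
    "ClassAtlas",
    "LatentBlockData",
    "great_circle_distance",
    "gen_parcel_sphere",
    "SmoothMapSampler",
    "gen_smooth_map",
    "gen_subject_panel",
    "gen_class_atlas",
    "gen_linear_target",
    "gen_two_block",
]

_GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


def great_circle_distance(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Great-circle distance (radians) between unit vectors.

    Broadcasts over leading axes; the last axis must be length 3.
    """
    dots = np.clip(np.sum(np.asarray(a) * np.asarray(b), axis=-1), -1.0, 1.0)
    return np.arccos(dots)


def _pairwise_gc(points_a: np.ndarray, points_b: np.ndarray) -> np.ndarray:
    dots = np.clip(points_a @ points_b.T, -1.0, 1.0)
    return np.arccos(dots)


@dataclass(frozen=True)
class ParcelGeometry:
    """Two-hemisphere spherical parcellation.

    Attributes
    ----------
    vertex_coords : (n_vertices, 3) unit vectors.
    vertex_parcel : (n_vertices,) parcel id per vertex.
    parcel_centroid : (n_parcels, 3) unit vectors.
    hemisphere : (n_parcels,) array of 'L'/'R'.
    homologue : (n_parcels,) int array mapping each parcel to its
        contralateral partner, or None.
    """

    vertex_coords: np.ndarray
    vertex_parcel: np.ndarray
    parcel_centroid: np.ndarray
    hemisphere: np.ndarray
    homologue: np.ndarray | None = None

    @property
    def n_parcels(self) -> int:
        return self.parcel_centroid.shape[0]

    @property
    def n_vertices(self) -> int:
        return self.vertex_coords.shape[0]

    def centroid_distances(self) -> np.ndarray:
        """(n_parcels, n_parcels) great-circle distance matrix."""
        return _pairwise_gc(self.parcel_centroid, self.parcel_centroid)

    def validate(self) -> None:
        if not np.allclose(np.linalg.norm(self.vertex_coords, axis=1), 1.0, atol=1e-9):
            raise ValueError("vertex coordinates must have unit norm")
        if not np.allclose(np.linalg.norm(self.parcel_centroid, axis=1), 1.0, atol=1e-9):
            raise ValueError("parcel centroids must have unit norm")
        counts = np.bincount(self.vertex_parcel, minlength=self.n_parcels)
        if (counts == 0).any():
            raise ValueError(f"empty parcels: {np.flatnonzero(counts == 0).tolist()}")
        if self.homologue is not None:
            h = self.homologue
            if not np.array_equal(h[h], np.arange(self.n_parcels)):
                raise ValueError("homologue map is not an involution")
            if (self.hemisphere[h] == self.hemisphere).any():
                raise ValueError("homologues must lie in opposite hemispheres")


@dataclass
class RegionMap:
    """One scalar value per parcel for a named metric; NaN marks missing."""

    values: np.ndarray
    metric_name: str = "value"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    @property
    def n_parcels(self) -> int:
        return self.values.shape[0]

    def zscored(self) -> "RegionMap":
        v = self.values
        return RegionMap((v - np.nanmean(v)) / np.nanstd(v, ddof=0), self.metric_name)


@dataclass
class SubjectPanel:
    """Rectangular subject x session x region x metric value array."""

    values: np.ndarray  # (n_subjects, n_sessions, n_regions, n_metrics)
    subjects: list = field(default_factory=list)
    metrics: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 4:
            raise ValueError("panel values must be 4-D (subject, session, region, metric)")
        if not self.subjects:
            self.subjects = [f"sub-{i:04d}" for i in range(self.values.shape[0])]
        if not self.metrics:
            self.metrics = [f"metric{i}" for i in range(self.values.shape[3])]

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_sessions(self) -> int:
        return self.values.shape[1]

    @property
    def n_regions(self) -> int:
        return self.values.shape[2]

    def metric_index(self, name: str) -> int:
        return self.metrics.index(name)


@dataclass
class ClassAtlas:
    """Parcel-to-class assignment with named classes."""

    labels: np.ndarray  # (n_parcels,) int class index
    class_names: list

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.class_names) < 2:
            raise ValueError("an atlas needs at least 2 classes")
        if self.labels.min() < 0 or self.labels.max() >= len(self.class_names):
            raise ValueError("labels out of range of class names")

    @property
    def n_classes(self) -> int:
        return len(self.class_names)


@dataclass
class LatentBlockData:
    """Two region x feature blocks sharing a planted latent gradient."""

    X: np.ndarray
    Y: np.ndarray
    latent: np.ndarray
    x_weights: np.ndarray
    y_weights: np.ndarray


def _sphere_lattice(n: int, azimuth_offset: float) -> np.ndarray:
    """Quasi-uniform Fibonacci lattice on the full unit sphere.

    Each hemisphere is modelled as its own complete sphere (as in inflated
    per-hemisphere cortical spheres), so spherical rotations are
    near-bijective on a hemisphere's parcels.
    """
    k = np.arange(n)
    t = 1.0 - (2.0 * k + 1.0) / n  # axial coordinate in (-1, 1)
    phi = k * _GOLDEN_ANGLE + azimuth_offset
    sin_theta = np.sqrt(np.clip(1.0 - t**2, 0.0, None))
    pts = np.column_stack([t, sin_theta * np.cos(phi), sin_theta * np.sin(phi)])
    return pts / np.linalg.norm(pts, axis=1, keepdims=True)


def _mirror_x(points: np.ndarray) -> np.ndarray:
    out = points.copy()
    out[..., 0] = -out[..., 0]
    return out


def gen_parcel_sphere(
    n_parcels_per_hemi: int, vertices_per_parcel: int, seed: int
) -> ParcelGeometry:
    """Two mirrored hemispheres of Voronoi parcels, one unit sphere each.

    Centroids and vertices are Fibonacci lattices (azimuth offset drawn
    from ``seed``); right-hemisphere geometry is the mirror image of the
    left across the x = 0 midline plane, which defines the homologue map.
    """
    if n_parcels_per_hemi < 4:
        raise ValueError("n_parcels_per_hemi must be >= 4")
    if vertices_per_parcel < 1:
        raise ValueError("vertices_per_parcel must be >= 1")
    rng = np.random.default_rng(seed)
    offset = rng.uniform(0.0, 2.0 * np.pi)

    cent_l = _sphere_lattice(n_parcels_per_hemi, offset)
    cent_r = _mirror_x(cent_l)
    centroids = np.vstack([cent_l, cent_r])

    n_vert_hemi = n_parcels_per_hemi * vertices_per_parcel
    vert_l = _sphere_lattice(n_vert_hemi, offset + 0.5 * _GOLDEN_ANGLE)
    vert_r = _mirror_x(vert_l)
    vertices = np.vstack([vert_l, vert_r])

    parcel_l = np.argmin(_pairwise_gc(vert_l, cent_l), axis=1)
    vertex_parcel = np.concatenate([parcel_l, parcel_l + n_parcels_per_hemi])

    # Guarantee every parcel owns at least one vertex.
    counts = np.bincount(parcel_l, minlength=n_parcels_per_hemi)
    for p in np.flatnonzero(counts == 0):
        v = int(np.argmin(great_circle_distance(vert_l, cent_l[p])))
        parcel_l[v] = p
        vertex_parcel[v] = p
        vertex_parcel[v + n_vert_hemi] = p + n_parcels_per_hemi

    hemisphere = np.array(["L"] * n_parcels_per_hemi + ["R"] * n_parcels_per_hemi)
    homologue = np.concatenate(
        [
            np.arange(n_parcels_per_hemi) + n_parcels_per_hemi,
            np.arange(n_parcels_per_hemi),
        ]
    )
    geom = ParcelGeometry(vertices, vertex_parcel, centroids, hemisphere, homologue)
    geom.validate()
    return geom


class SmoothMapSampler:
    """Draws zero-mean unit-variance fields with covariance exp(-d / l).

    The hemispheres are separate spheres, so "distance" is hemisphere-aware:
    within a hemisphere it is the great-circle distance; across hemispheres
    it is the homotopic distance (between mirror-normalized positions) and
    the kernel is attenuated by ``hemi_coupling``.  Homologous parcels thus
    correlate at ``hemi_coupling`` and the covariance class is exactly
    preserved by bilateral spin rotations (the covariance is a Kronecker
    product [[K, cK], [cK, K]], positive definite for |c| < 1).

    The Cholesky factor is computed once, so Monte-Carlo studies can draw
    many maps cheaply.
    """

    def __init__(
        self,
        geom: ParcelGeometry,
        length_scale: float,
        hemi_coupling: float = 0.5,
        jitter: float = 1e-10,
    ):
        if length_scale <= 0:
            raise ValueError("length_scale must be positive")
        if not 0 <= hemi_coupling < 1:
            raise ValueError("hemi_coupling must lie in [0, 1)")
        self.geom = geom
        self.length_scale = float(length_scale)
        self.hemi_coupling = float(hemi_coupling)
        pos = geom.parcel_centroid.copy()
        right = geom.hemisphere == "R"
        pos[right] = _mirror_x(pos[right])  # mirror-normalized (homotopic) frame
        cov = np.exp(-_pairwise_gc(pos, pos) / length_scale)
        cross = geom.hemisphere[:, None] != geom.hemisphere[None, :]
        cov[cross] *= hemi_coupling
        cov[np.diag_indices_from(cov)] += jitter
        try:
            self._chol = np.linalg.cholesky(cov)
        except np.linalg.LinAlgError as exc:
            raise FloatingPointError(
                "smooth-field covariance not positive definite after jitter"
            ) from exc

    def sample(self, rng: np.random.Generator, metric_name: str = "smooth") -> RegionMap:
        z = rng.standard_normal(self.geom.n_parcels)
        return RegionMap(self._chol @ z, metric_name)


def gen_smooth_map(
    geom: ParcelGeometry, length_scale: float, seed: int, metric_name: str = "smooth"
) -> RegionMap:
    """One spatially autocorrelated Gaussian map over parcel centroids."""
    sampler = SmoothMapSampler(geom, length_scale)
    return sampler.sample(np.random.default_rng(seed), metric_name)


def gen_subject_panel(
    group_map: RegionMap,
    sigma_between: float,
    sigma_within: float,
    n_subjects: int,
    n_sessions: int,
    seed: int,
) -> SubjectPanel:
    """Panel with value(s, k, r) = group(r) + u(s, r) + e(s, k, r).

    ``u ~ N(0, sigma_between^2)`` is a stable subject offset per region and
    ``e ~ N(0, sigma_within^2)`` is independent session noise.
    """
    if sigma_between < 0 or sigma_within < 0:
        raise ValueError("variance-component sigmas must be >= 0")
    if n_subjects < 2:
        raise ValueError("n_subjects must be >= 2")
    if n_sessions < 1:
        raise ValueError("n_sessions must be >= 1")
    rng = np.random.default_rng(seed)
    n_regions = group_map.n_parcels
    u = sigma_between * rng.standard_normal((n_subjects, 1, n_regions))
    e = sigma_within * rng.standard_normal((n_subjects, n_sessions, n_regions))
    values = group_map.values[None, None, :] + u + e
    return SubjectPanel(values[..., None], metrics=[group_map.metric_name])


def gen_class_atlas(geom: ParcelGeometry, n_classes: int, seed: int) -> ClassAtlas:
    """Contiguous class atlas: Voronoi patches of random per-hemisphere seeds.

    Class seed directions are drawn on the left hemisphere and mirrored to
    the right, so each class forms one contiguous patch per hemisphere.
    """
    if n_classes < 2:
        raise ValueError("need at least 2 classes")
    if n_classes > geom.n_parcels:
        raise ValueError("more classes than parcels")
    names = [f"class{i}" for i in range(n_classes)]
    if n_classes == geom.n_parcels:
        return ClassAtlas(np.arange(geom.n_parcels), names)

    rng = np.random.default_rng(seed)
    raw = rng.standard_normal((n_classes, 3))
    seeds_l = raw / np.linalg.norm(raw, axis=1, keepdims=True)
    seeds_r = _mirror_x(seeds_l)

    labels = np.empty(geom.n_parcels, dtype=int)
    left = geom.hemisphere == "L"
    labels[left] = np.argmin(_pairwise_gc(geom.parcel_centroid[left], seeds_l), axis=1)
    labels[~left] = np.argmin(_pairwise_gc(geom.parcel_centroid[~left], seeds_r), axis=1)

    # Random Voronoi patches can be empty; give each empty class its
    # nearest parcel so the atlas always partitions into n_classes.
    for c in range(n_classes):
        if not (labels == c).any():
            d = great_circle_distance(geom.parcel_centroid[left], seeds_l[c])
            labels[np.flatnonzero(left)[np.argmin(d)]] = c
    return ClassAtlas(labels, names)


def gen_linear_target(
    X: list[RegionMap],
    beta: np.ndarray,
    noise_scale: float,
    length_scale: float,
    geom: ParcelGeometry,
    seed: int,
    metric_name: str = "target",
) -> RegionMap:
    """y = sum_i beta_i * zscore(X_i) + noise_scale * smooth field."""
    beta = np.asarray(beta, dtype=float)
    if len(beta) != len(X):
        raise ValueError("beta length must match number of predictor maps")
    n = geom.n_parcels
    for m in X:
        if m.n_parcels != n:
            raise ValueError("predictor maps must share the geometry's parcel index")
    y = np.zeros(n)
    for b, m in zip(beta, X):
        y += b * m.zscored().values
    if noise_scale != 0.0:
        y = y + noise_scale * gen_smooth_map(geom, length_scale, seed).values
    return RegionMap(y, metric_name)


def gen_two_block(
    geom: ParcelGeometry,
    p: int,
    q: int,
    strength: float,
    noise: float,
    seed: int,
    length_scale: float = 0.5,
) -> LatentBlockData:
    """Two blocks sharing one planted latent gradient.

    X = strength * g w_x^T + noise * E1 and Y = strength * g w_y^T +
    noise * E2, where g is a smooth map and the planted weights are
    unit-norm.
    """
    if p < 2 or q < 2:
        raise ValueError("p and q must be >= 2")
    if strength < 0:
        raise ValueError("strength must be >= 0")
    rng = np.random.default_rng(seed)
    g = SmoothMapSampler(geom, length_scale).sample(rng).values
    wx = rng.standard_normal(p)
    wx /= np.linalg.norm(wx)
    wy = rng.standard_normal(q)
    wy /= np.linalg.norm(wy)
    X = strength * np.outer(g, wx) + noise * rng.standard_normal((geom.n_parcels, p))
    Y = strength * np.outer(g, wy) + noise * rng.standard_normal((geom.n_parcels, q))
    return LatentBlockData(X, Y, g, wx, wy)
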