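"""Vertex-sample filtering, nearest-neighbour fill, and parcel averaging.

Pipeline order: MAD outlier exclusion (propagator-derived metrics only),
then a 1-SD window computed cortex-wide per metric, then nearest-neighbour
fill over the geometry, then parcel means.  Each step's exclusion count is
recorded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .synthetic_cortex import ParcelGeometry, RegionMap

__all__ = [
    "VertexSamples",
    "filter_mad",
    "filter_sd",
    "fill_nearest",
    "parcellate",
    "assemble_map",
]

# Metrics subject to the extra MAD outlier pass (propagator scalars).
MAD_METRICS = ("QIV", "MSD", "RTOP", "RTAP", "RTPP")


@dataclass
class VertexSamples:
    """Per-vertex metric values with a validity mask; invalid entries are NaN."""

    values: np.ndarray
    valid: np.ndarray
    geom: ParcelGeometry
    metric_name: str = "value"
    log: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).copy()
        self.valid = np.asarray(self.valid, dtype=bool).copy()
        if self.values.shape != self.valid.shape:
            raise ValueError("values and validity mask must have equal length")
        if self.values.shape[0] != self.geom.n_vertices:
            raise ValueError("sample length must equal geometry vertex count")
        self.values[~self.valid] = np.nan

    @classmethod
    def from_values(
        cls, values: np.ndarray, geom: ParcelGeometry, metric_name: str = "value"
    ) -> "VertexSamples":
        values = np.asarray(values, dtype=float)
        return cls(values, np.isfinite(values), geom, metric_name)

    def copy_with(self, valid: np.ndarray, step: str, removed: int) -> "VertexSamples":
        out = VertexSamples(self.values, valid, self.geom, self.metric_name,
                            dict(self.log))
        out.log[step] = removed
        return out


def filter_mad(v: VertexSamples, threshold: float = 4.5) -> VertexSamples:
    """Invalidate vertices with |x - median| / MAD > threshold.

    MAD is the raw median absolute deviation (no normal-consistency
    factor).  If MAD = 0 no exclusions are made.
    """
    if v.valid.sum() < 3:
        raise ValueError("filter_mad needs at least 3 valid vertices")
    x = v.values[v.valid]
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0.0:
        return v.copy_with(v.valid, "mad", 0)
    keep = v.valid & ~(np.abs(v.values - med) / mad > threshold)
    keep &= v.valid
    removed = int(v.valid.sum() - keep.sum())
    if keep.sum() == 0:
        raise ValueError("filter_mad removed every vertex")
    return v.copy_with(keep, "mad", removed)


def filter_sd(v: VertexSamples, threshold: float = 1.0) -> VertexSamples:
    """Invalidate vertices with |x - mean| > threshold * sample SD.

    The window is computed over all currently valid vertices for the
    metric (cortex-wide).  Zero variance excludes nothing.
    """
    if v.valid.sum() < 3:
        raise ValueError("filter_sd needs at least 3 valid vertices")
    x = v.values[v.valid]
    mean = x.mean()
    sd = x.std(ddof=1)
    if sd == 0.0:
        return v.copy_with(v.valid, "sd", 0)
    keep = v.valid & ~(np.abs(v.values - mean) > threshold * sd)
    removed = int(v.valid.sum() - keep.sum())
    if keep.sum() == 0:
        raise ValueError("filter_sd removed every vertex")
    return v.copy_with(keep, "sd", removed)


def fill_nearest(v: VertexSamples, geom: ParcelGeometry | None = None) -> VertexSamples:
    """Give every invalid vertex the value of its nearest valid vertex.

    Distance is great-circle on the geometry sphere; ties are broken by
    the lowest donor vertex id.
    """
    geom = geom or v.geom
    if not v.valid.any():
        raise ValueError("fill_nearest: no valid vertices to copy from")
    if v.valid.all():
        return v.copy_with(v.valid, "fill", 0)
    invalid_idx = np.flatnonzero(~v.valid)
    valid_idx = np.flatnonzero(v.valid)
    dots = np.clip(
        geom.vertex_coords[invalid_idx] @ geom.vertex_coords[valid_idx].T, -1.0, 1.0
    )
    dist = np.arccos(dots)
    # argmin returns the first (lowest-id) donor on exact ties because
    # valid_idx is ascending.
    donor = valid_idx[np.argmin(dist, axis=1)]
    out = VertexSamples(v.values, v.valid, geom, v.metric_name, dict(v.log))
    out.values[invalid_idx] = v.values[donor]
    out.valid[:] = True
    out.log["fill"] = int(invalid_idx.size)
    return out


def parcellate(
    v: VertexSamples, geom: ParcelGeometry | None = None, allow_partial: bool = False
) -> RegionMap:
    """Parcel value = mean of its vertices' values."""
    geom = geom or v.geom
    if not allow_partial and not v.valid.all():
        raise ValueError("parcellate requires filled samples (or allow_partial=True)")
    values = np.full(geom.n_parcels, np.nan)
    for p in range(geom.n_parcels):
        members = v.values[(geom.vertex_parcel == p) & v.valid]
        if members.size:
            values[p] = members.mean()
        else:
            import warnings

            warnings.warn(f"parcellate: parcel {p} has no valid vertices",
                          RuntimeWarning, stacklevel=2)
    return RegionMap(values, v.metric_name)


def assemble_map(
    v: VertexSamples,
    mad_threshold: float = 4.5,
    sd_threshold: float = 1.0,
    apply_mad: bool | None = None,
) -> tuple[RegionMap, dict]:
    """Full filtering pipeline: MAD (propagator metrics) -> SD -> fill -> parcels.

    Returns the assembled map plus the per-step exclusion log.
    """
    if apply_mad is None:
        apply_mad = v.metric_name.upper() in MAD_METRICS
    if apply_mad:
        v = filter_mad(v, mad_threshold)
    v = filter_sd(v, sd_threshold)
    v = fill_nearest(v)
    return parcellate(v), dict(v.log)
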