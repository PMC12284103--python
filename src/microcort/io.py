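"""TSV / bval-bvec readers and writers.

TSV is the canonical interchange format (mandatory headers, UTF-8, '.'
decimal).  Acquisition schemes round-trip through FSL-style .bval/.bvec
text plus a timing sidecar TSV.  All writes are atomic (temp file in the
target directory, then rename).
"""

from __future__ import annotations

import os
import tempfile
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic_cortex import ClassAtlas, ParcelGeometry, RegionMap, SubjectPanel
from .synthetic_signals import AcquisitionScheme
from .map_assembly import VertexSamples

__all__ = [
    "atomic_write_text",
    "write_region_map",
    "read_region_map",
    "write_geometry",
    "read_geometry",
    "write_panel",
    "read_panel",
    "write_class_atlas",
    "read_class_atlas",
    "write_vertex_samples",
    "read_vertex_samples",
    "write_scheme",
    "read_scheme",
]


def atomic_write_text(path: str | Path, text: str) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.", suffix=".tmp")
    try:
        with os.fdopen(fd, "w", encoding="utf-8") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _atomic_to_tsv(df: pd.DataFrame, path: str | Path) -> None:
    atomic_write_text(path, df.to_csv(sep="\t", index=False))


def write_region_map(map_: RegionMap, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "parcel_id": np.arange(map_.n_parcels),
            "metric": map_.metric_name,
            "value": map_.values,
            "valid": np.isfinite(map_.values),
        }
    )
    _atomic_to_tsv(df, path)


def read_region_map(
    path: str | Path, n_parcels: int | None = None, metric: str | None = None
) -> RegionMap:
    df = pd.read_csv(path, sep="\t")
    required = {"parcel_id", "metric", "value"}
    if not required.issubset(df.columns):
        raise ValueError(f"region map TSV needs columns {sorted(required)}")
    if metric is not None:
        df = df[df["metric"] == metric]
    names = df["metric"].unique()
    if len(names) != 1:
        raise ValueError(f"expected one metric, found {list(names)}; pass metric=")
    dup = df["parcel_id"].duplicated()
    if dup.any():
        raise ValueError(
            f"duplicate parcel rows: {sorted(df.loc[dup, 'parcel_id'].unique().tolist())}"
        )
    ids = df["parcel_id"].to_numpy()
    n = n_parcels if n_parcels is not None else int(ids.max()) + 1
    if ids.min() < 0 or ids.max() >= n:
        raise ValueError("parcel ids outside the declared geometry")
    missing = sorted(set(range(n)) - set(ids.tolist()))
    if missing:
        raise ValueError(f"missing parcels: {missing}")
    values = np.full(n, np.nan)
    values[ids] = df["value"].to_numpy()
    if "valid" in df.columns:
        values[ids[~df["valid"].to_numpy(dtype=bool)]] = np.nan
    return RegionMap(values, str(names[0]))


def write_geometry(geom: ParcelGeometry, vertex_path: str | Path,
                   parcel_path: str | Path) -> None:
    vdf = pd.DataFrame(
        {
            "vertex_id": np.arange(geom.n_vertices),
            "x": geom.vertex_coords[:, 0],
            "y": geom.vertex_coords[:, 1],
            "z": geom.vertex_coords[:, 2],
            "parcel_id": geom.vertex_parcel,
        }
    )
    pdf = pd.DataFrame(
        {
            "parcel_id": np.arange(geom.n_parcels),
            "hemisphere": geom.hemisphere,
            "cx": geom.parcel_centroid[:, 0],
            "cy": geom.parcel_centroid[:, 1],
            "cz": geom.parcel_centroid[:, 2],
            "homologue_id": geom.homologue if geom.homologue is not None
            else [-1] * geom.n_parcels,
        }
    )
    _atomic_to_tsv(vdf, vertex_path)
    _atomic_to_tsv(pdf, parcel_path)


def read_geometry(vertex_path: str | Path, parcel_path: str | Path) -> ParcelGeometry:
    vdf = pd.read_csv(vertex_path, sep="\t").sort_values("vertex_id")
    pdf = pd.read_csv(parcel_path, sep="\t").sort_values("parcel_id")
    homologue = pdf["homologue_id"].to_numpy()
    geom = ParcelGeometry(
        vdf[["x", "y", "z"]].to_numpy(),
        vdf["parcel_id"].to_numpy(),
        pdf[["cx", "cy", "cz"]].to_numpy(),
        pdf["hemisphere"].to_numpy(),
        None if (homologue < 0).all() else homologue,
    )
    geom.validate()
    return geom


def write_panel(panel: SubjectPanel, path: str | Path) -> None:
    ns, nk, nr, nm = panel.values.shape
    subj, sess, region, metric = np.meshgrid(
        np.arange(ns), np.arange(nk), np.arange(nr), np.arange(nm), indexing="ij"
    )
    df = pd.DataFrame(
        {
            "subject": np.asarray(panel.subjects)[subj.ravel()],
            "session": sess.ravel(),
            "parcel_id": region.ravel(),
            "metric": np.asarray(panel.metrics)[metric.ravel()],
            "value": panel.values.ravel(),
        }
    )
    _atomic_to_tsv(df, path)


def read_panel(path: str | Path) -> SubjectPanel:
    df = pd.read_csv(path, sep="\t")
    subjects = sorted(df["subject"].unique().tolist())
    sessions = sorted(df["session"].unique().tolist())
    regions = sorted(df["parcel_id"].unique().tolist())
    metrics = sorted(df["metric"].unique().tolist())
    values = np.full((len(subjects), len(sessions), len(regions), len(metrics)), np.nan)
    s_i = {s: i for i, s in enumerate(subjects)}
    k_i = {k: i for i, k in enumerate(sessions)}
    r_i = {r: i for i, r in enumerate(regions)}
    m_i = {m: i for i, m in enumerate(metrics)}
    values[
        df["subject"].map(s_i), df["session"].map(k_i),
        df["parcel_id"].map(r_i), df["metric"].map(m_i),
    ] = df["value"]
    if np.isnan(values).any():
        raise ValueError("panel TSV is not rectangular over (subject, session, region, metric)")
    return SubjectPanel(values, subjects=subjects, metrics=metrics)


def write_class_atlas(atlas: ClassAtlas, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "parcel_id": np.arange(atlas.labels.size),
            "class_label": [atlas.class_names[c] for c in atlas.labels],
        }
    )
    _atomic_to_tsv(df, path)


def read_class_atlas(path: str | Path) -> ClassAtlas:
    df = pd.read_csv(path, sep="\t").sort_values("parcel_id")
    names = sorted(df["class_label"].unique().tolist())
    idx = {n: i for i, n in enumerate(names)}
    return ClassAtlas(df["class_label"].map(idx).to_numpy(), names)


def write_vertex_samples(v: VertexSamples, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "vertex_id": np.arange(v.values.size),
            "metric": v.metric_name,
            "value": v.values,
            "valid": v.valid,
        }
    )
    _atomic_to_tsv(df, path)


def read_vertex_samples(path: str | Path, geom: ParcelGeometry) -> VertexSamples:
    df = pd.read_csv(path, sep="\t").sort_values("vertex_id")
    return VertexSamples(
        df["value"].to_numpy(), df["valid"].to_numpy(dtype=bool), geom,
        str(df["metric"].iloc[0]),
    )


def write_scheme(
    scheme: AcquisitionScheme,
    bval_path: str | Path,
    bvec_path: str | Path,
    timing_path: str | Path,
) -> None:
    atomic_write_text(bval_path, " ".join(f"{b:g}" for b in scheme.b) + "\n")
    rows = [" ".join(f"{v:.10f}" for v in scheme.directions[:, i]) for i in range(3)]
    atomic_write_text(bvec_path, "\n".join(rows) + "\n")
    atomic_write_text(
        timing_path, f"delta_ms\tDelta_ms\n{scheme.delta_ms}\t{scheme.Delta_ms}\n"
    )


def read_scheme(
    bval_path: str | Path, bvec_path: str | Path, timing_path: str | Path | None = None
) -> AcquisitionScheme:
    """FSL-style bval/bvec plus timing sidecar.

    bvec orientation (3 rows or 3 columns) is auto-detected; non-unit
    vectors at b > 0 are renormalized with a warning above 1e-3 deviation.
    """
    b = np.loadtxt(bval_path).ravel()
    if not (b > 0).any():
        raise ValueError("read_scheme: all b-values are zero (no diffusion weighting)")
    vec = np.loadtxt(bvec_path)
    if vec.ndim != 2:
        raise ValueError("bvec file must be a 2-D table")
    if vec.shape[0] == 3 and vec.shape[1] != 3:
        vec = vec.T
    elif vec.shape[1] != 3:
        raise ValueError("bvec file must have 3 rows or 3 columns")
    if vec.shape[0] != b.size:
        raise ValueError("bval/bvec length mismatch")
    norms = np.linalg.norm(vec, axis=1)
    dwi = b > 0
    if (np.abs(norms[dwi] - 1.0) > 1e-3).any():
        warnings.warn("read_scheme: renormalized non-unit gradient directions",
                      RuntimeWarning, stacklevel=2)
    vec = vec.copy()
    vec[dwi] = vec[dwi] / norms[dwi, None]
    vec[~dwi] = 0.0
    if timing_path is not None:
        tdf = pd.read_csv(timing_path, sep="\t")
        delta, Delta = float(tdf["delta_ms"].iloc[0]), float(tdf["Delta_ms"].iloc[0])
    else:
        delta, Delta = 10.6, 43.1
    return AcquisitionScheme(b, vec, delta, Delta)
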