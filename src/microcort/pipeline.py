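"""End-to-end pipeline driver: simulate -> fit -> assemble -> factors -> spin.

A RunConfig (YAML-serializable) names the stages and their parameters;
run_pipeline executes them in order, writes every intermediate as TSV, and
records a RunManifest with per-stage output hashes, timings and warnings.
Deterministic configs reproduce identical hashes on rerun.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as mio
from .dti_dki import dki_scalars, dti_scalars, fit_dki, fit_dti
from .latent_factors import fit_minres_fa, factor_scores, metric_correlations
from .map_assembly import VertexSamples, assemble_map
from .spatial_inference import fdr_bh, spin_permutations, spin_test_correlation
from .synthetic_cortex import RegionMap, SmoothMapSampler, gen_parcel_sphere
from .synthetic_signals import (
    VoxelTruth,
    add_rician_noise,
    gen_scheme,
    rician_debias,
    signal_watson,
)
from .tissue_models import build_noddi_dictionary, fit_mapmri, fit_noddi, odi_to_kappa

__all__ = ["RunConfig", "RunManifest", "demo_config", "run_pipeline"]

STAGES = ("cortex", "signals", "fit", "assemble", "factors", "spintest")
_STOCHASTIC = ("cortex", "signals", "spintest")


@dataclass
class RunConfig:
    out_dir: str
    stages: dict

    def validate(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        # stages form a chain; each needs its predecessors' state
        wanted = [s for s in STAGES if s in self.stages]
        if wanted and wanted != list(STAGES[: len(wanted)]):
            raise ValueError(f"stages must be a prefix of {STAGES}, got {wanted}")
        for name in _STOCHASTIC:
            if name in self.stages and "seed" not in self.stages[name]:
                raise ValueError(f"stochastic stage {name!r} requires an explicit seed")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        return cls(out_dir=raw["out_dir"], stages=raw["stages"])

    def to_yaml(self, path: str | Path) -> None:
        mio.atomic_write_text(
            path, yaml.safe_dump({"out_dir": self.out_dir, "stages": self.stages})
        )


@dataclass
class RunManifest:
    config: dict
    stages: dict = field(default_factory=dict)

    def record(self, name: str, outputs: list[Path], elapsed: float,
               warning_msgs: list[str]) -> None:
        self.stages[name] = {
            "outputs": {str(p): _sha256(p) for p in outputs},
            "elapsed_s": round(elapsed, 3),
            "warnings": warning_msgs,
        }

    def to_json(self, path: str | Path) -> None:
        mio.atomic_write_text(
            path, json.dumps({"config": self.config, "stages": self.stages}, indent=2)
        )


def _sha256(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def demo_config(out_dir: str = "runs/demo") -> RunConfig:
    """Desk-scale end-to-end configuration (runs in a couple of minutes)."""
    return RunConfig(
        out_dir=out_dir,
        stages={
            "cortex": {"n_parcels_per_hemi": 40, "vertices_per_parcel": 12, "seed": 11},
            "signals": {
                "protocol": "custom",
                "shells": [[1000, 32], [2000, 32], [3000, 32]],
                "n_b0": 6,
                "snr": 50,
                "seed": 12,
            },
            "fit": {"noddi_grid": [16, 16]},
            "assemble": {"mad_threshold": 4.5, "sd_threshold": 1.0},
            "factors": {"max_factors": 6, "retain_threshold": 0.01},
            "spintest": {"n_perm": 500, "seed": 13, "target_length_scale": 0.4},
        },
    )


def _scaled(raw: np.ndarray, lo: float, hi: float) -> np.ndarray:
    r = (raw - raw.min()) / (raw.max() - raw.min())
    return lo + (hi - lo) * r


def run_pipeline(config: RunConfig, dry_run: bool = False) -> RunManifest:
    """Execute the configured stages; returns the manifest.

    Raises before any stage executes if the configuration is invalid; on a
    stage failure the manifest holds the completed stages' records.
    """
    config.validate()
    plan = [s for s in STAGES if s in config.stages]
    manifest = RunManifest({"out_dir": config.out_dir, "stages": config.stages})
    if dry_run:
        for name in plan:
            manifest.stages[name] = {"planned": config.stages[name]}
        return manifest

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    state: dict = {}
    for name in plan:
        t0 = time.perf_counter()
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            outputs = _STAGE_FUNCS[name](config.stages[name], state, out)
        manifest.record(
            name, outputs, time.perf_counter() - t0,
            [str(w.message) for w in caught],
        )
    manifest.to_json(out / "manifest.json")
    return manifest


def _stage_cortex(params: dict, state: dict, out: Path) -> list[Path]:
    geom = gen_parcel_sphere(
        params["n_parcels_per_hemi"], params["vertices_per_parcel"], params["seed"]
    )
    state["geom"] = geom
    state["cortex_seed"] = params["seed"]
    vp, pp = out / "vertices.tsv", out / "parcels.tsv"
    mio.write_geometry(geom, vp, pp)
    return [vp, pp]


def _stage_signals(params: dict, state: dict, out: Path) -> list[Path]:
    scheme = gen_scheme(
        params.get("protocol", "hcp_like"),
        shells=[tuple(s) for s in params.get("shells", [])] or None,
        n_b0=params.get("n_b0"),
    )
    geom = state["geom"]
    seed = params["seed"]
    rng = np.random.default_rng(seed)
    # smooth ground-truth parameter maps over the parcellation
    sampler = SmoothMapSampler(geom, 0.6)
    f_ic = _scaled(sampler.sample(rng).values, 0.35, 0.85)
    odi = _scaled(sampler.sample(rng).values, 0.1, 0.6)
    f_iso = _scaled(sampler.sample(rng).values, 0.02, 0.25)
    axes = rng.standard_normal((geom.n_parcels, 3))
    axes /= np.linalg.norm(axes, axis=1, keepdims=True)

    snr = params.get("snr", 50)
    sigma = 1.0 / snr if snr else 0.0
    signals = np.empty((geom.n_parcels, scheme.n_volumes))
    for r in range(geom.n_parcels):
        truth = VoxelTruth(
            "watson", f_ic=float(f_ic[r]), f_iso=float(f_iso[r]),
            kappa=float(odi_to_kappa(odi[r])), mu=axes[r],
        )
        s = signal_watson(truth, scheme)
        if sigma > 0:
            s = rician_debias(add_rician_noise(s, sigma, seed + 1000 + r), sigma)
        signals[r] = s
    state["scheme"] = scheme
    state["signals"] = signals
    bv, bc, tp = out / "scheme.bval", out / "scheme.bvec", out / "scheme_timing.tsv"
    mio.write_scheme(scheme, bv, bc, tp)
    sp = out / "signals.tsv"
    header = "\t".join(f"v{i}" for i in range(scheme.n_volumes))
    body = "\n".join("\t".join(f"{x:.8g}" for x in row) for row in signals)
    mio.atomic_write_text(sp, header + "\n" + body + "\n")
    return [bv, bc, tp, sp]


def _stage_fit(params: dict, state: dict, out: Path) -> list[Path]:
    scheme, signals = state["scheme"], state["signals"]
    n_fic, n_odi = params.get("noddi_grid", [16, 16])
    dictionary = build_noddi_dictionary(scheme, n_fic=n_fic, n_odi=n_odi)
    rows = []
    for sig in signals:
        sc: dict[str, float] = {}
        sc.update(dti_scalars(fit_dti(sig, scheme)))
        sc.update(dki_scalars(fit_dki(sig, scheme)))
        sc.update(fit_noddi(sig, scheme, dictionary).scalars())
        from .tissue_models import mapmri_scalars

        sc.update(mapmri_scalars(fit_mapmri(sig, scheme)))
        rows.append(sc)
    metrics = list(rows[0].keys())
    values = np.array([[r[m] for m in metrics] for r in rows])
    state["metric_names"] = metrics
    state["parcel_metrics"] = values
    path = out / "parcel_scalars.tsv"
    lines = ["parcel_id\t" + "\t".join(metrics)]
    for i, row in enumerate(values):
        lines.append(f"{i}\t" + "\t".join(f"{x:.8g}" for x in row))
    mio.atomic_write_text(path, "\n".join(lines) + "\n")
    return [path]


def _stage_assemble(params: dict, state: dict, out: Path) -> list[Path]:
    geom = state["geom"]
    values = state["parcel_metrics"]
    metrics = state["metric_names"]
    rng = np.random.default_rng(state["cortex_seed"] + 7)
    outputs = []
    maps = []
    for j, metric in enumerate(metrics):
        base = values[geom.vertex_parcel, j]
        scale = float(np.nanstd(values[:, j])) or 1.0
        noisy = base + 0.05 * scale * rng.standard_normal(geom.n_vertices)
        # plant a few gross outliers to exercise the filters
        k = max(2, geom.n_vertices // 200)
        idx = rng.choice(geom.n_vertices, size=k, replace=False)
        noisy[idx] += 10.0 * scale * rng.choice([-1, 1], size=k)
        v = VertexSamples.from_values(noisy, geom, metric)
        map_, _log = assemble_map(
            v, params.get("mad_threshold", 4.5), params.get("sd_threshold", 1.0)
        )
        maps.append(map_)
        p = out / f"map_{metric.replace('-', '_')}.tsv"
        mio.write_region_map(map_, p)
        outputs.append(p)
    state["maps"] = maps
    return outputs


def _stage_factors(params: dict, state: dict, out: Path) -> list[Path]:
    maps = state["maps"]
    R = metric_correlations(maps)
    model = fit_minres_fa(
        R, params.get("max_factors", 6), params.get("retain_threshold", 0.01),
        metric_names=[m.metric_name for m in maps],
    )
    X = np.column_stack([m.values for m in maps])
    Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=0)
    scores = factor_scores(Z, R, model) if model.n_factors else np.zeros((X.shape[0], 0))
    state["factor_scores"] = scores
    state["factor_model"] = model
    path = out / "factor_loadings.tsv"
    lines = ["metric\t" + "\t".join(f"F{j+1}" for j in range(model.n_factors))
             + "\tuniqueness"]
    for i, m in enumerate(maps):
        row = "\t".join(f"{model.loadings[i, j]:.6f}" for j in range(model.n_factors))
        lines.append(f"{m.metric_name}\t{row}\t{model.uniquenesses[i]:.6f}")
    lines.append(
        "variance_explained_pct\t"
        + "\t".join(f"{v:.4f}" for v in model.variance_explained_pct) + "\t"
    )
    mio.atomic_write_text(path, "\n".join(lines) + "\n")
    return [path]


def _stage_spintest(params: dict, state: dict, out: Path) -> list[Path]:
    geom = state["geom"]
    scores = state["factor_scores"]
    seed = params["seed"]
    null = spin_permutations(geom, params.get("n_perm", 500), seed)
    target = SmoothMapSampler(geom, params.get("target_length_scale", 0.4)).sample(
        np.random.default_rng(seed + 1), "target"
    )
    results = []
    for j in range(scores.shape[1]):
        res = spin_test_correlation(
            RegionMap(scores[:, j], f"F{j+1}"), target, null
        )
        results.append(res)
    p_adj = (fdr_bh(np.array([r.p for r in results]))[1]
             if results else np.zeros(0))
    path = out / "spin_results.tsv"
    lines = ["factor\tr\tp_spin\tp_fdr\tn_perm"]
    for j, res in enumerate(results):
        lines.append(
            f"F{j+1}\t{res.statistic:.6f}\t{res.p:.6g}\t{p_adj[j]:.6g}\t{res.n_perm}"
        )
    mio.atomic_write_text(path, "\n".join(lines) + "\n")
    return [path]


_STAGE_FUNCS = {
    "cortex": _stage_cortex,
    "signals": _stage_signals,
    "fit": _stage_fit,
    "assemble": _stage_assemble,
    "factors": _stage_factors,
    "spintest": _stage_spintest,
}
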