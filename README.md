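# microcort

Simulation and analysis of parcellated cortical dMRI microstructure maps,
end to end and at desk scale: synthetic two-hemisphere spherical cortices
and multi-shell diffusion signals with known ground truth; DTI, DKI,
AMICO-style NODDI and Laplacian-regularized MAP-MRI fitting; vertex-sample
filtering and parcel assembly; test-retest reliability statistics;
structural-covariance gradients; minres/promax factor analysis with an ICA
cross-check; spin-permutation inference with FDR, ANOVA/Tukey and tertile
contrasts; and multivariate prediction (dominance analysis,
distance-dependent cross-validation, PLS correlation, mediation).

## Test

```bash
python -m pytest tests/
```

`tests/test_acceptance.py` holds the end-to-end acceptance criteria; the
remaining files are per-module unit and property tests. One acceptance
assertion is a documented known failure: the MSD propagator scalar misses
its 2% Gaussian closed-form tolerance at the published Laplacian weighting
(0.05) — the reference MAPL implementation shows the same bias on identical
inputs.

## Command line

All functionality is exposed under a single `microcort` entry point:

```bash
# synthetic geometry and signals
microcort simulate cortex --n-parcels-per-hemi 180 --vertices-per-parcel 30 \
    --seed 1 --out out/geom
microcort simulate signals --protocol mgh --model dki --n-voxels 500 \
    --snr 30 --seed 7 --out out/sig

# model fitting (FSL-style bval/bvec plus a timing sidecar TSV)
microcort fit dti    --bval out/sig/scheme.bval --bvec out/sig/scheme.bvec \
    --timing out/sig/scheme_timing.tsv --signals out/sig/signals.tsv \
    --out out/dti.tsv
microcort fit noddi  ... --grid 24,24
microcort fit mapmri ... --radial-order 6 --lambda-l 0.05 --positivity

# map assembly and statistics
microcort assemble --samples samples.tsv --vertices v.tsv --parcels p.tsv \
    --mad 4.5 --sd 1.0 --out map.tsv
microcort reliability --panel panel.tsv --retest retest.tsv --out rel.tsv
microcort gradients --panel panel.tsv --k 2 --out gradients.tsv
microcort factors --maps maps.tsv --retain 0.01 --out factors.tsv
microcort spintest --x a.tsv --y b.tsv --parcels p.tsv --vertices v.tsv \
    --n-perm 10000 --seed 3
microcort anova / tukey / tertile / dominance / ddcv / pls / mediate ...

# reproducible end-to-end pipeline (simulate -> fit -> assemble ->
# factors -> spin inference), writes a manifest with per-stage hashes
microcort run --demo --out-dir runs/demo
microcort run --config my_run.yaml
```

Interchange formats are plain TSV with mandatory headers (region maps:
`parcel_id, metric, value, valid`; panels in long format; geometry as a
vertex table plus a parcel table) and FSL-style `.bval`/`.bvec` text for
acquisition schemes. Pipeline configs are YAML; every stochastic stage
requires an explicit seed and deterministic reruns reproduce identical
output hashes.

## Package layout

| module | contents |
| --- | --- |
| `synthetic_cortex` | spherical parcel geometry, smooth region maps, subject panels, class atlases, two-block latent data |
| `synthetic_signals` | acquisition schemes, DKI/Watson/Gaussian forward models, Rician noise and debiasing |
| `dti_dki` | OLS tensor and kurtosis fits, FA/MD/AD/RD and MK/AK/RK/MKT/KFA scalars |
| `tissue_models` | AMICO-style NODDI dictionary fit, Hermite-basis propagator fit with Laplacian penalty, MSD/QIV/RTOP/RTAP/RTPP |
| `map_assembly` | MAD and SD vertex filters, nearest-neighbour fill, parcellation |
| `reliability` | test-retest CoV, hybrid absolute-agreement ICC, corrected intersubject CoV, laterality index |
| `networks_gradients` | structural covariance networks, degree-normalized Laplacian gradients |
| `latent_factors` | metric correlations, minres factor analysis with promax rotation, FastICA cross-check |
| `spatial_inference` | spin permutations, spin correlation tests, BH-FDR, ANOVA/Tukey, class R², tertile contrasts |
| `multivariate` | multilinear prediction with spin p-values, dominance analysis, distance-dependent CV, PLS correlation, mediation |
| `io`, `pipeline`, `cli` | TSV/bval-bvec readers and writers, the pipeline driver with manifests, the click CLI |
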