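# lvmech — regional left-ventricular mechanics from velocity cines

`lvmech` is a tested pipeline for regional left-ventricular (LV) strain and
dyssynchrony analysis of short-axis velocity cines, aimed at studies of LV
dysfunction in congenital heart disease (e.g. repaired tetralogy of Fallot,
where right-ventricular volume overload drives paradoxical septal motion).
It covers the full chain:

1. **Phantom / cohort simulation** (`lvmech.phantom`, `lvmech.cohort`) — an
   incompressible contracting-annulus phantom with closed-form regional strain
   `ε_r(R,t) = R/r(R,t) − 1`, `r(R,t) = √(R² + R_endo(t)² − r_endo0²)`, and a
   4-phenotype patient simulator with cluster-dependent time-to-event hazards.
2. **Strain engine** (`lvmech.strain`) — Lagrangian tracking of the
   end-diastolic myocardium through the velocity field, per-pixel deformation
   gradients by neighborhood least squares, stretch strain `√(eᵀCe) − 1` on
   radial/circumferential directions, and AHA 16-segment curves (6 basal,
   6 mid, 4 apical; apex cap excluded).
3. **Dyssynchrony** (`lvmech.dyssynchrony`) — per-slice sdTTP, maxTTP,
   strain-rate cross-correlation lag (SRCC, ms), and the Fourier-based radial
   uniformity ratio estimate `RURE = Σ_t A0 / Σ_t (A0 + A1) ∈ [0, 1]`.
4. **Phenotype discovery** (`lvmech.cluster`) — z-scored 25-feature vectors,
   Ward/Euclidean agglomerative clustering, majority-rule cluster count over
   an 11-index validity suite, ANOVA/t-test/chi-square characterization at
   α = 0.01.
5. **Survival** (`lvmech.survival`) — Kaplan-Meier, pairwise log-rank, and a
   multivariable Cox model (Breslow ties) for progression to pulmonary valve
   replacement (PVR), via lifelines.

See `docs/methods.md` for the models, assumptions, and limitations.

## Worked example

Run the whole pipeline on synthetic data:

```bash
lvmech --seed 1 --out demo all
```

This writes, among other artifacts, per-slice dyssynchrony for the uniform
synchronous phantom (`demo/dyssynchrony.csv`):

```
slice,sdTTP_ms,maxTTP_ms,SRCC_ms,RURE
apical,0.0,500.0,0.0,0.999999999999996
mid,0.0,500.0,0.0,0.9999999999999947
basal,0.0,500.0,0.0,0.9999999999999947
```

— a perfectly synchronous contraction: zero TTP dispersion, zero
cross-correlation lag, uniformity ratio 1, and every segment peaking at half
the 1 s cycle. On the simulated 198-patient cohort, the majority rule selects
4 contraction phenotypes and the Cox model (`demo/cox.csv`) recovers the
planted phenotype-1 effect:

```
covariate,hazard_ratio,ci_lower,ci_upper,...,p
cluster1_flag,2.59,1.48,4.55,...,0.00088
LVEF_pct,1.10,0.85,1.43,...,0.45
...
```

The septal-dyssynchrony phenotype carries a hazard ratio of ≈2.6 (95 % CI
1.5–4.5) for progression to PVR while none of the LV volume/function
covariates reach significance — the planted generative structure.

Library use mirrors the CLI:

```python
from lvmech.phantom import PhantomSpec, generate_phantom
from lvmech.strain import (SliceGeometry, track_displacements, compute_strain,
                           build_segment_map, segment_curves, summarize)
from lvmech.dyssynchrony import slice_metrics

spec = PhantomSpec(activation_delay_ms=(0, 0, 0, 0, 0, 150.0))
cine, truth = generate_phantom(spec)
geom = SliceGeometry.from_cine(cine, spec.anterior_reference_angle_rad)
maps = compute_strain(track_displacements(cine, geom), geom)
curves = segment_curves(maps, build_segment_map(cine, geom), cine.frame_duration_ms)
print(summarize(curves).peak_rs_pct)
# [19.45 19.55 19.60 19.60 19.46 13.60]  — the delayed segment's mean peak is
#   lower because its boundary pixels peak out of phase with its core
print(slice_metrics(curves).sdTTP_ms)
# 53.4  — TTP dispersion (ms) induced by the single 150 ms activation delay
```

## CLI

`lvmech [--config cfg.yaml] [--seed N] [--out DIR] SUBCOMMAND` with
subcommands `phantom`, `strain`, `dyssynchrony`, `cohort`, `cluster`,
`survive`, `report`, `all`. Key options: `--srcc-agg {mean,max}`,
`--rure-variant {summed,framewise}`, `--k-range`, `--exclude-prior-pvr`.
Configuration is YAML validated against a strict schema (unknown keys are
rejected); every stage writes a JSON run manifest (versions, seed, config
hash, input hashes, row counts) sufficient to reproduce its outputs.
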