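# Methods

`lvmech` reconstructs a complete regional left-ventricular (LV) mechanics
analysis — pixel-velocity fields to AHA 16-segment strain curves, per-slice
dyssynchrony statistics, unsupervised contraction-phenotype discovery, and
survival analysis of the phenotypes — with a synthetic contracting-ventricle
phantom and a cohort simulator standing in for MRI data and for a deep-learning
velocity-inference model. This note records the models, the parameters that
matter, the numerical choices, and what the synthetic data can and cannot show.

## Contracting-annulus phantom

The phantom is a 2-D short-axis slice: an annular myocardium between
end-diastolic (ED) radii `r_endo0` and `r_epi0` centered on a pixel grid. Each
of `n_sectors` angular sectors contracts with amplitude `c_s ∈ [0, 1)` and
activation delay `δ_s`. The endocardial radius follows

    R_endo(t) = r_endo0 · (1 − c_s · w(t − δ_s)),   w(u) = sin²(π u / T),

with cycle length `T = n_frames · frame_duration_ms`. The `sin²` waveform was
chosen because it returns strain exactly to zero at end-cycle and makes the
true time to peak closed-form, `TTP_s = T/2 + δ_s`. In-plane incompressibility
maps the material point at ED radius `R` to

    r(R, t) = √(R² + R_endo(t)² − r_endo0²),

so the analytic radial engineering strain is `ε_r(R, t) = R / r(R, t) − 1`
(positive during wall thickening) and the Eulerian radial velocity at image
radius ρ ≥ R_endo is `R_endo · R_endo′ / ρ`. That profile is singular at the
center, and the annulus map does not define a velocity inside the blood pool
at all; there the phantom prescribes an affine contraction (`v ∝ ρ`, zero at
the center, continuous at the endocardium). This keeps the field bounded so
that tracked points which cross the moving endocardium — or are pushed past it
by velocity noise — see physically sensible velocities. Sector amplitudes and
delays are blended linearly over ±5° at sector boundaries so the velocity
field is continuous and the downstream gradient estimation is well posed.

Truth curves (`StrainTruth`) are evaluated at the sector mid-wall radius
`(r_endo0 + r_epi0)/2`. Defaults describe an adult mid-ventricular slice:
`r_endo0 = 20 mm`, `r_epi0 = 28 mm` (8 mm wall), `c = 0.25` uniform (peak
mid-wall radial strain ≈ 19.9 %, in the healthy-control range for mid-slice
global radial strain), 1 s cycle at 40 frames, 1 mm pixels (0.5 mm in the
high-resolution validation setting). Gaussian velocity noise (`noise_sd_mm_s`)
is additive and white in space and time. ED is frame 0 by construction.

Out of scope by design: no image-intensity synthesis (the phantom emits
velocity + mask bundles, not cine images), no 3-D or long-axis geometry, no
through-plane motion.

## Strain engine

Tracking is Lagrangian: ED-mask pixels are material points advected by forward
Euler, `x(k+1) = x(k) + v(x(k), k)·Δt`, with bilinear interpolation of the
velocity grid and nearest-neighbor extrapolation beyond the image bounds.
Euler (rather than a higher-order scheme) is adequate at cine frame rates; the
convergence test shows the truth error shrinking from ≈0.7 pp at
1 mm / 20 frames to ≈0.07 pp at 0.5 mm / 40 frames. Trajectories that leave
the image are flagged, logged, and excluded from segment averages.

The per-pixel deformation gradient `F(k)` solves the least-squares problem
`min_F Σ_j |dx_j(k) − F dX_j|²` over the pixel's ED neighbors within a 2-pixel
radius; pixels with fewer than 3 tracked neighbors or a collinear
(rank-deficient) neighborhood are flagged and excluded. With `C = FᵀF`,
strain is the stretch-based engineering strain `ε = √(eᵀCe) − 1` projected on
the ED radial and circumferential unit directions about the cavity centroid.
The stretch convention (not Green strain) was chosen because radial strains of
30–80 %, as seen in rTOF cohorts, are engineering-scale magnitudes.
Circumferential maps are computed but unused downstream, matching the radial
focus of the analysis.

AHA segmentation uses equal angular sectors about an explicit `SliceGeometry`
(cavity centroid + anterior reference direction): 6 segments of 60° on basal
and mid slices (anterior, anteroseptal, inferoseptal, inferior, inferolateral,
anterolateral, counterclockwise from the anterior boundary with the septum at
image left), 4 segments of 90° apically (anterior, septal, inferior, lateral).
The apex cap (segment 17) is never emitted. Automatic RV-insertion detection
is out of scope; geometry is an input.

Segment curves are means over each segment's valid pixels, baseline-shifted so
strain(0) = 0; strain rate is the centered finite difference (one-sided at the
ends), in 1/s. Peak RS is 100 × the curve maximum; TTP is the argmax frame
(earliest frame on ties) × frame duration; a flat curve has peak 0 and TTP
missing. Global RS defaults to the peak of the pixel-count-weighted mean
segmental curve; the mean-of-segmental-peaks variant is a config option
(`global_rs_rule`), since either convention is defensible and they agree on
homogeneous contraction.

## Dyssynchrony statistics (per slice, radial channel)

- **sdTTP** — population standard deviation (divisor n) of segmental TTPs.
- **maxTTP** — maximum segmental TTP ("maximum time to peak" is read as the
  maximum TTP, not the maximum pairwise difference).
- **SRCC** — for every unordered segment pair, the lag maximizing the circular
  normalized cross-correlation of the zero-meaned strain-rate curves, searched
  over ± half the cycle (beyond which circular lags are unidentifiable); the
  statistic is the mean absolute pairwise lag in ms (max-of-pairs available via
  `srcc_aggregation`). Ties in the lag search resolve to the smallest |lag|.
  Zero-variance curves are skipped pairwise.
- **RURE** — per frame, `A0` and `A1` are the magnitudes of the order-0 and
  order-1 spatial DFT coefficients of segmental strain around the
  circumference; `RURE = Σ_t A0 / Σ_t (A0 + A1)` over frames with a nonzero
  denominator (a per-frame-averaged variant is exposed via `rure_variant`).
  1 = perfectly uniform contraction; 0 = pure opposing-wall pattern. Magnitude
  (not power) coefficients and the time-summed ratio are the defaults; apical
  slices use their 4 segments directly (order 1 is still defined).

No single canonical formulation of SRCC or RURE exists in the field, so both
statistics are pinned by contract instead:
exact values at the synchronous/uniform and first-harmonic extremes, monotone
response to a planted delay, determinism, and invariance to positive rescaling
and to circular segment relabeling. Full-cycle windows are used (no
systole-only gating).

## Cohort simulator

Each synthetic patient carries the fixed 25-feature vector used for
clustering — 16 segmental peak radial strains (%) plus sdTTP, SRCC, and RURE
for each of the apical/mid/basal slices — clinical covariates, and a
right-censored time to pulmonary valve replacement (PVR). Four phenotype
templates (n = 39/29/56/74, total 198) encode the four contraction patterns
described in the rTOF literature: (1) severe septal hypokinesis with lateral
compensation and marked dyssynchrony, (2) global hypokinesis with the lowest lateral strain and
minimal dyssynchrony, (3) preserved septal strain and synchronous contraction,
(4) preserved strain with the highest lateral strain and mild dyssynchrony.

Template means start from whole-cohort rTOF reference ranges and are reshaped
by those qualitative contrasts; no per-phenotype feature tables exist to copy,
so the templates are approximate by construction and tagged as such in the code.
Within-cluster SDs are 0.7 × the pooled cohort SDs (the pooled SD includes
between-phenotype variance). Features are drawn independently per feature
(Gaussian, truncated to physical ranges: strains ≥ −100 %, time metrics ≥ 0,
RURE clipped to [0, 1]); a per-template covariance hook exists but defaults to
diagonal because reference ranges come as means ± SDs only.

Survival: event times are exponential with baseline hazard 0.004/month and
per-phenotype log-hazard multipliers, default `[log 2.69, 0, 0, 0]` — the
phenotype-1 hazard ratio of 2.69 with no independent effect of the LV
covariates, so the Cox model fitted downstream is correctly specified and its
CI coverage is a meaningful check. Censoring is uniform on [6, 160] months
(a realistic 0.5–13-year imaging follow-up window); under these defaults
≈ 33 % of patients reach PVR, a typical progression fraction for such cohorts.

What the simulator does **not** emulate: inter-feature correlation within a
phenotype (real segmental strains are strongly correlated), non-Gaussian
tails, site effects, measurement error correlated across slices,
non-exponential hazards, and covariate-dependent censoring. Passing the
recovery tests therefore shows the machinery is correct under the planted
model, not that four phenotypes would be recovered from any real cohort.

## Clustering and comparison statistics

Features are z-scored (population SD; rows with missing features dropped, not
imputed; a zero-variance feature is an error) so each metric is weighted
equally; no dimensionality reduction is applied. Clustering is agglomerative
with Ward's minimum-variance criterion on Euclidean distances
(`scipy.cluster.hierarchy`); an independent Lance-Williams implementation in
the test suite serves as the oracle. maxTTP is excluded from the default
25-feature vector (`include_max_ttp` adds it).

The cluster count is the majority vote of 11 validity indices, each voting by
its own rule: Calinski-Harabasz, silhouette, Dunn, Krzanowski-Lai,
point-biserial, Ball-Hall-drop (maximize); Davies-Bouldin, C-index,
McClain-Rao (minimize); gap statistic (Tibshirani one-SE rule, 20 uniform
reference draws from the data's bounding box, fixed seed → deterministic);
Hartigan (smallest k with H ≤ 10). Ties go to the smallest k. Majority votes
over larger index censuses (e.g. the 23-index NbClust suite in R) are common
in this field; re-implementing a full census was deliberately traded for a
documented, pluggable 11-index suite — the majority-rule behavior, not the
index census, is the contract, and the suite is an argument to `select_k`.

Cluster characterization follows the standard comparison plan: per-cluster
mean ± SD, one-way ANOVA across clusters for continuous variables, Pearson
chi-square for categorical, all pairwise two-sided equal-variance t-tests, and
Pearson correlations with two-sided p by the t transform. Significance is a
fixed α = 0.01 threshold (a Bonferroni-style family-wise guard applied as a
constant, not recomputed per family). Degenerate input (identical group
means) maps the ANOVA p to 1 rather than NaN.

## Survival analysis

Kaplan-Meier product-limit estimates with right censoring, pairwise two-group
log-rank tests between clusters, and a multivariable Cox proportional-hazards
model with Breslow tie handling, all via lifelines; the test suite cross-checks against a hand product-limit
calculation, a brute-force hypergeometric log-rank accumulation, the
closed-form two-group exponential MLE, and an independent Breslow fit
(statsmodels PHReg). Wald 95 % CIs are `exp(coef ± 1.96·se)`.

Continuous covariates are standardized per sample SD by default
(`covariate_scaling="per_sd"`): per-unit hazard ratios on volumes in mL/m²
are visually indistinguishable from 1, and per-SD effects are comparable
across covariates. `per_unit` is available when raw-unit interpretation is
wanted. Patients with a prior
PVR are included by default; `--exclude-prior-pvr` reproduces the sensitivity
design. Time zero is the imaging exam; months are the unit. Collinear
covariates raise; separation/non-convergence is flagged with the coefficients
still reported. No time-varying covariates, competing risks, or Efron ties.

## Numerical choices and problem sizes

- Lag search ties → smallest |lag|; TTP ties → earliest frame; vote ties →
  smallest k.
- Validation problem sizes: strain recovery on a 128² grid at 0.5 mm and 40
  frames (≈5 000 tracked pixels); clustering recovery over 20 cohort seeds of
  n = 198; CI coverage over 100 simulated cohorts; routine unit tests use a
  64² grid at 1 mm and 20 frames. These sizes make the full suite and the
  acceptance script run in well under a minute and a few minutes respectively
  while leaving the convergence margins comfortably inside the tolerances.
- All randomness flows through explicit integer seeds (`numpy.random.
  default_rng`); same seed ⇒ bit-identical cohorts and phantom noise.

## Known limitations

- 2-D, in-plane mechanics only; no longitudinal strain, no through-plane
  motion, no torsion.
- The phantom's deformation is radially aligned, so radial/circumferential
  projections are exact by construction; oblique shear is exercised only by
  the rotation-invariance tests.
- Phenotype templates are approximations assembled from whole-cohort
  reference ranges plus qualitative contrasts; the planted separation is
  realistic for the described patterns but not a reconstruction of the real
  feature distributions, so the k = 4 recovery rate should be read as a
  machinery check.
- Forward Euler under heavy velocity noise accumulates a random-walk error in
  relative positions; the regression-tested bound (peak segmental strain
  moves < 3 pp at noise = 5 % of peak velocity) holds at default resolutions
  but degrades for very long cines.
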