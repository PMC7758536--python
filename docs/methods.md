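# Methods

`restfc` implements a resting-state functional-connectome group analysis
as a tested, reusable pipeline: per-subject preprocessing of parcellated
BOLD signals, static and dynamic connectivity estimation, edge-wise
general linear models with standardized effect sizes, and cluster-level
multiple-comparison correction by network-based statistics (NBS).  A
synthetic cohort generator with recorded ground truth stands in for raw
MRI data, so every statistical property of the pipeline is checked by
parameter recovery rather than by eyeballing maps.

## Data model

A connectome lives on `n_roi` nodes (default 80: a Desikan–Killiany-like
layout of 34 cortical parcels per hemisphere tagged with lobes —
Frontal, Temporal, Parietal, Occipital, CingulateCortex, Limbic, Insula —
plus 12 subcortical structures).  All edge-valued quantities are flat
vectors over the `n_roi(n_roi−1)/2` unique pairs in upper-triangular
row-major order (`numpy.triu_indices`); this ordering is shared by every
module and round-trips through the file formats.

## Preprocessing

Operating on ROI-level time series (frames × ROIs, TR in seconds):

1. **Frame dropping** — the first 4 frames (~12 s at TR 2.8 s) are
   discarded for T1 equilibration.
2. **Cosine high-pass** — discrete-cosine drift regressors with
   frequencies `k/(2·N·TR)` for `k = 1…⌊2·N·TR·f_c⌋`; at the default
   cutoff `f_c = 0.008 Hz` and 133 retained frames this yields K = 5
   columns.  Filtering is implemented as residualization, and the basis
   is entered *jointly* with the other nuisance blocks in a single
   regression — equivalent to sequential residualization on the combined
   column space and immune to drift reintroduction.
3. **CompCor** — anatomical masks are eroded with a 6-connected
   structuring element (2 iterations; the most conservative "pure
   voxel" choice), and the top 5 principal-component time courses of the
   demeaned WM and CSF voxel sets (SVD; unit variance; first nonzero
   loading positive) become nuisance regressors.  No pre-whitening.
4. **Nuisance regression** — least-squares residual of every ROI signal
   on [constant | cosine | 6 motion parameters | 5 WM | 5 CSF], with
   linearly dependent columns dropped and logged.  Residuals are
   orthogonal to the regressors, so the step is idempotent.
5. **Variance normalization** — every column to sample mean 0, variance 1.

**RMS head motion.**  Rotations (radians) are converted to arc
displacements on a 50 mm sphere; the framewise displacement at frame *t*
is the Euclidean norm of the backward difference of the 6-vector, and
the subject summary is the RMS of those displacements.  Whether the
original computation used frame-to-frame differences or positions
relative to a reference is not recoverable from the source description;
the difference-based definition is used and noted here, and the per-frame
trace is exposed so either summary can be derived.

## Connectivity

**Static (`sfc_z`).**  Pearson correlation of every ROI pair over the
full preprocessed series, Fisher-z transformed (`atanh r`).  `|r| = 1`
and zero-variance inputs are hard errors naming the offending edge/ROI.

**Dynamic (`dfc_sd`).**  Rectangular windows slide in steps of 1 TR;
within each window the raw Pearson r is computed (no Fisher transform —
the transform is applied only to the static map), and each edge is
summarized by the SD (n−1 denominator) of its windowed correlations: a
temporal-variability index in which larger values mean a less stable
connection.  Partial end windows are discarded; zero-variance windows
are skipped with a logged count; fewer than 3 usable windows is an
error.

Two window policies:

- `fixed` (default): constant length `round(34 s / TR)` = 12 frames
  (33.6 s) — in the band recommended for sliding-window work and
  matching the ~34 s mean windows reported for this kind of analysis.
- `adaptive` ("sstd-approx"): per-edge, per-start length
  `clip(round(1/f̂/TR), 10, 20)` frames, where `f̂` is the smoothed mean
  instantaneous frequency (analytic-signal phase derivative, passband
  0.008–0.1 Hz) of the two ROI signals around the start frame.  The
  original single-scale time-dependent derivation is not spelled out in
  the source; this documented approximation is shipped instead, recorded
  in output metadata, with the fixed policy as the default for all
  quantitative runs.

## Edge-wise inference

Per edge, across subjects:

    y = x_nc·β_nc + x_non·β_non + x_im·β_im + X_cov·β_cov + ε

with three group indicators (no intercept; they span it) and five
covariates — age, sex, years of education, race, RMS motion.  Race is a
single integer-coded column so the covariate block is exactly five
columns wide, matching the stated model dimensions (n × 8 overall);
full dummy coding would change the dimensionality and is therefore not
the default.  Contrasts: `c1 = [1, −0.5, −0.5, 0…]` (controls greater
than all fighters) and `c2 = [0, 1, −1, 0…]` (non-impaired greater than
impaired), each one-sided; the opposite directions are the negated
vectors.  `t = c'β̂ / √(σ̂²·c'(X'X)⁻¹c)` with `df = n − rank(X)`
(168 subjects → df 160), and Cohen's `d = c'β̂ / std_pool`,
`std_pool = √(RSS/df)` — the covariate-adjusted pooled residual SD, so
`t = d / √(c'(X'X)⁻¹c)` exactly.

The association model (fighters only) replaces the indicators with an
intercept and the PSS score: `y = β₀ + β₁·PSS + covariates`, `df = n−7`
(133 fighters → 126), testing β₁ one-sidedly.

Degenerate edges (zero residual variance) carry NaN and never enter
supra-threshold sets; they are counted in logs.

## Network-based statistics

One-sided p-values are thresholded strictly (`p < p_unc`); surviving
edges form a graph whose connected components are the observed clusters,
sized by *edge count*.  The permutation null shuffles subject rows of
the connectivity matrix against the fixed design (which also breaks
covariate association — Freedman–Lane residual permutation is available
behind a flag for covariate-exact exchangeability), refits the identical
model, applies the identical threshold, and records the maximal
component size (0 if none).  Corrected p uses the add-one convention
`(1 + #{null ≥ k})/(1 + n_perm)`, so it is never below `1/(n_perm+1)`
and stays valid at the extremes.  Significance is flagged at 0.05 and
trend at 0.10.  The multi-threshold report reruns this over
{0.001, 0.005, 0.01, 0.05} × both directions, recording cluster size,
corrected p and the minimum |d| inside each best cluster.

## Synthetic cohort generator

The generator defines the study conditions: groups of (35, 65, 68)
subjects (controls, non-impaired fighters, impaired fighters), 80 ROIs,
137 frames at TR 2.8 s, frame timestamps at 0, TR, 2·TR, … with no
slice-timing structure.

**Signal model.**  A lobe-blocked ROI correlation matrix (within-lobe
r = 0.35, between-lobe r = 0.10) is sampled through its Cholesky factor
— a linear factor construction chosen because target covariances are
constructible analytically.  On top of the stationary draw:

- *Static effects*: designated edges get a population-correlation shift
  in designated groups; shifts that leave (−1, 1) are rejected.  The
  helper `correlation_shift_for_d` converts a target Cohen's d into a
  correlation shift via the between-subject Fisher-z SD
  `√(σ_z² + 1/(T′−3))`, where T′ is the residual frame count after
  preprocessing (137 − 4 dropped − 22 nuisance columns = 111) and σ_z
  the subject-level coupling SD below.  Realized d measured on
  generated cohorts matches the target within a few percent.
- *Subject-level coupling variability* (σ_z = 0.15 on the z scale,
  clipped at ±2σ, per designated edge): stable individual differences in
  connectivity strength, of the size seen between subjects in real FC
  data.  Without it, a behavioral score could only couple to the
  *sampling noise* of correlation estimates — which is shared among
  edges with common nodes and would make edge-level association
  recovery ill-posed.  Perturbed matrices are projected back to SPD
  (eigenvalue clip at 1e−4, unit-diagonal renormalization) in the rare
  cases the perturbation breaks definiteness.
- *Dynamic effects*: a modulated edge is rebuilt from its partner ROI
  with mixing coefficient `ρ(t) = r₀ + A·sin(2πft + φ)` (φ random per
  subject), making the instantaneous correlation trajectory exact by
  construction.  Defaults A = 0.9, f = 0.01 Hz: at 137 frames the
  windowed-correlation sampling SD is ≈ 0.30, so only a near-full-range
  swing at a frequency the 33.6 s window does not average out (and that
  the 0.008 Hz high-pass does not remove) is detectable at the single-
  edge level — consistent with this variability index being a weak
  instrument at clinical scan lengths.
- *Structured noise*: 5 latent series per subject are shared by the WM
  and CSF voxel sets (60 voxels each, unit-variance latents, voxel noise
  SD 0.5) and leak into ROI signals scaled by 0.2; two slow cosine
  drifts (periods 200–600 s, below the high-pass band) with random ROI
  loadings emulate scanner drift.  CompCor + the cosine basis remove
  both, which the paired-simulation tests verify.
- *Motion*: bounded Gaussian random walks (step SD 0.10 mm, bounds
  ±1.5 mm; rotations as the equivalent arc on the 50 mm sphere), giving
  RMS motion ≈ 0.25 mm — all subjects below the 0.8 mm exclusion
  ceiling, as in the emulated cohort.

**Covariates.**  Age, sex, education, 6-level race frequencies,
processing-speed (PSS) and psychomotor (PSY) scores, and fighting
history are drawn per group with the published means, SDs and category
frequencies, so demographic tables and covariate–group collinearity
behave realistically (e.g. the controls-vs-fighters contrast genuinely
loses efficiency to education/race imbalance).  When PSS is tied to
connectivity, each fighter's score is
`μ_g + σ_g·(√R²·s + √(1−R²)·ε)` with `s` the standardized sum of the
subject's realized Fisher-z values on the designated edges.  The edge
share R² = 0.7 was fixed by a design-stage power analysis: at the
emulated scan length and cohort size, smaller shares leave the top-k
recovery of the designated edges unstable, which would test the noise
floor rather than the pipeline.  This is a validation-harness setting,
not an empirical claim about brain–behavior effect sizes (which are far
weaker).

**What the generator does not emulate** — and hence what passing tests
do not show about real data: spatial structure within parcels,
physiological (cardiac/respiratory) noise, motion-correlated signal
artifacts, non-Gaussian BOLD marginals, hemodynamic autocorrelation, and
site/scanner effects.  Recovery results certify the *statistics*, not
robustness to every fMRI artifact.

## Validation experiments (problem sizes)

The recovery battery runs the full chain (generate → preprocess →
Fisher-z sFC → GLM with covariates → NBS) at sizes chosen so the whole
battery completes in minutes on one CPU:

- **Null calibration**: 50 null cohorts (18 subjects, 10 ROIs,
  independent baseline) — pooled contrast t is Kolmogorov–Smirnov-
  compatible with Student t at the model df.
- **FWER**: 200 global-null cohorts, 20 ROIs, 30 subjects, 500
  permutations, p_unc 0.005 — fraction with any corrected p < 0.05 stays
  within 2 binomial SEs of the nominal level.
- **Power**: a 10-edge hub-and-spoke cluster at d = 0.8 between 50
  non-impaired and 50 impaired fighters (the demographically matched
  contrast, so d maps onto t undiluted by covariate collinearity), hub
  in the single-ROI Insula lobe of the 34-ROI single-hemisphere map and
  leaves spread over lobes (uniform cross-lobe baseline r, minimal
  noise overlap between spokes); detection = one significant component
  covering ≥ 8 injected edges.
- **Dynamic discrimination**: 100 subjects, 20 ROIs, one modulated edge
  at zero baseline — top-rank rate of the temporal-variability index.
- **Association recovery**: 5 node-disjoint, lobe-spread PSS edges on
  the 34-ROI map, 133 fighters — ≥ 4 of 5 in the top 10 by |t|.

## Numerical choices and degenerate inputs

Ties at the cluster-forming threshold are excluded (strict inequality).
Window placement is left-aligned.  PCA sign convention: first nonzero
voxel loading positive.  Rank deficiency in nuisance or design matrices
drops dependent columns with a logged warning; constant covariate
columns are pruned (they are collinear with the group indicators).
`atanh` is guarded against |r| = 1; zero-variance ROIs/windows follow
the error paths described above.  All randomness flows from explicit
seeds through `numpy` `SeedSequence` spawning, so cohorts, permutations
and whole pipeline runs are bit-reproducible.

## Known limitations

The adaptive window policy is an approximation to an incompletely
specified procedure and is not used for quantitative claims.  The
permutation scheme's row shuffling is only approximately exact in the
presence of strong covariate effects (Freedman–Lane is provided but not
default).  dFC inference shares the GLM machinery with sFC but, as the
discrimination analysis shows, the windowed-SD index has little
single-edge sensitivity at 137-frame scans; group-level dFC findings at
this scale should be read as trends.  Race as an integer code imposes an
ordinal structure on a nominal variable; it is kept for dimensional
fidelity to the emulated model, with dummy coding available.
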