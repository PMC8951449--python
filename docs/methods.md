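# Methods

This note documents the models, estimators and design choices behind
`cstcnet`, and what the synthetic cohorts do and do not show about real
resting-state fMRI.

## The generative model

Every synthetic session is built from five latent cortical-system
signals `s_1..s_5`, independent zero-mean unit-variance series whose
Fourier support is restricted to the analysis band (0.01–0.08 Hz at
TR = 2 s; 250 volumes per session). Signals are drawn by sampling
complex Gaussian coefficients on the in-band DFT bins and inverse
transforming, so out-of-band power is exactly zero by construction.

A voxel of cortical system *c* carries `s_c` plus white noise
(`noise_sd`, default 0.5). A subcortical voxel with planted label
*L(v)* carries

```
x_v(t) = alpha_win * s_L(v)(t) + beta_cross * sum_{c != L(v)} s_c(t) + nuisance + noise
```

with `alpha_win = 1.0 > beta_cross = 0.2`, which makes the
winner-take-all label identifiable: the partial correlation with the
voxel's own system dominates the four cross-couplings at any realistic
series length. Nuisance structure shared by all brain voxels comprises
a global band-limited component (SD 0.5), a linear drift (amplitude
0.3) and a weak projection of the six simulated motion parameters
(random walks with 0.01 mm / 0.01° steps); WM and CSF compartments
carry their own latents. This gives the nuisance-regression stage real
signal to remove while keeping sessions below the 1.5 mm / 1.5° motion
exclusion threshold by default.

### Planted effects

Group effects act on pairs of the 20 analysis regions:

* **Static edge effects** add a shared band-limited component `w·e(t)`
  to both regions with `w² = |c|` and the sign applied to one side,
  where `c` is the configured coupling increment (default +0.3 on two
  thalamo-cortical edges in the generalized-epilepsy group and two
  cerebello-cortical edges in the focal group). `c` is a covariance
  increment, not the realized change in correlation — normalization
  compresses the latter — so recovery is assessed as detection, not as
  magnitude matching.
* **Dynamic effects** gate such a component with a two-state switching
  process (geometric dwell times, mean 40 TR) scaled by
  `dynamic_amplitude`. The default amplitude 2.0 swings the windowed
  correlation of the affected edge between its baseline (~0.2) and
  ~0.8, producing clearly separated windowed states for a 50-TR
  window. Smaller amplitudes are washed out because the mean dwell
  (40 TR) is shorter than the window (50 TR), so most windows mix both
  states; amplitude 2.0 keeps the between-window variance well above
  the sampling variance of a 50-sample correlation.
* **Duration slopes** add `slope × duration` to an edge's coupling
  (default ±0.01 per year with opposite signs in the two patient
  groups on the somatosensory thalamo-cortical edge, and a shared
  negative slope on a striato-thalamic edge).

Demographics reproduce the reference cohort: 75 males / 39 females per
group (the same sex assignment and age vector are reused across groups,
so balance tests are null by construction), ages ~ N(26, 7²) clipped to
18–55, durations lognormal matched to mean/SD 7.98/8.32 years (GE) and
9.42/6.56 years (FE), seizure frequencies lognormal with the matching
group means.

### The region-level fast path

`generate_roi_cohort` emits the twenty region mean series directly,
with region noise `noise_sd / sqrt(48)` (48 = smallest subregion voxel
count), skipping the voxel grid and the nuisance channels that
averaging and regression would remove. A dedicated test verifies the
fast path and the full voxel pipeline produce the same group-mean
static network (pattern r > 0.9). Statistics-, classification- and
reproducibility-scale simulations use this path; parcellation claims
always use full voxel cohorts.

### What the simulator does not emulate

No hemodynamic response function, no scanner physics or spatial noise
correlations, no motion-induced artifacts beyond regressor tables, one
bilateral set of cortical systems rather than per-hemisphere labels,
and block-shaped regions on a 24×24×16 grid (chosen for minutes-scale
runtimes). Passing tests therefore demonstrate that the estimators
recover what the generative model plants — not that real acquisitions
satisfy the model.

## Preprocessing

The chain is discard (10 volumes) → motion screening → nuisance
regression → band-pass. Motion screening uses the cumulative
realignment-style parameters as given; no frame censoring. The
nuisance design is intercept, linear trend, six motion parameters, WM
mean, CSF mean and the global mean (on by default; a flag disables
it). The band-pass is a pure DFT-mask projector: bins outside
[0.01, 0.08] Hz, including DC, are zeroed. Implementing the filter as
an orthogonal projection makes repeated filtering exactly idempotent
and gives a sharply testable contract (out-of-band attenuation is
complete in the DFT sense); the linear trend lives in the regression
design rather than inside the filter because subtracting a fitted
trend re-introduces its in-band component and would break idempotence.
The filter assumes the implicit periodic extension of the DFT;
edge effects are negligible once the mean and trend have been
regressed out, which the pipeline order guarantees.

Global-signal regression makes the 20 ROI means near-collinear (their
brain-wide weighted sum is ≈ 0), so the pipeline estimates the static
network with Ledoit–Wolf covariance shrinkage; the plain estimator
raises a diagnostic suggesting the flag when the covariance condition
number exceeds 1e12.

## Estimators

* **Voxel WTA.** For each system *c*, voxel series and `s_c` are
  projected off the other four parcel signals plus an intercept (QR
  basis) and the residuals correlated. The winner is the argmax of the
  five *signed* coefficients ("highest correlation coefficient" read
  literally); ties break to the lowest label index. Zero-variance
  voxels are labeled unassigned, carry NaN coefficients, and are
  excluded from Dice denominators.
* **Dynamic WTA.** Per-window coefficients use the same partial
  operator (50-sample windows with 4 covariates are well posed) and
  are averaged before the argmax. Whether windowed coefficients should
  be partial or plain is not uniquely determined by the protocol; the
  partial form is used for internal consistency with the static case.
* **Group maps** average subject coefficient vectors voxel-wise
  (NaN-aware) and then apply WTA. A voxel-wise majority vote is the
  obvious alternative; averaging is deterministic, uses the full
  coefficient information, and is what the tests pin down.
* **Static network.** Pairwise partial correlation conditioning on the
  other 18 regions, read off the precision matrix as
  `r_ij = -P_ij / sqrt(P_ii P_jj)`, clipped to |r| ≤ 1−1e−6 before
  `atanh` so z stays finite. Conditioning on all remaining regions is
  the natural reading of "partial correlation" for a 20-variable
  system at 240 samples; the shrinkage flag covers ill-conditioned
  inputs.
* **Dynamic network.** Windowed (50/5 TR) plain Pearson correlation,
  Fisher-z per window; 50 samples cannot support 18-covariate
  partialing stably, so the per-window estimator deliberately differs
  from the static one. Variability is the entrywise sample SD
  (denominator n−1) across windows.
* **Edgewise statistics** operate on the 190 unique off-diagonal
  edges. The default two-sample test is Student's pooled-variance t
  (Welch behind a flag); the FDR family is the 190 unique edges, never
  the 400-entry flattened view, because symmetric duplicates would
  distort the correction. Edges with zero within-group variance get
  NaN p and leave the family. The interaction model codes GE = 0,
  FE = 1 (recorded in every report) and contains no age/sex main
  effects — groups are matched by construction.
* **Classification.** Features are the full row-major 20×20 flattening
  (400 entries including symmetric duplicates and the zero diagonal),
  preserving the conventional feature counts 400/400/800. Folds are
  stratified and seeded. Within each training fold: standardize,
  rank by F-score
  `F = [(m⁺−m)² + (m⁻−m)²] / [s⁺² + s⁻²]`, and pick the retained
  count k from {10, 25, 50, 100, 200, all} by inner 5-fold accuracy
  (ties to the smaller k; inner selection is skipped when a training
  fold has fewer than 4 subjects per class). The SVM is linear with
  C = 1. AUC is computed from the pooled decision values across folds;
  the positive class for sensitivity is GE. Feature importance is the
  literal sum `w_j · Σ_i y_i x_ij` over training subjects, averaged
  over folds — the signed weight is kept rather than |w|, and the
  wording of the underlying recipe is ambiguous enough that the
  formula is pinned by a hand-computed unit test.
* **Split-half.** Within each group, subjects are stratified by sex,
  sorted by age (ties shuffled from the seed) and dealt alternately,
  each stratum starting with the currently smaller half; this
  reproduces 57/57 halves with 20/19 females from a 114-subject,
  39-female group and leaves age/sex balance p-values ≈ 1.

## Numerical choices and degenerate inputs

r-clipping at 1−1e−6; covariance condition threshold 1e12; rank
checks on every design matrix with collinear-column diagnostics;
oracle tolerances 1e−10 (partial correlation vs residual-correlation,
regression vs normal equations, ANOVA F vs explicit sums of squares)
and 1e−12 (SD vs two-pass). Dice of a label absent from both maps is
undefined and raises rather than returning 0; a label absent from one
map in a similarity profile is reported as missing, not as 0.

## Problem sizes used by the shipped checks

Voxel-level claims run on 10-subject healthy cohorts on the 24×24×16
grid; statistical validity uses 500 null replicates at n = 20/group
over 190 edges, power checks use 5 replicate cohorts at n = 30/group,
interaction recovery 20 replicates at n = 57/group, classification one
cohort of 30 per patient group, and reproducibility 28 per group —
sizes chosen so the full battery completes in minutes on a single core
while keeping Monte-Carlo error well below the asserted margins.

## Known limitations

Effect sizes are free parameters of the simulator, so all quantitative
results (accuracies, power) characterize the planted regime, not any
clinical population. The static classification signal at the default
deltas is strong enough to saturate accuracy at n = 30/group; ordering
comparisons between feature sets, not absolute accuracies, are the
meaningful output. The WTA toy atlas has no hemispheric structure and
no partial-volume voxels, so Dice values near 1 are expected rather
than impressive. The DFT band-pass assumes periodic extension; for
real data with strong non-stationarities a tapered filter would be
preferable.
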