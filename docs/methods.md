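# Methods

This document specifies the statistical models implemented in
`anxvbm`, the scope of the synthetic data generator, the numerical
choices that matter for reproducing results, and known limitations.

## 1. Cohort generator (`anxvbm.synthetic`)

Groups are defined by the diagnostic rules

- AD (anxious depression): HAMD-17 ≥ 17 and HAMA-14 ≥ 14,
- NAD (non-anxious depression): HAMD-17 ≥ 17 and HAMA-14 < 14,
- HC (healthy control): HAMD-17 < 17 and HAMA-14 < 14,

with an external-sample variant that classifies on HAMA-14 ≥ 14 alone.

Each subject draws age, education, and the two Hamilton scores from
per-group normal distributions whose default means and SDs follow
published three-group cohort summaries (n = 89/group defaults; e.g. AD
age 39.93 ± 14.76, AD HAMA-14 25.36 ± 6.79). Scores are rounded to
integers and clipped to instrument ranges; draws violating the group's
diagnostic rule are rejected and redrawn (with an iteration cap that
raises if the score distribution is incompatible with the rule). Sex is
Bernoulli per group, sites are assigned cyclically. HC Hamilton-score
parameters (2.0 ± 1.5) are generator choices typical of screened
controls; they are not taken from any published table.

Consequences of the discretisation: integer rounding adds ≈ 1/12 to the
score variance, and clipping truncates tails when a bound lies within
~3 SD of the mean. Moment-convergence tests account for both.

## 2. Image generator

Images are 3D GMV-like volumes on a configurable grid (default 20×24×20
at 6 mm isotropic, RAS+ affine centered on the origin) inside an
ellipsoidal "brain" mask. Each image is

    baseline + planted effects + smoothed noise (+ optional site offset),

clipped to be nonnegative. Planted effects (all smoothed with the same
kernel as the noise, restricted to the mask):

- `group_mean_shift`: adds a constant inside an ROI for one group —
  a group GMV difference of known location and magnitude.
- `covariate_slope` / `hama_signal`: adds `magnitude × z(score)` inside
  the ROI, where z is the score standardised over the generated cohort —
  a linear GMV–severity association.
- `seed_coupling`: a per-subject latent factor enters a seed ROI with a
  fixed amplitude and a *partner* ROI with a per-group slope — a
  structural-covariance difference (e.g. slopes {AD: 0.2, NAD: 0.8}).

Smoothing uses a truncated Gaussian (FWHM default 8 mm) with
*scatter normalisation*: each source voxel's kernel mass is renormalised
over the in-mask voxels it can reach, so the in-mask sum (hence mean) of
the field is preserved exactly and no intensity bleeds across the brain
boundary. `noise_sd` is the white-noise SD *before* smoothing; smoothing
shrinks the realised voxel SD (≈ 0.43× at the default kernel/voxel
size). `realized_noise_sd()` measures the post-smoothing SD, and all
"effect size d" conditions in the tests and acceptance script set
magnitudes relative to this realised SD. Optional per-site scalar
offsets (`site_offset_sd`) model multicenter level differences; they are
off by default so that with no effects and zero noise every image equals
the baseline exactly.

## 3. Voxel-wise ANCOVA and cluster inference (`anxvbm.vbm`)

The design matrix contains an intercept, k−1 group dummies (reference
HC when present), age, sex (F = 0 / M = 1), education, and s−1 site
dummies; rank deficiency is reported naming the offending column. The
group effect is tested per voxel by the partial F comparing the full
model to the model with the group columns removed:

    F = ((RSS0 − RSS1)/(k−1)) / (RSS1/(n − p)).

Residual sums are computed for all in-mask voxels at once from an
orthonormal basis (QR) of each design, using explicit residuals
`Y − Q(QᵀY)` rather than the norm-difference identity, which loses
precision under large common offsets. Voxels with (near-)zero residual
variance are set undefined and counted. Pairwise post-hoc t maps test a
single group contrast on the full model (positive t = first-named group
larger).

Cluster correction is dual-threshold: voxels with uncorrected p below
`voxel_p` (default 0.001) form clusters under 26-connectivity (t maps
are split by sign before clustering). The cluster-size null is built by
permuting group labels within site strata `n_perm` times (≥ 100) and
pooling all null cluster sizes, recording a size of 0 for permutations
with no supra-threshold voxels. Each observed cluster gets

    p = (1 + #{null sizes ≥ observed size}) / (1 + #null sizes),

and Benjamini–Hochberg at `cluster_q` (default 0.05) over the observed
clusters decides survival. Under a global null this controls the
family-wise surviving-cluster rate at ≈ q (verified empirically in the
acceptance suite). Peak coordinates are reported in millimetres via the
image affine; peaks are the maximal |statistic| with ties broken by
lowest linear index for determinism.

Cluster GMV is the per-subject mean over cluster voxels. Clinical
association uses partial correlation (residualising both variables on
an intercept + covariates + site dummies; df = n − 2 − q). Age-stratified
reruns repeat the full procedure inside age bands (default < 25,
25–40, > 40), dropping site dummies and any covariate that is constant
within a stratum, and skipping (with a warning) strata with fewer than
two subjects in any group.

## 4. Seed-based structural covariance (`anxvbm.structcov`)

For a seed region (typically the leading VBM cluster, excluded from the
search volume), each in-mask voxel j is fit by least squares with the
seed mean GMV as the response:

    seed_i = b0 + b1·voxel_ij + b2·group_i + b3·(voxel_ij·group_i)
             + covariates + e_i,

with group coded NAD = 0 / AD = 1, so reduced AD coupling appears as
negative b3. The interaction is tested by Student t with df = n − p.
Voxel-wise two-sided p-values undergo BH-FDR at `sc_q`; survivors are
clustered by sign and labelled by the peak interaction's direction.

A structural property of this parameterisation: because the voxel value
appears as a noisy predictor, the per-voxel interaction |t| is bounded
in the realistic noise regime regardless of sample size scaling of the
planted slope difference; single-voxel significance is therefore rare
and detection operates through extended regions contributing many
moderately small p-values to the FDR step. The synthetic SC experiment
accordingly plants the coupling into a several-hundred-voxel partner
region (see the decisions that sized it in the acceptance tests).

## 5. Severity prediction (`anxvbm.svr`)

Features are the GMV values of a region's voxels (columns in
lexicographic voxel order so weights map back onto the grid). For each
leave-one-out fold, using the training rows only: (1) voxels are
screened by Pearson correlation with the outcome at p < 0.05; (2)
retained features are z-scored and the outcome centred; (3) a linear
ε-SVR (C = 10, ε = 0.1) is fit and the held-out subject predicted. A
fold that screens out every feature predicts the training-fold mean
(counted and logged). Performance is the Pearson r and MSE between
predictions and observed scores. Consensus features are the voxels
retained by *every* fold; a final model refit on them (full-sample
scaling) provides the interpretable weight map and the frozen model for
external validation, which applies the primary cohort's scaling and
model to a new cohort without refitting.

Permutation inference reruns the entire pipeline (screening included)
on `n_perm ≥ 100` outcome permutations, with

    perm_p = (1 + #{r_perm ≥ r_obs}) / (n_perm + 1),

counting ties against significance so the smallest achievable value is
1/(n_perm + 1) and the estimate is never zero.

The optimisation uses the liblinear primal solver (`LinearSVR`,
`random_state=0` for determinism); the libsvm dual with an explicit
linear kernel solves the same objective one to two orders of magnitude
slower on correlated voxel features and is retained in the test suite
as an independent oracle (agreement verified there).

## 6. Numerical and reproducibility choices

- All stochastic steps take explicit seeds or `numpy` Generators; fixed
  seed implies bit-identical outputs (enforced by tests for the
  generator, the SVR report, and the CLI).
- Classical tests (t, ANOVA, χ², partial correlation, BH-FDR) are
  closed-form implementations cross-checked against scipy, statsmodels,
  and pingouin in the test suite; summary-based and raw-data overloads
  agree exactly.
- Connected components use `scipy.ndimage.label` (26- or
  6-connectivity), verified against a brute-force flood fill.
- NIfTI I/O is float64 end to end; images round-trip bit-identically.
- Monte-Carlo checks against nominal rates always include a
  pre-specified 2-standard-error sampling allowance.

## 7. Limitations

- The generator produces phantom-like volumes (ellipsoid mask, box
  ROIs, stationary Gaussian noise); it does not model anatomy,
  segmentation, registration, or spatially varying smoothness. Results
  on synthetic data validate the *statistical machinery*, not any
  neurobiological claim.
- Site effects are scalar per-site intensity offsets; real multicenter
  heterogeneity (scanner-specific smoothness, variance differences) is
  out of scope. The prediction stage carries no site covariate, so
  strong common-mode site offsets degrade it by construction.
- The cluster-size null pools clusters across permutations rather than
  using the per-permutation maximum; its family-wise behaviour is
  established empirically at the default thresholds, not analytically.
- Only the linear SVR kernel is provided (weight maps require primal
  coefficients); no hyperparameter search is performed.
- Demographic computations reproduce classical statistics from
  (n, mean, SD) group summaries; published summary values that are
  internally inconsistent (a statistic incompatible with its own
  printed inputs) are deliberately not used as checks.
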