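# Methods

`sexdecode` implements a two-experiment protocol for asking whether visual
sexual stimuli evoke sex-dependent brain activity: univariate group
contrasts, multivariate decoding of subject sex from activation patterns,
and an eye-tracking analysis of where male and female viewers look.  Because
no subject-level recordings are publicly distributable for this kind of
study, the package ships a first-class synthetic-data module and every
statistical guarantee is validated against planted ground truth.

## Forward model and first-level GLM

One subject's BOLD run is modelled as

    Y(v, t) = sum_r A_r(v) · x_r(t) + e(v, t)

where `x_r` are the task regressors and `A_r(v)` the per-voxel response
amplitudes.  Two stimulus paradigms are built:

* **movie**: a dynamic sexual-content rating (0–100, 4-s steps, nine
  ~12-s episodes) plus a nonsexual control rating on disjoint episodes.
  Ratings are linearly resampled to the volume midpoints (TR = 2.6 s),
  rescaled to a 0–1 content fraction, and convolved with the canonical HRF.
  The rating regressor is not mean-centred before entry (configurable
  upstream of the fit; the intercept absorbs the offset, so betas are
  unaffected).
* **picture**: 1.5-s picture events (sexual / landscape / nonsexual-human
  categories, 2–3-s jittered ITI) modelled as unit impulses on a micro-time
  grid of 16 bins per TR (nearest bin), convolved with the HRF and read out
  at volume midpoints.  The contrast of interest is sexual minus landscape.

The HRF is the SPM-convention double gamma (response peak parameter 6 s,
undershoot 16 s, unit dispersions, 1:6 undershoot ratio, 32-s support,
unit-peak normalised; mode ≈ 5 s).  Designs carry an intercept and Legendre
polynomial drift (default order 1; configurable to off).  Estimation is
ordinary least squares per voxel with `df = T − rank(X)`; no prewhitening is
applied because single-subject inference is never consumed downstream —
betas feed the group statistics and the classifier.  Rank deficiency is an
error that names the collinear columns.

## Synthetic cohorts

A cohort is parameterised by group sizes, grid shape (default 12³ ≈ 1,728
voxels — the real ~189k-voxel gray-matter mask is deliberately not
emulated), TR, volume count, effect regions, and an AR(1) Gaussian noise
model (marginal SD `noise_sd`, lag-1 coefficient 0.3; AR(1) is the minimal
temporally realistic residual).  Each effect region ties a voxel block to a
regressor and draws one amplitude per subject from
`Normal(mean_for_sex, subject_sd)`, so the planted between-sex separation is
`d = (amp_male − amp_female) / subject_sd` — one knob for decoding
difficulty.  Defaults: `d = 2` (amplitudes 1.0 vs 0.0, subject SD 0.5) in a
3³ sexual-response region, a disjoint 3³ control-dimension region with the
same separation, `noise_sd = 1.5`.

Two calibration choices matter and were fixed while composing the study:

* `noise_sd = 1.5` makes first-level beta noise ≈ 0.34 amplitude units per
  voxel — an appreciable fraction of the between-subject SD.  With nearly
  noiseless maps, all map variance concentrates in the planted voxels and
  the per-map standardisation (below) couples regions through the
  subtracted mean strongly enough to push the disjoint-topography control
  cross-test systematically *below* chance — an artifact real, richly
  structured maps do not show.
* Effect regions are 27 voxels (1.6% of the grid) for the same reason: the
  mean-subtraction coupling scales with the planted fraction of the mask,
  and ~1% is the realistic regime.

Amplitude draws are separable from noise draws (`draw_amplitudes`), so the
movie and picture experiments can share one subject-level effect topography
while keeping independent acquisition noise — exactly the structure that
cross-experiment decoding probes.  Every generator output carries its ground
truth (amplitude volumes, event lists, preference weights).

## Group statistics

Voxel-wise pooled-variance two-sample t (male minus female), zero-variance
voxels flagged and zeroed.  Cluster-level family-wise error is controlled by
max-cluster-size permutation: supra-threshold voxels (default two-sided
voxel-wise p < .001, a common cluster-forming convention) are joined under
26-connectivity and a cluster of size s gets
`p_FWE = (1 + #{perm max size ≥ s}) / (n_perm + 1)` over group-label
shuffles that respect group sizes.  Permutation was chosen over random-field
theory because it is exact under exchangeability and needs no smoothness
estimation.  Null simulations show the realised FWE well below the nominal
5% (max-statistic corrections are conservative when few clusters form).

## Decoding protocol

Features are first-level maps restricted to the gray-matter mask (strict
`> 0.25` threshold on the tissue-probability volume) and standardised per
subject map to zero mean / unit variance across voxels.  Per-map (rather
than per-voxel) standardisation makes every result invariant to affine
rescaling of any subject's map; per-voxel normalisation remains available as
an option.

Classification is a soft-margin max-margin classifier with fixed C = 1 (no
inner tuning loop, keeping leave-one-subject-out unbiased), linear kernel
within-task and a radial-basis kernel (bandwidth `1/(n_features · var(X))`,
the conventional "scale" heuristic) for cross-task generalisation, where the
nonlinear kernel is the documented default rather than a claim about any
particular prior implementation.  Kernels are precomputed once per feature
matrix; label permutations reuse the Gram matrix, which is what makes
1000-shuffle nulls cheap.

**Decision rule.**  Predictions use the offset-free kernel discriminant
`sign(Σᵢ αᵢ yᵢ K(xᵢ, x))`, i.e. the SVM solution without its offset term.
In LOSO on a balanced cohort the held-out subject's class is always the
training-fold minority; the offset tracks the fold majority and empirically
drags the label-shuffle null mean to ~33–41% instead of the theoretical 50%
(measured on pure-noise cohorts at n = 20).  Dropping the offset restores
chance calibration without touching the margin geometry.  A decision value
of exactly zero predicts the class with the smaller training prevalence,
deterministically.

Cross-task classification holds the subject out entirely: training uses the
other subjects' rows from the training task, testing the held-out subject's
row from the other task; `cross_classify(X, X)` reduces exactly to
`loso_classify(X)`.

**Inference.**  Each permutation replicate shuffles the labels once and
reruns the full LOSO loop.  `p = #{null ≥ observed} / n_perm`; the
significance flag requires the observed accuracy to be *strictly greater*
than the null's 95% quantile, taken as the 95th order statistic (ties and
interpolation both bias an interpolated quantile liberal; the order
statistic realises the stated "higher than 95% of the null" rule and brings
the empirical false-positive rate to ~5%).  Weight maps come from a linear
fit on all subjects, re-embedded in the mask with positive = male-indicative,
and are compared to the second-level contrast by Pearson correlation over
mask voxels.

## Eye tracking

Gaze is simulated at 1000 Hz: fixations (exponential duration, mean 300 ms,
floor 120 ms, optional slow positional jitter) alternate with saccades
following a symmetric raised-cosine velocity profile, duration
21 ms + 2.2 ms/deg, which guarantees peak velocity `2A/D` above 30°/s and
peak acceleration above 4000°/s² for amplitudes ≥ 1°.  Fixation targets are
drawn from group-specific preference weights over eight body-region ROIs
(face/chest/genital/buttocks × two actors) plus background; the planted
asymmetry gives male viewers ≈ 7% and female viewers ≈ 5% dwell on the
female actor's chest, and the reverse bias on the male actor's face.
Ground-truth saccade events record the *analytic velocity-threshold
crossing* span, since a velocity-threshold detector cannot observe the
sub-threshold tails of the profile; the kinematic motion span is one tail
wider on each side.

Detection: 3-sample moving-average position smoothing, central-difference
velocity and acceleration; saccades are maximal runs with speed strictly
above 30°/s whose onset half accelerates past +4000°/s² and offset half
decelerates past −4000°/s².  The thresholds are as conventionally printed;
the differentiation scheme is this package's own (commercial parsers are
proprietary).  On clean data, boundaries match ground truth within one
inter-sample interval.  Fixations are the complement intervals of at least
50 ms (a conventional floor).

Dwell: a fixation sample counts toward an ROI when it lies inside
(boundary-inclusive, even-odd rule; polygons are simple) the ROI polygon of
the concurrent frame (timestamp flooring at the frame rate).  The default
denominator is the clip duration, so track loss dilutes every ROI equally;
total fixated time is available as an alternative, under which disjoint ROIs
plus background sum to exactly 100%.

The group model is a linear mixed model, `dwell ~ ROI × actor sex × subject
sex` with a per-subject random intercept, fitted by REML (delegated to
statsmodels).  Per-term Wald chi-square statistics are reported (the
statsmodels-native equivalent of per-effect F tests); the planted chest
preference is additionally assessed by a targeted single-degree-of-freedom
contrast (`dwell_sex_contrast`), which is the better-powered question when a
specific cell is of interest.

## Validation strategy, problem sizes, and what it shows

The tests validate calibration and recovery, not any real-data effect:
chance-level null mean (10+10 cohort, 12³ grid, 200 shuffles); ~5%
false-positive rate of the significance rule (200 null cohorts at 8³, 99
shuffles each); accuracy monotone in planted d over {0, 0.5, 1, 2, 3} (6³
grid, 30 common-noise seeds per level) reaching 1.0 on separable ±1
amplitudes; the cross-experiment logic (20 seeds at 16+16: shared topography
significant, disjoint control not) ; FWE ≤ nominal on 150 null second-level
simulations at 500 permutations; exact saccade recovery; dwell conservation
and ≥90% sign recovery of the chest bias (20 repeats, 15+15 viewers, four
12-s clips at 500 Hz; the LMM power check uses 48+48 viewers and five clips,
comparable to a real ~100-subject eye-tracking sample).  These sizes are
chosen so the whole suite runs on a laptop-class single core.

What passing does *not* show: the generator has no hemodynamic
nonlinearity, motion, anatomy, spatial autocorrelation, or inter-region
covariance; classification difficulty is a single planted knob, so synthetic
accuracies say nothing about real-world effect sizes.  The pipeline's
statistical machinery — not the biology — is what the synthetic results
certify.

## Known limitations

* OLS without prewhitening slightly misstates single-subject standard
  errors under AR(1) noise; irrelevant here because only betas propagate.
* The permutation FWE is conservative (few clusters form on a small grid).
* The offset-free decision rule can under-use asymmetric
  ("pattern-present vs pattern-absent") class structure, which is why the
  separable-case validation plants symmetric amplitudes.
* MixedLM Wald tests are asymptotic; with very small cohorts the targeted
  contrast is the more trustworthy read-out.
* The gaze generator's main sequence is a fixed linear duration rule, not a
  fitted oculomotor model; it is sufficient for detector validation only.
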