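# Methods

This note documents the models, algorithms and design choices behind
`gazedyn`: what each stage computes, which parameters matter, what the
synthetic cohort does and does not emulate, and the numerical decisions a
reader would need to reproduce or challenge the results.

## The scientific question

During free viewing of natural scenes, eye movements are classically
explained by what is *in* the image — sensory saliency and semantic
content.  The analyses implemented here ask a complementary question about
*how* people look: whether the spatiotemporal dynamics of gaze (fixation
durations, gaze-step statistics, pupil behaviour) are low-dimensional
across observers, whether they define discrete viewing styles, and whether
the dominant latent dimension is predicted by stimulus content or by an
intrinsic dynamical signature — the similarity of the gaze-step length
distribution to a power law, measured as a Kolmogorov–Smirnov distance
(KSD; lower = more power-law-like).

## Synthetic cohort

The package is exercised end to end on a simulator because the analyses
need raw gaze logs, and the pipeline must be testable without hardware or
downloads.  The generator is a minimal fixation–saccade grammar, not a
biophysical model:

* **Trial structure.** Self-paced image trials drawn from a truncated
  normal centred on the viewer's exploration-time mean (bounded by the
  session's 2,000–10,000 ms window; 1,500 ms ITI), plus one 30 s
  blank-screen trial.  Sampling at 120 Hz (8.33 ms), binocular columns
  with per-eye validity codes; samples are invalidated independently per
  eye at the profile's dropout rate (default 2%).
* **Fixations.** Durations are gamma distributed (style-specific mean and
  shape; an 80 ms refractory floor).  Within a fixation, gaze jitters
  isotropically with 0.05° SD per axis, and pupil diameter declines
  linearly at the profile's coupling rate (≈ −0.2 to −0.35 mm/s) from a
  style-specific baseline, so longer fixations produce smaller mean pupil
  — the anticorrelation the feature analysis should discover.
* **Saccades.** Each saccade is executed between two consecutive samples
  ("instantaneous" at 120 Hz).  Amplitudes come from a two-component
  mixture: with probability *w* (the long-step mixture weight) a Pareto
  tail with the profile's exponent α and a 0.3° lower cutoff, truncated
  at the largest on-screen amplitude; otherwise a lognormal component
  with a ~3° median — a characteristic-scale "preferred amplitude".
  Static viewers are tail-dominated (*w* ≈ 0.85, α ≈ 2.0), so their step
  distribution is close to a pure power law (low KSD); dynamic viewers
  mix in the characteristic-scale component (*w* ≈ 0.45), which no power
  law fits well (higher KSD).  Directions are isotropic with rejection
  sampling to keep endpoints on screen; with a style-dependent
  probability the saccade instead aims at a location sampled from the
  scene's combined saliency+semantic map (dynamic viewers are more
  stimulus-driven).
* **Scenes.** Saliency and semantic maps are normalised mixtures of 2–8
  Gaussian blobs; the semantic map mixes half of the saliency field with
  independent blobs, so the two are correlated but distinct.  These stand
  in for model-derived maps; no image content is rendered.
* **Blank screen.** Same grammar without scene targeting.  Style
  parameters are shrunk toward the population midpoint by `1 −
  carry_over` (default carry-over 0.8: strong but imperfect persistence
  of the style into stimulus-free viewing).  With probability 0.1 a
  viewer simply holds one unbroken central fixation for the whole 30 s
  (no track loss, so the fixation is never split by gaps), emulating
  observers who do not spontaneously explore an empty screen; the single
  fixation leaves dispersion statistics undefined, which is what excludes
  these subjects from the blank-screen analyses.
* **Covariates.** A demographic/cognitive/personality table in which age
  and Stroop interference carry a genuine association with style (static
  viewers older, less impulsive) and all other scores are noise.

What the simulator does **not** emulate: microsaccade/drift structure
within fixations (invisible at 120 Hz anyway), saccade kinematics
(amplitudes jump in one sample), luminance-driven pupil responses,
head-movement artefacts, image content effects beyond blob maps, and any
temporal non-stationarity across the session.  Tests passing on this
cohort therefore demonstrate that the *pipeline* measures what it claims
under a known ground truth — not that real gaze obeys the generator.

## Preprocessing and features

Only samples with validity code 0 in **both** eyes enter the analysis;
positions and pupil are two-eye averages (single-eye fallback is
deliberately not used).  Subjects with less than 50% usable samples in
more than 25% of trials are excluded; both boundaries count as acceptable.

Fixations are detected with an adaptive velocity-threshold algorithm:
sample velocities from a 5-sample moving-window central difference,
per-trial robust dispersion estimates σ = √(median(v²) − median(v)²) per
axis, and an elliptic criterion (vx/λσx)² + (vy/λσy)² > 1 with λ = 15
marking saccadic samples.  Maximal non-saccadic runs of at least 50 ms
(and ≥ 2 samples) become fixations; dropout gaps split fixations.  Note
one property of any *adaptive* threshold: the criterion is relative to
the trial's own dispersion, so a trace cannot be "all saccade"; the test
suite checks the detector against a brute-force per-sample oracle instead
of against absolute-velocity intuitions.

Gaze steps are Euclidean displacements between consecutive valid samples,
never across trial or gap boundaries; a direction flip is a sign change
between consecutive nonzero deltas on an axis.  Step lengths are analysed
in degrees (axis-wise pixel→degree conversion through the 27.1° × 20.5°
stimulus extent on the 683 × 512 map).

The per-subject catalogue has 58 named features (53 for blank screen,
which drops the exploration-time family): fixations (14), pupil (8), gaze
steps (31), exploration time (5).  Per-trial statistics are averaged
across trials; temporal-course features use per-trial quarters (half-open
intervals of each trial's own duration).  The exact composition is a
reconstruction honouring the four families, all named exemplars, and the
printed totals; the manifest (`results/catalogue.yaml`) lists every
feature with family and unit.  A subject with no (or a single) fixation
carries NaN in the affected features and is excluded from feature-matrix
analyses of that condition.

## Power law and KSD

Step lengths x ≥ xmin are modelled as a continuous power law
p(x) ∝ x^(−α), α estimated by maximum likelihood
(α = 1 + n/Σ ln(x_i/xmin)).  By default xmin is chosen by scanning
candidate cutoffs and minimising the KS distance between the tail ECDF
and the fitted law; a config switch fixes xmin instead (at the smallest
observation or at a given value).  KSD is that KS distance.  Numerical
decisions:

* zero-length steps are excluded from fitting (support x > 0) but remain
  in counts and features;
* every fit needs ≥ 50 tail observations (n_min); cells and thresholds
  below that are missing-coded, never extrapolated;
* the xmin scan additionally requires the tail to keep at least 0.5% of
  the positive sample, so a 10⁵-step subject cannot be "fitted" on a few
  dozen extreme values;
* at most 100 quantile-spaced candidate cutoffs are scanned.

Because on-screen amplitudes are truncated at the image diagonal, the
plain MLE on simulator data carries a small upward bias (≈ +0.1 at
α = 2 with the 0.3° cutoff); the exponent-recovery test on pooled
simulator steps therefore fixes xmin at the known mixture knee, while the
estimator-correctness tests use untruncated Pareto draws.

Spatial KSD maps assign each step to the 10 × 10 grid cell containing its
originating sample (integer cell edges `floor(i·size/10)`, shared with the
map-subsampling operation so cells align across data types) and fit each
cell independently.  The pipeline pools a subject's steps across images
(per-image maps rarely reach n_min at 10 s per image); the per-image
variant is available by passing a step subset.

## Attention maps

Gaze heatmaps are per-pixel visit counts normalised to unit mass; their
Shannon entropy is reported in bits (base only rescales; all inferential
uses are scale-invariant).  Fixation density maps put unit mass at each
fixation centroid and smooth with a Gaussian of FWHM 2° (σ = FWHM/2.355,
anisotropic in pixels), zero-padded then renormalised.  "Local" saliency
and semantic values at fixations are means within a 1° disc around the
centroid (point sampling is the config alternative); the pipeline
precomputes disc-mean maps per scene by FFT convolution with edge
renormalisation, making per-fixation sampling a pixel lookup.

## Latent structure

Features are z-scored; PCA is an eigendecomposition of the correlation
matrix.  Components are retained when the eigenvalue exceeds 1 (Kaiser)
**and** the component explains ≥ 10% of variance (the blank-screen
analysis overrides the count to 3 to match the image-viewing structure).
Retained loadings are promax-rotated (kappa = 4, conventional default;
the implementation is validated against R's `stats::promax` on a frozen
fixture and degenerates to varimax at kappa = 1).  Scores use the
regression method — weights R⁻¹(PΦ) with a pseudo-inverse guarding
rank-deficient correlation matrices.  Signs are fixed deterministically:
PC1 correlates positively with mean fixation duration ("static = high
PC1"); other components have their largest-magnitude loading positive.

Viewing styles come from k-means (k = 2; silhouette scores over k = 2…6
reported as a diagnostic) on the component scores; the cluster with the
longer mean fixation duration is "static".  Reliability diagnostics:
co-membership Jaccard similarity against average-linkage hierarchical
partitions under euclidean, manhattan and correlation distances (the
correlation metric is skipped for < 3 dimensions, where it is
degenerate).  ROC separation along PC1 uses a Youden-J cutoff with a
seeded 2,000-resample bootstrap CI.

Feature-table reconstruction from a component subset regresses the
standardised features on the selected scores (optimal rank-limited
reconstruction; reduces to the loadings formula for unrotated components
and to the identity at full rank).

## Inferential layer

*Nested OLS.* M1 (SAL) ⊂ M2 (+SEM) ⊂ M3 (+ShEn) ⊂ M4 (+KSD), compared by
sequential F tests — the likelihood-ratio chain for Gaussian linear
models (what an `anova()` over nested `lm` fits reports, and what the
bracketed df convention implies).  Listwise deletion on the largest
model's columns; singular designs are rejected naming the collinear
columns.

*Split-half validation.* 1,000 seeded random half/half splits; fit on one
half, predict the other, record Pearson r(actual, predicted).  Note a
property the tests respect: within a *fixed* dataset the expected r under
the null is not zero (both halves share the dataset's sampling
fluctuation), so calibration checks average over independent datasets.

*Mixed models.* MM1–MM3 over vectorised 10×10 cells with crossed random
intercepts for subjects and images, implemented as variance components
over indicator sets on a single all-encompassing group.  Maximum
likelihood (not REML) because the LRT compares fixed-effect sets;
fixed-effect t statistics are reported without denominator-df correction.
When the optimiser degenerates (random-effect variance at zero, singular
Hessian, or non-finite likelihood) the model is refitted with fallback
optimisers and, in the limit, collapses to OLS — which is exactly the
model with zero random-effect variance.  The per-subject variant uses a
random intercept for images only; a subject's "winning model" is the
largest one whose addition is significant in the sequential LRT chain at
α = 0.05.  Marginal R² is var(fixed)/var(fixed + random + residual).

*Cluster characterisation.* Welch t-tests per feature (robust default;
the pooled-SD form of Cohen's d), Benjamini–Hochberg FDR across the full
catalogue; constant features are missing-coded.

*Covariate model.* One full OLS of PC1 on the covariate table
(complete cases), validated by the same split-half scheme.  DASS and
ROCF-copy scores are screening instruments and never enter the model.

## Cross-condition analyses

The random forest (500 trees, √p features per split, unlimited depth —
conventional defaults) predicts image-derived style labels from
blank-screen features under stratified 10-fold CV.  Significance comes
from a label-permutation null (the permutation refits use 100-tree
forests for tractability; the pipeline default is 200 permutations, and
the permutation count and forest sizes are config parameters); the 95% CI
is a subject-level bootstrap over out-of-fold correctness.

Between-subject similarity is the Pearson correlation of z-scored feature
vectors for every subject pair, per condition; within- vs between-cluster
comparisons use two-sample t-tests with Bonferroni correction, and the
two conditions' matrices are correlated over their upper triangles.

Cross-condition label stability projects blank-screen features onto the
image-viewing PC1 *loading* pattern over the 53 shared features, with the
blank features z-scored within-condition, then clusters each condition's
scores (k-means, k = 2, higher PC1 = static) and reports the agreement
fraction.  The loading pattern — rather than the regression score weights
— is used for the transfer because regression weights are a
high-dimensional contrast tuned to the image-condition covariance and do
not survive the covariance change across conditions; more fundamentally,
per-trial count features *reverse* direction between conditions (longer
self-paced trials mean more fixations per trial during image viewing,
while on the fixed 30 s blank screen static viewers produce fewer
fixations), which caps the attainable stability regardless of projection:
with default parameters the pipeline measures agreement between ~56%
(full default scale: 120 subjects, 185 images) and ~72% (mid-scale
cohorts of 40–60 subjects) at carry-over 0.8, against a 50% floor at
carry-over 0.

## Problem sizes and runtime

The default study runs 60 static + 60 dynamic viewers over 185 scenes
(~14 M raw samples) on one CPU in a few minutes.  Stages whose cost grows
faster than the data are run on documented subsamples as the package's
standard configuration: the topography mixed models use 24 subjects × 8
images × 100 cells; the KSD threshold-robustness curves use 12 subjects;
the RF permutation null uses 200 permutations with 100-tree forests.  All
sizes are `StudyConfig` fields.

## Known limitations

* The simulator's step mixture is a device for planting a KSD contrast;
  real step distributions are shaped by oculomotor kinematics and image
  content in ways no two-component mixture captures.
* The plain power-law MLE is biased upward under screen truncation; a
  truncated-Pareto likelihood would remove this but is out of scope
  (the analysis uses KSD, which is computed under the same convention for
  every subject).
* Mixed-model t statistics use the normal approximation (no
  Satterthwaite correction).
* The exact 58-feature composition is a documented reconstruction; any
  renaming against a particular published supplementary table would be a
  relabelling, not a structural change.
* Explained-variance percentages on the synthetic cohort are much higher
  than in real data (the two planted styles dominate every family);
  structural conclusions (component count rules, sign conventions,
  recovery) are what the tests assert, not variance percentages.
* Because every subject-level predictor (SAL, SEM, ShEn, KSD) is driven
  by the same planted style latent, the nested models distribute the
  shared variance among collinear predictors: M4 explains PC1 very well,
  but the *partial* KSD coefficient need not be significant on the
  default cohort.  The calibration of that coefficient under a KSD-null
  (type-I error at the nominal rate) is the property the tests assert.
  In real data the predictors carry distinct sources of variance, which
  is precisely what the synthetic confound structure cannot emulate.
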