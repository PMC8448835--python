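# gazedyn

Analysis toolkit for the **spatiotemporal dynamics of visual exploration**:
how people move their eyes over natural scenes, whether those dynamics are
low-dimensional across observers, and whether they are driven by the
stimulus (saliency, semantics) or by intrinsic dynamics of the oculomotor
system.

It is written for eye-movement researchers who have raw gaze logs
(timestamped binocular samples with validity codes) and want to go from
those logs to:

1. **fixations and gaze steps** — adaptive velocity-threshold fixation
   detection (elliptic criterion with multiplier λ = 15 over per-trial
   median-based velocity dispersions) and sample-to-sample gaze steps;
2. **a 58-feature spatiotemporal profile** per subject (fixations, pupil,
   gaze steps, exploration time; 53 features for stimulus-free viewing);
3. **power-law similarity (KSD)** — each subject's gaze-step length
   distribution is fitted to a continuous power law
   p(x) ∝ x^(−α) for x ≥ x_min, with α̂ = 1 + n/Σᵢ ln(xᵢ/x_min)
   (maximum likelihood) and x_min by KS-minimising scan; the
   Kolmogorov–Smirnov distance between the tail ECDF and the fitted law,
   KSD = sup_x |F̂(x) − F(x)|, measures how power-law-like a viewer's
   dynamics are (lower = closer);
4. **latent structure** — PCA of the subjects × features matrix with
   promax rotation (components kept when eigenvalue > 1 and explained
   variance ≥ 10%), k-means viewing styles (*static*: fewer, longer
   fixations; *dynamic*: frequent short fixations), ROC separation along
   PC1, odd/even and category-projection stability;
5. **inference** — nested regressions M1 (SAL) ⊂ M2 (+SEM) ⊂ M3 (+ShEn)
   ⊂ M4 (+KSD) with sequential F tests and 1,000-iteration split-half
   validation; crossed-random-intercept mixed models MM1–MM3 of fixation
   topography over a 10 × 10 grid; Welch t / Cohen's d / FDR style
   characterisation; a cognitive-personality covariate model;
6. **cross-condition analyses** — random-forest classification of viewing
   style from blank-screen features, between-subject similarity matrices,
   and cross-condition label stability.

A synthetic gaze simulator (`gazedyn.simulate`) generates raw recordings
with the statistical structure these analyses assume — two viewer styles,
gamma fixation durations, mixture step laws with controllable power-law
tails, saliency-biased targeting, pupil–fixation coupling, dropouts and
fabricated scene maps — so the entire pipeline runs and is tested without
any eye-tracking hardware or downloads.  See `docs/methods.md` for the
full model description and design decisions.

## Worked example

Simulate one static and one dynamic viewer over 20 scenes, detect
fixations, extract gaze steps, and fit the step-length power law:

```python
from gazedyn import (SessionConfig, generate_cohort, generate_scene_maps,
                     simulate_image_viewing)
from gazedyn.preprocess import (DetectionParams, filter_validity,
                                detect_fixations, compute_gaze_steps)
from gazedyn.steplaw import fit_power_law

config = SessionConfig(n_images=20)
scenes = generate_scene_maps(20, config, seed=7)
static, dynamic = generate_cohort(1, 1, seed=1234)

for viewer in (static, dynamic):
    rec = simulate_image_viewing(viewer, scenes, config, seed=42)
    samples, usable = filter_validity(rec)
    fixations = detect_fixations(samples, DetectionParams(), config)
    steps, flips = compute_gaze_steps(samples, config)
    fit = fit_power_law(steps["length_deg"])
    print(f"{viewer.style:8s} mean fixation {fixations['duration'].mean():6.1f} ms, "
          f"{len(fixations)/len(scenes):5.1f} fixations/image, "
          f"alpha = {fit.alpha:.2f}, KSD = {fit.ksd:.3f}")
```

Output:

```
static   mean fixation  239.2 ms,  24.9 fixations/image, alpha = 1.83, KSD = 0.067
dynamic  mean fixation  193.1 ms,  16.6 fixations/image, alpha = 2.64, KSD = 0.096
```

The static viewer holds longer fixations and its step distribution sits
closer to a power law (lower KSD); the dynamic viewer mixes in
characteristic-scale saccades, which no power law fits as well.  (At this
scale the static viewer also logs more fixations per image because it
explores each image for longer — the self-paced trials are style-dependent
too.)

## The full study

The numbered drivers under `analysis/` run the study end to end and write
tables under `results/`:

```
analysis/01_simulate_cohort.py     cohort, scene maps, covariates
analysis/02_extract_features.py    feature tables + SAL/SEM/ShEn/KSD predictors
analysis/03_step_law.py            per-subject power-law fits, KSD threshold robustness
analysis/04_latent_structure.py    PCA + promax, styles, ROC, stability controls
analysis/05_stimulus_vs_intrinsic.py  nested models M1-M4, split-half validation
analysis/06_fixation_topography.py    spatial KSD maps, mixed models MM1-MM3
analysis/07_blank_screen.py           blank-screen PCA, RF cross-classification
```

Each driver prints what it found and can be run as
`cd analysis && python 01_simulate_cohort.py` (02 before 04, 04 before
05/07).  Equivalently, `gazedyn.pipeline.run_full_study(config, seed)`
executes every stage in one call and writes a results bundle.

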