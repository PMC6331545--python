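# Methods

`thermoshock` implements a non-contact pipeline for detecting and
forecasting hemodynamic shock in critically ill children from pseudo-thermal
body-surface images. Shock redistributes blood flow away from the
periphery, so the skin over the abdomen stays warm while the feet cool; the
pipeline quantifies that gradient and feeds it into a longitudinal model of
an age-adjusted shock label. This note records the models, the parameters
that matter, the numerical choices, and what the synthetic validation does
and does not establish.

## Region-of-interest detection

Thermal frames carry no texture or colour cues, so the abdomen and foot
regions are found by shape alone.

1. **Preprocessing.** RGB frames are converted to grayscale with BT.601 luma
   weights (0.299, 0.587, 0.114) — the dominant convention in the imaging
   tooling this pipeline targets. Pixels strictly below the per-image
   median are zeroed (ambient/thermal noise suppression; pixels equal to
   the median are kept so the operation is exactly reproducible), then
   contrast-limited adaptive histogram equalization (CLAHE) restores local
   contrast for the cooler feet. CLAHE is implemented in-package with the
   8-bit tile-LUT semantics (clip ceiling = `clip_limit * tile_area / 256`,
   uniform excess redistribution, bilinear inter-tile interpolation);
   defaults `clip_limit = 2.0`, `8 x 8` tiles. With a single tile and a
   large clip limit it reduces exactly to histogram equalization
   `v -> round(255 * cdf(v) / N)`, which is what the unit tests pin.
2. **Features.** Histogram-of-oriented-gradients descriptors: 9 unsigned
   orientation bins over [0°, 180°), 8-px cells, 2x2-cell blocks at stride
   1 cell, L2-Hys normalization (clip 0.2) — the descriptor's canonical
   settings. Gradients use centered [-1, 0, 1] filters, orientation mass is
   linearly interpolated between the two nearest bins, and cells that do
   not fully fit the patch are discarded. The implementation is authored
   here because the required conventions (bin interpolation, signed-gradient
   option, configurable block stride) are not all available in the installed
   libraries; tests cross-check it against `skimage.feature.hog` on smooth
   patches.
3. **Classifiers.** One random forest per target class on HOG features of
   pad-to-square, resized patches — abdomen patches at 50x50 px with 310
   trees, foot patches at 100x100 px with 160 trees (tree counts tuned by
   out-of-bag error; `tune_forest` reproduces that procedure and breaks ties
   toward the smaller forest). Negative training patches are random crops
   with IoU < 0.2 against every truth box, sampled 3:1 negative:positive.
4. **Localization.** The body silhouette is the bounding box of the largest
   8-connected nonzero component of the thresholded frame (area ties break
   topmost-leftmost). Window side is proportional to silhouette height —
   0.30x for abdomen, 0.18x for feet — swept at scales {0.8, 1.0, 1.2} with
   stride side/4, restricted to the upper silhouette half (abdomen) or lower
   third (feet); both priors encode supine, head-up framing and can be
   disabled. The single best-scoring window per class is returned (one CPD
   per frame; no non-maximum suppression).

## The CPD statistic

`cpd_percent = (median(abdomen) - median(foot)) / median(abdomen) * 100`.

Medians resist outlier pixels (tubes, probes cover large ROI fractions
without moving the median far), and the ratio form makes the statistic
invariant to multiplicative intensity rescaling — ambient thermal drift —
but deliberately not to additive offsets; tests assert both directions.
Medians are computed on the **raw** grayscale raster, not the
thresholded/CLAHE raster: thresholding zeroes background inside a loose box
and CLAHE distorts absolute levels, either of which would corrupt the
physical quantity. The manual-box and detected variants share one formula
implementation; the denominator is always the (detected or supplied)
abdomen median.

## Shock labels

Shock index SI = median heart rate / median systolic arterial pressure,
medians over a 30-minute window straddling the reference time (±15 min,
endpoints inclusive), from vitals sampled every 15 s. SI is binarized with
age-banded cutoffs (pediatric age-adjusted convention): 1.22 below 7 years,
1.0 from 7 to <13 years, 0.9 above. The published bands start at 4 years;
for younger infants the package extends the 1.22 cutoff downward and emits
a warning. This keeps the age adjustment monotone but is a documented
package choice, not a clinical recommendation — infants physiologically run
higher shock indices, so with realistic infant vitals this default labels a
substantial share of non-shock infants positive (the synthetic cohort's
label prevalence, ~0.8, reflects exactly this; the cutoff table is
configurable). Horizon labels at +3/+6/+12 h recentre the window on
`reference_time + horizon`.

## Longitudinal model

Repeated frames per child violate independence, so the binary label at each
horizon is modeled as logistic with a per-patient random intercept:

    logit P(y_ij = 1) = b0 + b1*CPD% + b2*age + b3*pulse + u_i,
    u_i ~ N(0, sigma_u^2).

Covariates enter on raw scales (percent, months, beats/min); the optimizer
works on internally standardized covariates and estimates are mapped back
through the exact linear reparameterization, so reported coefficients are
raw-scale log-odds per unit. The marginal likelihood integrates u_i by
fixed Gauss–Hermite quadrature (15 nodes by default, configurable) — at
this node count the quadrature is effectively exact for the variance range
seen here, and the package's fits agree with `lme4::glmer` (bobyqa,
`nAGQ = 15`) to ~4 decimals on shared data, which a test enforces.
Optimization uses scipy's bounded Powell method (derivative-free), relative
objective tolerance 1e-6, at most 10^4 evaluations; sigma_u is bounded to
[0, 10]. Standard errors come from the inverse of a central-difference
observed-information matrix over all parameters (falling back to the
fixed-sigma beta block when that matrix is not positive definite).
Quasi-separation is flagged (a standardized coefficient reaching magnitude
12) and flagged fits refuse to predict rather than emit silent estimates.
Prediction for unseen patients uses the population-mean random effect
(zero), as required by patient-disjoint evaluation.

A caveat the tests surface deliberately: with binary outcomes and few
observations per cluster, the maximum-likelihood sigma_u has heavy
finite-sample noise — datasets generated with sigma_u = 0 can have a
genuine interior MLE (verified against lme4). The oracle-equivalence test
therefore uses 400 patients x 10 observations, where sigma_u is well
identified and the fit collapses onto plain logistic regression to 1e-2.

## Evaluation protocol

Ten random patient-wise 70/30 partitions (patient-disjoint by
construction; disjointness is re-asserted on every run and a contaminated
partition raises). Per replicate: fit on training patients, choose the
operating cutoff maximizing Youden's J = Se + Sp - 1 **on the training
scores** (candidates: midpoints of adjacent distinct scores plus ±inf, ties
to the smallest cutoff; the printed-table convention leaves the set
ambiguous, and using training scores avoids test-set leakage at the cost of
slightly different cutoff values), then report AUROC, accuracy,
sensitivity, specificity, PPV and NPV on the test patients at `score >=
cutoff`. Undefined ratios (empty denominators) are reported as missing,
never as zero. Replicates with a single-class training or test side are
skipped with a logged warning and the report carries the effective count.
Summary = mean and SE (sd/sqrt(effective replicates)) per metric.

## Synthetic cohort generator

The generator is first-class, tested code: it plants exactly the structure
each stage must recover.

* **Frames** (default 320x180 portrait; configurable — the pipeline is
  scale-relative through silhouette-proportional windows): an ellipse-
  composite body (head, torso, arms, legs, feet) at a warm level on a
  cooler noisy background; legs ramp linearly from abdominal to foot level;
  a darker pelvic band emulates a diaper and produces the characteristic
  U-shaped dip in the abdomen-to-foot midline intensity profile; i.i.d.
  Gaussian pixel noise (sd 4 by default). The planted CPD (abdomen minus
  foot level) is drawn per image: non-shock N(19.56, 23.48), shock
  N(25.39, 28.88) — the cohort-calibration values. Truth boxes are placed
  so that box medians recover the planted CPD to within ~2 intensity units.
* **Vitals** every 15 s, i.i.d. around state-conditional means: heart rate
  120.75 (24.53) non-shock vs 136.16 (22.78) shock; SBP 97.55 (21.81) vs
  88.97 (21.62); pulse rate = heart rate + N(0, 2). One continuous record
  per patient; each sample's state comes from the nearest imaging/horizon
  anchor. A consequence of the i.i.d. draw is that 30-minute medians
  concentrate tightly per frame (between-frame spread is much smaller than
  the quoted SDs); this makes the derived labels nearly deterministic given
  state and age, which is a simplification relative to ward data.
* **Shock process.** Per-image Bernoulli state at imaging time (prevalence
  0.42, weakly increasing with age), horizon states flip with probability
  1 - persistence (defaults 0.90 / 0.80 / 0.65 at 3/6/12 h). The
  persistence values are free parameters chosen to produce horizon-decaying
  predictability; no published transition rates exist to calibrate them.
* **Ages** log-uniform over 0.2–144 months; body height fraction grows
  weakly with age (0.72–0.93 of frame height) so the detector is exercised
  across scales. One RNG stream per patient (spawned from the master seed)
  makes cohorts bit-reproducible.

What passing on this generator shows: the detector learns shape under
noise, scale variation and the planted geometry; the CPD chain recovers a
known gradient; the labeling and modeling stages recover planted
associations and decay with horizon; the protocol is leak-free and
deterministic. What it does not show: performance on real thermal frames —
no pose variation, occlusions, tubes/dressings, palette inversions or
radiometric drift are simulated, and the reported synthetic AUCs are
analogues of, not estimates of, clinical performance.

## Problem sizes used in the checked experiments

Detector validation: 12 training patients (~240 abdomen / ~480 foot
patches, image-wise 70/30 held-out split for patch AUC) and 10 fresh
patients (~50 frames) for localization IoU. End-to-end experiment: the
default 51-patient cohort (~250 frames), detectors trained on a disjoint
12-patient cohort, ten partitions per horizon. Parameter recovery: 200
patients x 5 observations (plus 100 vs 400 across 10 seeds for the
shrinking-error check). These sizes are the package's validation
conditions; all are configurable.

## Known limitations

* The infant extension of the shock-index cutoffs is a convention, not a
  validated threshold; with the calibrated vitals it inflates label
  prevalence (see above).
* The CPD coefficient in the synthetic end-to-end fit is small and its sign
  unstable: the derived label is driven by the vitals, and the pulse-rate
  covariate absorbs most of the signal. The planted CPD-state association
  is still verified directly at the extraction level.
* Detection returns exactly one window per class even when a foot is
  occluded; downstream filtering must be explicit (batch extraction flags
  failed frames rather than guessing).
* `sigma_u` is reported without a standard error; its finite-sample
  distribution at small values is boundary-constrained and a Wald SE would
  mislead.
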