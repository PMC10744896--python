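# Methods

`neckpose` implements a complete posture-analytics pipeline for classifying
non-specific neck pain from the output of 2D pose estimators applied to
office-style video: per-frame head orientation (yaw, pitch, roll in degrees)
and six upper-body keypoints (eyes, nose, neck, shoulders) with confidence
scores, sampled at 1 Hz over a 30-minute protocol of three 10-minute computer
tasks (typing, mouse-only gaming, hands-free video watching).  This note
records the model, the conventions the implementation commits to, and what
the synthetic benchmark does and does not demonstrate.

## Input model and coordinate conventions

A recording is a flat frame table (one row per second, 1800 rows for a full
protocol): 15 pose values plus 6 confidences.  Coordinates are
image-normalized to [0, 1] with the origin at the top-left corner, so y
increases *downward*; "a shoulder rises" therefore means its y decreases.
Pixel-valued input is accepted with an explicit width/height conversion.  The
reader treats empty cells as missing and never imputes; range violations
(coordinates outside [0, 1], angles outside ±180°) and non-numeric cells are
hard errors that name the offending row.

The three tasks partition the recording into windows 1–3; window 0 is the
whole recording, computed from all kept frames (not as the mean of the three
task values, which would mis-weight tasks after QC removes different numbers
of frames from each).  The first 10 seconds — when the subject sits upright
and centers themselves in an on-screen bounding box — double as the
*baseline window*; those frames also belong to the typing window, since
nothing in the protocol excludes them from the task.

## Frame quality control

Two per-subject rules, applied in order:

1. **Completeness.**  A frame missing any of the 15 estimated values is
   dropped (this is how unanalyzably blurred frames surface downstream of
   the pose networks).  A missing *confidence* alone does not drop a frame:
   the rule is about the estimates, not their scores.
2. **Confidence fence.**  For each keypoint, the first quartile Q1 and
   interquartile range IQR of that subject's confidences define a Tukey
   lower fence Q1 − 1.5·IQR; a frame is dropped when *any* keypoint's
   confidence is strictly below its fence.  Per-keypoint fences are used
   (a single blocked landmark is the realistic failure mode) and quartiles
   use linear interpolation between order statistics (the "type 7"
   convention), pinned by an oracle test.  Fences are computed once over the
   whole recording rather than per task: 30 minutes of data give stabler
   quartiles, and occlusion risk does not reset at task boundaries.

QC runs before the baseline is computed, so the baseline sees only valid
frames; fewer than 5 valid frames in the baseline window is a hard error
(the subject cannot be calibrated).  Thresholds depend only on the subject's
own frames — there is no cross-subject leakage by construction.

## Personal baseline and the feature schema

The baseline is the arithmetic mean of each raw value over valid
baseline-window frames.  It calibrates out body size, camera placement and
resting asymmetry, which differ across subjects far more than the
task-induced posture changes of interest.

Each window contributes 94 features (names carry the window suffix `_0`
whole, `_1` typing, `_2` gaming, `_3` watching):

| family | count | definition |
|---|---|---|
| original | 15 | window mean of each raw value (`RAW_<q>_AVG_<w>`) |
| offset | 15 | window mean of (value − baseline) (`OFFSET_<q>_AVG_<w>`) |
| status | 25 | interval-occupancy proportions, below |
| normalized | 20 | neck-relative coordinates of 5 points × 2 axes, raw and offset (`<p>_<ax>_Mneck_<w>`) |
| variation | 19 | window SD of each raw value + 4 shoulder-difference aggregates |

plus five clinical covariates (gender coded female = 1, age, height, weight,
BMI), for 4 × 94 + 5 = 381 features per subject.

**Head-pose status.**  Each angle's frames are binned into seven intervals
around μ with half-width steps of one window-SD: Normal (|dev| < SD),
Mild/Moderate/Severe on each side, "Right" denoting the negative side.
μ is the *baseline* mean of the angle — that is the calibration rationale of
the baseline window — while the SD is the *task window's* SD, so interval
widths adapt to how much the subject moved during that task.  (An
alternative reading takes μ from the task itself; the choice is exposed for
sensitivity analysis but baseline-μ is the default and the tested path.)
Boundary frames (angle exactly μ ± k·SD) go to the interval nearer Normal —
a measure-zero choice pinned by a test.  A zero-SD window puts every frame
in Normal.

**Shoulder imbalance.**  The per-frame gap d = Lshoulder_y − Rshoulder_y is
binned into three intervals with cutoffs at μ_d ± 2·SD_d (μ_d from the
baseline, SD_d from the window).  The side labels mirror the head-pose sign
convention: d at or below the lower cutoff is `Shoulder_Imbalance_Right`
(right shoulder sitting low relative to habit… the label names the deviating
direction of d, not a clinical judgement).

**Shrug.**  A frame is a shrug when *both* shoulders are simultaneously
raised beyond one SD: for each shoulder, δ = y − baseline_y must fall below
−1·SD(δ) (negative because y grows downward).  One-sided raises never count.
If either shoulder's δ has zero SD the proportion is 0.

**Shoulder-difference aggregates.**  `Shoulder_Diff` is the window mean of
the signed gap; `Offset_Shoulder_Diff` subtracts the baseline gap first;
the `ABS_` variants take per-frame absolute values before averaging.  All
four are means over the window's *kept* frames — after QC there is no fixed
frame count to sum over.

Invariants enforced by property tests: each proportion family sums to one
(tolerance 1e−9); all 381 names are unique and frozen; a rigid translation
of all coordinates (with the baseline recomputed) leaves every offset,
neck-relative, status, shrug and variation feature unchanged; scaling y
scales the `Shoulder_Diff` family linearly.

## Feature selection

Two selectors run on a training set and the model trains on their union:

* **Mann–Whitney U screen** — two-sided test per feature, case vs control,
  keep p < 0.01.  Exact null distribution for small untied samples,
  tie-corrected normal approximation otherwise.  No multiple-testing
  correction is applied — the screen is a filter, not an inference, and is
  deliberately left uncorrected rather than silently changed.
  Constant features are skipped with a warning.
* **Lasso** — L1-penalized logistic regression on internally standardized
  features, penalty chosen by stratified cross-validated AUROC over a
  log-spaced grid; "selected" means an exactly nonzero coefficient.

Selection *scope* matters.  `global` scope selects once on all subjects and
then evaluates — the classical workflow, but the test folds have influenced
the feature set, which inflates apparent performance.  `per_fold` scope
re-runs selection inside every outer training fold of the nested CV and is
the default for benchmarking; a test asserts the selector never sees a test
subject.

## Models and evaluation

Model families: random forest (100 trees, `max_features=log2`), logistic
regression (standardized), gradient-boosted trees (xgboost when installed,
otherwise the sklearn implementation), and three ensembles over
random-forest base learners — bagging (50 estimators, bootstrap over both
samples and features, `max_features=max_samples=0.5`), AdaBoost, and
gradient boosting.  The bagging-of-random-forests model is the final model
of interest.

Evaluation is repeated stratified nested cross-validation: outer 5-fold
(each subject tested exactly once per repeat), inner 5-fold grid search by
AUROC (grid empty ⇒ the family defaults are used directly), refit on the
outer training fold, scored on the outer test fold at probability threshold
0.5, averaged over folds then repeats.  Repeat r derives every shuffle from
seed + r, so runs are reproducible from one integer.  Metrics: accuracy,
precision, recall, specificity, F1 and AUROC (rank definition, ties ½ —
checked against a brute-force concordant-pair oracle).  Per-repeat spread is
reported alongside the mean because small-cohort nested CV is noticeably
variable across repetitions.

Feature importance for the final model uses permutation importance on a
stratified holdout (drop in holdout AUROC when one column is shuffled,
averaged over repeats).  It answers the same "which features drive the
model" question as Shapley-value attributions while staying model-agnostic
and dependency-free; exact SHAP values are out of scope.

## Synthetic cohort generator

No public recording of this protocol exists, so the generator is first-class
tested code, not a fixture.  Per subject it draws an idiosyncratic upright
posture (angles ~N(0, 2°); coordinates jittered around a neutral seated
geometry), then renders 10 tight-noise baseline frames and three 600-frame
task segments as Gaussian AR(1) series (ρ = 0.8) around per-task means.
AR(1) drift matters: i.i.d. frame noise would make within-window SDs — a
third of the variation family — unrealistically well-estimated.  Marginal
noise SDs default to 2.5°/2.0°/1.5° for yaw/pitch/roll and 0.008 for
coordinates.

Planted case effects (directions chosen to mirror the clinical picture of
asymmetric, rightward-rotated posture with restless shoulders):

* typing-task yaw mean shifted −5° (head turned away from center), plus a
  5% excess of frames far beyond the severe-right cutoff;
* right-shoulder y noise SD 0.019 in cases vs 0.014 in controls;
* left shoulder sitting 0.01 units lower during all tasks (baseline
  unaffected, so offset and imbalance features move).

The manifest lists every feature a planted effect genuinely moves — a
typing-window shift also moves whole-recording features, and a mean shift
moves raw means, offset means and interval occupancies alike — and serves
as ground truth for recovery tests.  Clinical covariates are drawn from
per-group marginals typical of a neck-pain clinic (cases older, shorter,
lighter, more often female); `clinical_group_effect=False` pools the
marginals so only posture carries signal, and `EffectConfig.null()` zeroes
every effect for calibration runs.

Frame corruption: 9% of frames lose all 15 values (missing), and 1% carry
one implausibly low keypoint confidence (uniform 0.05–0.30).  Baseline
confidences are uniform bands per keypoint, so the Tukey fence sits below
the band and fires only on planted frames; the expected QC removal rate is
1 − 0.91 × 0.99 ≈ 9.9%.  A cohort is byte-reproducible from its seed.

What passing on synthetic data does **not** show: real pose-estimator noise
is neither Gaussian nor AR(1) (it has occlusion bursts and identity swaps),
real effect sizes and their correlations are unknown, and the generator's
separability is by construction stronger than a clinical cohort's — the
benchmark validates the *machinery* (calibration, schema, leakage-free
evaluation, effect recovery), not clinical performance.

## Problem sizes and numerical choices

Defaults throughout: cohorts of 27 cases / 33 controls at 1800 frames;
nested CV 5×5 with 5 repeats.  The test suite and the acceptance script use
2 repeats for the bagging model, 5–10 repeats for cheaper models, and
3 permutation-importance repeats — sizes chosen so a full run stays
comfortable on a single CPU while keeping Monte-Carlo error well inside the
asserted margins.  Sample SDs use ddof = 1 everywhere.  Windows with fewer
than two frames have SD 0 (degenerate-rule path).  All randomness flows
from `numpy.random.SeedSequence` spawns of one seed.

## Known limitations

* The pipeline consumes pose-estimator output; it cannot detect estimator
  failure modes that produce confident but wrong keypoints.
* Global-scope selection is provided for fidelity to the classical workflow
  but is leakage-prone; per-fold results are the defensible ones.
* The seven-interval status features assume roughly unimodal within-task
  angle distributions; strongly bimodal behavior (e.g. alternating between
  two screens) inflates the window SD and washes out the intervals.
* Clinical covariates enter as plain numeric features; no effort is made to
  disentangle posture signal from demographic confounding beyond the
  generator's pooled-marginals mode.
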