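# Methods

## Overview

`fatigueml` reimplements, as a tested pipeline, an analysis that classifies
sleep-deprivation-induced performance impairment from eye-tracking (ET) and
face-tracking (FT) indices. The pipeline has six stages:

1. **Synthetic cohort generation** — study-shaped raw data (gaze streams,
   facial-channel probabilities, PVT event logs) with known ground truth.
2. **Index extraction** — 4 ET indices (mean blink duration, blink
   frequency, mean fixation duration, fixation frequency) and 21 FT
   channel means per 10-min session; 25 indices per observation.
3. **PVT scoring** — per-session performance score and per-subject
   normalization.
4. **Labeling** — a statistically derived normal/impaired threshold.
5. **Per-index statistics** — Welch's t and Fisher score per index.
6. **Selection × classification** — five feature-selection regimes crossed
   with 14 classifiers under leave-one-subject-out cross-validation.

## The emulated study design

A cohort of 20 subjects completes a 10-min psychomotor vigilance task (PVT)
every 2 h across a 24-h sleep-deprivation protocol — 13 sessions, the first
at ~1 h awake. Session 1 is treated as a practice session and excluded from
all analyses, leaving 12 analysed sessions per subject (3–25 h awake).
About 3% of sessions are lost to technical malfunction, which the generator
draws uniformly at random per subject-session slot.

During the PVT, stimuli appear at uniform random inter-stimulus intervals
of 2–10 s (measured from the previous response); the subject's reaction
time (RT) is recorded per stimulus, along with false starts (responses with
no stimulus present).

## PVT score and labels

Per session: a **lapse** is RT > 500 ms, a **major lapse** is RT > 1000 ms
(strict inequalities), a **false start** is an extra response. The session
score is

    score = #lapses + #major lapses + #false starts,

so a major lapse, being also a lapse, carries weight 2. The wording that
defines this score admits a disjoint-bins reading (majors counted once); we
use double counting because the score is explicitly constructed to give
"greater weight" to majors. Scores are normalized per subject by the
Euclidean norm of that subject's 12 analysed sessions (missing sessions are
excluded from the norm, not imputed), which removes between-subject scale
differences while preserving each subject's session profile.

The impairment threshold is derived at the group level: a one-way ANOVA of
normalized scores across the 12 sessions, followed by Tukey-Kramer pairwise
comparisons (studentized-range based, with the unequal-n correction;
delegated to `scipy.stats.tukey_hsd`). The **onset session** is the
earliest session whose across-subject mean exceeds that of *every* baseline
session and differs from every baseline session at p < 0.05. The baseline
defaults to the first three analysed sessions (3–7 h awake, inside the
window where performance is stable); requiring significance against *all*
baselines rather than *any one* is the stricter of the two readings the
source design admits and is configurable. The threshold τ is the onset
session's mean normalized score; observations strictly above τ are labeled
**impaired**, all others **normal**. A flat cohort yields an explicit
"no impairment detected" status rather than a threshold.

## ET/FT index extraction

The binocular gaze stream (t, xL, yL, xR, yR) is reduced to a magnitude
signal: per sample, the mean of the two eyes' Euclidean coordinate
magnitudes. **Blinks** are maximal runs where the magnitude falls below a
near-zero threshold for strictly more than 20 ms; a blink ends at the first
sample back above threshold (runs reaching the end of the recording close
at the last sample). The threshold is inherently a per-recording judgement
for real hardware; the default here is 5% of the session's median
magnitude, with an absolute override. Durations are computed in whole
sample periods to avoid float cancellation at the 20 ms boundary.

**Fixations** use the dispersion-threshold algorithm (I-DT) on blink-free
samples of the averaged-eye position: a window grows while
(max−min of x) + (max−min of y) stays within the dispersion threshold
(default 1% of the session's coordinate range) and is emitted if it spans
at least 100 ms. The upstream tooling of the emulated study does not
document its fixation algorithm or whether blink samples were removed
first; I-DT with blink exclusion is the documented, configurable choice
here. Event-free sessions report frequency 0 and a missing mean duration,
imputed as 0 with a warning before model training.

FT channels are consumed as 21 probability time series in [0, 1] (head
pose and interocular distance pre-scaled to [0, 1] by the generator;
min-max rescaling is available for real exports) and summarised by their
arithmetic means.

## Per-index statistics

Welch's unequal-variances t-test compares each index between classes with
the sign convention (normal − impaired): indices elevated under impairment
(e.g., blink duration) get negative t. Degrees of freedom follow
Welch–Satterthwaite and are rounded to integers only in the printed report.
The Fisher score uses the grand-mean form

    F = [n₀(μ₀−μ)² + n₁(μ₁−μ)²] / [n₀σ₀² + n₁σ₁²]

with a 1e-12 variance floor; the two-class form (μ₀−μ₁)²/(σ₀²+σ₁²) is
available behind a switch since the source analysis does not name its
variant. The ranked report flags significance at α = 0.05 and at the
Bonferroni level α/25 = 0.002.

## Feature selection

The feature budget follows the one-parameter-per-20-observations rule:
floor(n/20), i.e. 12 for a complete 240-observation study. The emulated
study quotes 12 although only 233 observations were usable
(floor(233/20) = 11); the budget is therefore an explicit parameter.
Five regimes:

- **all** — control, every index, no budget;
- **t-filter** — indices with p < α, ranked by |t|, truncated to budget;
- **Fisher filter** — top-budget indices by Fisher score (name-lexicographic
  tie-break);
- **SFS** — greedy forward selection maximizing the classifier's balanced
  accuracy, stopping at the budget or when no candidate improves
  (lowest-position tie-break);
- **GA** — genetic algorithm over 25-bit subset chromosomes: fitness =
  objective after budget repair (random set bits cleared), tournament
  selection (size 3), uniform crossover (p = 0.8), per-bit mutation
  (p = 0.02), elitism 2. Defaults population 40 × 50 generations; grid runs
  use smaller, documented settings per run. Fully seeded.

The wrapper objective is the balanced accuracy of the classifier under a
grouped (by-subject) evaluation of the data handed to the selector, with
undersampling and standardization inside each training split; splits and
seeds are fixed per evaluation so all candidate subsets are compared on
identical data. Two scopes:

- **nested** (default): selection re-run inside each outer training fold;
  the held-out subject never influences its own feature set. The inner
  objective is grouped k-fold CV (k = 3 by default) on the training
  subjects — the source design fixes "training portion only" but not the
  inner protocol.
- **global** ("study mode"): selection once on the full dataset before the
  outer loop, as the source analysis most plausibly did; with
  `objective_mode="loso"` the wrapper maximizes the exact leave-one-
  subject-out quantity that is afterwards reported. This is the mode used
  to replicate the selection-method ordering (wrappers ≥ filters ≥ all),
  which is partly a consequence of optimizing the reported metric
  directly; the nested mode gives the honest generalization estimate.

## Classifier grid and evaluation protocol

14 classifiers: SVMs with linear/quadratic/cubic/Gaussian kernels
(polynomial kernels with coef0 = 1; Gaussian kernel scale from the median
pairwise-distance heuristic), LDA, a ridge-regularized QDA (class
covariances S + 10⁻³·tr(S)/d·I, keeping the quadratic boundary defined
when a class has fewer rows than features), KNN (k = 5, Euclidean), a CART
tree (Gini, unpruned), Gaussian Naive Bayes, kernel-density Naive Bayes
with box/Epanechnikov/triangular kernels (per-feature 1-D KDE, Silverman
bandwidth), and MLPs with one (10) and two (10, 5) hidden layers, logistic
activations. The original analysis ran in another numerical environment
with unstated defaults; these hyperparameters are this package's
documented defaults and are all configurable per classifier id.

Protocol per (classifier, selector) cell: leave-one-subject-out CV; for
each held-out subject the remaining subjects' rows are balanced by random
undersampling of the majority class (minority untouched, without
replacement), z-scored with training-fold statistics only, used to train,
and the held-out subject's rows are predicted. Because undersampling
discards rows at random, the loop repeats for 5 iterations; confusion
counts are pooled over all subjects and iterations ("aggregated" is not
further specified in the source; pooling weights subjects by row count and
is exactly reconstructible — a metric-averaging mode exists). Metrics with
impaired as the positive class:

    sensitivity = TP/(TP+FN)        specificity = TN/(TN+FP)
    balanced accuracy = √(sens·spec)    bias = sens − spec

Every cell satisfies BA = √(sens·spec) to 1e-12, the AM–GM bound
BA ≤ (sens+spec)/2, and pooled-count conservation; the entire grid is
bit-for-bit reproducible under a fixed master seed.

## Synthetic-data generator

The generator is first-class, tested code; its defaults encode the study
conditions above. Per subject a latent profile is drawn (baseline RT
lognormal median 260–300 ms, shape 0.10–0.18; lapse base probability
0.01–0.04; blink duration base 120–180 ms; blink rate 8–14/min; fixation
duration base 220–300 ms; per-channel FT means jittered around population
values) together with an impairment onset in hours awake
(N(17, 3) clipped to [11, 23], centred on the group onset the emulated
study reports). Past onset, the impairment level grows
linearly with hours awake (the onset session itself carries one
inter-session spacing of drive so the first affected session is
measurably elevated) and drives:

- **lapse probability**: min(1, base + slope·level), slope 0.025–0.05 per
  hour; lapse RTs are 500 ms + Exponential(≈280 ms), so ~17% of lapses are
  major — mirroring the empirical pattern that scores are flat for the
  first ~12 h awake and rise steeply after ~17 h;
- **blink duration/frequency and fixation duration** (slopes per
  impairment-hour, with session-level lognormal jitter);
- **FT channel means**, shifted by signed per-channel amounts saturating
  6 h past onset, with the directions of the real class differences (eye
  closure, brow raise, mouth open up; smile, head roll down) and
  magnitudes tapering to zero across channels.

Effect sizes are not reported per index by the source beyond t-scores, so
the generator's magnitudes were calibrated once against that t-score
table: with the defaults, the strongest synthetic index (blink duration)
lands near |t| ≈ 7–10 at n ≈ 233, roughly 12 of 25 indices are significant
at 0.05 and ~9 survive Bonferroni, and the class split is ≈ 145/86 —
close to the reported 153/80. Gaze is a fixation–saccade process
(piecewise-constant centres, 1-unit jitter, ≥60-unit saccades) with blinks
inserted as (0, 0) signal-loss runs aligned to sample boundaries; the
generator keeps a private ledger of true blink/fixation events and true
onsets used only as test oracles. RT distribution shape, blink encoding
and missing-session mechanism are modelling choices (the source reports
none of them); only threshold-crossing counts matter downstream.

What the generator does *not* emulate: circadian modulation (impairment is
monotone in hours awake), pupil dynamics, head-motion artifacts,
inter-channel FT correlations, and RT sequential effects. Passing tests
therefore demonstrate correctness of the pipeline's machinery and
recoverability of planted structure — not that the classifiers would reach
the same accuracies on real recordings.

## Numerical and reproducibility choices

- All randomness flows from one master seed through per-(subject, session,
  signal) substreams (`numpy` `SeedSequence` spawn keys), so enlarging the
  cohort does not perturb earlier subjects' draws.
- Run durations are computed in whole sample periods; the >20 ms blink
  rule is strict, so an exact 20 ms run (one sample at 50 Hz) is not a
  blink.
- Standardization uses training-fold statistics only; zero-variance
  features get unit scale.
- Degenerate cases: all-zero score vectors return zeros with a warning;
  single-observation ANOVA groups are excluded with a warning; empty-event
  sessions impute mean durations as 0 with a warning; cell failures in the
  grid are recorded and skipped, never silently zeroed.

## Problem sizes used in tests and the acceptance script

The test suite and `scripts/acceptance.py` exercise the pipeline at sizes
chosen for desk-scale runs: unit and property tests use 8-subject cohorts
with 120 s sessions at 25 Hz gaze sampling (cohorts small enough that the
group-level threshold derivation still behaves; below ~8 subjects the
Tukey-based onset grows erratic and the impaired class collapses); the
acceptance script runs the full 20-subject protocol shape for generation,
scoring, labeling and index statistics, and evaluates the classifier grid
on a 12-subject subset with global selection, the LOSO wrapper objective
(one undersampling draw), GA population 12 × 8 generations, and MLPs
capped at 100 epochs. The properties asserted
(oracle equivalence, planted-structure recovery, protocol invariants,
selection-method ordering) are size-independent; the reduced sizes widen
Monte-Carlo error, which the stated tolerances absorb.

## Known limitations

- The synthetic cohort's class separation, although calibrated to the
  reported t-score magnitudes, yields grid accuracies somewhat above the
  reported tables (stronger features, no label noise); grid numbers are
  comparable in ordering, not magnitude.
- Tukey-Kramer p-values rely on the studentized-range distribution's
  equal-variance assumption; late sessions are more variable, which the
  source analysis shares.
- The kernel Naive Bayes uses per-feature product densities with a fixed
  Silverman bandwidth; no cross-validated bandwidth selection.
- The nested wrapper objective (grouped 3-fold CV) is noisy at small n;
  nested-scope wrapper columns can trail filter columns on small cohorts —
  the known cost of leakage-free selection.
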