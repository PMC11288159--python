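# Methods

## Problem setting

Direct RNA nanopore sequencing reads native RNA strands; a modified base
such as 5-methoxyuridine (5moU) changes how the pore-occupying 5-mer
modulates the ionic current, so modification status is, in principle,
readable from signal statistics at and around the modified position. The
package models this at the level of *re-squiggled events*: per (read,
reference position) summaries — normalized current mean and median,
within-event current standard deviation, and dwell time in raw samples —
supplied as a TSV. Producing that table (basecalling, alignment, signal
re-assignment) is upstream tooling and out of scope; everything downstream
of it is implemented here.

## Event model and read filter

Coordinates are 0-based on the reference transcript; only the template
strand exists, and U is written T. Read length is measured as the aligned
reference span (max − min position + 1): the event table carries no
unaligned bases, so the basecalled length is unavailable by construction.
The default threshold (≥ 200 bases, inclusive — 200 itself is admissible)
suits real transcript-scale data; the bundled smoke/pipeline configurations
use short synthetic templates (40–60 nt) and scale the threshold to 20 so
the filter stage remains exercised.

## Feature extraction

A window is an NNUNN 5-mer: reference position p with base T and
2 ≤ p ≤ L−3. A read contributes the window only when all five positions
p−2…p+2 have events; windows with gaps are dropped rather than imputed,
because an incomplete signal context cannot be verified. The 20 feature
columns are ordered mean₁…₅, mdintense₁…₅, sd₁…₅, L₁…₅. The 5-mer identity
comes from the reference, not the basecall, matching how re-squiggling
anchors signal to reference positions.

Three feature-selection schemes are supported: `all` (20 columns), `mid`
(central position, 4 columns), and `midn` (centre and one neighbour on each
side: 4 statistics × positions 2–4 = 12 columns). A 15-column variant of a
centre-plus-neighbours scheme is sometimes quoted elsewhere; 15 is not
divisible by the four per-position statistics, so this package implements
the arithmetically consistent 12-column reading.

## Mann-Whitney feature tests

Per feature, modified vs unmodified values are compared with the two-sided
Mann-Whitney test. The statistic U counts pairs with the modified value
higher, ties counted half; it doubles as the effect size (U/(n₀n₁) is the
common-language effect size). For tie-free samples with combined n ≤ 10 the
p-value is exact (null U distribution); otherwise the normal approximation
with tie correction and continuity correction is used, with p = 1 when the
rank variance is zero (fully tied data). The exact/approximate switch at
n = 10 keeps the exact path cheap while the test suite uses it to validate
the approximation. Raw p < 0.05 is the significance convention; a
Benjamini–Hochberg q-value column is emitted as clearly-separated
supplementary output only. Within each window position, the most
significant of the four statistics is flagged for display.

## Classifiers

One binary classifier per expressed 5-mer, algorithm ∈ {svm,
random_forest, gbt}, scheme ∈ {all, mid, midn}. Hyperparameters are chosen
by stratified 5-fold CV maximizing AUROC over small documented grids
(`models.DEFAULT_GRIDS`: SVM C ∈ {1, 10} with RBF kernel and standardized
inputs; forest depth ∈ {∞, 8} at 200 trees; boosting depth ∈ {3, 6} at 150
trees, learning rate 0.1). The winning configuration is refit on the full
dataset; the per-fold metrics of the winner form the model's CV report
(mean ± sd). Choices that matter:

- **Probabilities.** SVMs get Platt-style sigmoid calibration on internal
  CV folds; forests and boosting are used natively. Profiling requires
  comparable [0,1] outputs from all three.
- **Imbalance.** Class weighting (`class_weight="balanced"`,
  `scale_pos_weight`) rather than resampling: resampling would distort the
  calibration that the stoichiometry estimator depends on.
- **Minimum coverage.** Training requires ≥ 20 rows per class per 5-mer
  (5-fold stratified CV needs several per class per fold); lower-coverage
  5-mers are skipped and reported.
- **Determinism.** All estimators are seeded; per-5-mer seeds derive from
  the root seed and a CRC of the 5-mer string, so multi-5-mer training is
  reproducible and independent of training order and parallelism.

## Evaluation metrics

Implemented from the closed forms so oracles can check them: AUROC as the
rank formulation P(score⁺ > score⁻) + ½P(tie); AUPRC as average precision
with stepwise integration at distinct thresholds (no linear interpolation,
which is optimistic); accuracy, precision, recall, F1, and Matthews
correlation from confusion counts at threshold 0.5 (score ≥ 0.5 ⇒
modified; ties positive). Zero-denominator ratios return 0 with an explicit
degenerate flag instead of NaN, so aggregated report tables never silently
propagate missing values.

## Profiling and stoichiometry

Models applied along a read score every window whose 5-mer has a trained
model; unmodelled 5-mers are counted and skipped (training is strictly
per-5-mer; a pooled fallback would mix incomparable signal contexts). The
sample-level modified fraction is estimated as the proportion of window
probabilities ≥ 0.5. This thresholded estimator is unbiased only insofar as
the classifiers are calibrated and accurate; the mean probability is
reported beside it as a smoother alternative. Mixture validation treats
each window as an instance (read-level framing); a per-read mean aggregate
is available as an option. Curated mixtures contain exactly
round(n·a/(a+b)) modified reads (half-values rounded away from zero),
sampled without replacement and seed-reproducible, with ground-truth labels
retained.

## Synthetic data generator

The simulator emulates exactly the statistical structure the pipeline
consumes:

- **Pore response.** Each of the 1024 5-mers gets, deterministically from
  the seed, a baseline current mean (spread 1.0 across 5-mers, z-score-like
  scale), an event-to-event noise sigma (uniform 0.25–0.45), and a
  within-event current-sd level (uniform 0.15–0.35). Dwell is log-normal
  (log-mean 2.2 ≈ 9 samples, log-sd 0.5) — values chosen once as plausible
  for normalized direct-RNA event data.
- **Events.** mean ~ N(μ + δ·σ, σ); median = mean + N(0, 0.15 σ) (the
  pipeline consumes event summaries, not raw samples, so the median is
  modelled as a correlated copy rather than recomputed from a squiggle);
  sd = level × scale × lognormal jitter; dwell = round(lognormal × scale),
  floored at 1.
- **Modification effect.** At every template T, a `ModEffect` applies an
  additive mean shift (units of the local σ) and multiplicative sd/dwell
  scales at offsets −2…+2. Neighbour effects default to half the central
  effect, reflecting attenuated-but-real perturbation beyond the modified
  base. Effects from adjacent Us compose (deltas add, scales multiply).
  Presets: `null` (no effect), `weak` (0.5 σ centre), `strong` (2 σ centre,
  1 σ neighbours, 1.25× sd, 1.5× dwell).

What the simulator does **not** model: raw squiggle segmentation,
basecalling and alignment error, re-squiggle mis-assignment, coverage
gaps beyond random read spans, or k-mer-composition biases of real pores.
Passing tests on synthetic data therefore demonstrate the correctness and
internal consistency of the statistical machinery under its own
assumptions — an upper bound on, not a measurement of, real-flowcell
performance.

## Validation design and problem sizes

The validation suite (tests plus `scripts/acceptance.py`) runs at desk
scale, chosen to make each check statistically meaningful while keeping the
whole suite in minutes on one CPU: exact enumeration oracles for the
Mann-Whitney p (all tie-free size splits with combined n ≤ 10), AUROC
(1000 random instances, n ≤ 50) and scalar metrics (all 1295 confusion
matrices with entries ≤ 5); null calibration with 20 independent
zero-effect simulations of 500 windows per class (the mean CV AUROC over
seeds is the calibration summary — a single seed's null AUROC fluctuates
by ±0.02 sampling noise — with the Mann-Whitney false-positive band
0.01–0.10 fixed a priori around the nominal 5 %); strong-effect detection
at 500 windows per class; and mixture recovery from ~2000 windows per
ratio over a 60-nt template with 120 training reads per class. Pipeline
determinism is audited by hashing all text outputs (manifests, TSV, JSON)
of two same-seed smoke runs; serialized model binaries are excluded from
the byte comparison (pickle bytes are not a semantic equality check) and
model determinism is instead asserted on CV reports and predictions.

## Known limitations

- Event tables are the entry point; FAST5/POD5 and BAM ingestion are
  deliberately out of scope.
- Per-5-mer training means rare 5-mers (below the per-class minimum) are
  never scored; sparse templates can leave coverage holes in profiles.
- The thresholded stoichiometry estimator inherits classifier
  miscalibration; at accuracy ~0.95 its bias is within a few percentage
  points, but it degrades gracefully toward 0.5 as separability drops.
- Only 5moU-style single-modification, fully-modified-training-pool designs
  are supported; co-occurring modifications are not modelled.
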