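# Methods

This note records the modeling conventions, numerical choices and known
limitations behind `pentrace`. Everything stated here is computed by the
test suite or `scripts/acceptance.py`; nothing is quoted from external runs.

## Signals and segmentation

A recording is a uniformly-or-unevenly sampled stream of
`(x, y, t, on_surface, azimuth, altitude, pressure)` tuples, `t` in integer
milliseconds, coordinates in device units with y increasing upward, 0-based
sample indexing. Validation rejects non-increasing or duplicate timestamps
outright (derivatives need strictly increasing time; silently merging
duplicates would hide device faults), requires a binary contact flag, at
least two samples and at least one on-surface sample. Pressure, azimuth and
altitude are read for in-air samples but treated as undefined there: the
in-air feature set omits them entirely.

A *segment* is a maximal constant-contact run. Single-sample segments are
retained with zero geometry rather than dropped — dropping them would
silently change pen-lift counts. A *pen lift* is a surface→air flag
transition; for in-air feature vectors the mirrored air→surface count is
used, so the same scalar slot is meaningful for both movement types.

## Kinematics

Derivatives are first-order forward differences on actual timestamps, never
across a segment boundary; a segment of `n` samples contributes
`max(n − k, 0)` samples to a k-th-order signal. No smoothing is applied by
default (`smoothing_window`, in samples, is exposed and defaults to 0): the
synthetic data is band-limited by construction, and any fixed filter would
be one more unstated convention.

Speed is the Euclidean norm of the component derivatives. Acceleration is
the derivative of scalar speed (change of speed over time) — not the norm of
the component-acceleration vector — and jerk the derivative of that.
Vertical/horizontal *velocity* is summarized as a magnitude (overall change
of per-axis position), while component accelerations and jerks
differentiate the *signed* component velocities; whether summaries should
use signed or absolute components is genuinely open, so
`signed_component_velocity=True` switches the convention. Published feature
lists in this field do not always itemize component accelerations; they are
included here because the 133-feature arithmetic (12 × 7 + 6 × 5 + 19)
requires twelve vector signals, and horizontal-acceleration percentiles are
among the features such studies report as relevant.

Summary statistics are fixed for reproducibility: population standard
deviation (÷ n), percentiles by linear interpolation between order
statistics (numpy's default). The 5th/95th percentiles accompany min/max
because raw extrema are dominated by single-sample spikes. Local extrema of
a signal are interior sign changes of the first difference after collapsing
equal-value plateaus, so a flat peak counts once.

## Row-drift ("inclination") features

For each per-segment y statistic (min, median, mean, max): the signed
difference first-segment − last-segment, the signed difference
second − penultimate, and the population variance across all segments.
Signs are kept (first minus last) because the drift *direction* — rows
climbing vs sinking — is itself informative; no established sign convention
exists, so this one is documented here. Degenerate fallbacks return 0 (all
twelve with < 2 segments; the pre-end differences with < 4 segments, where
"second" and "penultimate" would otherwise alias the end segments) and the
affected names are reported in the vector's degeneracy flags rather than as
missing values, keeping feature matrices finite for the classifiers.

Vertical/horizontal *length* of a segment is the summed absolute per-axis
step (a path-length component), distinct from *height*/*width* which are
bounding-box extents — both appear as separate features, so they must be
distinct quantities.

## Feature vectors

The registry fixes name and order: 12 signals × 7 statistics, then 6
geometry measures × 5 statistics, then 19 scalars — 133 on-surface;
dropping pressure/altitude/azimuth summaries leaves 112 in-air. A session
merges task-major in template order, the sentence's in-air block last:
8 × 133 + 112 = 1176. In-air extraction is restricted to the sentence task
in the merged vector (the short tasks' in-air content adds nothing but
noise); `extract_task_features` will nevertheless compute an in-air vector
for any task on request.

Standardization is per-feature z-scoring with population statistics;
zero-variance columns are flagged at fit time and map to exactly 0.
Feature-relevance reporting is a pluggable hook: `feature_weight_report`
accepts any externally computed weight vector keyed by registry names and
ranks it, optionally summing weights of the same base feature across tasks;
no feature-selection algorithm is implemented here.

## Evaluation protocol

Stratified 10-fold cross-validation, repeated 10 times with reshuffled
folds, all randomness derived from one seed through independent
`SeedSequence` streams (bit-for-bit reproducible). The standardizer is
fitted on the training folds of each split only — fitting on the full
matrix before splitting would leak test-set location/scale into training,
and the null-cohort calibration below verifies the protocol sits at chance.
Fold predictions are pooled per repeat before computing the metric triple:
with ~6 positives per fold, per-fold sensitivity is far too unstable to
average. Reported ± values are the population std across the 10 repeats.

Classifier defaults are the grid-search optima for this kind of cohort:
AdaBoost with 340 stumps (base-estimator depth is the library default,
depth 1), random forest with 60 trees / `min_samples_split` 4 /
`max_features` 5, SVM with C = 4 and γ = 2⁻⁹. Grids: AdaBoost estimator
counts 20..500 step 20 (25 points); RF 25 × 4 × 5 = 500; SVM C and γ over
odd powers of two 2⁻⁹..2⁹ (100 points). Grid search evaluates every point
with a configurable CV protocol and breaks ties deterministically (first in
enumeration order). When enabled inside the benchmark it runs on the full
row matrix with a 1-repeat protocol by default; the headline benchmark uses
the fixed optima so it stays cheap and deterministic.

## Synthetic cohorts

Strokes follow a minimum-jerk position law (bell-shaped speed) along a
straight advance, arched perpendicular by `letter_height·sin(πτ)` so traces
look like letter bodies; in-air transits hop between strokes the same way
with zero pressure. Hand tremor is moving-average-smoothed white noise
added to both coordinates with amplitude `tremor_base × tremor_gain`
(default base 0.06 device units against a 8-unit arch); pressure rides a
per-subject baseline (60 ± 5) with a within-stroke bell modulation; azimuth
and altitude wander slowly around per-subject set-points. Sampling is
100 Hz by default — a typical tablet rate; nothing downstream assumes a
fixed rate. Per-task stroke counts grow with task length (4–6 for the
single letter up to 26–34 for the sentence); the "fast" variants multiply
stroke speed by 1.6.

The dysgraphia effect profile targets exactly the feature families known to
discriminate: extra pen lifts (Poisson, +3/task at full strength), a
baseline random walk across strokes (σ = 6 units, about a third of letter
height), tremor gain 2 (raising local speed-extrema density), a −15-unit
pressure offset (pulling minimum pressure down), and 15% slower strokes.
`graded_effect(s)` interpolates linearly; the weak/medium/strong presets
use s = 0.15 / 0.4 / 1.0. Cohort demographics mirror the target population:
120 subjects, 57 labeled, ages uniform 8–15, two-thirds boys, 16/120
left-handed. Each subject consumes an independent child RNG stream, so
cohorts are reproducible and locally editable.

What the generator does *not* emulate: real letterforms or orthography,
age-dependent maturation, correlated task-to-task fatigue, device
quantization and dropout, and the heterogeneity of real dysgraphia (which
is not one construct). Passing the planted-effect tests therefore shows the
*pipeline* recovers group structure it is pointed at — it says nothing
about classification accuracy on recorded clinical data, which depends on
effect sizes no simulation fixes.

## Calibration contracts and problem sizes

Three behavioural contracts pin the pipeline end to end, each on a
120-subject cohort with full 10×10 CV over the 1176-feature merged matrix:
a null cohort (identical distributions for both groups) must classify in
[40, 60]% — this is also the leakage canary; the strong profile must reach
≥ 90%; and accuracy must be non-decreasing across the three graded profiles
within ~2 points (about one across-repeat std). These runs use the
random-forest configuration, whose runtime is essentially independent of
class separability; boosting with 340 stumps only early-stops on separable
data, which would make the null run disproportionately expensive without
changing its outcome — both classifiers sit at chance on the null cohort,
as the acceptance script recomputes on every run.

## Known limitations

* The 133-feature decomposition is reconstructed from the printed totals
  and the feature table; the registry makes it auditable name by name.
* Acceleration-as-derivative-of-speed discards the centripetal component;
  the alternative (norm of component accelerations) is not offered.
* Forward differences are first-order accurate and noise-amplifying for
  jerk; with real (noisier) data a smoothing window should be set.
* The SVC dialect covers the common text corpora; binary vendor formats are
  out of scope.
* Classification benchmarks on synthetic cohorts saturate quickly: with
  1176 features and many independently planted channels, even the weak
  profile is nearly separable at n = 120. Monotonicity, not absolute
  accuracy, is the meaningful synthetic readout.
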