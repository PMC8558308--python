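# Methods

## The synthetic study

No public recordings exist for this paradigm, so the package ships a
generator whose defaults *are* the study conditions: four groups (younger /
older × less creative / creative, 12 subjects each at full scale), one
six-block oddball session per subject (80 trials per block: 8 deviant
butterflies, 36 unambiguous and 36 ambiguous standard portraits; 48/216/216
per session), 300 ms stimuli, ISIs drawn uniformly from
{1500, 1550, 1600, 1650, 1700} ms, 1000 Hz sampling on a 32-channel extended
10-20 montage plus bipolar HEOG/VEOG.

**Sequences.** Ordering constraints — 4–12 standards between consecutive
deviants, at most 3 same-type standards in a row — are satisfied by
constraint-aware sequential sampling with rejection and a 10,000-retry budget
per block; an unsatisfiable specification raises an explicit error. The
spacing constraint is enforced within blocks; a block break (feedback screen)
is taken to interrupt the deviant-spacing count, as it interrupts the
stimulus stream. An independent scanner (`check_sequence`) re-derives all
invariants from the emitted labels and shares no state with the generator.
Because the jitter distribution is unstated in the design, ISIs are uniform
on the 50 ms grid — the minimal assumption — and sequences are re-randomized
per subject by default (both configurable).

**Evoked model.** Each component is a Gaussian time course
`a · exp(−(t − μ)² / 2σ²)` times a fixed per-channel topography
(max |weight| = 1). Defaults: a P1-like positivity (μ = 100 ms, σ = 18 ms,
5 μV, lateral parieto-occipital), an N1-like negativity (μ = 160 ms,
σ = 24 ms, 7 μV, broad parieto-occipital) and a late positivity (μ = 400 ms,
σ = 130 ms, 4 μV). These place every component inside the measurement
windows used downstream. Components superpose linearly, so the *waveform*
extrema — the ground truth the measure tests compare against — are those of
the summed curve, not of individual components (the default P1 peak of the
sum sits at 98 ms, not 100 ms; tests that assert latency identity use an
isolated component).

**Effects.** Condition and group differences are additive boxcar shifts
(`EffectSpec`): a window, a channel subset, a μV delta, and selectors for
condition, age and creativity. A noiseless simulation therefore has class
means exactly equal (to float accumulation, ~1e-13) to the deterministic
component sum plus applicable deltas — the identity every recovery test
rests on.

**Noise.** Default: independent Gaussian noise per channel, low-pass
filtered at 30 Hz (4th-order Butterworth applied causally with a 300 ms
pre-roll so the filter transient never reaches the epoch), then rescaled so
`noise_sd` (default 10 μV) is the *post-filter* per-sample standard
deviation. An optional spatial stage mixes channels with a distance-based
Gaussian kernel (λ = 4 cm, positions from the standard 10-05 montage; rows
normalized to preserve variance) for realistic inter-electrode correlation.
A `white` model is available for diagnostics. Noise is generated in float32
for speed; identical (config, seed) gives bit-identical output.

What the generator does **not** emulate: ocular/muscle artifacts and their
ICA-based removal (out of scope; the rejection stage sees clean data unless
artifacts are constructed explicitly), drifting electrode impedances,
1/f background spectra, biophysical volume conduction (the spatial kernel is
a stand-in), and trial-to-trial latency jitter of components. Passing tests
therefore validate the *pipeline arithmetic and inference calibration*, not
robustness to every property of real EEG.

**Creativity scores.** Raw figural-test scores are drawn per participant ×
subtest from normal distributions around plausible group means (fluency
resampled until positive, others clipped at 0; creative strengths drawn once
per participant). With the default 25% coefficient of variation the clipping
bias is negligible (<1e-4 relative).

## Preprocessing

Kaiser FIR design derives the attenuation from β (β = 0.1102(A − 8.7) above
50 dB, the standard intermediate branch below) and the tap count from
N ≈ (A − 7.95)/(2.285 Δω), forced odd. The 30 Hz/β = 12.2653/10 Hz design
implies 120 dB stopband attenuation (781 taps at 1000 Hz); the
0.1 Hz/β = 5.6533/0.2 Hz high-pass implies 60 dB (~18,000 taps — meaningful
only for continuous real recordings, which is why the synthetic path never
needs it). Zero-phase application is a single centred pass of the symmetric
taps (exact group-delay compensation), matching a non-causal FIR;
forward-backward filtering is available as an option. The first/last
half-filter-length samples are edge-contaminated and epochs never overlap
recording edges.

Epochs live on a half-open grid: sample k at −100 + k·(1000/fs) ms, so a
[−100, 1000) ms epoch at 1000 Hz has 1100 samples and every fourth sample
gives exactly 275 decoded points. All analysis windows are half-open for the
same reason (no double-counted boundaries).

Artifact rejection: an epoch is dropped if any scalp channel's peak-to-peak
range exceeds 100 μV, or if the minimum-change criterion fires. Whether
"smaller than 2 μV voltage change" applies per channel or per epoch is
ambiguous; the default requires *every* analyzed channel below 2 μV (a
flat-recording detector — a single quiet channel should not discard a valid
epoch), with the stricter any-channel reading selectable
(`RejectionRule(min_mode="any")`). EOG channels are excluded from the ranges
by default. Rejection is idempotent.

## ERP measures

All measures operate on ROI-averaged evoked waveforms (ROI = unweighted
channel mean; the peak search runs on the ROI series, not per electrode).
P1: largest positivity in [30, 130) ms, amplitude = mean over ±5 ms around
the peak. N1 is quantified only through peak-to-peak differences, since a
superimposed positivity makes its absolute amplitude group-dependent:
P1−N1 and the (largest positivity in [200, 300) ms) − N1, the latter
mirroring the P1 convention because the extremum rule for the 200–300 ms
positivity is not otherwise specified. Peak-to-peak values are reported as
positive extremum minus negative extremum, so a genuine deflection pair is
positive. Argmax ties resolve to the earliest sample (latency-conservative);
flat windows are flagged. Window means use point samples on the half-open
window.

The mixed ANOVA is computed from the classical balanced-design
sums-of-squares decomposition (inclusion–exclusion over cell totals, subject
nested in between-cells): between effects tested against
subjects-within-groups, any effect involving within-set W against
W × subjects-within-groups. Only balanced complete designs are accepted —
the design is balanced by construction, and silently unbalanced input is an
error, not a fallback. Degrees of freedom are uncorrected (no sphericity
adjustment, matching the reporting convention of the design); effect size is
partial eta squared. The implementation is validated against pingouin
(1 between × 1 within), statsmodels AnovaRM (2 within) and the F = t²
identity. Tukey HSD uses the studentized range with the error term matching
the factor set (validated against scipy's one-way implementation).

## Decoding

Features are the 27-electrode scalp distribution at one decoded time point.
Trials of each class are randomly partitioned into 3 equal sets (remainder
discarded at random), set means form the 3 × 2 × 27 exemplar matrix, and
each fold trains on 2 sets/class and tests on 1. Partitions are drawn once
per iteration and shared across time points (set construction precedes the
per-timepoint loop); per-iteration seeds are spawned from the master seed,
so results are reproducible while iterations stay independent.

The classifier is a linear soft-margin SVM inside a generic
error-correcting-output-codes wrapper (±1/0 code matrix, one-vs-one by
default; with two classes this is a single binary SVM, and the wrapper is
tested for equality with a plain SVM). Hyperparameters are unstated in the
design, so the standard small-sample choices apply: linear kernel, C = 1,
features z-scored per electrode with training-set statistics (test exemplars
transformed with the training parameters; a zero training SD falls back to
1). The quadratic program is solved by a compact Platt-SMO routine
(numba-compiled; ~10 µs per 4-exemplar fit, which is what makes the
replicated group analyses tractable) whose predictions are checked against
an independent reference SVM and a brute-force margin-search oracle. The
intercept falls back to the midpoint of the KKT-feasible interval when all
multipliers are at bounds.

Accuracy at each point aggregates 2 classes × 3 folds × 50 iterations = 300
attempts, then a 5-point centred moving average (±8 ms) is applied *after*
aggregation; edge windows shrink so the series keeps 275 points. Per-attempt
predictions are stored so permutation inference can re-use decoder outputs
without retraining.

## Cluster permutation inference

Pointwise one-sample t (df = n−1) against chance 0.5, one-tailed by default
(only above-chance decoding is meaningful; two-tailed by flag). Zero-variance
points get t ∈ {+∞, 0, −∞} by the sign of the mean-minus-chance, are
flagged, and are excluded from cluster formation. Clusters are maximal runs
of p < 0.05 points scored by summed t. The null permutes at the decoder
output stage: within each subject, the assignment of true labels to test
predictions is shuffled per fold × iteration, with one swap decision shared
across time points — this preserves each subject's temporal correlation
structure, which is what makes the permutation distribution exchangeable
with the observed smoothed series. With two classes a swap simply flips the
correctness of both attempts in a fold, so the permuted series is computed
in closed form from stored fold-pair accuracies. Each permuted dataset is
smoothed identically, re-tested pointwise, and contributes its maximum
cluster mass; p = (1 + #{null ≥ observed})/(1 + n_perm), never exactly zero.
Default n_perm = 1000 (p resolution 0.001).

Family-wise-error calibration at desk scale uses a decoder-output-level null
generator (`simulate_null_predictions`): predictions are signs of a latent
Gaussian process (white noise smoothed with σ = 2 decoded samples ≈ 8 ms,
matching the correlation the 30 Hz low-pass induces), drawn independently of
the true labels — a valid null with realistic temporal structure that makes
200-replicate calibration runs affordable where 200 full decoding pipelines
would not be.

## Group statistics and Creativity Index

Window aggregation averages the *smoothed* series (the series the cluster
statistics test; the raw series by flag) over five half-open 100-ms windows,
25 decoded points each; the aggregates enter the Age × Creativity × Time
mixed ANOVA via the same machinery as the ERP measures.

Creativity scoring normalizes the five variables (F, O, E, C, CS) by their
age-group means first and forms the fluency ratios afterwards
(CR1 = (F + O/F + E/F)/3 from the circles subtest;
CR2 = ((E/F + C/F)/2 + F + O/F)/3 from incomplete figures — the published
bracketing of CR2 is typographically unbalanced, and this reading mirrors
CR1's structure). CS enters CI = (CR1 + CR2 + CS)/3 undivided, as it appears
bare in the composite. Consequences asserted by tests: the all-at-mean
participant has CI = 1 exactly; rescaling all of an age group's raw scores
leaves every CI unchanged; group-mean CI need not be 1 (the ratios are
nonlinear). Extreme-group selection sorts stably by (CI, participant id).

## Problem sizes

The analysis drivers default to 3 subjects per group (full scale via
`--n-per-group 12`). The test suite runs replicated checks at reduced scale
as its own design choice: null calibration uses 12 full-pipeline subjects
for the grand-mean check plus 200 output-level null datasets (n_perm = 200)
for family-wise error; the power check uses 50 replicates of 10 subjects
with two-block sessions (72 trials/class), 10 decoding iterations and 200
permutations — at these sizes the injected +2 μV effect is detected in
essentially every replicate, so the 80% bound is conservative. The
acceptance script runs the full 12-subject, 216-trial, 50-iteration null
pipeline.

## Known limitations

- The simulator's noise is stationary and Gaussian; decoding accuracies on
  real EEG will be lower and more variable than on these synthetics.
- ICA-based ocular correction is a pass-through hook; the rejection stage is
  the only artifact defense implemented.
- The averaged-set pipeline is implemented for the two-class design; the
  ECOC wrapper itself is k-class but `run_decoding` raises for k > 2.
- Peak-to-peak measures are reported positive-minus-negative; analyses that
  expect the opposite sign convention should negate them.
- `mixed_anova` requires balanced complete data by design; it does not
  implement Type-II/III decompositions for unbalanced tables.
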