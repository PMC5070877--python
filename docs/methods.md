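# Methods

`tempomem` analyses absolute-tempo (AT) memory experiments in which
participants learn a labelled scale of metronome tempi and later either
*identify* a heard tempo by its label or *produce* a cued tempo by tapping.
This note records the models, conventions and design choices behind each
stage, and what the synthetic-data validation does and does not establish.

## The semitempo scale

Tempo is treated on a logarithmic axis, consistent with
Weber-fraction behaviour of tempo discrimination (just-noticeable
differences are roughly proportional deviations). One **semitempo** is a
frequency ratio of 2^(1/12) (~ +6%), so 12 semitempi double the beat rate
(one tempo "octave"), in direct analogy with equal-tempered semitones.

`build_semitempo_series(base_bpm=40, n_steps=37)` generates the geometric
series 40 × 2^(k/12), k = 0..36 (three octaves, 40–320 bpm).
`select_experimental_scale(series, start=10, stride=2, count=7)` picks every
second step starting at 71 bpm, producing the seven labelled experimental
tempi (rounded: 71, 80, 90, 101, 113, 127, 143 bpm), adjacent tempi two
semitempi (+12%) apart and hence comfortably discriminable.

Numerical conventions:

* **All computation uses unrounded bpm**; integer bpm values are a display
  convention only, so rounding error never compounds.
* **Rounding is half-up** on the decimal value (63.496 → 63, 100.79 → 101).
  Half-even would produce the same integers for this series; half-up is the
  simpler rule consistent with every displayed value.
* The displayed **IOI list (845.1 … 419.6 ms) and per-clip beat counts
  (12, 13, 15, 17, 19, 21, 24 for 10 s clips) are derived from the rounded
  display bpm**, matching how the stimulus clips are conventionally
  described; `bpm_to_ioi_ms` and `beats_in_clip` accept any bpm.

## Tempo estimation from tap trains

`produced_bpm` discards the first and last tap of a train (attack/stop
artefacts), then returns `60 × (k − 1) / window` where `k` is the number of
retained onsets and `window` the time they span. Counting **inter-onset
intervals** rather than onsets is the only convention under which a
perfectly periodic train returns exactly `60 / IOI`; counting onsets would
bias every estimate upward by a factor `k/(k−1)`. A minimum of four onsets
is required (trimming must leave at least one interval). Tempo drift within
a trial is deliberately not modelled — only the aggregate tempo is
estimated.

## Error metric and correctness band

Errors are signed semitempo distances, `12 × log2(response / target)`,
positive when the response is too fast. The metric is antisymmetric and
additive by construction. Production responses within **±1 semitempo**
(±~6%) of the target count as correct; the band is inclusive, with a 1e−9
absolute tolerance on the semitempo value so boundary responses do not flip
on floating-point noise. Identification is correct only on an exact label
match; its error in semitempo units is twice the label distance (adjacent
labels are two semitempi apart), which puts both tasks' errors on a common
axis. The ±1-semitempo band equals half the label spacing, so it is the
strictest band at which the two tasks' accuracies are comparable.

## Chance models and thresholds

A participant is above chance in a task when their correct count k out of
n = 7 trials has binomial upper-tail probability P(X ≥ k) < α = 0.05; the
threshold `T` is the smallest such k (strict inequality). Tails are exact
binomial sums (`scipy.stats.binom.sf`).

* **Identification**: p = 1/7 (uniform guessing over labels) gives T = 4
  (tail 0.0102).
* **Production, permutation null**: the pooled produced tempi are
  repeatedly permuted over the trial slots (unrestricted uniform
  permutations — fixed points allowed, the simplest reading of a random
  permutation) and assignments are scored with the same ±1-semitempo band
  as real responses. The pooled correct rate estimates the per-trial chance
  probability; its expectation equals the mean of the all-pairs
  correctness matrix, which the tests verify. 100 cycles is the default;
  the per-cycle counts are retained so a Monte-Carlo standard error is
  always available.
* **Production, analytic null**: guesses uniform in log-tempo over an
  empirical range land in the correct band with probability
  p1 = (band width)/(range width), both measured in semitempi — the ratio
  is a probability only under a log-uniform density, which is why the
  simulator's guessers use the same density. With the reference range
  23–233 bpm and band 67–150.4 bpm, p = p1/7 ≈ 0.05. The band endpoints
  are explicit inputs rather than derived from the scale, because the
  reference analysis quotes endpoints based on the rounded extreme tempi.

The two production nulls disagree about T under the strict rule (a
permutation estimate near 0.12 gives T = 3; the analytic p = 0.05 gives
T = 2, since P(X ≥ 2) = 0.044 < 0.05). The pipeline therefore takes the
adopted thresholds as configuration — defaults (T_id, T_prod) = (4, 3) —
and always reports both nulls' raw thresholds alongside, rather than
silently resolving the tension. Crossing the two thresholds partitions a
cohort into four classes (`both_above`, `identification_only`,
`production_only`, `chance`); no multiple-testing correction is applied
across participants.

## Serial-position analysis

`counts_by_position` tallies correct responses per target position
(slowest → fastest). `central_contrast` compares the central position
against the **pooled other six** in a 2×2 correct/incorrect table using the
Pearson chi-square **without continuity correction** (df = 1, p-value from
the χ² distribution) and φ = √(χ²/N) with N the total responses in the
table. Both choices are deliberate: they are the conventions under which
the reference counts reproduce their published statistics, and they are
stated here rather than assumed silently. `bow_index` is the orthogonal
quadratic contrast over positions (coefficients (5, 0, −3, −4, −3, 0, 5)
for seven positions, normalised by their sum of squares): positive for a
U-shaped curve (edge advantage, the classic absolute-identification bow
effect), negative for an inverted U, zero for a flat curve, and
antisymmetric under reflecting the counts about the central value.

## Group statistics

`summarize_groups` reports, per group × task cell, the mean and SD across
participants of percent correct (100 × count/7) and of the mean signed
error. `fit_response_line` is ordinary least squares of response bpm on
target bpm with classical standard errors and Pearson r
(`scipy.stats.linregress`). `mixed_anova_2x2` is the balanced split-plot
decomposition for two groups (between) × two tasks (within): the between
effect is tested against subjects-within-groups, the within effect and
interaction against task-by-subjects, each on (1, N−2) df. Sums of squares
are computed from cell/subject/task means and must add to the total (a
tested invariant); the implementation is cross-checked against
`pingouin.mixed_anova` in the test suite. Partial η² divides each effect's
SS by itself plus its own error SS. Normality (Shapiro–Wilk) and
homoskedasticity (Bartlett) checks are delegated to scipy and reported
descriptively only. Unbalanced input is refused rather than approximated,
because the intended design is balanced.

## Synthetic cohort generator

The generator exists so every stage can be validated and calibrated
without raw experimental data. Defaults emulate the reference design: 2
groups × 15 participants × 2 tasks × 7 trials, targets a fresh random
permutation of the labels per participant and task.

Per participant and task, AT possession is Bernoulli: defaults
`p_at_id = 14/30` and `p_at_prod = 7/30`, the above-chance fractions
observed in the reference cohort. Response models:

| responder | model |
|---|---|
| AT identification | remembered magnitude = log2(target) + N(0, σ_mem); respond with the nearest scale label in log space (ties to the slower label, a measure-zero event) |
| non-AT identification | uniform label 1..7 |
| AT production | produced log2 bpm = (1−λ)(log2 target + N(0, σ_mem)) + λ·log2(SMT) |
| non-AT production | log2 bpm uniform on [log2 23, log2 233] |

Parameters and defaults: `sigma_mem = 0.10` log2 units (1.2 semitempi) —
memory noise is Gaussian on log tempo because a constant relative JND is
equivalent to additive noise on a log scale (scalar timing); a mid-range
value at which interior targets are genuinely confusable but edge targets
are not. `lambda_smt = 0.35` — the central-tendency weight toward the
spontaneous motor tempo `smt_bpm = 100`, the canonical body-based reference
rate; values above ~0.3 make production accuracy peak at the scale tempo
nearest the SMT. `guess_range_bpm = (23, 233)` mirrors the analytic null's
range so calibration of guessers against that null is exact in
expectation. `tap_jitter_ms = 10` per-tap Gaussian timing noise, a typical
motor-timing scale. Same config + seed ⇒ byte-identical tables.

`generate_tap_train` places one onset per beat of the clip —
`round(bpm × duration/60)` onsets on the exact grid, so zero-jitter counts
at the seven scale tempi are the clip beat counts 12..24 — then jitters
each onset, resampling any ordering violations. Jitter of half the IOI or
more is rejected outright: ordering could then only be kept by luck, which
would distort the jitter distribution.

`recover_parameters` inverts the AT production model by OLS on log2 scales:
slope = 1 − λ and residual SD = (1 − λ)σ identify both parameters;
simulation tests require recovery within ±0.03 at 200 participants.

What the generator does **not** emulate: real "chance" participants are
not uniform guessers (they retain strong relative-tempo information), so
simulated cohorts show weaker response–target regressions than real data;
there is no learning, feedback, sequential (relative-judgment) dependence
between trials, or distractor interference; and AT possession is binary,
not graded. Passing calibration therefore shows the *statistical machinery*
is correct under its stated nulls — not that the generative model is a
faithful account of human participants.

## Problem sizes and runtime

Validation uses exact enumeration for binomial oracles (2⁷ outcomes),
10⁴-participant simulated cohorts for false-positive calibration,
2×10⁵-draw Monte-Carlo for the log-uniform null, and 4–10×10³ permutation
cycles against the exact pairwise expectation; the full suite completes in
well under a minute. The acceptance script runs the complete pipeline on
one reference-design cohort (420 trials) with the default 100 permutation
cycles.

## Known limitations

* The permutation pool uses every scoreable production; exclusion rules
  for unusable trials, if any, are the caller's responsibility upstream.
* `mixed_anova_2x2` is specialised to the 2×2 balanced split plot; it is
  not a general mixed-model engine.
* Published partial η² values for this class of design are not always
  consistent with their F statistics (F = 11.68 on (1, 28) df implies
  ηp² ≈ 0.29); ηp² is reported but should be interpreted with that caveat.
* Spreadsheet ingestion requires a user-supplied column map; deposited
  sheets vary in layout and no layout is hard-coded.
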