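# tempomem

Analysis pipeline for **absolute tempo** (AT) memory experiments — the
ability to identify or produce a musical tempo without an external
reference, the tempo analogue of absolute pitch.

The package is aimed at auditory-cognition researchers running (or
re-analysing) label-learning tempo experiments: participants learn a
seven-step scale of metronome tempi labelled 1 (slowest) to 7 (fastest),
then either hear a tempo and report its label (*identification*) or see a
label and tap the tempo (*production*). `tempomem` covers every analysis
stage and ships a synthetic-cohort generator so the whole pipeline runs,
and is tested, without raw experimental data.

## What it computes

* **Tempo scale** — the geometric *semitempo* series `40 · 2^(k/12)` bpm
  (one semitempo = 2^(1/12) ≈ +6%, 12 semitempi = one doubling) and the
  seven-tempo experimental scale 71–80–90–101–113–127–143 bpm (rounded),
  with IOIs and per-clip beat counts.
* **Tap metrics** — produced tempo from tap onsets (trim first/last tap,
  then `bpm = 60(k−1)/window` over the k retained onsets), signed errors in
  semitempo units `12·log2(response/target)`, and the ±1-semitempo
  correctness band.
* **Chance models** — exact binomial tails `P(X ≥ k)` and above-chance
  thresholds `T` (smallest k with tail < α); a permutation null that
  reassigns the pooled productions to trial slots; an analytic log-uniform
  null `p = p1/7` with `p1` the band-to-range width ratio in semitempi; and
  the four-quadrant participant classification.
* **Serial position** — correct counts per target position, the
  central-vs-other 2×2 chi-square (uncorrected) with φ = √(χ²/N), and a
  quadratic bow index (positive = U-shaped curve, negative = inverted U).
* **Group statistics** — percent-correct and mean-error tables by
  group × task, response-on-target OLS fits, and the balanced 2×2
  split-plot ANOVA (training between, task within).
* **Synthetic cohorts** — log-normal noisy rememberers vs uniform guessers,
  central-tendency pull toward the ~100 bpm spontaneous motor tempo,
  jittered tap trains, and parameter recovery. See `docs/methods.md` for
  models, parameters and limitations.

## Worked example

```python
import tempomem as tm

scale = tm.default_scale()
print(scale.bpm_rounded)     # (71, 80, 90, 101, 113, 127, 143)
print(scale.ioi_ms)          # (845.1, 750.0, 666.7, 594.1, 531.0, 472.4, 419.6)

err = tm.semitempo_error(118, 101)
print(f"{err:.1f}")                          # 2.7  (semitempi, too fast)
print(tm.is_correct_production(118, 101))    # False (outside the ±1 band)

sim = tm.simulate_cohort(tm.CohortConfig(seed=42), scale)
report = tm.run_pipeline(sim.trials, tm.PipelineConfig(seed=42))
print(report["thresholds"]["identification"]["T"])                      # 4
print(report["thresholds"]["production"]["permutation"]["p_hat"])       # 0.076
print(report["classification"]["quadrant_counts"])
# {'chance': 20, 'identification_only': 7, 'both_above': 3}
print(round(report["mixed_anova"]["F"]["task"], 2))                     # 18.17
```

Reading the output: a 118 bpm response to the 101 bpm target is 2.7
semitempi too fast, outside the ±1-semitempo (±6%) correctness band. On
this simulated cohort of 30 participants, the binomial null (guessing
p = 1/7 over 7 trials) puts the identification threshold at T = 4 correct
responses; permuting the cohort's 210 pooled productions estimates a
per-trial chance rate of 0.076, giving a production threshold of T = 3.
Ten of thirty simulated participants exceed a threshold in at least one
task, and the split-plot ANOVA finds the usual strong task effect
(identification easier than production) with F(1, 28) = 18.17.

The same stages are available from the shell:

```bash
tempomem scale --base 40 --start 10 --stride 2 --count 7 --out scale.json
tempomem simulate --seed 42 --out trials.csv
tempomem score --trials trials.csv --scale scale.json --out scored.csv
tempomem thresholds --scored scored.csv --seed 42 --out thresholds.json
tempomem serial-position --scored scored.csv --out serialpos.json
tempomem run --trials trials.csv --seed 42 --out report.json
```

## Data formats

Trial tables are delimited text with columns `participant_id, group, task,
trial_index, target_label` plus `response_label` (identification) and
`response_bpm` or `onsets_file` (production); tap trains are one CSV
(column `onset_s`) or JSON list per trial; scales are JSON; reports are
JSON with the resolved configuration echoed for reproducibility. Rows that
fail validation are dropped with per-row diagnostics, never fatally.
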