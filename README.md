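# scanpathselect

Selecting the gaze-velocity threshold of the I-VT algorithm by comparing
visual scan paths with string-edit similarity.

## The problem

Turning raw eye-tracking data into a *visual scan path* — the time-ordered
sequence of fixated areas of interest (AOIs) — requires an event-detection
algorithm. The velocity-threshold identification algorithm (I-VT)
classifies each pair of consecutive gaze samples by angular speed: below
the threshold the samples belong to an eye fixation, at or above it to a
saccade. The threshold matters. Too low, and fixations are split or lost
entirely; too high, and distinct fixations merge into one placed where the
eyes never rested. Either way the scan-path sequence is distorted, and the
accurate threshold differs between populations, tasks and trackers.

When the *ideal* scan path is known (for example, a target-following task
where participants track a bullseye that relocates every second), one can
sweep thresholds and keep those whose sequences best match it. This
package implements that sweep **and** two selection methods that need no
ideal sequence at all, so they work for ordinary free-viewing studies:

* **between-participant comparisons** — at threshold *i*, the average
  similarity over all *m* = *p*(*p*−1)/2 unordered pairs of participants'
  sequences:

  h̄ᵢ = (1/m) Σ_{(xⱼ,xₖ)∈Wᵢ} S(xⱼ, xₖ)

* **within-participant comparisons** — for one participant, the average
  similarity of threshold *i*'s sequence to the sequence at every *other*
  threshold (divisor *t*−1; a sequence is never compared with itself),
  then averaged over participants:

  vᵢ = (1/(t−1)) Σ_{j≠i} S(fᵢ, fⱼ),   v̄ᵢ = (1/p) Σⱼ vᵢⱼ

Here S is the normalized string-edit similarity of two token sequences:
one minus the Levenshtein distance (insertions + deletions +
substitutions, unit cost, operating on whole two-digit AOI tokens)
divided by the length of the longer sequence. For example, turning
`03,04,05` into `01,02,03,04,05` takes two insertions, so
S = 1 − 2/5 = 0.6: the sequences are 60% similar.

Accurate thresholds are the contiguous plateau of high, stable trend
values; the package replaces by-eye plateau reading with an explicit rule
(all grid points within δ of the maximum, contiguous around the argmax)
and quantifies trend agreement with Spearman rank correlation.

## What's in the package

- `gaze_io` — CSV dialect for per-sample gaze tables (+ target schedules),
  missing-sample accounting and the >10%-missing participant filter.
- `event_detection` — point-to-point velocities, I-VT classification,
  fixation assembly with a 60 ms minimum duration.
- `scanpath` — circular time-windowed AOIs (radius 2 dva), temporal +
  spatial fixation-to-AOI mapping, token sequences (consecutive repeats
  preserved).
- `similarity` — token-level edit distance and normalized similarity.
- `threshold_selection` — sweeps, the three trends, plateau/range
  selection, Spearman agreement, benchmark comparison.
- `synthetic_gaze` — seedable simulator of the bullseye-following task
  with known ground truth.
- `model` — `ThresholdSelectionModel` / `ThresholdSelectionResults`, a
  statsmodels-style front end over the above.
- `cli` — the `scanpathselect` command (`simulate`, `detect`, `sequences`,
  `similarity`, `sweep`, `select`, `evaluate`, `run`).

## Worked example

Simulate a 20-participant cohort following 50 targets each (0.5 dva
fixational offsets, blink-like missing data), then sweep thresholds from
10 to 400 °/s:

```python
from scanpathselect import SimulationParams, ThresholdSelectionModel, generate_cohort

params = SimulationParams(n_targets=50, seed=11)
cohort = generate_cohort(20, params)
model = ThresholdSelectionModel([c.recording for c in cohort])
results = model.fit()
print(results.summary())
```

```
        Gaze-Velocity Threshold Selection (I-VT)
==========================================================
participants: 20     thresholds: 40 (10-400 deg/s)
min fixation: 60 ms    AOI radius: 2 dva    plateau delta: 0.05
----------------------------------------------------------
trend       argmax   max sim     range (deg/s)
between        310     0.715           230-380
within         310     0.799           170-400
ideal          310     0.809           230-400
----------------------------------------------------------
Spearman rho(between, within) = 0.998  (p = 1e-47)
Spearman rho(between, ideal) = 0.992  (p = 1.6e-35)
Spearman rho(within, ideal) = 0.992  (p = 1.1e-35)
----------------------------------------------------------
benchmark 30 deg/s ideal similarity: 0.382
  between argmax 310 deg/s: 0.809 (+0.427 vs benchmark)
  within argmax 310 deg/s: 0.809 (+0.427 vs benchmark)
==========================================================
```

Reading it: both selection methods — neither of which sees the ideal
sequence — rank thresholds almost exactly as the ideal trend does
(ρ ≈ 0.99) and pick 310 °/s, inside the ideal trend's accurate range
(230–400 °/s), where sequences are 81% similar to the true target order.
A commonly recommended default of 30 °/s would have produced sequences
only 38% similar: at that threshold this cohort's velocity noise still
shatters fixations. `results.plot()` draws the three trends with their
shaded ranges; `results.to_csv(out_dir)` writes the tables.

The same analysis runs from files (one per-sample CSV per participant,
plus `*_targets.csv` schedules) without touching Python:

```sh
scanpathselect simulate --n-participants 20 --n-targets 50 --seed 11 --out-dir data/
scanpathselect evaluate --input-dir data/ --grid 10:400:10 --benchmark 30 --out-dir results/
```

Point `--input-dir` at any directory in the same dialect — for example an
export of a real target-tracking dataset — and the workflow is unchanged.

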