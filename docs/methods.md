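# Methods

This note records the scientific and numerical choices behind
`scanpathselect`: what each stage computes, which knobs matter, what the
synthetic-data generator does and does not emulate, and where genuinely
open design questions were settled.

## Event detection (I-VT)

Velocity is point-to-point: for each pair of consecutive samples that are
both valid, speed = Euclidean distance in dva / Δt in seconds. No
smoothing window is applied — the classic formulation is point-to-point,
and a window length is exposed nowhere else in the analysis. Distances
are planar Euclidean in dva; positions are already angles and target
eccentricities are modest, so no spherical correction is made.

Classification is strict: speed < threshold → fixation pair, speed ≥
threshold → saccade pair. A pair with either endpoint missing is a *gap*:
it carries no speed, receives no label, and always breaks runs — missing
data are dropped, never interpolated or bridged.

A maximal run of k fixation pairs spans k+1 samples; its duration is
offset − onset over member timestamps. Candidates shorter than the
minimum fixation duration (default **60 ms**, the common default in
commercial I-VT implementations) are discarded, and the discarded span is
reported as saccade time (the interval between two retained fixations
separated by a discarded candidate has no principled label; saccade time
is the conservative choice and is visible in the event export).
Sub-minimum candidates are discarded, not merged into neighbours:
merge-by-time-and-angle is a separate algorithm parameter outside this
package's scope. Fixation centroids are unweighted means of member
samples (all valid by construction).

## AOI mapping and token sequences

Each target defines a circular AOI with its visibility window and a
two-character token. A fixation emits the token of an AOI when

* its interval overlaps the AOI's window (any nonzero overlap; an
  onset-in-window mode is available as `temporal_mode="onset"`), and
* its centroid lies within the AOI radius (default **2 dva**, sized to
  typical tracker validation error; the disc is closed, so distance ==
  radius counts as inside).

A fixation straddling two AOI windows that both match spatially is
assigned the AOI with the larger temporal overlap, ties to the earlier
AOI — a deterministic tie-break where no convention exists. Each fixation
emits at most one token; a fixation genuinely spanning two targets is an
event-detection failure (a merge) that the method is designed to detect,
not something the mapper should paper over. Consecutive repeats of a
token are preserved: a split fixation legitimately produces "AA", and
collapsing repeats would hide exactly the low-threshold pathology the
trends must see. The ideal sequence is the AOI labels in onset order.

## Similarity

Token-level Levenshtein distance with unit costs, computed by the full
O(|a||b|) dynamic program (sequences here are at most a few hundred
tokens; no banding needed). The inner row is vectorised; the
left-neighbour dependency is resolved with a prefix minimum. Similarity
is 1 − distance / max(|a|, |b|). Two empty sequences are defined as
identical (similarity 1) since the normalisation there is 0/0; the
library warns when this convention fires. Empty sequences are *legal*
sweep outputs (extreme thresholds produce them) and are never dropped:
dropping would silently change the pair count m and the divisor t−1.
Edit operations act on whole tokens, never characters — with 100
two-digit labels, character-level alignment could straddle token
boundaries and inflate similarity.

## Trends and range selection

* Between-participant: exhaustive enumeration of all p(p−1)/2 pairs per
  threshold. A seeded pair subsample (`max_pairs`) is available for very
  large cohorts; the default is exhaustive because the metric is defined
  over all combinations.
* Within-participant: for each participant a symmetric t×t similarity
  matrix over thresholds; vᵢⱼ excludes the self-comparison (divisor
  t−1); v̄ᵢ is the unweighted participant mean. The full vᵢⱼ matrix is
  kept on the trend object.
* Ideal: per-threshold unweighted mean over participants of the
  similarity to the ideal sequence.

Range selection replaces by-eye plateau reading with an explicit rule:
argmax threshold (ties → lowest), then the maximal contiguous grid run
containing the argmax with values ≥ max − δ (default **δ = 0.05**) and
optionally ≥ an absolute floor (default 0; set 0.70 to mimic
"similarity of 0.70 or higher" conventions). Trend agreement uses
Spearman rank correlation with average ranks and the large-sample
two-sided p approximation — adequate at 40 grid points. A zero-variance
trend has no defined rank correlation and is reported as NaN, not a
number.

The default sweep grid is 10–400 °/s in steps of 10, bracketing the
range where published threshold choices live.

## The synthetic-data generator

The simulator emulates a random-saccade (target-following) task: by
default 100 bullseye targets, each visible 1 s, windows abutting exactly
(no inter-target blank is modelled), positions uniform on a display of
±23.3 × ±15.1 dva (a 474 × 297 mm monitor at 550 mm), first and last
targets at the centre, sampled at 1000 Hz. The gaze follows with a
per-target latency (normal, mean 200 ms, sd 20 ms, negative draws
clipped to zero) and straight-line saccades with a raised-cosine speed
profile; duration follows a main-sequence-style linearisation
(21 ms + 2.2 ms/dva), so peak speed is 2·amplitude/duration. Any smooth
profile whose peak well exceeds fixational speeds would do; the raised
cosine is simple and gives an unambiguous high-velocity band.

Noise is decomposed into two parts with different roles:

* **Fixational offset** (`fixation_jitter_sd`, default 0.5 dva): a
  per-dwell constant displacement of the dwell position. Physiological
  drift at realistic drift velocities moves the eye so slowly that
  within a one-second dwell it acts as a static offset; modelling it as
  per-sample white noise of this amplitude at 1000 Hz would imply
  sample-to-sample speeds of hundreds of °/s, which no fixation
  detector could ever survive. The offset degrades *spatial* accuracy
  (tokens are lost when the offset approaches the AOI radius).
* **Tracker noise** (`tracker_noise_sd`, default 0.01 dva RMS): white
  per-sample noise whose sd varies between dwells, lognormal with
  geometric sd `tracker_noise_dispersion` (default 2.5). Video-based
  trackers are genuinely heteroscedastic — noise varies with pupil
  state, eyelid coverage and gaze eccentricity — and this variation is
  what makes token recovery improve *gradually* with threshold, the
  characteristic rising limb of the similarity trends. Homogeneous
  Gaussian noise instead produces an all-or-nothing step within ~one
  grid interval. Tracker noise degrades *velocity* classification
  (splits at low thresholds) but barely affects centroids.

Missing samples default to blink-like bursts of 150 ms at an expected
5% of samples. Sample-wise independent missingness is available
(`burst_missing=False`) but is not the default: at 1000 Hz, 5%
independent dropouts leave mean valid runs of ~20 ms — shorter than the
minimum fixation duration — so the gaps-split-runs rule would shatter
nearly every fixation at every threshold, which is not how blinks and
occlusions behave.

All randomness flows from one master seed through numpy `SeedSequence`
spawning: per-participant streams are spawn children, and within a
recording the draw order is fixed and independent of parameter values,
so recordings sharing a seed are comparable across noise settings (unit
draws are scaled by the requested sd).

What the generator does **not** emulate: microsaccades, glissades,
smooth pursuit, tracker filtering artefacts, calibration drift over a
session, or any spectral structure of tracker noise. Consequently,
passing end-to-end tests show that the selection methods rank thresholds
correctly when fixations and saccades are the dominant signal and noise
is of plausible magnitude — they do not certify behaviour on data whose
oculomotor events violate the task model (e.g. pursuit-heavy stimuli).
Absolute similarity levels in simulation also need not match any real
dataset; the analysis consumes ranks and plateaus, not absolute values.

## Degenerate inputs and numerical details

* Recordings with fewer than two valid samples yield an empty velocity
  trace (not an error); empty traces yield no events.
* The participant filter excludes strictly-greater-than `max_missing`
  (default 0.10) missing fractions, applied over the full recording.
* CSV round-trips are bit-exact: floats are written with `%.17g` and
  parsed with round-trip precision.
* Similarity values are validated to [0,1]; trend containers reject
  values outside it.
* The benchmark comparison requires all thresholds on the sweep grid;
  an off-grid benchmark is a validation error raised before any
  computation.

## Problem sizes

Library defaults target cohorts of hundreds of participants with 100
targets each; the bundled tests and examples run a 20-participant,
50-target cohort (about one million gaze samples and ~23,000 sequence
comparisons for the full 40-threshold sweep), which completes in well
under a minute on one core and exhibits all the qualitative behaviour of
interest: a rising limb at low thresholds, an interior maximum, and a
gentle merge-driven decline at high thresholds.
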