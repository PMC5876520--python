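# Methods

## Problem and model

`motionseg` segments a continuous single-IMU stream into the phases of
a known, strictly linear motion.  The motion model is a chain of `N`
sub-motions; each is a start / performing / end state triple, boundary
states are single-frame, and adjacent sub-motions share their boundary
state.  All state algebra (class counts `2N + 2` including the none
class, `N + 1` boundary states, the expected temporal pattern) lives in
`motionseg.model` and everything downstream is generic in `N` — the
bundled five-phase kick and three-phase throw configs are examples, not
special cases.  Cyclic or branching motions are out of scope: the
pattern search and the ordered-argmax segmentation both assume one
linear pass through the states.

## Features

Each 100 Hz sample yields 11 features: global-Z acceleration, the
magnitudes of acceleration, angular velocity and their first and second
backward differences, and the angles between consecutive acceleration,
angular-velocity and first-difference vectors.  Choices a user should
know:

- **Differences are raw sample differences**, not divided by the 10 ms
  period.  At a fixed rate the factor is constant and absorbed by
  standardization.
- **Gravity stays in the acceleration channels** (the vertical
  component is informative about posture); `subtract_gravity=True`
  removes the nominal 1 g from Z first.
- Rows 0–1 use zero vectors for undefined differences so features stay
  index-aligned with the raw stream — the accumulator and the label
  files index the same frames.
- Angles of near-zero vectors (norm `< 1e-8` in input units) are 0 by
  contract, keeping the output finite for resting sensors.
- Per-column z-scoring is fitted on the training split only and stored
  with the checkpoint.  Units are g and deg/s; without scaling the
  gyro magnitudes (hundreds) dominate the accelerations (ones).

## Sequence labeler

Per window of `L = 100` feature vectors: time-distributed dense(48)
with ELU, two stacked bidirectional GRUs (48 and 32 units per
direction, outputs concatenated to 96 and 64), and a per-timestep
softmax over the `2N + 2` classes.  Batch normalization precedes the
dense activation and follows each recurrent layer; dropout (default
0.2) applies to every layer except the output.  The network, BPTT and
Adam are implemented in numpy; the test suite checks every parameter's
gradient against central finite differences (relative tolerance 1e−4).

Training uses Adam (lr 1e−3), batch size 100, and the class-weighted
cross-entropy with weights `α_i = total / (K · count_i)` (zero-count
classes get weight 0).  Boundary states occur once per recording
(~0.2% of frames), so unweighted training can ignore them entirely;
the weights make boundary mistakes expensive.  A visible consequence:
the converged labeler spreads boundary labels onto 1–2 adjacent frames
around each transition, trading plain per-frame accuracy (~94% on
training windows) for reliable boundary evidence; accuracy away from
transitions exceeds 99%.  Batch-norm running statistics use momentum
0.9 so inference statistics are usable after a short training run.
All randomness (init, shuffling, dropout) derives from the config seed;
training is bit-reproducible on a fixed BLAS.

Sliding-window extraction defaults to stride 1 (dense windows); the
stride is exposed because dense windows from overlapping ~500-frame
recordings are highly redundant — the shipped experiments thin to
stride 8 with no measured loss of segmentation quality.

## On-line accumulation, detection, segmentation

The accumulator keeps one probability row per consumed sample; each new
window overwrites the rows it covers (last-write semantics), so a
sample's final estimate comes from the last window containing it and
rows older than the current window never change — verified by a replay
oracle in the tests.  `update(..., advance=k)` generalizes the
per-sample update so a classifier invoked every `k` frames uses the
same primitive.

Detection discretizes the buffer by per-row argmax (ties to the lower
class index) and searches the most recent `horizon` frames for the
boundary-state pattern.  The horizon must cover the longest motion you
expect, or the pattern can never complete inside the search window; the
library default is `3L` and the recovery study derives it from the
generator's duration bounds (maximum motion span plus one window of
detection latency).  `exact` mode requires all `N + 1` boundary states in order;
`lcss` mode accepts when the longest common subsequence against the
pattern reaches `min_ratio` (default 0.8).  A completed match is
consumed — detection resumes after the matched span — so one motion
yields one result.  The exact-pattern criterion is the package's
definition of a "successful detection" and is what the evaluation
reports.

Segmentation maximizes the summed log-probability of the boundary
states subject to strictly increasing frame indices.  The per-state
argmax with an ordering side-condition is ambiguous when unconstrained
argmaxes conflict; the implementation solves the constrained problem
globally by dynamic programming (suffix-max recurrence over
(frame, boundary) pairs, ties resolved to the lexicographically
smallest tuple) and is tested against exhaustive search over all
ordered tuples.  A greedy sequential-argmax variant
(`method="greedy"`) exists for comparison.  Probabilities are floored
at 1e−300 inside logs.

Evaluation reports the detection rate over recordings and, for
detected recordings only, the per-boundary mean absolute error in
frames — undetected recordings lower the rate but do not enter the
error averages.

## Synthetic recordings

The generator emulates the structure of instrumented ~5 s recordings:
50–150 frames of none-state clutter, one motion instance (performing
states 10–80 frames, boundaries exactly 1 frame), then clutter again;
at 100 Hz a recording averages ≈430 frames.  Each state has a signature
(base acceleration with a 1 g vertical offset, base angular velocity,
sinusoidal modulation at 1–4 Hz) drawn once and deterministically per
(model, seed); per-channel Gaussian noise defaults to 0.05 g and
10 deg/s.  Boundary frames carry the *mean* of the neighboring phase
signatures, so they are genuinely transitional — the hardest case for
single-frame localization — rather than a distinctive spike.  The
none state oscillates gently around rest to mimic walking.  Signals
exceeding the sensor ranges (±16 g, ±2000 deg/s) are clipped with a
warning.

What the generator does *not* model: biomechanical dynamics, sensor
drift or orientation-estimation error, inter-subject execution
variability, and the label ambiguity of slow terminal movements that
dominates real start/end boundary error.  Passing the recovery study
therefore shows the pipeline recovers boundaries when the states are
statistically distinguishable; it does not predict error magnitudes on
human recordings, where terminal boundaries are known to be much
harder than interior ones.

## The recovery study

`motionseg.experiments.run_recovery_study` is the package's end-to-end
experiment: 150 recordings of the five-phase model (recording-level
80/20 split → 120 train / 30 test), feature standardization fitted on
the training split, window stride 8, 12 epochs, then each held-out
recording streamed through the on-line pipeline (classifier stride 1).
These sizes were chosen so the full study completes in minutes on a
single CPU while leaving the training set ~50× larger than the number
of network parameters per class; the expectation, met with margin in
the shipped acceptance run, is a detection rate ≥ 0.9 and interior
boundary error ≤ 3 frames (30 ms).  The first and last boundaries are
excluded from the headline error because the motion's extremes border
the none state, where even the generator makes the transition gradual
— mirroring how terminal boundaries behave in practice.

## Known limitations

- One motion model per classifier; detecting several motion types
  concurrently requires one pipeline per model.
- The numpy network trains small models quickly but is not a general
  deep-learning stack (no GPU, no arbitrary architectures).
- Streaming replays precompute window outputs in batches for speed;
  this is bit-identical to per-sample invocation because the labeler is
  stateless across windows, but true sample-by-sample latency is not
  simulated.
- `lcss` detection mode reports no per-boundary match positions;
  segmentation after an LCSS match relies on the DP over the whole
  search range.
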