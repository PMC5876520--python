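# motionseg

On-line detection and phase segmentation of sports motions from a single
wearable inertial sensor (IMU).

Coaches and movement scientists analyze a motion — a soccer kick, a
two-handed throw — as a sequence of *phases* separated by sharp events
(toe-off, ball impact, maximum arm stretch).  `motionseg` takes a
continuous 100 Hz stream of tri-axis acceleration (global frame) and
angular velocity (sensor frame), decides *that* a modeled motion just
happened, and localizes every phase boundary to a single 10 ms frame,
so each repetition can be reviewed phase by phase.

## The model and method

A motion model is an ordered chain of `N` sub-motions.  Sub-motion
`i` is the state triple `(m_s, m_p, m_e)` — start, performing, end —
where transitions are instantaneous: every boundary state occupies
exactly one frame and the end state of sub-motion `i` *is* the start
state of sub-motion `i+1`.  A model therefore has `2N + 1` distinct
states and `N + 1` boundary states; a classifier over those states plus
a *none/unknown* class (index 0) has `2N + 2` classes.  Two example
models ship as configs: a five-phase soccer kick (states `LS1..LS11`,
12 classes) and a three-phase two-handed throw (`LT1..LT7`, 8 classes).

Each sensor sample maps to an 11-element feature vector (vertical
acceleration; magnitudes of acceleration, angular velocity, and their
first and second differences; angles between consecutive acceleration,
angular-velocity, and first-difference vectors).  A sliding window of
`L = 100` feature vectors feeds a per-timestep sequence labeler —
dense(48, ELU) → bidirectional GRU(48) → bidirectional GRU(32) →
softmax, with batch normalization and dropout — implemented directly in
numpy (forward, backpropagation-through-time and Adam; gradients are
verified against finite differences in the test suite).  Training
minimizes a class-weighted categorical cross-entropy

    L(y, ŷ) = −Σ_i α_i y_i log ŷ_i,   α_i ∝ 1 / count(state i),

because single-frame boundary states are hundreds of times rarer than
performing or none frames.

On-line, each new window's output overwrites the trailing estimates in
an accumulated state sequence `a(t)`, so every sample's final estimate
comes from the last window containing it.  A motion is detected when
the model's boundary-state pattern appears in temporal order in the
argmax state string (or, tolerantly, when the longest common
subsequence against the pattern is long enough).  Boundary frames are
then recovered as

    b_1 < b_2 < ... < b_{N+1}  maximizing  Σ_k log y_{b_k}^{k},

solved globally by dynamic programming over (frame, boundary) pairs.

Because real instrumented recordings are not distributable, the package
includes a seeded generator of IMU-like labeled recordings (~5 s, one
motion embedded in walking-like clutter, per-state signal signatures,
single-frame boundaries whose signal blends the neighboring phases), so
training, streaming and evaluation run end to end with no external data.

## Worked example

```python
import numpy as np
from motionseg import (load_model, bundled_config_path, SyntheticSpec,
                       generate_corpus, PipelineConfig, run_stream, evaluate,
                       boundary_states)
from motionseg.experiments import run_recovery_study

res = run_recovery_study(seed=7, n_recordings=50, epochs=8)
print(res.report)
```

prints (seed 7, 40 training / 10 held-out recordings):

```
{'n_recordings': 10, 'n_detected': 10, 'detection_rate': 1.0,
 'boundary_mae': {'LS1': 0.0, 'LS3': 0.0, 'LS5': 0.0,
                  'LS7': 0.0, 'LS9': 0.0, 'LS11': 0.0}}
```

i.e. the kick was detected in all 10 held-out streams and every
boundary state (landing, toe-off, maximum hip extension, ball impact,
toe-speed inflection, end of kick) was localized at the exact
ground-truth frame; `boundary_mae` is the mean absolute error in 10 ms
frames over detected recordings.

The same workflow is available from the shell:

```
motionseg simulate --model-config src/motionseg/configs/soccer_kick.yaml \
    --n 50 --seed 7 --out corpus/
motionseg train    --model-config src/motionseg/configs/soccer_kick.yaml \
    --data corpus/ --epochs 12 --checkpoint clf
motionseg detect   --model-config src/motionseg/configs/soccer_kick.yaml \
    --data corpus/ --checkpoint clf --out seg.csv
motionseg evaluate --model-config src/motionseg/configs/soccer_kick.yaml \
    --data corpus/ --segmentation seg.csv --out report.json
```

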