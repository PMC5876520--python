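"""Seeded generator of labeled IMU-like streams for training and evaluation.

Real recordings of instrumented sports motions are scarce, so the
package ships a generator that emulates their statistical structure: a
~5 s, 100 Hz six-channel recording containing one motion instance
embedded in irrelevant "clutter" movement (walking-like low-amplitude
oscillation), with ground-truth per-sample state labels.

Each motion state carries a signature — a base acceleration vector
(global frame, gravity included), a base angular-velocity vector, and a
sinusoidal modulation (frequency, amplitude) — distinct enough that the
labeling task is learnable.  Boundary states occupy exactly one frame
and their signal is the mean of the adjacent performing-state
signatures, which makes boundaries genuinely transitional and their
localization non-trivial.  Gaussian noise is added per channel.

The generator targets statistical structure only; it makes no attempt
at biomechanical realism (no skeletal model, no physics).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .features import ACCEL_RANGE_G, GYRO_RANGE_DPS, ImuStream
from .model import MotionModel, NONE_CLASS

__all__ = ["StateSignature", "SyntheticSpec", "generate_recording", "generate_corpus"]

#: fixed stream used (with the user seed) to derive per-state signatures,
#: so a given model always maps to the same study conditions
_SIGNATURE_STREAM = 0x5157


@dataclass(frozen=True)
class StateSignature:
    """Base channel levels and oscillation for one motion state."""

    accel: np.ndarray       # (3,) g, global frame, gravity included
    gyro: np.ndarray        # (3,) deg/s, sensor frame
    freq_hz: float
    accel_amp: float        # g
    gyro_amp: float         # deg/s


@dataclass
class SyntheticSpec:
    """Study conditions for one synthetic corpus.

    Defaults mimic the instrumented-kick setting: a five-phase motion
    whose performing states last 10–80 frames, embedded in 50–150 frames
    of clutter on each side, for a total of roughly 500 frames (~5 s at
    100 Hz).
    """

    model: MotionModel
    phase_duration_range: tuple[int, int] = (10, 80)
    pre_post_noise_range: tuple[int, int] = (50, 150)
    signatures: dict[int, StateSignature] = field(default_factory=dict)
    noise_sd_accel: float = 0.05    # g
    noise_sd_gyro: float = 10.0     # deg/s
    sample_rate: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.phase_duration_range[0] < 2:
            raise ValueError("performing states need at least 2 frames")
        if not self.signatures:
            self.signatures = default_signatures(self.model, self.seed)


def default_signatures(model: MotionModel, seed: int = 0) -> dict[int, StateSignature]:
    """Draw one signature per class, deterministically for a given model+seed.

    Performing and boundary-defining levels are spread over the sensor's
    mid range so that states are separated by much more than the default
    noise; the none class gets a gentle walking-like oscillation around
    rest (1 g on the vertical axis).
    """
    rng = np.random.default_rng(np.random.SeedSequence([_SIGNATURE_STREAM, seed]))
    sigs: dict[int, StateSignature] = {}
    sigs[NONE_CLASS] = StateSignature(
        accel=np.array([0.0, 0.0, 1.0]),
        gyro=np.zeros(3),
        freq_hz=1.5,
        accel_amp=0.15,
        gyro_amp=25.0,
    )
    for k in range(1, model.n_classes):
        accel = rng.uniform(-3.0, 3.0, size=3)
        accel[2] += 1.0  # gravity offset on the global Z axis
        sigs[k] = StateSignature(
            accel=accel,
            gyro=rng.uniform(-400.0, 400.0, size=3),
            freq_hz=float(rng.uniform(1.0, 4.0)),
            accel_amp=float(rng.uniform(0.1, 0.4)),
            gyro_amp=float(rng.uniform(20.0, 60.0)),
        )
    return sigs


def _label_sequence(model: MotionModel, rng: np.random.Generator,
                    spec: SyntheticSpec) -> np.ndarray:
    """Per-sample ground-truth labels for one recording."""
    lead = rng.integers(spec.pre_post_noise_range[0], spec.pre_post_noise_range[1] + 1)
    tail = rng.integers(spec.pre_post_noise_range[0], spec.pre_post_noise_range[1] + 1)
    labels = [NONE_CLASS] * int(lead)
    for sm in model.sub_motions:
        labels.append(model.state_index[sm.start_label])  # 1 frame
        dur = int(rng.integers(spec.phase_duration_range[0], spec.phase_duration_range[1] + 1))
        labels.extend([model.state_index[sm.performing_label]] * dur)
    labels.append(model.state_index[model.sub_motions[-1].end_label])
    labels.extend([NONE_CLASS] * int(tail))
    return np.asarray(labels, dtype=np.int64)


def _boundary_signature(spec: SyntheticSpec, model: MotionModel, k: int) -> StateSignature:
    """Boundary frames blend the signatures of the neighboring phases."""
    # neighbors in the temporal pattern: boundary k sits between two
    # performing states (or a performing state and the none state at the
    # motion's extremes)
    pattern = [model.state_index[lab] for lab in model.state_labels()]
    i = pattern.index(k)
    left = pattern[i - 1] if i > 0 else NONE_CLASS
    right = pattern[i + 1] if i + 1 < len(pattern) else NONE_CLASS
    a, b = spec.signatures[left], spec.signatures[right]
    return StateSignature(
        accel=(a.accel + b.accel) / 2,
        gyro=(a.gyro + b.gyro) / 2,
        freq_hz=(a.freq_hz + b.freq_hz) / 2,
        accel_amp=(a.accel_amp + b.accel_amp) / 2,
        gyro_amp=(a.gyro_amp + b.gyro_amp) / 2,
    )


def generate_recording(spec: SyntheticSpec,
                       seed: int | None = None) -> tuple[ImuStream, np.ndarray]:
    """One ~5 s labeled recording: a single motion amid clutter.

    Identical (spec, seed) always produces identical output.  Channels
    exceeding the nominal sensor ranges (±16 g, ±2000 deg/s) are clipped
    with a warning.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    labels = _label_sequence(spec.model, rng, spec)
    T = len(labels)
    boundary_set = {
        spec.model.state_index[lab]
        for lab in ([spec.model.sub_motions[0].start_label]
                    + [sm.end_label for sm in spec.model.sub_motions])
    }
    t = np.arange(T) / spec.sample_rate
    phase_off = rng.uniform(0, 2 * np.pi, size=6)
    accel = np.empty((T, 3))
    gyro = np.empty((T, 3))
    for k in np.unique(labels):
        sig = (_boundary_signature(spec, spec.model, int(k))
               if int(k) in boundary_set else spec.signatures[int(k)])
        m = labels == k
        osc = np.sin(2 * np.pi * sig.freq_hz * t[m, None] + phase_off[:3])
        accel[m] = sig.accel + sig.accel_amp * osc
        osc = np.sin(2 * np.pi * sig.freq_hz * t[m, None] + phase_off[3:])
        gyro[m] = sig.gyro + sig.gyro_amp * osc
    accel += rng.normal(0, spec.noise_sd_accel, size=(T, 3))
    gyro += rng.normal(0, spec.noise_sd_gyro, size=(T, 3))
    if (np.abs(accel) > ACCEL_RANGE_G).any() or (np.abs(gyro) > GYRO_RANGE_DPS).any():
        warnings.warn("synthetic signal exceeds sensor range; clipping", stacklevel=2)
        accel = np.clip(accel, -ACCEL_RANGE_G, ACCEL_RANGE_G)
        gyro = np.clip(gyro, -GYRO_RANGE_DPS, GYRO_RANGE_DPS)
    return ImuStream(accel, gyro, rate_hz=spec.sample_rate), labels


def generate_corpus(spec: SyntheticSpec, n_recordings: int,
                    train_fraction: float = 0.8, seed: int | None = None) -> dict:
    """A labeled corpus split at the recording level into train and test.

    Returns a dict with ``train`` and ``test`` lists of
    ``(recording_id, ImuStream, labels)`` plus a ``manifest`` recording
    the per-recording seeds and the split.
    """
    if n_recordings < 2:
        raise ValueError("need at least 2 recordings to split")
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    base = spec.seed if seed is None else seed
    ss = np.random.SeedSequence(base)
    rec_seeds = [int(s) for s in
                 np.random.default_rng(ss).integers(0, 2**31, size=n_recordings)]
    n_train = round(n_recordings * train_fraction)
    if n_train == 0 or n_train == n_recordings:
        raise ValueError("degenerate split")
    order = np.random.default_rng(np.random.SeedSequence([base, 1])).permutation(n_recordings)
    train_ids = set(order[:n_train].tolist())
    out = {"train": [], "test": [], "manifest": {"seed": base, "recordings": []}}
    for i, rs in enumerate(rec_seeds):
        rid = f"rec{i:04d}"
        stream, labels = generate_recording(spec, seed=rs)
        part = "train" if i in train_ids else "test"
        out[part].append((rid, stream, labels))
        out["manifest"]["recordings"].append({"id": rid, "seed": rs, "split": part})
    return out
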