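"""Per-sample feature extraction from a 6-channel IMU stream.

Each 100 Hz sample (tri-axis global-frame acceleration, tri-axis
sensor-frame angular velocity) maps to an 11-element feature vector:

==== ==========================================================
col  feature
==== ==========================================================
0    acceleration along the global Z axis (opposite to gravity)
1    magnitude of acceleration
2    magnitude of angular velocity
3    magnitude of the first difference of acceleration
4    magnitude of the first difference of angular velocity
5    magnitude of the second difference of acceleration
6    magnitude of the second difference of angular velocity
7    angle between adjacent acceleration vectors
8    angle between adjacent angular-velocity vectors
9    angle between adjacent first-difference acceleration vectors
10   angle between adjacent first-difference angular-velocity vectors
==== ==========================================================

Differences are raw backward sample differences (not divided by the
10 ms sample period); the constant rate makes that scale factor
absorbable by standardization.  Rows whose differences are undefined
(the first one or two samples) use zero vectors for the missing
differences, so the feature sequence stays index-aligned with the raw
stream.  Gravity is kept in the acceleration channels by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ImuStream",
    "FeatureSequence",
    "Standardizer",
    "angle_between",
    "extract_features",
    "FEATURE_NAMES",
]

FEATURE_NAMES = [
    "a_z",
    "|a|",
    "|w|",
    "|da|",
    "|dw|",
    "|dda|",
    "|ddw|",
    "ang(a)",
    "ang(w)",
    "ang(da)",
    "ang(dw)",
]

#: below this magnitude a vector is treated as directionless (angle 0)
ANGLE_EPS = 1e-8

ACCEL_RANGE_G = 16.0
GYRO_RANGE_DPS = 2000.0


@dataclass
class ImuStream:
    """A fixed-rate 6-channel inertial recording.

    accel: (T, 3) global/earth-frame acceleration, gravity included, in g.
    gyro:  (T, 3) sensor-frame angular velocity in deg/s.
    """

    accel: np.ndarray
    gyro: np.ndarray
    rate_hz: float = 100.0
    accel_units: str = "g"

    def __post_init__(self) -> None:
        self.accel = np.asarray(self.accel, dtype=np.float64)
        self.gyro = np.asarray(self.gyro, dtype=np.float64)
        if self.accel.ndim != 2 or self.accel.shape[1] != 3:
            raise ValueError(f"accel must be (T, 3), got {self.accel.shape}")
        if self.gyro.shape != self.accel.shape:
            raise ValueError("accel and gyro must have the same shape")
        if not (np.isfinite(self.accel).all() and np.isfinite(self.gyro).all()):
            raise ValueError("non-finite values in IMU stream")

    def __len__(self) -> int:
        return self.accel.shape[0]

    def slice(self, start: int, stop: int) -> "ImuStream":
        return ImuStream(
            self.accel[start:stop], self.gyro[start:stop], self.rate_hz, self.accel_units
        )


@dataclass
class FeatureSequence:
    """T x 11 matrix of per-sample features, column order as in the module docs."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[1] != len(FEATURE_NAMES):
            raise ValueError(f"expected (T, 11), got {self.values.shape}")

    def __len__(self) -> int:
        return self.values.shape[0]


def angle_between(u: np.ndarray, v: np.ndarray, eps: float = ANGLE_EPS) -> float:
    """Angle in [0, pi] between two 3-vectors; 0 if either is near zero."""
    u = np.asarray(u, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu < eps or nv < eps:
        return 0.0
    c = float(np.dot(u, v) / (nu * nv))
    return float(np.arccos(np.clip(c, -1.0, 1.0)))


def _pairwise_angles(x: np.ndarray, eps: float) -> np.ndarray:
    """Angles between consecutive rows of (T, 3) x; row 0 gets 0."""
    T = x.shape[0]
    out = np.zeros(T)
    if T < 2:
        return out
    a, b = x[1:], x[:-1]
    na = np.linalg.norm(a, axis=1)
    nb = np.linalg.norm(b, axis=1)
    ok = (na >= eps) & (nb >= eps)
    dots = np.einsum("ij,ij->i", a, b)
    cosang = np.zeros(T - 1)
    np.divide(dots, na * nb, out=cosang, where=ok)
    ang = np.where(ok, np.arccos(np.clip(cosang, -1.0, 1.0)), 0.0)
    out[1:] = ang
    return out


def extract_features(stream: ImuStream, eps: float = ANGLE_EPS,
                     subtract_gravity: bool = False) -> FeatureSequence:
    """Compute the 11-element feature vector for every sample of *stream*.

    With ``subtract_gravity`` the nominal 1 g is removed from the global
    Z acceleration before anything is computed (off by default: the
    Z component carrying gravity is itself informative about posture).
    """
    T = len(stream)
    if T == 0:
        raise ValueError("empty stream")
    a = stream.accel.copy()
    if subtract_gravity:
        a[:, 2] -= 1.0
    w = stream.gyro

    da = np.zeros_like(a)
    da[1:] = np.diff(a, axis=0)
    dw = np.zeros_like(w)
    dw[1:] = np.diff(w, axis=0)
    dda = np.zeros_like(a)
    dda[2:] = da[2:] - da[1:-1]
    ddw = np.zeros_like(w)
    ddw[2:] = dw[2:] - dw[1:-1]

    out = np.empty((T, 11))
    out[:, 0] = a[:, 2]
    out[:, 1] = np.linalg.norm(a, axis=1)
    out[:, 2] = np.linalg.norm(w, axis=1)
    out[:, 3] = np.linalg.norm(da, axis=1)
    out[:, 4] = np.linalg.norm(dw, axis=1)
    out[:, 5] = np.linalg.norm(dda, axis=1)
    out[:, 6] = np.linalg.norm(ddw, axis=1)
    out[:, 7] = _pairwise_angles(a, eps)
    out[:, 8] = _pairwise_angles(w, eps)
    # angles between consecutive *differences*: row t compares da_t with
    # da_{t-1}; da_0 is the zero vector, so rows 0..1 are 0 by the
    # degenerate-vector contract
    out[:, 9] = _pairwise_angles(da, eps)
    out[:, 10] = _pairwise_angles(dw, eps)
    return FeatureSequence(out)


@dataclass
class Standardizer:
    """Per-column z-score transform fitted on training data only."""

    mean: np.ndarray = field(default_factory=lambda: np.zeros(11))
    scale: np.ndarray = field(default_factory=lambda: np.ones(11))
    enabled: bool = True

    @classmethod
    def fit(cls, features: np.ndarray | FeatureSequence) -> "Standardizer":
        x = features.values if isinstance(features, FeatureSequence) else np.asarray(features)
        mean = x.mean(axis=0)
        scale = x.std(axis=0)
        zero = scale < 1e-12
        if zero.any():
            warnings.warn(
                f"constant feature column(s) {np.where(zero)[0].tolist()}: scale clamped to 1",
                stacklevel=2,
            )
            scale = np.where(zero, 1.0, scale)
        return cls(mean=mean, scale=scale)

    def transform(self, features: FeatureSequence) -> FeatureSequence:
        if not self.enabled:
            return features
        return FeatureSequence((features.values - self.mean) / self.scale)

    def inverse_transform(self, features: FeatureSequence) -> FeatureSequence:
        if not self.enabled:
            return features
        return FeatureSequence(features.values * self.scale + self.mean)

    def to_dict(self) -> dict:
        return {
            "mean": self.mean.tolist(),
            "scale": self.scale.tolist(),
            "enabled": self.enabled,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Standardizer":
        return cls(np.asarray(d["mean"]), np.asarray(d["scale"]), d.get("enabled", True))
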