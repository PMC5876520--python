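"""Feature extraction: the 11-element per-sample vector and its invariants."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from motionseg.features import (FeatureSequence, ImuStream, Standardizer,
                                angle_between, extract_features)


def reference_features(accel, gyro, eps=1e-8):
    """Straight-loop recomputation of all 11 formulas, kept independent
    of the vectorized implementation."""
    T = len(accel)

    def ang(u, v):
        nu, nv = np.linalg.norm(u), np.linalg.norm(v)
        if nu < eps or nv < eps:
            return 0.0
        return math.acos(max(-1.0, min(1.0, float(np.dot(u, v)) / (nu * nv))))

    rows = []
    for t in range(T):
        a, w = accel[t], gyro[t]
        da = accel[t] - accel[t - 1] if t >= 1 else np.zeros(3)
        dw = gyro[t] - gyro[t - 1] if t >= 1 else np.zeros(3)
        da_prev = accel[t - 1] - accel[t - 2] if t >= 2 else np.zeros(3)
        dw_prev = gyro[t - 1] - gyro[t - 2] if t >= 2 else np.zeros(3)
        dda = da - da_prev if t >= 2 else np.zeros(3)
        ddw = dw - dw_prev if t >= 2 else np.zeros(3)
        rows.append([
            a[2],
            np.linalg.norm(a),
            np.linalg.norm(w),
            np.linalg.norm(da),
            np.linalg.norm(dw),
            np.linalg.norm(dda),
            np.linalg.norm(ddw),
            ang(a, accel[t - 1]) if t >= 1 else 0.0,
            ang(w, gyro[t - 1]) if t >= 1 else 0.0,
            ang(da, da_prev),
            ang(dw, dw_prev),
        ])
    return np.asarray(rows)


class TestAngle:
    @pytest.mark.parametrize("u,v,expected", [
        ((1, 0, 0), (0, 1, 0), math.pi / 2),
        ((2, 0, 0), (1, 0, 0), 0.0),
        ((1, 0, 0), (-3, 0, 0), math.pi),
        ((0, 0, 0), (1, 2, 3), 0.0),        # degenerate by contract
        ((1e-12, 0, 0), (1, 0, 0), 0.0),    # below epsilon
    ])
    def test_examples(self, u, v, expected):
        assert angle_between(np.array(u), np.array(v)) == pytest.approx(expected)

    def test_nearly_parallel_is_finite(self):
        u = np.array([1.0, 1.0, 1.0])
        assert angle_between(u, u * (1 + 1e-15)) == pytest.approx(0.0, abs=1e-6)


class TestExtract:
    def test_constant_stream(self):
        stream = ImuStream(np.tile([0, 0, 1.0], (5, 1)), np.zeros((5, 3)))
        f = extract_features(stream).values
        expected = np.array([1.0, 1.0] + [0.0] * 9)
        assert np.allclose(f, expected)

    def test_two_sample_hand_arithmetic(self):
        stream = ImuStream(np.array([[0, 0, 1.0], [0, 1.0, 0]]), np.zeros((2, 3)))
        f = extract_features(stream).values
        assert f[1, 3] == pytest.approx(math.sqrt(2))   # |da|
        assert f[1, 7] == pytest.approx(math.pi / 2)    # angle(a_1, a_0)
        assert f[1, 5] == pytest.approx(0.0)            # second difference undefined

    def test_matches_straight_loop_oracle(self):
        rng = np.random.default_rng(7)
        accel = rng.normal(0, 2, (10, 3))
        gyro = rng.normal(0, 300, (10, 3))
        got = extract_features(ImuStream(accel, gyro)).values
        assert np.allclose(got, reference_features(accel, gyro), atol=1e-12)

    def test_row_count_and_ranges(self):
        rng = np.random.default_rng(1)
        stream = ImuStream(rng.normal(0, 1, (50, 3)), rng.normal(0, 100, (50, 3)))
        f = extract_features(stream).values
        assert f.shape == (50, 11)
        assert (f[:, 1:7] >= 0).all()                       # magnitudes
        assert ((f[:, 7:] >= 0) & (f[:, 7:] <= math.pi)).all()  # angles
        assert np.isfinite(f).all()

    def test_rejects_empty_and_nonfinite(self):
        with pytest.raises(ValueError):
            extract_features(ImuStream(np.zeros((0, 3)), np.zeros((0, 3))))
        with pytest.raises(ValueError):
            ImuStream(np.array([[np.nan, 0, 0]]), np.zeros((1, 3)))

    def test_gravity_subtraction_flag(self):
        stream = ImuStream(np.tile([0, 0, 1.0], (3, 1)), np.zeros((3, 3)))
        f = extract_features(stream, subtract_gravity=True).values
        assert np.allclose(f[:, 0], 0.0)

    @settings(deadline=None, max_examples=25)
    @given(st.integers(min_value=0, max_value=60), st.integers(min_value=461, max_value=500))
    def test_time_shift_equivariance(self, a, b):
        rng = np.random.default_rng(42)
        stream = ImuStream(rng.normal(0, 2, (500, 3)), rng.normal(0, 200, (500, 3)))
        whole = extract_features(stream).values[a:b]
        sliced = extract_features(stream.slice(a, b)).values
        # rows at offset >= 2 relative to the slice start agree exactly
        assert np.allclose(whole[2:], sliced[2:])

    def test_gyro_scaling_scales_magnitudes_not_angles(self):
        rng = np.random.default_rng(3)
        accel = rng.normal(0, 1, (30, 3))
        gyro = rng.normal(0, 100, (30, 3))
        f1 = extract_features(ImuStream(accel, gyro)).values
        f2 = extract_features(ImuStream(accel, 2.5 * gyro)).values
        assert np.allclose(f2[:, [2, 4, 6]], 2.5 * f1[:, [2, 4, 6]])
        assert np.allclose(f2[:, [8, 10]], f1[:, [8, 10]])
        assert np.allclose(f2[:, [0, 1, 3, 5, 7, 9]], f1[:, [0, 1, 3, 5, 7, 9]])


class TestStandardizer:
    def test_identity_stats(self):
        f = FeatureSequence(np.random.default_rng(0).random((5, 11)))
        s = Standardizer()
        assert np.allclose(s.transform(f).values, f.values)

    def test_round_trip(self):
        rng = np.random.default_rng(5)
        x = FeatureSequence(rng.normal(3, 2, (100, 11)))
        s = Standardizer.fit(x)
        z = s.transform(x)
        assert abs(z.values.mean()) < 1e-10
        assert np.allclose(s.inverse_transform(z).values, x.values)

    def test_constant_column_clamped(self):
        x = np.random.default_rng(0).normal(size=(50, 11))
        x[:, 4] = 7.0
        with pytest.warns(UserWarning, match="clamped"):
            s = Standardizer.fit(x)
        z = s.transform(FeatureSequence(x))
        assert np.allclose(z.values[:, 4], 0.0)

    def test_disabled_is_identity(self):
        f = FeatureSequence(np.random.default_rng(1).random((5, 11)))
        s = Standardizer(enabled=False)
        assert s.transform(f) is f

    def test_dict_round_trip(self):
        s = Standardizer.fit(np.random.default_rng(2).normal(size=(40, 11)))
        s2 = Standardizer.from_dict(s.to_dict())
        assert np.allclose(s.mean, s2.mean) and np.allclose(s.scale, s2.scale)
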