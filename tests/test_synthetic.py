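"""The synthetic IMU generator: determinism, label structure, learnability."""

import numpy as np
import pytest

from motionseg.model import NONE_CLASS, boundary_states, state_pattern
from motionseg.synthetic import (StateSignature, SyntheticSpec, default_signatures,
                                 generate_corpus, generate_recording)


@pytest.fixture()
def spec(kick_model):
    return SyntheticSpec(model=kick_model, seed=3)


class TestRecording:
    def test_same_seed_is_identical(self, spec, tmp_path):
        from motionseg.io import write_imu_csv
        s1, l1 = generate_recording(spec, seed=5)
        s2, l2 = generate_recording(spec, seed=5)
        assert np.array_equal(s1.accel, s2.accel)
        assert np.array_equal(l1, l2)
        write_imu_csv(s1, tmp_path / "a.csv")
        write_imu_csv(s2, tmp_path / "b.csv")
        assert (tmp_path / "a.csv").read_bytes() == (tmp_path / "b.csv").read_bytes()

    def test_different_seeds_differ(self, spec):
        s1, _ = generate_recording(spec, seed=1)
        s2, _ = generate_recording(spec, seed=2)
        assert not np.array_equal(s1.accel[:50], s2.accel[:50])

    def test_labels_follow_state_pattern_with_single_frame_boundaries(self, spec, kick_model):
        _, labels = generate_recording(spec, seed=7)
        # collapse runs -> must equal none, s1, p1, b12, ..., eN, none
        runs = [labels[0]]
        lengths = [1]
        for x in labels[1:]:
            if x == runs[-1]:
                lengths[-1] += 1
            else:
                runs.append(x)
                lengths.append(1)
        assert runs == [NONE_CLASS] + state_pattern(kick_model) + [NONE_CLASS]
        bset = set(boundary_states(kick_model))
        for state, n in zip(runs, lengths):
            if state in bset:
                assert n == 1
            elif state != NONE_CLASS:
                lo, hi = spec.phase_duration_range
                assert lo <= n <= hi

    def test_duration_is_about_five_seconds(self, spec):
        lengths = [len(generate_recording(spec, seed=s)[1]) for s in range(10)]
        # 5 phases of 10-80 frames plus 50-150 frames context each side
        assert all(150 <= n <= 720 for n in lengths)
        assert 300 < np.mean(lengths) < 700

    def test_zero_noise_constant_signatures_are_piecewise_constant(self, kick_model):
        sigs = {
            k: StateSignature(accel=np.full(3, float(k)), gyro=np.full(3, 10.0 * k),
                              freq_hz=1.0, accel_amp=0.0, gyro_amp=0.0)
            for k in range(kick_model.n_classes)
        }
        spec = SyntheticSpec(model=kick_model, signatures=sigs,
                             noise_sd_accel=0.0, noise_sd_gyro=0.0, seed=0)
        stream, labels = generate_recording(spec, seed=0)
        breaks = np.nonzero(np.abs(np.diff(stream.accel[:, 0])) > 1e-12)[0] + 1
        label_breaks = np.nonzero(np.diff(labels) != 0)[0] + 1
        assert set(breaks) <= set(label_breaks)

    def test_sensor_range_clipping_warns(self, kick_model):
        sigs = {
            k: StateSignature(accel=np.full(3, 30.0), gyro=np.full(3, 3000.0),
                              freq_hz=1.0, accel_amp=0.0, gyro_amp=0.0)
            for k in range(kick_model.n_classes)
        }
        spec = SyntheticSpec(model=kick_model, signatures=sigs, seed=0)
        with pytest.warns(UserWarning, match="clip"):
            stream, _ = generate_recording(spec, seed=0)
        assert np.abs(stream.accel).max() <= 16.0
        assert np.abs(stream.gyro).max() <= 2000.0

    def test_infeasible_durations_rejected(self, kick_model):
        with pytest.raises(ValueError):
            SyntheticSpec(model=kick_model, phase_duration_range=(1, 5))


class TestDistinguishability:
    def test_nearest_signature_classifier_recovers_labels(self, spec, kick_model):
        """With per-state signatures far apart relative to the noise, a
        naive nearest-signature frame classifier must already exceed 95%
        per-frame accuracy on non-boundary frames -- the learning task the
        corpus poses is then feasible by construction."""
        stream, labels = generate_recording(spec, seed=21)
        sigs = spec.signatures
        keys = sorted(sigs)
        # scale-balance the two channel groups before measuring distance
        ref_a = np.stack([sigs[k].accel for k in keys])
        ref_g = np.stack([sigs[k].gyro for k in keys])
        d = (
            np.linalg.norm(stream.accel[:, None] - ref_a[None], axis=2) / 1.0
            + np.linalg.norm(stream.gyro[:, None] - ref_g[None], axis=2) / 100.0
        )
        pred = np.asarray(keys)[d.argmin(axis=1)]
        interior = ~np.isin(labels, list(boundary_states(kick_model)))
        acc = (pred[interior] == labels[interior]).mean()
        assert acc > 0.95

    def test_default_signatures_deterministic_per_model_and_seed(self, kick_model):
        a = default_signatures(kick_model, seed=3)
        b = default_signatures(kick_model, seed=3)
        c = default_signatures(kick_model, seed=4)
        assert all(np.array_equal(a[k].accel, b[k].accel) for k in a)
        assert not np.array_equal(a[1].accel, c[1].accel)


class TestCorpus:
    def test_split_sizes_and_level(self, spec):
        corpus = generate_corpus(spec, 10, train_fraction=0.8, seed=5)
        assert len(corpus["train"]) == 8
        assert len(corpus["test"]) == 2
        ids = [r["id"] for r in corpus["manifest"]["recordings"]]
        assert len(set(ids)) == 10

    def test_recordings_are_distinct(self, spec):
        corpus = generate_corpus(spec, 6, seed=5)
        streams = [s.accel for _, s, _ in corpus["train"] + corpus["test"]]
        for i in range(len(streams)):
            for j in range(i + 1, len(streams)):
                a, b = streams[i], streams[j]
                n = min(len(a), len(b))
                assert not np.array_equal(a[:n], b[:n])

    def test_boundary_states_are_rare(self, spec, kick_model):
        corpus = generate_corpus(spec, 10, seed=2)
        labels = np.concatenate([lab for _, _, lab in corpus["train"] + corpus["test"]])
        counts = np.bincount(labels, minlength=kick_model.n_classes)
        bset = boundary_states(kick_model)
        for k in bset:
            assert counts[k] == 10  # exactly one frame per recording
        performing = [k for k in range(1, kick_model.n_classes) if k not in bset]
        assert counts[performing].min() > 5 * counts[bset].max()

    def test_degenerate_splits_rejected(self, spec):
        with pytest.raises(ValueError):
            generate_corpus(spec, 1)
        with pytest.raises(ValueError):
            generate_corpus(spec, 4, train_fraction=0.999)
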