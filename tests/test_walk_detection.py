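import numpy as np
import pytest

from stridekit import walk_detection as wd
from stridekit.preprocess import frame, magnitude
from stridekit.simulate import GaitModelParams, compose_session
from stridekit.types import random_rotation

from conftest import bruteforce_best_split

RATE = 200.0


def tone_frames(freq, n_frames=5, frame_len=600, amp=1.0):
    t = np.arange(frame_len) / RATE
    return [amp * np.sin(2 * np.pi * freq * t) for _ in range(n_frames)]


class TestThresholdFit:
    def test_separable_low_walk_variance(self):
        """Walk variances below non-walk: the fitted rule must flip polarity."""
        stats = np.array([1.0, 2.0, 10.0, 20.0])
        labels = np.array([1, 1, 0, 0])
        model = wd.best_threshold(stats, labels)
        assert model.train_accuracy == 1.0
        assert not model.walk_above
        assert 2.0 < model.threshold < 10.0
        np.testing.assert_array_equal(model.predict(stats), labels)

    def test_single_frame_per_class(self):
        model = wd.best_threshold(np.array([1.0, 5.0]), np.array([0, 1]))
        assert 1.0 < model.threshold <= 5.0
        assert model.train_accuracy == 1.0

    def test_matches_bruteforce_on_interleaved(self, rng):
        for _ in range(50):
            n = int(rng.integers(4, 60))
            stats = rng.normal(size=n)
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            model = wd.best_threshold(stats, labels)
            assert model.train_accuracy == pytest.approx(
                bruteforce_best_split(stats, labels), abs=1e-12
            )
            pred = model.predict(stats)
            assert np.mean(pred == labels) == pytest.approx(model.train_accuracy)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            wd.best_threshold(np.array([1.0, 2.0]), np.array([1, 1]))


class TestSignalDetectors:
    def test_constant_frames_are_nonwalk(self):
        frames = tone_frames(1.0) + [np.full(600, 1.0)] * 5
        labels = np.array([1] * 5 + [0] * 5)
        model = wd.thr_fit(frames, labels)
        pred = wd.thr_predict(frames, model)
        np.testing.assert_array_equal(pred.states, labels)

    def test_stft_band_separation(self):
        frames = tone_frames(1.0) + tone_frames(5.0) + [np.zeros(600)]
        labels = np.array([1] * 5 + [0] * 6)
        pred, model = wd.stft_wd(frames, RATE, labels=labels)
        np.testing.assert_array_equal(pred.states, labels)
        # band energies themselves behave as expected
        e = wd.band_energy(frames, RATE)
        assert e[0] > 100 * max(e[5], 1e-12)
        assert e[-1] == 0.0

    def test_stft_band_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            wd.band_energy([np.zeros(16)], 3.0)

    def test_dwt_band_separation(self):
        """Levels 7-8 at 200 Hz (~0.39-1.56 Hz) see a 1 Hz tone, not 20 Hz."""
        t = np.arange(12000) / RATE
        stats = {}
        for name, freq in (("slow", 1.0), ("fast", 20.0)):
            sig = np.sin(2 * np.pi * freq * t)
            fset = frame(sig, 3.0, 0.5, rate_hz=RATE)
            s = wd.dwt_frame_energy(sig, fset)
            stats[name] = s[2:-2]  # interior frames, away from edge effects
        assert stats["slow"].min() > 10 * stats["fast"].max()

    def test_dwt_wd_classifies_mixed_frames(self):
        """Long bouts dominate the level-7/8 coefficient support (~12 s at
        200 Hz for db10), so frame-level accuracy is high away from the
        transition."""
        t = np.arange(36000) / RATE
        sig = np.where(t < 90, np.sin(2 * np.pi * 1.0 * t), 0.0)
        fset = frame(sig, 3.0, 0.5, rate_hz=RATE)
        labels = np.array([1 if e <= 18000 else 0 for _, e, _ in fset.frames])
        _, model = wd.dwt_wd(sig, fset, labels=labels)
        assert model.train_accuracy > 0.9

    def test_zero_signal_is_nonwalk(self):
        frames = tone_frames(1.0) + [np.zeros(600)] * 5
        labels = np.array([1] * 5 + [0] * 5)
        pred, _ = wd.stft_wd(frames, RATE, labels=labels)
        assert pred.states[5:].sum() == 0


class TestMLDetectors:
    def test_separable_clouds(self, rng):
        X = np.vstack([
            rng.normal(0.0, 1.0, size=(100, 8)),
            rng.normal(10.0, 1.0, size=(100, 8)),
        ])
        y = np.array([0] * 100 + [1] * 100)
        for algo in ("knn", "svm"):
            _, acc = wd.ml_wd_fit_predict(X, y, algo=algo, folds=10, seed=0)
            assert acc >= 0.99

    def test_permuted_labels_chance(self, rng):
        X = rng.normal(size=(1000, 8))
        y = rng.permutation([0, 1] * 500)
        _, acc = wd.ml_wd_fit_predict(X, y, algo="knn", folds=10, seed=0)
        assert abs(acc - 0.5) < 0.1

    def test_knn_k1_memorizes_training_set(self, rng):
        from sklearn.neighbors import KNeighborsClassifier

        X = rng.normal(size=(60, 4))
        y = rng.integers(0, 2, size=60)
        clf = KNeighborsClassifier(n_neighbors=1).fit(X, y)
        assert clf.score(X, y) == 1.0

    def test_too_few_samples_rejected(self, rng):
        X = rng.normal(size=(8, 4))
        y = np.array([0, 1] * 4)
        with pytest.raises(ValueError):
            wd.ml_wd_fit_predict(X, y, folds=10)


def test_detector_statistics_rotation_invariant(rng):
    """Magnitude-based per-frame statistics are identical under sensor rotation."""
    params = GaitModelParams(noise_sd=0.02)
    rec, _ = compose_session([("walk", 20.0), ("stand", 10.0)], seed=3, walk_params=params)
    fset = frame(magnitude(rec), 3.0, 0.5)
    base_frames = [magnitude(rec).samples[s:e] for s, e, _ in fset.frames]
    base = {
        "var": wd.frame_variance(base_frames),
        "band": wd.band_energy(base_frames, rec.rate_hz),
        "dwt": wd.dwt_frame_energy(magnitude(rec).samples, fset),
    }
    for _ in range(5):
        rot = rec.rotated(random_rotation(rng))
        frames_r = [magnitude(rot).samples[s:e] for s, e, _ in fset.frames]
        np.testing.assert_allclose(wd.frame_variance(frames_r), base["var"], atol=1e-9)
        np.testing.assert_allclose(wd.band_energy(frames_r, rec.rate_hz), base["band"], atol=1e-9)
        np.testing.assert_allclose(
            wd.dwt_frame_energy(magnitude(rot).samples, fset), base["dwt"], atol=1e-9
        )
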