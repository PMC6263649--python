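import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from stridekit.preprocess import (
    frame,
    lowpass,
    magnitude,
    normalize_variance,
    resample,
)
from stridekit.simulate import GaitModelParams, simulate_walk
from stridekit.types import AccelRecording, random_rotation

from conftest import bruteforce_frame_count


def make_recording(samples, rate=200.0):
    samples = np.asarray(samples, dtype=float)
    return AccelRecording(np.arange(len(samples)) / rate, samples, rate)


def test_magnitude_345():
    rec = make_recording([[3.0, 4.0, 0.0], [0.0, 0.0, 1.0]])
    np.testing.assert_allclose(magnitude(rec).samples, [5.0, 1.0])


def test_magnitude_rotation_oracle(rng):
    samples = rng.normal(size=(500, 3))
    rec = make_recording(samples)
    base = magnitude(rec).samples
    for _ in range(20):
        rot = rec.rotated(random_rotation(rng))
        np.testing.assert_allclose(magnitude(rot).samples, base, atol=1e-9)


def tone_gain(freq, cutoff, rate, duration=10.0):
    t = np.arange(int(duration * rate)) / rate
    x = np.sin(2 * np.pi * freq * t)
    y = lowpass(x, cutoff, rate)
    core = slice(int(rate), int((duration - 1) * rate))  # ignore edges
    return np.max(np.abs(y[core]))


def test_lowpass_dc_and_tones():
    const = np.full(2000, 3.7)
    np.testing.assert_allclose(lowpass(const, 15.0, 200.0), const, atol=1e-9)
    assert tone_gain(50.0, 15.0, 200.0) < 10 ** (-20 / 20)  # >= 20 dB down
    assert abs(tone_gain(1.0, 15.0, 200.0) - 1.0) < 0.05


def test_lowpass_idempotent_on_band_limited():
    t = np.arange(2000) / 200.0
    x = np.sin(2 * np.pi * 1.0 * t) + 0.3 * np.sin(2 * np.pi * 3.0 * t)
    once = lowpass(x, 15.0, 200.0)
    twice = lowpass(once, 15.0, 200.0)
    assert np.max(np.abs(twice - once)) < 1e-3


def test_lowpass_clips_cutoff_above_nyquist(caplog):
    x = np.random.default_rng(0).normal(size=400)
    with caplog.at_level("WARNING"):
        y = lowpass(x, 50.0, 50.0)  # 50 Hz cutoff at 50 Hz sampling
    assert y.shape == x.shape
    assert any("clipping" in r.message for r in caplog.records)
    with pytest.raises(ValueError):
        lowpass(x, -1.0, 200.0)


def test_frame_counts():
    x = np.zeros(60 * 200)
    fs = frame(x, 3.0, 0.5, rate_hz=200.0)
    assert len(fs) == 23  # floor((12000 - 600) / 500) + 1
    fs1 = frame(np.zeros(600), 3.0, 0.5, rate_hz=200.0)
    assert len(fs1) == 1
    # evaluation mode: overlap is one-sixth of the window
    fs6 = frame(np.zeros(30 * 200), 6.0, None, rate_hz=200.0)
    assert fs6.overlap_s == pytest.approx(1.0)


@settings(deadline=None, max_examples=60, derandomize=True)
@given(
    n=st.integers(50, 4000),
    w=st.integers(10, 400),
    overlap_frac=st.floats(0.0, 0.9),
)
def test_frame_count_matches_bruteforce(n, w, overlap_frac):
    rate = 100.0
    overlap = int(w * overlap_frac)
    if w > n:
        with pytest.raises(ValueError):
            frame(np.zeros(n), w / rate, overlap / rate, rate_hz=rate)
        return
    fs = frame(np.zeros(n), w / rate, overlap / rate, rate_hz=rate)
    assert len(fs) == bruteforce_frame_count(n, w, w - overlap)
    for s, e, _ in fs.frames:
        assert 0 <= s < e <= n
        assert e - s == w


def test_frame_majority_labels():
    rec, _ = simulate_walk(GaitModelParams(noise_sd=0.0), 10.0, 100.0, seed=0)
    rec.labels = [(0.0, 4.0, "walk"), (4.0, 10.0, "stand")]
    fs = frame(magnitude(rec), 2.0, 0.0)
    assert [f[2] for f in fs.frames] == ["walk", "walk", "stand", "stand", "stand"]
    # exact tie resolves against walk
    rec.labels = [(0.0, 1.0, "walk"), (1.0, 2.0, "stand")]
    fs = frame(magnitude(rec), 2.0, 0.0)
    assert fs.frames[0][2] == "stand"


def test_normalize_variance_properties(rng):
    x = rng.normal(2.0, 3.0, size=1000)
    z = normalize_variance(x)
    assert abs(z.mean()) < 1e-9
    assert abs(z.var() - 1.0) < 1e-9
    np.testing.assert_allclose(normalize_variance(5.0 * x + 2.0), z, atol=1e-9)
    with pytest.raises(ValueError, match="constant"):
        normalize_variance(np.full(100, 3.0))


def test_normalize_equalizes_subject_amplitudes():
    """Two subjects with 4x different amplitude give matching normalized peaks."""
    peaks = []
    for scale in (0.5, 2.0):
        p = GaitModelParams(stride_frequency_hz=1.0, noise_sd=0.0, subject_scale=scale)
        rec, _ = simulate_walk(p, 30.0, 200.0, seed=0)
        z = normalize_variance(magnitude(rec).samples)
        peaks.append(np.percentile(z, 99))
    assert abs(peaks[0] - peaks[1]) / peaks[1] < 0.05


def test_resample():
    rec, _ = simulate_walk(GaitModelParams(noise_sd=0.0), 60.0, 200.0, seed=0)
    same = resample(rec, 200.0)
    np.testing.assert_array_equal(same.samples, rec.samples)
    down = resample(rec, 50.0)
    assert down.n == 3000
    with pytest.raises(ValueError, match="upsampling"):
        resample(down, 100.0)


def test_resample_preserves_tone_amplitude():
    t = np.arange(60 * 200) / 200.0
    x = np.sin(2 * np.pi * 1.0 * t)
    rec = make_recording(np.column_stack([x, x, x]))
    down = resample(rec, 20.0)
    core = down.samples[100:-100, 0]
    assert abs(np.max(np.abs(core)) - 1.0) < 0.02
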