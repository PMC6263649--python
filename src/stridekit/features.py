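"""Per-frame feature extraction for the machine-learning walk detectors.

The feature vector combines time-domain statistics (mean, variance, min,
max, energy, skewness, kurtosis, mean-crossing rate, RMS) with the first
K one-sided FFT amplitude bins of a Hann-windowed frame. Features are
computed on the magnitude signal by default, or on all three axes
concatenated when the sensor orientation is known.
"""

from __future__ import annotations

from typing import List, Optional, Tuple

import numpy as np

STAT_NAMES = (
    "mean",
    "variance",
    "min",
    "max",
    "energy",
    "skewness",
    "kurtosis",
    "mean_crossing_rate",
    "rms",
)

#: Default number of FFT amplitude bins kept as features.
DEFAULT_FFT_BINS = 32


def feature_names(k: int = DEFAULT_FFT_BINS, axes: int = 1) -> List[str]:
    names = []
    prefixes = [""] if axes == 1 else [f"ax{i}_" for i in range(axes)]
    for p in prefixes:
        names.extend(p + s for s in STAT_NAMES)
        names.extend(f"{p}fft_{i}" for i in range(k))
    return names


def mean_crossing_count(x: np.ndarray) -> int:
    """Number of crossings of the frame mean (plateaus counted once).

    Counted as sign changes of x - mean after dropping exact zeros, so a
    flat run on the mean contributes a single crossing at most.
    """
    d = np.asarray(x, dtype=float) - np.mean(x)
    signs = np.sign(d)
    signs = signs[signs != 0]
    if signs.size < 2:
        return 0
    return int(np.sum(signs[1:] != signs[:-1]))


def _frame_stats(x: np.ndarray, rate_hz: float) -> np.ndarray:
    n = x.size
    mean = float(np.mean(x))
    var = float(np.var(x))  # population variance
    energy = float(np.mean(x**2))  # so rms**2 == energy
    rms = float(np.sqrt(energy))
    if var > 0:
        z = (x - mean) / np.sqrt(var)
        skew = float(np.mean(z**3))
        kurt = float(np.mean(z**4) - 3.0)  # excess kurtosis
    else:
        skew = 0.0  # degenerate frames map to 0 by convention
        kurt = 0.0
    mcr = mean_crossing_count(x) * rate_hz / n
    return np.array([mean, var, float(np.min(x)), float(np.max(x)), energy, skew, kurt, mcr, rms])


def _fft_amplitudes(x: np.ndarray, k: int) -> np.ndarray:
    w = np.hanning(x.size)
    spec = np.abs(np.fft.rfft(x * w)) / x.size
    out = np.zeros(k)
    m = min(k, spec.size)
    out[:m] = spec[:m]
    return out


def extract_features(
    frame_signal: np.ndarray,
    rate_hz: float,
    k: int = DEFAULT_FFT_BINS,
) -> np.ndarray:
    """Feature vector for one frame.

    ``frame_signal`` is either a 1-D magnitude frame or an (n, 3) axis
    frame; the latter yields the per-axis features concatenated (the
    orientation-known configuration).
    """
    x = np.asarray(frame_signal, dtype=float)
    if x.ndim == 1:
        if x.size < 8:
            raise ValueError("frame too short (need >= 8 samples)")
        return np.concatenate([_frame_stats(x, rate_hz), _fft_amplitudes(x, k)])
    if x.ndim == 2 and x.shape[1] == 3:
        if x.shape[0] < 8:
            raise ValueError("frame too short (need >= 8 samples)")
        return np.concatenate(
            [np.concatenate([_frame_stats(x[:, j], rate_hz), _fft_amplitudes(x[:, j], k)])
             for j in range(3)]
        )
    raise ValueError("frame must be 1-D or (n, 3)")


def balanced_indices(y: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Row indices balancing a binary label vector 1:1 by seeded random
    subsampling of the majority class, shuffled."""
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("need both classes to balance")
    n_min = int(counts.min())
    keep = []
    for c in classes:
        idx = np.flatnonzero(y == c)
        if idx.size > n_min:
            idx = rng.choice(idx, size=n_min, replace=False)
        keep.append(idx)
    keep = np.concatenate(keep)
    return keep[rng.permutation(keep.size)]


def balance_classes(
    X: np.ndarray,
    y: np.ndarray,
    rng: np.random.Generator,
    groups: Optional[np.ndarray] = None,
) -> Tuple[np.ndarray, np.ndarray, Optional[np.ndarray]]:
    """Balance a binary dataset 1:1 and shuffle the rows."""
    X = np.asarray(X)
    y = np.asarray(y)
    keep = balanced_indices(y, rng)
    g = None if groups is None else np.asarray(groups)[keep]
    return X[keep], y[keep], g


def build_dataset(
    frame_signals: list,
    activities: list,
    rate_hz: float,
    rng: np.random.Generator,
    k: int = DEFAULT_FFT_BINS,
    groups: Optional[list] = None,
) -> Tuple[np.ndarray, np.ndarray, Optional[np.ndarray]]:
    """Feature matrix + binary walk labels, balanced 1:1 and shuffled.

    ``activities`` are activity names; the walk-detection label is 1 for
    "walk" and 0 otherwise.
    """
    X = np.vstack([extract_features(f, rate_hz, k) for f in frame_signals])
    y = np.array([1 if a == "walk" else 0 for a in activities], dtype=int)
    g = None if groups is None else np.asarray(groups)
    return balance_classes(X, y, rng, groups=g)
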