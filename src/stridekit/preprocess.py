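"""Signal conditioning shared by every detector and counter.

Raw tri-axial recordings are reduced to the orientation-invariant
magnitude signal, low-pass filtered (walk detection), variance-normalized
(step counting), segmented into overlapping frames, or resampled to a
target rate. All operations preserve sample alignment so that gait-cycle
annotations remain valid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from fractions import Fraction
from typing import List, Optional, Tuple

import numpy as np
from scipy import signal as sps

from .types import AccelRecording

log = logging.getLogger(__name__)

#: Walk-detection low-pass cutoff (Hz).
WD_LOWPASS_HZ = 15.0
#: Default evaluation frame length (s) and overlap (s).
DEFAULT_WINDOW_S = 3.0
DEFAULT_OVERLAP_S = 0.5


@dataclass
class MagnitudeSignal:
    """Per-sample Euclidean norm of the three acceleration axes."""

    samples: np.ndarray
    rate_hz: float
    source: Optional[AccelRecording] = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return self.n / self.rate_hz


@dataclass
class FrameSet:
    """Overlapping analysis frames over a signal.

    ``frames`` holds ``(start_idx, end_idx, label)`` half-open intervals,
    label being the majority activity of the covered samples ("other"
    when the source carries no labels). The trailing partial frame is
    discarded.
    """

    window_s: float
    overlap_s: float
    rate_hz: float
    frames: List[Tuple[int, int, str]] = field(default_factory=list)

    @property
    def hop_s(self) -> float:
        return self.window_s - self.overlap_s

    def __len__(self) -> int:
        return len(self.frames)

    def labels(self) -> np.ndarray:
        return np.array([f[2] for f in self.frames])

    def slices(self, x: np.ndarray) -> List[np.ndarray]:
        return [x[s:e] for s, e, _ in self.frames]


def magnitude(recording: AccelRecording) -> MagnitudeSignal:
    """Orientation-invariant magnitude d = sqrt(ax^2 + ay^2 + az^2)."""
    mag = np.linalg.norm(recording.samples, axis=1)
    return MagnitudeSignal(mag, recording.rate_hz, source=recording)


def _effective_cutoff(cutoff_hz: float, rate_hz: float) -> float:
    """Clip a cutoff at/above Nyquist to 0.45 * rate with a warning."""
    if cutoff_hz <= 0:
        raise ValueError("cutoff must be positive")
    nyquist = rate_hz / 2.0
    if cutoff_hz >= nyquist:
        clipped = 0.45 * rate_hz
        log.warning(
            "low-pass cutoff %.3g Hz >= Nyquist (%.3g Hz); clipping to %.3g Hz",
            cutoff_hz, nyquist, clipped,
        )
        return clipped
    return cutoff_hz


def lowpass(x: np.ndarray, cutoff_hz: float, rate_hz: float, order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth low-pass (DC gain 1, length preserved).

    A forward-backward 4th-order Butterworth keeps peak timing intact,
    which matters for the event-based step counters downstream.
    """
    x = np.asarray(x, dtype=float)
    cutoff = _effective_cutoff(cutoff_hz, rate_hz)
    sos = sps.butter(order, cutoff, btype="low", fs=rate_hz, output="sos")
    padlen = min(x.size - 1, 3 * (2 * order + 1))
    if padlen < 1:
        return x.copy()
    return sps.sosfiltfilt(sos, x, padlen=padlen)


def frame(
    sig: MagnitudeSignal | np.ndarray,
    window_s: float = DEFAULT_WINDOW_S,
    overlap_s: Optional[float] = DEFAULT_OVERLAP_S,
    rate_hz: Optional[float] = None,
    labels: Optional[list] = None,
) -> FrameSet:
    """Segment a signal into frames of ``window_s`` with ``overlap_s`` overlap.

    When ``overlap_s`` is None the evaluation-mode rule applies: the
    overlap is one-sixth of the window size. Each frame's label is the
    majority activity of its samples; ties resolve to non-walk
    (conservative for walk detection).
    """
    if isinstance(sig, MagnitudeSignal):
        x = sig.samples
        rate = sig.rate_hz
        if labels is None and sig.source is not None:
            labels = sig.source.labels
    else:
        x = np.asarray(sig, dtype=float)
        if rate_hz is None:
            raise ValueError("rate_hz required for bare arrays")
        rate = rate_hz
    if overlap_s is None:
        overlap_s = window_s / 6.0
    if not 0 <= overlap_s < window_s:
        raise ValueError("overlap must lie in [0, window)")
    w = int(round(window_s * rate))
    hop = w - int(round(overlap_s * rate))
    if w > x.size:
        raise ValueError("window longer than signal")
    if hop < 1:
        raise ValueError("hop must be at least one sample")

    frames = []
    for start in range(0, x.size - w + 1, hop):
        end = start + w
        frames.append((start, end, _majority_label(labels, start, end, rate)))
    return FrameSet(window_s=window_s, overlap_s=overlap_s, rate_hz=rate, frames=frames)


def _majority_label(labels, start: int, end: int, rate: float) -> str:
    if not labels:
        return "other"
    counts: dict = {}
    t0, t1 = start / rate, end / rate
    for seg_start, seg_end, activity in labels:
        ov = min(t1, seg_end) - max(t0, seg_start)
        if ov > 0:
            counts[activity] = counts.get(activity, 0.0) + ov
    if not counts:
        return "other"
    best = max(counts.values())
    winners = sorted(a for a, c in counts.items() if c == best)
    if len(winners) > 1 and "walk" in winners:
        winners.remove("walk")  # ties resolve against walk
    return winners[0]


def normalize_variance(x: np.ndarray) -> np.ndarray:
    """Remove the mean and scale to unit variance.

    Step-counting thresholds (e.g. the FSM's four levels) are defined on
    this normalized scale, making them comparable across subjects,
    placements and movement intensities.
    """
    x = np.asarray(x, dtype=float)
    sd = float(np.std(x))
    if sd == 0.0 or not np.isfinite(sd):
        raise ValueError("cannot variance-normalize a constant signal")
    return (x - np.mean(x)) / sd


def resample(recording: AccelRecording, target_rate_hz: float) -> AccelRecording:
    """Anti-alias filter and downsample a recording to ``target_rate_hz``.

    Polyphase resampling (scipy ``resample_poly``) per axis; label
    segments are in seconds and carry over unchanged.
    """
    if target_rate_hz > recording.rate_hz + 1e-9:
        raise ValueError("upsampling above the source rate is not supported")
    if abs(target_rate_hz - recording.rate_hz) < 1e-9:
        return replace(recording)
    frac = Fraction(target_rate_hz / recording.rate_hz).limit_denominator(1000)
    up, down = frac.numerator, frac.denominator
    out = np.column_stack(
        [sps.resample_poly(recording.samples[:, k], up, down) for k in range(3)]
    )
    n = out.shape[0]
    time_s = recording.time_s[0] + np.arange(n) / target_rate_hz
    return AccelRecording(
        time_s=time_s,
        samples=out,
        rate_hz=target_rate_hz,
        units=recording.units,
        placement=recording.placement,
        subject=recording.subject,
        labels=list(recording.labels),
    )


def rescale_cycles(cycles: np.ndarray, source_rate: float, target_rate: float) -> np.ndarray:
    """Map gait-cycle sample indices between sampling rates."""
    factor = target_rate / source_rate
    return np.round(np.asarray(cycles, dtype=float) * factor).astype(np.int64)
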