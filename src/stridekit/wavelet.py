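"""Shared discrete-wavelet helpers (db10, eight-level decomposition).

Level indexing convention: level 1 is the finest detail band. At the
reference 200 Hz rate, level L covers approximately
[rate / 2**(L+1), rate / 2**L] Hz, so levels 7-8 straddle the walking
band (~0.39-1.56 Hz). At other sampling rates the stated levels are
shifted by log2(200 / rate) rounded to nearest, keeping the passband in
physical frequency rather than in level index.
"""

from __future__ import annotations

import logging
import math
from typing import List, Sequence

import numpy as np
import pywt

log = logging.getLogger(__name__)

WAVELET = "db10"
MAX_LEVEL = 8
REFERENCE_RATE_HZ = 200.0


def shift_levels(levels: Sequence[int], rate_hz: float) -> List[int]:
    """Shift reference-rate detail levels to another sampling rate."""
    shift = int(round(math.log2(REFERENCE_RATE_HZ / rate_hz)))
    return [max(1, l - shift) for l in levels]


def usable_depth(n: int, requested: int = MAX_LEVEL) -> int:
    """Decomposition depth supported by a signal of length n (warn if reduced)."""
    cap = pywt.dwt_max_level(n, pywt.Wavelet(WAVELET).dec_len)
    if cap < requested:
        log.warning("signal length %d supports only %d DWT levels (requested %d)", n, cap, requested)
    depth = min(requested, cap)
    if depth < 2:
        raise ValueError("signal too short for wavelet analysis (depth < 2)")
    return depth


def detail_energy_per_sample(
    x: np.ndarray,
    levels: Sequence[int],
    rate_hz: float,
    smooth_s: float = 1.0,
) -> np.ndarray:
    """Squared detail coefficients of the requested levels mapped back to
    sample positions and smoothed by a moving average of ``smooth_s``.

    Coefficient energies are expanded by repetition (each level-L
    coefficient covers ~2**L samples), summed across levels, then
    box-smoothed; the result aligns with the input signal.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    levels = shift_levels(levels, rate_hz)
    depth = usable_depth(n, max(max(levels), 2))
    levels = sorted({min(l, depth) for l in levels})
    coeffs = pywt.wavedec(x, WAVELET, level=depth)
    # coeffs = [cA_depth, cD_depth, cD_depth-1, ..., cD_1]
    energy = np.zeros(n)
    for lvl in levels:
        d = coeffs[depth - lvl + 1]
        e = np.repeat(d.astype(float) ** 2, 2**lvl)
        if e.size >= n:
            energy += e[:n]
        else:
            energy[: e.size] += e
    width = max(1, int(round(smooth_s * rate_hz)))
    kernel = np.ones(width) / width
    return np.convolve(energy, kernel, mode="same")


def reconstruct_from_details(
    x: np.ndarray,
    levels: Sequence[int],
    rate_hz: float,
) -> np.ndarray:
    """Zero all coefficients except the requested detail levels and invert.

    Used by the wavelet step counters: the reconstruction isolates the
    subband where one oscillation per step (or per observed period) lives.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    levels = shift_levels(levels, rate_hz)
    depth = usable_depth(n, max(max(levels), 2))
    levels = {min(l, depth) for l in levels}
    coeffs = pywt.wavedec(x, WAVELET, level=depth)
    kept = [np.zeros_like(coeffs[0])]
    for i, c in enumerate(coeffs[1:], start=1):
        lvl = depth - i + 1
        kept.append(c if lvl in levels else np.zeros_like(c))
    rec = pywt.waverec(kept, WAVELET)
    return rec[:n]
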