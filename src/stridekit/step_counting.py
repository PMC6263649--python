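"""Step-event detection within walking bouts.

Five counters share one scored-peak interface: each transforms the
magnitude signal so that (ideally) one local maximum remains per step,
then ``detect_peaks`` prunes spurious maxima by minimum height, minimum
prominence and minimum inter-peak distance. The surviving peaks carry
their transformed-signal height as a detection score; the score
threshold is the single ROC sweep variable for every algorithm.

Counters
--------
fsm   : four-threshold finite state machine on the normalized magnitude.
ptm   : Pan-Tompkins chain — FIR low-pass (order 200, 50 Hz cutoff),
        first-difference differentiator, squaring, 0.5 s moving-window
        integrator.
stft  : spectral sparsifier keeping the largest coefficients until 20%
        of the spectral energy is retained, inverse transform, then a
        differentiator.
dwt   : db10 reconstruction from detail levels {6,7,8} (gait band).
dwt2  : db10 reconstruction from detail levels {2,3} (impact band).
"""

from __future__ import annotations

import logging
from itertools import product
from typing import Optional, Sequence

import numpy as np
from scipy import signal as sps

from . import wavelet
from .evaluation import strict_match
from .preprocess import normalize_variance
from .types import FSMConfig, GaitGroundTruth, PeakCriteria, StepDetections

log = logging.getLogger(__name__)

SC_ALGORITHMS = ("fsm", "ptm", "stft", "dwt", "dwt2")

#: Pan-Tompkins parameterization (FIR order, cutoff Hz, integrator s).
PTM_FILTER_ORDER = 200
PTM_CUTOFF_HZ = 50.0
PTM_INTEGRATOR_S = 0.5
#: Fraction of spectral energy retained by the STFT counter's filter.
STFT_ENERGY_FRACTION = 0.20
#: Detail levels (200 Hz reference) for the two wavelet counters.
DWT_LEVELS = (6, 7, 8)
DWT2_LEVELS = (2, 3)


def default_criteria(transformed: np.ndarray, min_distance_s: float = 0.25) -> PeakCriteria:
    """Default pruning rules: 0.25 s minimum distance and a prominence
    floor of 0.1 x the transformed signal's interquartile range."""
    q75, q25 = np.percentile(transformed, [75, 25])
    iqr = float(q75 - q25)
    prom = 0.1 * iqr if iqr > 0 else None
    return PeakCriteria(min_distance_s=min_distance_s, min_prominence=prom)


def detect_peaks(transformed: np.ndarray, criteria: PeakCriteria, rate_hz: float,
                 algorithm: str = "", params: Optional[dict] = None) -> StepDetections:
    """Scored peak detection with height/prominence/distance pruning.

    Candidate peaks are strict local maxima (plateau middles). After the
    height and prominence filters, candidates are greedily pruned by
    minimum distance in decreasing height order (ties to the earlier
    peak): a candidate survives only if no retained higher peak lies
    within ``min_distance_s``. The decision threshold is applied last so
    a stricter threshold always yields a subset of the events.
    """
    x = np.asarray(transformed, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("transformed signal must be finite")
    peaks, _ = sps.find_peaks(x)
    if peaks.size == 0:
        return StepDetections(np.array([], dtype=np.int64), np.array([]), algorithm, params or {})
    heights = x[peaks]
    keep = np.ones(peaks.size, dtype=bool)
    if criteria.min_height is not None:
        keep &= heights >= criteria.min_height
    if criteria.min_prominence is not None:
        prominences = sps.peak_prominences(x, peaks)[0]
        keep &= prominences >= criteria.min_prominence
    peaks, heights = peaks[keep], heights[keep]

    d = max(1, int(round(criteria.min_distance_s * rate_hz)))
    order = np.lexsort((peaks, -heights))  # height desc, then index asc
    accepted: list = []
    for i in order:
        p = peaks[i]
        if all(abs(p - a) >= d for a in accepted):
            accepted.append(p)
    accepted.sort()
    acc = np.array(accepted, dtype=np.int64)
    scores = x[acc]
    if criteria.threshold is not None:
        keep = scores >= criteria.threshold
        acc, scores = acc[keep], scores[keep]
    return StepDetections(acc, scores, algorithm, params or {})


# ---------------------------------------------------------------------------
# FSM

def fsm_count(normalized: np.ndarray, config: FSMConfig, rate_hz: float) -> StepDetections:
    """Five-state step machine on the variance-normalized magnitude.

    IDLE -(x > t2)-> RISING -(x > t1)-> PEAK -(x < t3)-> FALLING
    -(x < t4)-> VALLEY: emit one event at the PEAK-phase maximum and
    return to IDLE. Incomplete traversals emit nothing. The event score
    is the peak-phase maximum, enabling the shared ROC sweep.
    """
    x = np.asarray(normalized, dtype=float)
    IDLE, RISING, PEAK, FALLING = range(4)
    state = IDLE
    peak_idx = -1
    peak_val = -np.inf
    indices, scores = [], []
    for i, v in enumerate(x):
        if state == IDLE:
            if v > config.t2:
                state = RISING
        elif state == RISING:
            if v > config.t1:
                state = PEAK
                peak_idx, peak_val = i, v
            elif v < config.t3:
                state = IDLE  # dropped without reaching the peak band
        elif state == PEAK:
            if v > peak_val:
                peak_idx, peak_val = i, v
            if v < config.t3:
                state = FALLING
        elif state == FALLING:
            if v < config.t4:  # valley confirmed: one step
                indices.append(peak_idx)
                scores.append(peak_val)
                state = IDLE
            elif v > config.t1:  # bounced back into the peak band
                state = PEAK
    return StepDetections(np.array(indices, dtype=np.int64), np.array(scores),
                          "fsm", {"t1": config.t1, "t2": config.t2, "t3": config.t3, "t4": config.t4})


#: Default FSM grid on the unit-variance scale.
FSM_DEFAULT_GRID = {
    "t1": (0.6, 1.0, 1.4),
    "t2": (0.1, 0.3),
    "t3": (-0.3, -0.1),
    "t4": (-1.4, -1.0, -0.6),
}


def fsm_grid_search(
    normalized: np.ndarray,
    truth: GaitGroundTruth,
    rate_hz: float,
    grid: Optional[dict] = None,
    fpr_budget: float = 0.05,
) -> FSMConfig:
    """Grid search the four FSM thresholds on an annotated training bout.

    Maximizes strict TPR subject to FPR <= ``fpr_budget``; ties prefer a
    larger t1 (stricter peak band), then a larger t4 (the valley gate
    keeps margin from the valley floor, which generalizes better to
    unseen bouts). If no configuration meets the budget the minimum-FPR
    configuration is returned with a warning.
    """
    grid = grid or FSM_DEFAULT_GRID
    configs = [
        FSMConfig(t1, t2, t3, t4)
        for t1, t2, t3, t4 in product(grid["t1"], grid["t2"], grid["t3"], grid["t4"])
        if t1 > t2 >= 0 >= t3 > t4
    ]
    if not configs:
        raise ValueError("empty feasible threshold grid")
    results = []
    for cfg in configs:
        det = fsm_count(normalized, cfg, rate_hz)
        m = strict_match(det, truth)
        results.append((cfg, m.tpr, m.fpr))
    feasible = [r for r in results if r[2] <= fpr_budget]
    pool = feasible
    if not feasible:
        log.warning("no FSM config meets FPR budget %.3g; falling back to min-FPR", fpr_budget)
        min_fpr = min(r[2] for r in results)
        pool = [r for r in results if r[2] == min_fpr]
    best = max(pool, key=lambda r: (r[1], r[0].t1, r[0].t4))
    log.info("FSM grid search: t=(%.2f, %.2f, %.2f, %.2f) TPR %.3f FPR %.3f",
             best[0].t1, best[0].t2, best[0].t3, best[0].t4, best[1], best[2])
    return best[0]


# ---------------------------------------------------------------------------
# Pan-Tompkins

def ptm_transform(mag: np.ndarray, rate_hz: float) -> np.ndarray:
    """Low-pass -> differentiate -> square -> moving-window integrate."""
    x = np.asarray(mag, dtype=float)
    numtaps = PTM_FILTER_ORDER + 1
    if x.size <= numtaps:
        raise ValueError("bout shorter than the Pan-Tompkins filter transient")
    cutoff = PTM_CUTOFF_HZ
    if cutoff >= rate_hz / 2.0:
        cutoff = 0.45 * rate_hz
        log.warning("PTM cutoff clipped to %.3g Hz at rate %.3g Hz", cutoff, rate_hz)
    taps = sps.firwin(numtaps, cutoff, fs=rate_hz)
    # edge-padded linear-phase filtering: no group delay, no boundary
    # transients (a constant input stays exactly constant)
    half = numtaps // 2
    padded = np.pad(x, half, mode="edge")
    filtered = np.convolve(padded, taps, mode="same")[half:-half]
    deriv = np.diff(filtered, prepend=filtered[0])
    squared = deriv**2
    width = max(1, int(round(PTM_INTEGRATOR_S * rate_hz)))
    return np.convolve(squared, np.ones(width) / width, mode="same")


def ptm_count(mag: np.ndarray, rate_hz: float,
              criteria: Optional[PeakCriteria] = None) -> StepDetections:
    """Pan-Tompkins step counter: one integrator maximum per step."""
    integ = ptm_transform(mag, rate_hz)
    crit = criteria if criteria is not None else default_criteria(integ)
    return detect_peaks(integ, crit, rate_hz, "ptm",
                        {"order": PTM_FILTER_ORDER, "cutoff_hz": PTM_CUTOFF_HZ,
                         "integrator_s": PTM_INTEGRATOR_S})


# ---------------------------------------------------------------------------
# spectral sparsifier

def stft_transform(mag: np.ndarray, rate_hz: float, mode: str = "magnitude") -> np.ndarray:
    """Keep 20% of the spectral energy, invert, differentiate.

    The mean is removed first (on raw magnitude the gravity DC bin would
    absorb the entire energy budget). ``mode`` selects which coefficients
    fill the 20% budget: "magnitude" (default) keeps the largest
    coefficients; "lowfreq" accumulates from the low-frequency end.
    """
    x = np.asarray(mag, dtype=float)
    if x.size < 4:
        raise ValueError("bout too short for spectral filtering")
    x = x - x.mean()
    X = np.fft.rfft(x)
    # conjugate-symmetric pairs count double except DC / Nyquist bins
    weights = np.full(X.size, 2.0)
    weights[0] = 1.0
    if x.size % 2 == 0:
        weights[-1] = 1.0
    energies = weights * np.abs(X) ** 2
    total = energies.sum()
    if total == 0:
        raise ValueError("degenerate (all-zero) spectrum")
    if mode == "magnitude":
        order = np.lexsort((np.arange(energies.size), -energies))
    elif mode == "lowfreq":
        order = np.arange(energies.size)
    else:
        raise ValueError("mode must be 'magnitude' or 'lowfreq'")
    cum = np.cumsum(energies[order])
    n_keep = int(np.searchsorted(cum, STFT_ENERGY_FRACTION * total) + 1)
    kept = order[:n_keep]
    X_sparse = np.zeros_like(X)
    X_sparse[kept] = X[kept]
    rec = np.fft.irfft(X_sparse, n=x.size)
    return np.diff(rec, prepend=rec[0])


def stft_kept_energy_fraction(mag: np.ndarray, mode: str = "magnitude") -> float:
    """Fraction of spectral energy actually retained by the 20% filter."""
    x = np.asarray(mag, dtype=float)
    x = x - x.mean()
    X = np.fft.rfft(x)
    weights = np.full(X.size, 2.0)
    weights[0] = 1.0
    if x.size % 2 == 0:
        weights[-1] = 1.0
    energies = weights * np.abs(X) ** 2
    total = energies.sum()
    if mode == "magnitude":
        order = np.lexsort((np.arange(energies.size), -energies))
    else:
        order = np.arange(energies.size)
    cum = np.cumsum(energies[order])
    n_keep = int(np.searchsorted(cum, STFT_ENERGY_FRACTION * total) + 1)
    return float(cum[n_keep - 1] / total)


def stft_count(mag: np.ndarray, rate_hz: float, mode: str = "magnitude",
               criteria: Optional[PeakCriteria] = None) -> StepDetections:
    """Spectral-sparsifier step counter."""
    deriv = stft_transform(mag, rate_hz, mode=mode)
    crit = criteria if criteria is not None else default_criteria(deriv)
    return detect_peaks(deriv, crit, rate_hz, "stft",
                        {"energy_fraction": STFT_ENERGY_FRACTION, "mode": mode})


# ---------------------------------------------------------------------------
# wavelet counters

def dwt_count(mag: np.ndarray, rate_hz: float, variant: str = "dwt",
              criteria: Optional[PeakCriteria] = None) -> StepDetections:
    """Wavelet-reconstruction step counter (variant 'dwt' or 'dwt2')."""
    if variant == "dwt":
        levels: Sequence[int] = DWT_LEVELS
    elif variant == "dwt2":
        levels = DWT2_LEVELS
    else:
        raise ValueError("variant must be 'dwt' or 'dwt2'")
    rec = wavelet.reconstruct_from_details(mag, levels, rate_hz)
    crit = criteria if criteria is not None else default_criteria(rec)
    return detect_peaks(rec, crit, rate_hz, variant, {"levels": tuple(levels)})


# ---------------------------------------------------------------------------
# shared entry point

def count_steps(
    mag: np.ndarray,
    rate_hz: float,
    algo: str,
    fsm_config: Optional[FSMConfig] = None,
    truth: Optional[GaitGroundTruth] = None,
    criteria: Optional[PeakCriteria] = None,
    stft_mode: str = "magnitude",
) -> StepDetections:
    """Run one step counter on a magnitude signal.

    The FSM requires either a config or annotated training truth for its
    grid search; the other counters are training-free.
    """
    if algo == "fsm":
        norm = normalize_variance(mag)
        if fsm_config is None:
            if truth is None:
                raise ValueError("FSM needs a config or training ground truth")
            fsm_config = fsm_grid_search(norm, truth, rate_hz)
        return fsm_count(norm, fsm_config, rate_hz)
    if algo == "ptm":
        return ptm_count(mag, rate_hz, criteria=criteria)
    if algo == "stft":
        return stft_count(normalize_variance(mag), rate_hz, mode=stft_mode, criteria=criteria)
    if algo in ("dwt", "dwt2"):
        return dwt_count(normalize_variance(mag), rate_hz, variant=algo, criteria=criteria)
    raise ValueError(f"unknown step-counting algorithm {algo!r}")


def fold_group2_events(detections: StepDetections) -> StepDetections:
    """Collapse Group II event pairs to one step per gait cycle.

    Group II placements show two observed periods per gait cycle, so the
    counters emit two events per step; consecutive events are paired and
    the higher-scored member of each pair kept (ties to the earlier).
    """
    n = len(detections)
    keep = []
    for j in range(0, n - 1, 2):
        keep.append(j if detections.scores[j] >= detections.scores[j + 1] else j + 1)
    if n % 2 == 1:
        keep.append(n - 1)
    keep = np.array(sorted(keep), dtype=int)
    return StepDetections(detections.indices[keep], detections.scores[keep],
                          detections.algorithm, dict(detections.params))
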