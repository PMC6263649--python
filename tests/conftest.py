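import numpy as np
import pytest

from stridekit.simulate import GaitModelParams, simulate_walk


@pytest.fixture(scope="session")
def clean_bout():
    """Zero-noise Group I walking bout: 60 cycles at 1 Hz stride, 200 Hz."""
    params = GaitModelParams(stride_frequency_hz=1.0, noise_sd=0.0)
    rec, truth = simulate_walk(params, 60.0, 200.0, seed=0)
    return rec, truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


# ---------------------------------------------------------------------------
# independent brute-force oracles (deliberately simple and loop-based)

def bruteforce_strict_counts(indices, cycles):
    """Per-cycle strict counting by explicit enumeration."""
    ctp = cfp = 0
    for start, end in cycles:
        n_in = sum(1 for i in indices if start <= i < end)
        if n_in > 0:
            ctp += 1
            cfp += n_in - 1
    outside = sum(
        1 for i in indices if not any(start <= i < end for start, end in cycles)
    )
    return ctp, cfp + outside


def bruteforce_prominence(x, i):
    """Prominence of a local maximum by explicit left/right scans."""
    h = x[i]
    left_min = h
    j = i - 1
    while j >= 0 and x[j] <= h:
        left_min = min(left_min, x[j])
        j -= 1
    right_min = h
    j = i + 1
    while j < len(x) and x[j] <= h:
        right_min = min(right_min, x[j])
        j += 1
    return h - max(left_min, right_min)


def bruteforce_peaks(x, min_height, min_distance_s, min_prominence, threshold, rate_hz):
    """Exhaustive scored-peak pruning: strict local maxima, height and
    prominence filters, greedy distance pruning in decreasing-height
    order (ties to the earlier index), score threshold last."""
    x = np.asarray(x, dtype=float)
    cand = [i for i in range(1, len(x) - 1) if x[i - 1] < x[i] > x[i + 1]]
    if min_height is not None:
        cand = [i for i in cand if x[i] >= min_height]
    if min_prominence is not None:
        cand = [i for i in cand if bruteforce_prominence(x, i) >= min_prominence]
    d = max(1, int(round(min_distance_s * rate_hz)))
    accepted = []
    for i in sorted(cand, key=lambda i: (-x[i], i)):
        if all(abs(i - j) >= d for j in accepted):
            accepted.append(i)
    accepted.sort()
    if threshold is not None:
        accepted = [i for i in accepted if x[i] >= threshold]
    return accepted


def bruteforce_best_split(stats, labels):
    """Best achievable thresholding accuracy over both polarities, by
    trying every midpoint and the extremes."""
    stats = np.asarray(stats, dtype=float)
    labels = np.asarray(labels, dtype=int)
    distinct = sorted(set(stats))
    candidates = [distinct[0]] + [
        (a + b) / 2 for a, b in zip(distinct[:-1], distinct[1:])
    ] + [distinct[-1] + 1.0]
    best = 0.0
    for thr in candidates:
        for walk_above in (True, False):
            pred = (stats >= thr) if walk_above else (stats <= thr)
            best = max(best, float(np.mean(pred.astype(int) == labels)))
    return best


def bruteforce_frame_count(n, w, hop):
    count = 0
    start = 0
    while start + w <= n:
        count += 1
        start += hop
    return count
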