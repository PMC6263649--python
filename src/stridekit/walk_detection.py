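"""Per-frame walk detection by five detectors.

Three signal-statistic detectors threshold a scalar per-frame statistic
(magnitude variance for THR; spectral energy in the [0.66, 1.66] Hz walk
band for STFT; smoothed level-7/8 wavelet detail energy for DWT), with
the threshold fitted by the same exhaustive best-accuracy scan in every
case. Two machine-learning detectors (k-NN with k=5 and an RBF-kernel
SVM) classify the full feature vector under stratified 10-fold
cross-validation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from . import wavelet
from .preprocess import FrameSet

log = logging.getLogger(__name__)

#: Canonical walking band for the spectral detector (Hz), closed interval.
WALK_BAND_HZ = (0.66, 1.66)
#: Detail levels used by the wavelet walk detector at the 200 Hz reference.
WD_DWT_LEVELS = (7, 8)


@dataclass
class WDPrediction:
    """Binary per-frame walk states aligned with a FrameSet."""

    states: np.ndarray
    algorithm: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=int)

    def __len__(self) -> int:
        return int(self.states.size)


@dataclass
class WDThresholdModel:
    """A fitted scalar decision rule on a per-frame statistic.

    ``walk_above`` gives the polarity: walk iff statistic >= threshold
    (or <= when False). Both polarities are scanned at fit time because
    walking variance sits between sedentary and vigorous activities.
    """

    threshold: float
    statistic: str
    walk_above: bool = True
    train_accuracy: float = float("nan")

    def predict(self, stats: np.ndarray) -> np.ndarray:
        stats = np.asarray(stats, dtype=float)
        if self.walk_above:
            return (stats >= self.threshold).astype(int)
        return (stats <= self.threshold).astype(int)


def best_threshold(stats: np.ndarray, labels: np.ndarray, statistic: str = "statistic") -> WDThresholdModel:
    """Exhaustive accuracy-maximizing threshold scan.

    Candidates are all midpoints between consecutive distinct sorted
    statistic values plus the extremes (all-walk / no-walk rules). Ties
    resolve to the smallest threshold; polarity ties prefer walk-above.
    """
    stats = np.asarray(stats, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if np.unique(labels).size < 2:
        raise ValueError("both classes required to fit a threshold")
    distinct = np.unique(stats)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    candidates = np.concatenate(([distinct[0]], mids, [distinct[-1] + 1.0]))

    ge = stats[None, :] >= candidates[:, None]
    acc_above = np.mean(ge == (labels[None, :] == 1), axis=1)
    acc_below = np.mean(~ge == (labels[None, :] == 1), axis=1)

    best_above = int(np.argmax(acc_above))  # argmax takes first = smallest thr
    best_below = int(np.argmax(acc_below))
    if acc_above[best_above] >= acc_below[best_below]:
        model = WDThresholdModel(float(candidates[best_above]), statistic, True, float(acc_above[best_above]))
    else:
        model = WDThresholdModel(float(candidates[best_below]), statistic, False, float(acc_below[best_below]))
    log.info("fitted %s threshold %.6g (walk_%s, train acc %.3f)",
             statistic, model.threshold, "above" if model.walk_above else "below", model.train_accuracy)
    return model


# ---------------------------------------------------------------------------
# per-frame statistics

def frame_variance(frames: Sequence[np.ndarray]) -> np.ndarray:
    """Magnitude variance per frame (the THR statistic)."""
    return np.array([np.var(f) for f in frames])


def band_energy(frames: Sequence[np.ndarray], rate_hz: float,
                band_hz: Tuple[float, float] = WALK_BAND_HZ) -> np.ndarray:
    """One-sided spectral energy within the closed walk band per frame."""
    lo, hi = band_hz
    if hi >= rate_hz / 2.0:
        raise ValueError("walk band must lie below Nyquist")
    out = np.empty(len(frames))
    for i, f in enumerate(frames):
        spec = np.abs(np.fft.rfft(f)) ** 2
        freqs = np.fft.rfftfreq(len(f), d=1.0 / rate_hz)
        mask = (freqs >= lo) & (freqs <= hi)
        out[i] = spec[mask].sum()
    return out


def dwt_frame_energy(signal: np.ndarray, frameset: FrameSet,
                     levels: Sequence[int] = WD_DWT_LEVELS) -> np.ndarray:
    """Mean smoothed level-7/8 detail energy per frame (the DWT statistic).

    Computed once on the whole signal (1 s moving-average smoothing),
    then averaged over each frame's samples.
    """
    energy = wavelet.detail_energy_per_sample(signal, levels, frameset.rate_hz, smooth_s=1.0)
    return np.array([energy[s:e].mean() for s, e, _ in frameset.frames])


# ---------------------------------------------------------------------------
# detectors

def thr_fit(frames: Sequence[np.ndarray], labels: np.ndarray) -> WDThresholdModel:
    """Fit the variance-threshold detector on labeled training frames."""
    return best_threshold(frame_variance(frames), labels, statistic="variance")


def thr_predict(frames: Sequence[np.ndarray], model: WDThresholdModel) -> WDPrediction:
    states = model.predict(frame_variance(frames))
    return WDPrediction(states, "thr", {"threshold": model.threshold, "walk_above": model.walk_above})


def stft_wd(frames: Sequence[np.ndarray], rate_hz: float, labels: Optional[np.ndarray] = None,
            model: Optional[WDThresholdModel] = None,
            band_hz: Tuple[float, float] = WALK_BAND_HZ) -> Tuple[WDPrediction, WDThresholdModel]:
    """Walk detection by thresholded walk-band spectral energy.

    Fits the threshold on ``labels`` when no model is given; returns the
    per-frame prediction together with the (possibly freshly fitted)
    model.
    """
    stats = band_energy(frames, rate_hz, band_hz)
    if model is None:
        if labels is None:
            raise ValueError("either a fitted model or labels are required")
        model = best_threshold(stats, labels, statistic="band_energy")
    pred = WDPrediction(model.predict(stats), "stft",
                        {"band_hz": band_hz, "threshold": model.threshold, "walk_above": model.walk_above})
    return pred, model


def dwt_wd(signal: np.ndarray, frameset: FrameSet, labels: Optional[np.ndarray] = None,
           model: Optional[WDThresholdModel] = None,
           levels: Sequence[int] = WD_DWT_LEVELS) -> Tuple[WDPrediction, WDThresholdModel]:
    """Walk detection by smoothed wavelet detail energy in the gait band."""
    stats = dwt_frame_energy(signal, frameset, levels)
    if model is None:
        if labels is None:
            raise ValueError("either a fitted model or labels are required")
        model = best_threshold(stats, labels, statistic="dwt_energy")
    pred = WDPrediction(model.predict(stats), "dwt",
                        {"levels": tuple(levels), "threshold": model.threshold, "walk_above": model.walk_above})
    return pred, model


#: Small SVM hyperparameter grid searched inside training folds.
SVM_GRID = {"svc__C": [1.0, 10.0, 100.0]}


def _classifier(algo: str, seed: int):
    if algo == "knn":
        return Pipeline([("scale", StandardScaler()),
                         ("knn", KNeighborsClassifier(n_neighbors=5))])
    if algo == "svm":
        pipe = Pipeline([("scale", StandardScaler()),
                         ("svc", SVC(kernel="rbf", gamma="scale", random_state=seed))])
        return GridSearchCV(pipe, SVM_GRID, cv=3, n_jobs=1)
    raise ValueError(f"unknown ML algorithm {algo!r}")


def ml_wd_fit_predict(
    X: np.ndarray,
    y: np.ndarray,
    algo: str = "svm",
    folds: int = 10,
    seed: int = 0,
) -> Tuple[WDPrediction, float]:
    """Stratified k-fold cross-validated walk detection (k-NN or SVM-RBF).

    Features are standardized per training fold; the SVM's C is chosen by
    a small grid search inside each training fold. Accuracy is the pooled
    fraction of correctly classified frames.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < folds:
        raise ValueError(f"need at least {folds} samples per class (have {counts.min()})")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    pred = np.empty_like(y)
    for train_idx, test_idx in skf.split(X, y):
        clf = _classifier(algo, seed)
        clf.fit(X[train_idx], y[train_idx])
        pred[test_idx] = clf.predict(X[test_idx])
    acc = float(np.mean(pred == y))
    log.info("%s %d-fold CV accuracy %.3f (n=%d)", algo, folds, acc, y.size)
    return WDPrediction(pred, algo, {"folds": folds, "seed": seed}), acc


def adaptive_folds(y: np.ndarray, folds: int = 10) -> int:
    """Largest usable fold count (per-subject slices can be small)."""
    _, counts = np.unique(np.asarray(y), return_counts=True)
    return max(2, min(folds, int(counts.min())))
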