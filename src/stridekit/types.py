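"""Core containers shared by the simulator, detectors, counters and evaluators.

Conventions used throughout the package:

* sample indexing is 0-based; segments and gait cycles are half-open
  ``[start, end)`` intervals;
* acceleration is expressed in g unless a recording declares otherwise
  (a static sensor therefore has magnitude ~1);
* a "step" is one annotated gait cycle of the instrumented side — counters
  are expected to emit exactly one event per cycle.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

#: Closed activity vocabulary for label segments.
ACTIVITIES = (
    "walk",
    "stairs_up",
    "stairs_down",
    "run",
    "ride",
    "brush_teeth",
    "drive",
    "bus",
    "sit",
    "stand",
    "other",
)

#: Sensor wearing placements.
PLACEMENTS = ("Foot", "FrontPocket", "BackPocket", "UpPocket", "Hand", "HandU")

#: Placements whose magnitude shows one signal period per gait cycle.
GROUP_I = frozenset({"Foot", "FrontPocket", "BackPocket", "Hand", "HandU"})
#: Placements whose magnitude shows two periods per gait cycle (the free
#: leg's swing also modulates the signal).
GROUP_II = frozenset({"UpPocket"})


def group_of(placement: str, hand_group: str = "I") -> str:
    """Map a placement to its signal-period group ("I" or "II").

    Hand-held placements are ambiguous (hand swing may either mirror the
    instrumented leg or both legs); ``hand_group`` overrides the default
    Group I assignment for Hand/HandU.
    """
    if placement not in PLACEMENTS:
        raise ValueError(f"unknown placement {placement!r}; expected one of {PLACEMENTS}")
    if placement in ("Hand", "HandU"):
        if hand_group not in ("I", "II"):
            raise ValueError("hand_group must be 'I' or 'II'")
        return hand_group
    return "I" if placement in GROUP_I else "II"


@dataclass
class AccelRecording:
    """Tri-axial accelerometer time series with optional activity labels.

    Attributes
    ----------
    time_s : (n,) array of strictly increasing sample times in seconds.
    samples : (n, 3) array of accelerations (ax, ay, az).
    rate_hz : nominal sampling rate.
    units : unit of the samples, "g" (default) or "m/s2".
    labels : list of ``(start_s, end_s, activity)`` half-open segments.
    """

    time_s: np.ndarray
    samples: np.ndarray
    rate_hz: float
    units: str = "g"
    placement: Optional[str] = None
    subject: Optional[str] = None
    labels: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != 3:
            raise ValueError("samples must have shape (n, 3)")
        if self.time_s.shape[0] != self.samples.shape[0]:
            raise ValueError("time_s and samples must have equal length")
        if self.time_s.size >= 2 and not np.all(np.diff(self.time_s) > 0):
            raise ValueError("time_s must be strictly increasing")
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")

    @property
    def n(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n / self.rate_hz

    def rotated(self, rotation: np.ndarray) -> "AccelRecording":
        """Return a copy observed through a rotated sensor frame."""
        rotation = np.asarray(rotation, dtype=float)
        if rotation.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if not np.allclose(rotation @ rotation.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation must be orthonormal")
        return replace(self, samples=self.samples @ rotation.T)

    def activity_at(self, t: float) -> str:
        """Activity label covering time ``t`` ('other' if uncovered)."""
        for start, end, activity in self.labels:
            if start <= t < end:
                return activity
        return "other"


@dataclass
class GaitGroundTruth:
    """Annotated gait cycles of a walking bout.

    ``cycles`` is an (C, 2) integer array of half-open ``[start, end)``
    sample-index intervals, ordered and non-overlapping. The true step
    count is the number of cycles.
    """

    cycles: np.ndarray

    def __post_init__(self) -> None:
        self.cycles = np.asarray(self.cycles, dtype=np.int64).reshape(-1, 2)
        if len(self.cycles):
            if np.any(self.cycles[:, 0] >= self.cycles[:, 1]):
                raise ValueError("each cycle must satisfy start < end")
            if np.any(self.cycles[1:, 0] < self.cycles[:-1, 1]):
                raise ValueError("cycles must be ordered and non-overlapping")

    @property
    def cgt(self) -> int:
        return len(self.cycles)

    def shifted(self, offset: int) -> "GaitGroundTruth":
        return GaitGroundTruth(self.cycles + int(offset))


@dataclass
class StepDetections:
    """Detected step events with per-event detection scores.

    Scores are peak heights in the algorithm's transformed signal; the
    ROC sweep filters events by score, so the container must stay sorted
    by sample index.
    """

    indices: np.ndarray
    scores: np.ndarray
    algorithm: str = ""
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=np.int64)
        self.scores = np.asarray(self.scores, dtype=float)
        if self.indices.shape != self.scores.shape:
            raise ValueError("indices and scores must align")
        if self.indices.size >= 2 and not np.all(np.diff(self.indices) > 0):
            raise ValueError("event indices must be strictly increasing")

    def __len__(self) -> int:
        return int(self.indices.size)

    def above(self, threshold: float) -> "StepDetections":
        """Events whose score is >= ``threshold`` (the ROC sweep variable)."""
        keep = self.scores >= threshold
        return StepDetections(self.indices[keep], self.scores[keep], self.algorithm, dict(self.params))


@dataclass
class StrictSCMetrics:
    """Per-gait-cycle step-counting metrics.

    A cycle with n > 0 detected events contributes one true positive and
    n - 1 false positives; events outside every cycle are false positives.
    FPR = Cfp / Cgt may exceed 1.
    """

    ctp: int
    cfp: int
    cgt: int
    cest: int

    def __post_init__(self) -> None:
        if self.cgt <= 0:
            raise ValueError("Cgt must be positive")
        if not (0 <= self.ctp <= self.cgt):
            raise ValueError("Ctp must lie in [0, Cgt]")
        if self.cfp < 0:
            raise ValueError("Cfp must be non-negative")

    @property
    def tpr(self) -> float:
        return self.ctp / self.cgt

    @property
    def fpr(self) -> float:
        return self.cfp / self.cgt

    @property
    def misses(self) -> int:
        return self.cgt - self.ctp

    @property
    def loose_error_pct(self) -> float:
        """Signed loose error (Cest - Cgt) / Cgt * 100%."""
        return (self.cest - self.cgt) / self.cgt * 100.0

    def as_dict(self) -> dict:
        return {
            "ctp": self.ctp,
            "cfp": self.cfp,
            "cgt": self.cgt,
            "cest": self.cest,
            "tpr": self.tpr,
            "fpr": self.fpr,
            "loose_error_pct": self.loose_error_pct,
        }


@dataclass(frozen=True)
class ContextSpec:
    """The five evaluation-context variables.

    io_known: sensor orientation known (features on all three axes).
    ip_known: personalized (train and test per subject).
    rate_hz:  sampling rate R in [5, 200].
    window_s: frame size W in [1.5, 6].
    placement: restrict to one wearing location, or None for pooled data.
    """

    io_known: bool = False
    ip_known: bool = False
    rate_hz: float = 200.0
    window_s: float = 3.0
    placement: Optional[str] = None

    def __post_init__(self) -> None:
        if not (5.0 <= self.rate_hz <= 200.0):
            raise ValueError("rate_hz must lie in [5, 200]")
        if not (1.5 <= self.window_s <= 6.0):
            raise ValueError("window_s must lie in [1.5, 6]")
        if self.placement is not None and self.placement not in PLACEMENTS:
            raise ValueError(f"unknown placement {self.placement!r}")


BASELINE_CONTEXT = ContextSpec()


@dataclass(frozen=True)
class FSMConfig:
    """Four thresholds of the step-counting finite state machine.

    Applied to the variance-normalized magnitude; must satisfy
    t1 > t2 >= 0 >= t3 > t4.
    """

    t1: float
    t2: float
    t3: float
    t4: float

    def __post_init__(self) -> None:
        if not (self.t1 > self.t2 >= 0.0 >= self.t3 > self.t4):
            raise ValueError("FSM thresholds must satisfy t1 > t2 >= 0 >= t3 > t4")


@dataclass(frozen=True)
class PeakCriteria:
    """Pruning rules for scored peak detection.

    ``threshold`` is the ROC sweep variable and is applied last, after
    height/prominence filtering and greedy distance pruning, so that a
    higher threshold always selects a subset of the events.
    """

    min_height: Optional[float] = None
    min_distance_s: float = 0.25
    min_prominence: Optional[float] = None
    threshold: Optional[float] = None

    def __post_init__(self) -> None:
        if self.min_distance_s <= 0:
            raise ValueError("min_distance_s must be positive")


@dataclass
class ROCCurve:
    """Ordered ROC points: thresholds strictly decreasing, rates non-decreasing."""

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray

    def __post_init__(self) -> None:
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        self.fpr = np.asarray(self.fpr, dtype=float)
        self.tpr = np.asarray(self.tpr, dtype=float)
        if not (self.thresholds.shape == self.fpr.shape == self.tpr.shape):
            raise ValueError("ROC columns must align")
        if self.thresholds.size >= 2 and not np.all(np.diff(self.thresholds) < 0):
            raise ValueError("thresholds must be strictly decreasing")

    def __len__(self) -> int:
        return int(self.thresholds.size)

    def best_tpr_at_fpr(self, fpr_max: float) -> float:
        """Highest TPR among points with FPR <= fpr_max (0.0 if none)."""
        ok = self.fpr <= fpr_max
        return float(self.tpr[ok].max()) if ok.any() else 0.0

    def operating_point(self, fpr_target: float) -> tuple:
        """(threshold, fpr, tpr) nearest to fpr_target; ties to lower FPR."""
        gap = np.abs(self.fpr - fpr_target)
        best = np.lexsort((self.fpr, gap))[0]
        return float(self.thresholds[best]), float(self.fpr[best]), float(self.tpr[best])


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniformly random proper rotation matrix (Haar via QR)."""
    a = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(a)
    q = q * np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
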