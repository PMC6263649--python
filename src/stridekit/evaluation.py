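"""Evaluation metrics: frame-level walk-detection error, loose and strict
step-counting error, per-gait-cycle ROC curves, error-source
decomposition, and context-delta reporting.

The strict step-counting definition scores detections per annotated gait
cycle: a cycle holding n > 0 events contributes one true positive and
n - 1 false positives; an empty cycle is a miss; events landing outside
every cycle are false positives. TPR = Ctp/Cgt and FPR = Cfp/Cgt, so the
FPR can exceed 1 when an algorithm over-counts heavily.
"""

from __future__ import annotations

from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .types import GaitGroundTruth, ROCCurve, StepDetections, StrictSCMetrics


def wd_error(prediction: np.ndarray, truth: np.ndarray) -> Tuple[int, float]:
    """Frame-level disagreement count and accuracy.

    error = sum_t |s_t - f_t| over aligned binary frame states;
    accuracy = 1 - error / T.
    """
    p = np.asarray(prediction, dtype=int)
    s = np.asarray(truth, dtype=int)
    if p.shape != s.shape:
        raise ValueError("prediction and truth must align")
    err = int(np.sum(np.abs(s - p)))
    return err, 1.0 - err / s.size


def sc_error(cest: int, n_true: int) -> Tuple[float, float]:
    """Relative step-count error and the signed loose variant.

    Returns (|n_true - cest| / n_true, (cest - n_true) / n_true * 100%).
    The relative error can exceed 1 when the counter over-counts more
    than twofold.
    """
    if n_true <= 0:
        raise ValueError("true step count must be positive")
    rel = abs(n_true - cest) / n_true
    loose_pct = (cest - n_true) / n_true * 100.0
    return rel, loose_pct


def strict_match(detections: StepDetections, truth: GaitGroundTruth) -> StrictSCMetrics:
    """Score detected events against annotated gait cycles (strict rule)."""
    if truth.cgt == 0:
        raise ValueError("ground truth has no gait cycles")
    idx = detections.indices
    starts = truth.cycles[:, 0]
    ends = truth.cycles[:, 1]
    # cycles are ordered and non-overlapping: locate each event's cycle
    pos = np.searchsorted(starts, idx, side="right") - 1
    inside = (pos >= 0) & (idx < ends[np.clip(pos, 0, len(ends) - 1)])
    per_cycle = np.bincount(pos[inside], minlength=truth.cgt)
    ctp = int(np.sum(per_cycle > 0))
    cfp = int(np.sum(per_cycle[per_cycle > 0] - 1)) + int(np.sum(~inside))
    return StrictSCMetrics(ctp=ctp, cfp=cfp, cgt=truth.cgt, cest=len(detections))


def roc_curve(
    detections: StepDetections,
    truth: GaitGroundTruth,
    thresholds: Optional[np.ndarray] = None,
) -> ROCCurve:
    """Strict-metric ROC by sweeping the detection-score threshold.

    ``detections`` must be the full scored event stream (threshold not
    yet applied). The default grid is one point above the maximum score,
    then every distinct score in decreasing order, so the curve starts at
    (0, 0) and ends at the all-events operating point. Because
    thresholding selects score-subsets of a fixed event stream, TPR and
    FPR are non-decreasing along the curve.
    """
    if thresholds is None:
        if len(detections) == 0:
            thresholds = np.array([1.0])
        else:
            uniq = np.unique(detections.scores)[::-1]
            thresholds = np.concatenate(([uniq[0] + 1.0], uniq))
    thresholds = np.asarray(thresholds, dtype=float)
    fprs, tprs = [], []
    for thr in thresholds:
        m = strict_match(detections.above(thr), truth)
        fprs.append(m.fpr)
        tprs.append(m.tpr)
    return ROCCurve(thresholds, np.array(fprs), np.array(tprs))


def error_sources(
    metrics_by_placement: Dict[str, StrictSCMetrics],
) -> Dict[str, float]:
    """Each placement's share of the total false positives at a common
    operating point; shares sum to 1."""
    total = sum(m.cfp for m in metrics_by_placement.values())
    if total == 0:
        raise ValueError("no false positives to apportion")
    return {p: m.cfp / total for p, m in metrics_by_placement.items()}


def metrics_at_operating_point(
    detections: StepDetections,
    truth: GaitGroundTruth,
    fpr_target: float,
) -> StrictSCMetrics:
    """Strict metrics at the ROC point nearest ``fpr_target`` (ties to
    lower FPR)."""
    curve = roc_curve(detections, truth)
    thr, _, _ = curve.operating_point(fpr_target)
    return strict_match(detections.above(thr), truth)


def pooled_tpr_at_fpr(
    detections: Sequence[StepDetections],
    truths: Sequence[GaitGroundTruth],
    fpr_target: float,
) -> Tuple[float, float, float]:
    """One shared score threshold across several bouts, chosen so the
    pooled FPR is nearest ``fpr_target`` (ties to lower FPR).

    Returns (tpr, fpr, threshold) of the pooled counts at that point.
    """
    if len(detections) != len(truths) or not detections:
        raise ValueError("need matching, non-empty detection/truth lists")
    scores = np.concatenate([d.scores for d in detections])
    if scores.size == 0:
        thresholds = np.array([1.0])
    else:
        uniq = np.unique(scores)[::-1]
        thresholds = np.concatenate(([uniq[0] + 1.0], uniq))
    best = None
    for thr in thresholds:
        ctp = cfp = cgt = 0
        for det, truth in zip(detections, truths):
            m = strict_match(det.above(thr), truth)
            ctp += m.ctp
            cfp += m.cfp
            cgt += m.cgt
        tpr, fpr = ctp / cgt, cfp / cgt
        key = (abs(fpr - fpr_target), fpr, -tpr)
        if best is None or key < best[0]:
            best = (key, (tpr, fpr, float(thr)))
    return best[1]


def context_report(
    baseline: float,
    by_axis: Dict[str, Dict[str, float]],
    metric_name: str = "accuracy",
) -> pd.DataFrame:
    """Delta table of context effects against a baseline value.

    ``by_axis`` maps a context axis (e.g. "orientation", "placement") to
    its per-setting metric values. Each axis reports per-setting deltas
    plus a [min delta, max delta] range row, mirroring the usual context
    summary tables.
    """
    rows = [{"axis": "baseline", "setting": "-", metric_name: baseline,
             "delta": 0.0, "delta_min": 0.0, "delta_max": 0.0}]
    for axis, settings in by_axis.items():
        if not settings:
            raise ValueError(f"context axis {axis!r} has no runs")
        deltas = {s: v - baseline for s, v in settings.items()}
        for setting, value in settings.items():
            rows.append({"axis": axis, "setting": setting, metric_name: value,
                         "delta": deltas[setting],
                         "delta_min": min(deltas.values()),
                         "delta_max": max(deltas.values())})
    return pd.DataFrame(rows)
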