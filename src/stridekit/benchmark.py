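"""Synthetic study conditions: reproducible walk-detection and
step-counting benchmarks built from the simulator.

The walk-detection benchmark emulates a cohort of subjects, each with a
personal amplitude scale, preferred cadence and movement signature,
recording labeled sessions (walk, stairs, run, ride, sedentary) at
several placements with free sensor orientation. Frames, per-frame
statistics and feature matrices are precomputed so the five detectors
can be evaluated under any context (orientation / personalization /
sampling rate / window size / placement).

The step-counting benchmark simulates annotated walking bouts and
sweeps each counter's score threshold into a strict per-cycle ROC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import evaluation, features, step_counting, walk_detection
from .preprocess import WD_LOWPASS_HZ, frame, lowpass, magnitude, resample
from .simulate import (
    DEFAULT_ACTIVITY_MODELS,
    ActivityModel,
    GaitModelParams,
    SubjectProfile,
    compose_session,
    make_subjects,
    simulate_walk,
)
from .types import ContextSpec, GaitGroundTruth, random_rotation

log = logging.getLogger(__name__)

WD_ALGORITHMS = ("thr", "stft", "dwt", "knn", "svm")

#: Session plan used by the walk-detection benchmark (activity, seconds).
DEFAULT_SESSION_PLAN = (
    ("walk", 45.0),
    ("stairs_up", 21.0),
    ("run", 21.0),
    ("ride", 21.0),
    ("stand", 15.0),
    ("walk", 24.0),
    ("sit", 15.0),
)

#: Placements cycled through by the benchmark sessions.
BENCH_PLACEMENTS = ("FrontPocket", "BackPocket", "Hand", "Foot")

BASE_WALK_HARMONICS = (0.40, 0.20, 0.10)


@dataclass
class WDFrameTable:
    """Framed benchmark sessions with precomputed statistics/features.

    ``meta`` has one row per frame (subject, placement, activity, label);
    ``stats`` holds the scalar detector statistics for the magnitude and
    each axis; ``X_mag`` / ``X_3ax`` are the ML feature matrices.
    """

    meta: pd.DataFrame
    stats: pd.DataFrame
    X_mag: np.ndarray
    X_3ax: np.ndarray
    rate_hz: float
    window_s: float

    def __len__(self) -> int:
        return len(self.meta)

    def subset(self, mask: np.ndarray) -> "WDFrameTable":
        mask = np.asarray(mask)
        return WDFrameTable(
            self.meta.loc[mask].reset_index(drop=True),
            self.stats.loc[mask].reset_index(drop=True),
            self.X_mag[mask],
            self.X_3ax[mask],
            self.rate_hz,
            self.window_s,
        )


def subject_walk_params(
    subject: SubjectProfile,
    placement: str,
    rng: np.random.Generator,
    noise_sd: float = 0.05,
    orientation: Optional[np.ndarray] = None,
) -> GaitModelParams:
    """Walking-model parameters for one subject at one placement."""
    jitter = subject.jitter_for("walk", len(BASE_WALK_HARMONICS), rng)
    harmonics = tuple(a * j for a, j in zip(BASE_WALK_HARMONICS, jitter))
    return GaitModelParams(
        stride_frequency_hz=subject.stride_hz,
        harmonic_amplitudes=harmonics,
        subject_scale=subject.scale,
        placement=placement,
        noise_sd=noise_sd,
        orientation=orientation,
    )


def _subject_activity_models(
    subject: SubjectProfile,
    rng: np.random.Generator,
    stairs_like: Optional[SubjectProfile] = None,
) -> dict:
    """Per-subject variants of the non-walk activities.

    Harmonics are jittered once per subject per activity (personal
    movement signatures). Stair climbing is modeled as a slightly slowed
    walk-like gait drawn from ``stairs_like``'s walking signature (a
    different cohort member by default): pooled across subjects, walk and
    stairs distributions then overlap irreducibly, while each subject's
    own walk remains separable from their own stairs — the regime where
    personalization pays off.
    """
    stairs_like = stairs_like if stairs_like is not None else subject
    models = {}
    for name, base in DEFAULT_ACTIVITY_MODELS.items():
        if base.fundamental_hz is None or not base.harmonic_amplitudes:
            models[name] = base
            continue
        if name.startswith("stairs"):
            jitter = stairs_like.jitter_for("walk", len(BASE_WALK_HARMONICS), rng)
            slow = 0.95 if name == "stairs_up" else 0.90
            harmonics = tuple(a * j * stairs_like.scale
                              for a, j in zip(BASE_WALK_HARMONICS, jitter))
            models[name] = ActivityModel(
                name, stairs_like.stride_hz * slow, harmonics, noise_sd=base.noise_sd,
                impulse_amplitude=0.40 * stairs_like.scale, impulse_width_s=0.05,
            )
            continue
        jitter = subject.jitter_for(name, len(base.harmonic_amplitudes), rng)
        harmonics = tuple(a * j * subject.scale for a, j in zip(base.harmonic_amplitudes, jitter))
        models[name] = ActivityModel(
            name, base.fundamental_hz, harmonics, noise_sd=base.noise_sd,
            impulse_amplitude=base.impulse_amplitude * subject.scale,
            impulse_width_s=base.impulse_width_s,
        )
    return models


def build_wd_benchmark(
    seed: int,
    n_subjects: int = 6,
    rate_hz: float = 200.0,
    window_s: float = 3.0,
    overlap_s: Optional[float] = 0.5,
    sessions_per_subject: int = 2,
    orientation_known: bool = False,
    noise_sd: float = 0.08,
    k: int = features.DEFAULT_FFT_BINS,
    plan: Sequence[Tuple[str, float]] = DEFAULT_SESSION_PLAN,
) -> WDFrameTable:
    """Simulate the cohort and assemble the framed benchmark table.

    Sessions are always synthesized at the 200 Hz reference rate and
    downsampled to ``rate_hz``, matching a collect-high/evaluate-low
    protocol. Orientation is a fresh uniform rotation per session unless
    ``orientation_known`` (then identity, gravity on z).
    """
    rng = np.random.default_rng(seed)
    subjects = make_subjects(n_subjects, rng)
    meta_rows: List[dict] = []
    stat_rows: List[dict] = []
    X_mag_rows: List[np.ndarray] = []
    X_3ax_rows: List[np.ndarray] = []

    for subj_no, subject in enumerate(subjects):
        neighbor = subjects[(subj_no + 1) % len(subjects)]
        models = _subject_activity_models(subject, rng, stairs_like=neighbor)
        for s_idx in range(sessions_per_subject):
            placement = BENCH_PLACEMENTS[(s_idx + subj_no) % len(BENCH_PLACEMENTS)]
            orientation = np.eye(3) if orientation_known else random_rotation(rng)
            params = subject_walk_params(subject, placement, rng, noise_sd, orientation)
            rec, _ = compose_session(
                plan, rate_hz=200.0, seed=rng, walk_params=params,
                activity_models=models, orientation=orientation,
                subject=subject.subject_id,
            )
            if rate_hz < 200.0:
                rec = resample(rec, rate_hz)
            mag = magnitude(rec)
            filt = lowpass(mag.samples, WD_LOWPASS_HZ, rate_hz)
            fset = frame(mag, window_s, overlap_s)
            mag_frames = [filt[s:e] for s, e, _ in fset.frames]
            dwt_stat = walk_detection.dwt_frame_energy(filt, fset)
            var_stat = walk_detection.frame_variance(mag_frames)
            band_stat = walk_detection.band_energy(mag_frames, rate_hz)
            axis_filt = [lowpass(rec.samples[:, j], WD_LOWPASS_HZ, rate_hz) for j in range(3)]
            axis_stats = {}
            for j in range(3):
                fr = [axis_filt[j][s:e] for s, e, _ in fset.frames]
                axis_stats[f"var_ax{j}"] = walk_detection.frame_variance(fr)
                axis_stats[f"band_ax{j}"] = walk_detection.band_energy(fr, rate_hz)
                axis_stats[f"dwt_ax{j}"] = walk_detection.dwt_frame_energy(axis_filt[j], fset)
            for i, (s, e, activity) in enumerate(fset.frames):
                meta_rows.append({
                    "subject": subject.subject_id,
                    "placement": placement,
                    "activity": activity,
                    "label": 1 if activity == "walk" else 0,
                })
                row = {"var_mag": var_stat[i], "band_mag": band_stat[i], "dwt_mag": dwt_stat[i]}
                for key, arr in axis_stats.items():
                    row[key] = arr[i]
                stat_rows.append(row)
                X_mag_rows.append(features.extract_features(mag_frames[i], rate_hz, k))
                X_3ax_rows.append(features.extract_features(rec.samples[s:e], rate_hz, k))

    return WDFrameTable(
        meta=pd.DataFrame(meta_rows),
        stats=pd.DataFrame(stat_rows),
        X_mag=np.vstack(X_mag_rows),
        X_3ax=np.vstack(X_3ax_rows),
        rate_hz=rate_hz,
        window_s=window_s,
    )


_STAT_OF = {"thr": "var", "stft": "band", "dwt": "dwt"}


def _heuristic_accuracy(bench: WDFrameTable, algo: str, y: np.ndarray,
                        idx: np.ndarray, io_known: bool) -> float:
    """Training accuracy of the exhaustively fitted threshold; when the
    orientation is known, the best single axis is chosen (ties to the
    gravity axis)."""
    base = _STAT_OF[algo]
    if not io_known:
        stats = bench.stats[f"{base}_mag"].to_numpy()[idx]
        return walk_detection.best_threshold(stats, y, statistic=base).train_accuracy
    best = -1.0
    for j in (2, 0, 1):  # gravity axis first so exact ties keep it
        stats = bench.stats[f"{base}_ax{j}"].to_numpy()[idx]
        acc = walk_detection.best_threshold(stats, y, statistic=f"{base}_ax{j}").train_accuracy
        if acc > best:
            best = acc
    return best


def _slice_accuracy(bench: WDFrameTable, algo: str, idx: np.ndarray,
                    io_known: bool, seed: int, folds: int = 10) -> float:
    y = bench.meta["label"].to_numpy()[idx]
    if algo in _STAT_OF:
        return _heuristic_accuracy(bench, algo, y, idx, io_known)
    X = (bench.X_3ax if io_known else bench.X_mag)[idx]
    usable = walk_detection.adaptive_folds(y, folds)
    _, acc = walk_detection.ml_wd_fit_predict(X, y, algo=algo, folds=usable, seed=seed)
    return acc


def wd_accuracy(bench: WDFrameTable, algo: str, context: ContextSpec, seed: int) -> float:
    """Accuracy of one detector on a benchmark table under a context.

    Classes are balanced 1:1 by seeded subsampling first. Personalized
    (IP-known) evaluation fits and scores per subject, then averages;
    placement-known evaluation restricts to that placement's frames.
    """
    if algo not in WD_ALGORITHMS:
        raise ValueError(f"unknown WD algorithm {algo!r}")
    rng = np.random.default_rng(seed)
    if context.placement is not None:
        mask = (bench.meta["placement"] == context.placement).to_numpy()
        if not mask.any():
            raise ValueError(f"no frames for placement {context.placement!r}")
        bench = bench.subset(mask)
    y_all = bench.meta["label"].to_numpy()
    idx = features.balanced_indices(y_all, rng)
    if not context.ip_known:
        return _slice_accuracy(bench, algo, idx, context.io_known, seed)
    accs = []
    subjects = bench.meta["subject"].to_numpy()
    for subject in np.unique(subjects):
        sub_idx = idx[subjects[idx] == subject]
        if np.unique(y_all[sub_idx]).size < 2:
            continue
        accs.append(_slice_accuracy(bench, algo, sub_idx, context.io_known, seed))
    if not accs:
        raise ValueError("no subject slice holds both classes")
    return float(np.mean(accs))


def evaluate_context_wd(
    context: ContextSpec,
    algo: str,
    seed: int,
    n_subjects: int = 6,
    **bench_kwargs,
) -> float:
    """Build the context-appropriate benchmark and score one detector."""
    bench = build_wd_benchmark(
        seed,
        n_subjects=n_subjects,
        rate_hz=context.rate_hz,
        window_s=context.window_s,
        overlap_s=None if context.window_s != 3.0 else 0.5,
        orientation_known=context.io_known,
        **bench_kwargs,
    )
    return wd_accuracy(bench, algo, context, seed)


def wd_context_report(
    seed: int,
    algos: Sequence[str] = WD_ALGORITHMS,
    n_subjects: int = 6,
    rates: Sequence[float] = (50.0, 100.0, 200.0),
) -> pd.DataFrame:
    """Baseline-vs-context accuracy deltas for the walk detectors."""
    frames = []
    base_ctx = ContextSpec()
    base_bench = build_wd_benchmark(seed, n_subjects=n_subjects)
    io_bench = build_wd_benchmark(seed, n_subjects=n_subjects, orientation_known=True)
    for algo in algos:
        baseline = wd_accuracy(base_bench, algo, base_ctx, seed)
        by_axis: Dict[str, Dict[str, float]] = {
            "orientation": {"known": wd_accuracy(io_bench, algo, ContextSpec(io_known=True), seed)},
            "personalization": {"known": wd_accuracy(base_bench, algo, ContextSpec(ip_known=True), seed)},
            "placement": {
                p: wd_accuracy(base_bench, algo, ContextSpec(placement=p), seed)
                for p in BENCH_PLACEMENTS
            },
            "sampling_rate": {
                f"{r:g}Hz": wd_accuracy(
                    build_wd_benchmark(seed, n_subjects=n_subjects, rate_hz=r),
                    algo, ContextSpec(rate_hz=r), seed)
                for r in rates
            },
        }
        df = evaluation.context_report(baseline, by_axis)
        df.insert(0, "algorithm", algo)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# step counting

def simulate_sc_bout(
    seed: int,
    placement: str = "FrontPocket",
    noise_sd: float = 0.05,
    n_cycles: int = 120,
    rate_hz: float = 200.0,
    stride_hz: float = 1.0,
    subject_scale: float = 1.0,
    rotate: bool = True,
) -> Tuple[np.ndarray, GaitGroundTruth]:
    """One annotated walking bout; returns (magnitude signal, truth)."""
    rng = np.random.default_rng(seed)
    orientation = random_rotation(rng) if rotate else np.eye(3)
    params = GaitModelParams(
        stride_frequency_hz=stride_hz,
        placement=placement,
        noise_sd=noise_sd,
        subject_scale=subject_scale,
        orientation=orientation,
    )
    rec, truth = simulate_walk(params, n_cycles / stride_hz, rate_hz, seed=rng)
    return magnitude(rec).samples, truth


def simulate_sc_recording(
    seed: int,
    placement: str = "FrontPocket",
    noise_sd: float = 0.05,
    n_cycles: int = 120,
    rate_hz: float = 200.0,
    stride_hz: float = 1.0,
    subject_scale: float = 1.0,
    rotate: bool = True,
):
    """Annotated walking bout as a full tri-axial recording."""
    rng = np.random.default_rng(seed)
    orientation = random_rotation(rng) if rotate else np.eye(3)
    params = GaitModelParams(
        stride_frequency_hz=stride_hz,
        placement=placement,
        noise_sd=noise_sd,
        subject_scale=subject_scale,
        orientation=orientation,
    )
    return simulate_walk(params, n_cycles / stride_hz, rate_hz, seed=rng)


def _bout_detections(signal: np.ndarray, rate_hz: float, algo: str,
                     truth: GaitGroundTruth, train: Tuple[np.ndarray, GaitGroundTruth]) -> "object":
    from .preprocess import normalize_variance

    fsm_config = None
    if algo == "fsm":
        fsm_config = step_counting.fsm_grid_search(
            normalize_variance(train[0]), train[1], rate_hz)
    return step_counting.count_steps(signal, rate_hz, algo, fsm_config=fsm_config)


def sc_context_report(
    seed: int,
    algos: Sequence[str] = step_counting.SC_ALGORITHMS,
    n_subjects: int = 3,
    n_cycles: int = 100,
    rate_hz: float = 200.0,
    noise_sd: float = 0.05,
    fpr_target: float = 0.03,
) -> pd.DataFrame:
    """Context deltas for the step counters: TPR at FPR ~ target.

    Baseline pools heterogeneous subject bouts under one shared score
    threshold; personalization-known picks the operating threshold per
    subject; orientation-known runs each counter on the best single axis
    of unrotated bouts.
    """
    rng = np.random.default_rng(seed)
    profiles = [(float(rng.uniform(0.6, 1.6)), float(rng.uniform(0.8, 1.2)))
                for _ in range(n_subjects)]
    bouts, bouts_plain = [], []
    for i, (scale, stride) in enumerate(profiles):
        seed_i = seed + 101 * (i + 1)
        rec, truth = simulate_sc_recording(seed_i, noise_sd=noise_sd, n_cycles=n_cycles,
                                           rate_hz=rate_hz, stride_hz=stride,
                                           subject_scale=scale, rotate=True)
        train = simulate_sc_recording(seed_i + 1, noise_sd=noise_sd, n_cycles=n_cycles,
                                      rate_hz=rate_hz, stride_hz=stride,
                                      subject_scale=scale, rotate=True)
        bouts.append((rec, truth, train))
        rec0, truth0 = simulate_sc_recording(seed_i, noise_sd=noise_sd, n_cycles=n_cycles,
                                             rate_hz=rate_hz, stride_hz=stride,
                                             subject_scale=scale, rotate=False)
        train0 = simulate_sc_recording(seed_i + 1, noise_sd=noise_sd, n_cycles=n_cycles,
                                       rate_hz=rate_hz, stride_hz=stride,
                                       subject_scale=scale, rotate=False)
        bouts_plain.append((rec0, truth0, train0))

    frames = []
    for algo in algos:
        dets, truths = [], []
        for rec, truth, (train_rec, train_truth) in bouts:
            mag = magnitude(rec).samples
            train_mag = magnitude(train_rec).samples
            dets.append(_bout_detections(mag, rate_hz, algo, truth, (train_mag, train_truth)))
            truths.append(truth)
        baseline, _, _ = evaluation.pooled_tpr_at_fpr(dets, truths, fpr_target)
        # personalization: per-subject operating threshold
        per_subject = [evaluation.pooled_tpr_at_fpr([d], [t], fpr_target)[0]
                       for d, t in zip(dets, truths)]
        ip_tpr = float(np.mean(per_subject))
        # orientation known: best single axis on unrotated bouts
        best_axis_tpr = -1.0
        for axis in (2, 0, 1):
            dets_ax, truths_ax = [], []
            for rec, truth, (train_rec, train_truth) in bouts_plain:
                sig = rec.samples[:, axis]
                train_sig = train_rec.samples[:, axis]
                dets_ax.append(_bout_detections(sig, rate_hz, algo, truth, (train_sig, train_truth)))
                truths_ax.append(truth)
            tpr_ax, _, _ = evaluation.pooled_tpr_at_fpr(dets_ax, truths_ax, fpr_target)
            best_axis_tpr = max(best_axis_tpr, tpr_ax)
        df = evaluation.context_report(baseline, {
            "orientation": {"known": best_axis_tpr},
            "personalization": {"known": ip_tpr},
        }, metric_name="tpr_at_fpr")
        df.insert(0, "algorithm", algo)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def sc_roc(
    algo: str,
    seed: int,
    placement: str = "FrontPocket",
    noise_sd: float = 0.05,
    n_cycles: int = 120,
    rate_hz: float = 200.0,
    stride_hz: float = 1.0,
    **bout_kwargs,
):
    """Strict ROC of one counter on a simulated Group I bout.

    The FSM's thresholds are grid-searched on an independent training
    bout drawn from the same conditions (seed + 1).
    """
    mag, truth = simulate_sc_bout(seed, placement, noise_sd, n_cycles, rate_hz,
                                  stride_hz, **bout_kwargs)
    fsm_config = None
    if algo == "fsm":
        train_mag, train_truth = simulate_sc_bout(seed + 1, placement, noise_sd,
                                                  n_cycles, rate_hz, stride_hz, **bout_kwargs)
        from .preprocess import normalize_variance

        fsm_config = step_counting.fsm_grid_search(
            normalize_variance(train_mag), train_truth, rate_hz)
    det = step_counting.count_steps(mag, rate_hz, algo, fsm_config=fsm_config)
    return evaluation.roc_curve(det, truth), det, truth
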