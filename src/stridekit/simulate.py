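"""Synthetic tri-axial accelerometer gait and activity simulator.

Real pedometer benchmarks require instrumented walking trials with
per-gait-cycle video annotation; this module emulates such sessions so
that every detector, counter and metric in the package can be exercised
with exact ground truth.

The walking model is deliberately phenomenological rather than
biomechanical: in the body frame, gravity sits on the z axis, a harmonic
burst (fundamental plus >= 2 harmonics) rides on the vertical and forward
axes at the *observed* signal frequency, and each observed period carries
one sharp negative heel-strike impulse. Group I placements (Foot,
FrontPocket, BackPocket, Hand, HandU) show one observed period per gait
cycle of the instrumented leg; Group II (UpPocket) shows two, because the
free leg's swing also modulates the signal. The whole body-frame signal
is rotated by an arbitrary proper rotation (free sensor orientation) and
white Gaussian noise is added.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .types import (
    ACTIVITIES,
    AccelRecording,
    GaitGroundTruth,
    group_of,
)

#: Default stride-frequency band (Hz). Chosen inside the canonical walk
#: band [0.66, 1.66] Hz used by the spectral walk detector.
STRIDE_BAND_HZ = (0.8, 1.2)


@dataclass
class GaitModelParams:
    """Parameters of one simulated walking bout.

    Amplitudes are in g before the per-subject scale factor. The
    heel-strike impulse is a negative Gaussian pulse of standard
    deviation ``heel_strike_width_s`` placed once per observed period,
    offset from the harmonic peak so the pulse deepens the valley rather
    than cancelling the peak.
    """

    stride_frequency_hz: float = 1.0
    harmonic_amplitudes: Tuple[float, ...] = (0.40, 0.20, 0.10)
    heel_strike_amplitude: float = 0.40
    heel_strike_width_s: float = 0.05
    noise_sd: float = 0.05
    placement: str = "FrontPocket"
    periods_per_cycle: Optional[int] = None  # derived from placement if None
    subject_scale: float = 1.0
    orientation: Optional[np.ndarray] = None  # 3x3 proper rotation, None = identity
    hand_jitter_sd: float = 0.0  # extra noise for diverse hand movement
    hand_group: str = "I"

    def resolved_periods(self) -> int:
        if self.periods_per_cycle is not None:
            if self.periods_per_cycle not in (1, 2):
                raise ValueError("periods_per_cycle must be 1 or 2")
            return self.periods_per_cycle
        return 1 if group_of(self.placement, self.hand_group) == "I" else 2


@dataclass
class ActivityModel:
    """Spectral signature of a non-walk activity.

    Static activities have no fundamental (gravity plus noise only);
    periodic ones are harmonic bursts like the walk model. Impact-driven
    activities (stair climbing) additionally carry one negative foot-fall
    impulse per period, so they are not trivially separable from walking
    by broadband impact energy alone.
    """

    name: str
    fundamental_hz: Optional[float]
    harmonic_amplitudes: Tuple[float, ...] = ()
    noise_sd: float = 0.02
    impulse_amplitude: float = 0.0
    impulse_width_s: float = 0.05

    def __post_init__(self) -> None:
        if self.name not in ACTIVITIES:
            raise ValueError(f"unknown activity {self.name!r}")


#: Default non-walk activity vocabulary. Running is faster and stronger
#: than walking (fundamental above the walk band); stair climbing shares
#: the walk band with a different harmonic profile (the hard confuser for
#: spectral detectors); riding is a low-variance narrow-band vibration;
#: sedentary activities are gravity plus noise.
DEFAULT_ACTIVITY_MODELS = {
    "run": ActivityModel("run", 2.8, (1.10, 0.45, 0.15), noise_sd=0.10),
    "stairs_up": ActivityModel("stairs_up", 0.85, (0.36, 0.20, 0.09), noise_sd=0.08,
                               impulse_amplitude=0.35),
    "stairs_down": ActivityModel("stairs_down", 0.90, (0.38, 0.18, 0.11), noise_sd=0.08,
                                 impulse_amplitude=0.48),
    "ride": ActivityModel("ride", 6.0, (0.06,), noise_sd=0.03),
    "brush_teeth": ActivityModel("brush_teeth", 3.5, (0.25, 0.08), noise_sd=0.05),
    "drive": ActivityModel("drive", None, (), noise_sd=0.05),
    "bus": ActivityModel("bus", None, (), noise_sd=0.08),
    "sit": ActivityModel("sit", None, (), noise_sd=0.02),
    "stand": ActivityModel("stand", None, (), noise_sd=0.02),
    "other": ActivityModel("other", None, (), noise_sd=0.04),
}


def _harmonic_burst(
    t: np.ndarray,
    fundamental_hz: float,
    amplitudes: Sequence[float],
    phases: Sequence[float],
) -> np.ndarray:
    out = np.zeros_like(t)
    for k, (a, p) in enumerate(zip(amplitudes, phases), start=1):
        out += a * np.cos(2.0 * math.pi * k * fundamental_hz * t + p)
    return out


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_walk(
    params: GaitModelParams,
    duration_s: float,
    rate_hz: float,
    seed=0,
) -> Tuple[AccelRecording, GaitGroundTruth]:
    """Simulate a steady-cadence walking bout with per-cycle ground truth.

    Returns the rotated, noisy recording and the exact half-open cycle
    boundaries; the true step count is the number of cycles,
    ``floor(duration * stride_frequency)``.
    """
    rng = _as_rng(seed)
    f_stride = params.stride_frequency_hz
    if not (5.0 <= rate_hz <= 200.0):
        raise ValueError("rate_hz must lie in [5, 200]")
    if f_stride <= 0 or f_stride >= rate_hz / 2.0:
        raise ValueError("stride frequency must lie in (0, rate/2)")
    n_cycles = int(math.floor(duration_s * f_stride))
    if n_cycles < 3:
        raise ValueError("duration must cover at least 3 gait cycles")

    ppc = params.resolved_periods()
    f_obs = f_stride * ppc
    n = int(round(duration_s * rate_hz))
    t = np.arange(n) / rate_hz
    scale = params.subject_scale

    amps = tuple(a * scale for a in params.harmonic_amplitudes)
    # Cycles are annotated from heel strike to heel strike, so the
    # harmonic burst peaks mid-period (half an observed period after the
    # boundary), never on an annotation edge.
    phases = tuple(0.0 for _ in amps)
    osc = _harmonic_burst(t - 0.5 / f_obs, f_obs, amps, phases)

    # One negative heel-strike pulse per observed period, 80% into it
    # (0.3 periods after the harmonic peak).
    heel = np.zeros(n)
    sigma = params.heel_strike_width_s
    amp = params.heel_strike_amplitude * scale
    if amp > 0 and sigma > 0:
        period = 1.0 / f_obs
        centers = (np.arange(int(math.ceil(duration_s * f_obs))) + 0.80) * period
        half_support = 4.0 * sigma
        for c in centers:
            lo = max(0, int((c - half_support) * rate_hz))
            hi = min(n, int((c + half_support) * rate_hz) + 1)
            if lo < hi:
                heel[lo:hi] -= amp * np.exp(-0.5 * ((t[lo:hi] - c) / sigma) ** 2)

    body = np.zeros((n, 3))
    body[:, 2] = 1.0 + 0.8 * (osc + heel)  # gravity + vertical bounce
    body[:, 0] = 0.30 * (osc + heel)       # forward sway, same periodicity
    body[:, 1] = 0.10 * scale * np.sin(2.0 * math.pi * f_stride * t)  # lateral

    rotation = params.orientation if params.orientation is not None else np.eye(3)
    samples = body @ np.asarray(rotation, dtype=float).T

    noise_sd = params.noise_sd
    if params.placement in ("Hand", "HandU"):
        noise_sd = math.hypot(noise_sd, params.hand_jitter_sd)
    if noise_sd > 0:
        samples = samples + rng.normal(scale=noise_sd, size=samples.shape)

    boundaries = np.round(np.arange(n_cycles + 1) * rate_hz / f_stride).astype(np.int64)
    boundaries = np.clip(boundaries, 0, n)
    cycles = np.column_stack([boundaries[:-1], boundaries[1:]])
    cycles = cycles[cycles[:, 0] < cycles[:, 1]]

    rec = AccelRecording(
        time_s=t,
        samples=samples,
        rate_hz=rate_hz,
        placement=params.placement,
        labels=[(0.0, duration_s, "walk")],
    )
    return rec, GaitGroundTruth(cycles)


def simulate_activity(
    model: ActivityModel | str,
    duration_s: float,
    rate_hz: float,
    seed=0,
    orientation: Optional[np.ndarray] = None,
    subject_scale: float = 1.0,
    placement: Optional[str] = None,
) -> AccelRecording:
    """Simulate a non-walk activity bout (no gait annotations)."""
    if isinstance(model, str):
        if model == "walk":
            raise ValueError("use simulate_walk for walking bouts")
        if model not in DEFAULT_ACTIVITY_MODELS:
            raise ValueError(f"unknown activity {model!r}")
        model = DEFAULT_ACTIVITY_MODELS[model]
    rng = _as_rng(seed)
    n = int(round(duration_s * rate_hz))
    t = np.arange(n) / rate_hz

    body = np.zeros((n, 3))
    body[:, 2] = 1.0
    if model.fundamental_hz is not None:
        if model.fundamental_hz >= rate_hz / 2.0:
            raise ValueError("activity fundamental must be below Nyquist")
        amps = tuple(a * subject_scale for a in model.harmonic_amplitudes)
        # Coherent harmonics (a repeatable movement waveform) with one
        # random global time offset; independent random phases would
        # randomize the waveform shape itself.
        tau = rng.uniform(0.0, 1.0 / model.fundamental_hz)
        phases = tuple(0.0 for _ in amps)
        osc = _harmonic_burst(t - tau - 0.5 / model.fundamental_hz, model.fundamental_hz, amps, phases)
        if model.impulse_amplitude > 0:
            period = 1.0 / model.fundamental_hz
            sigma = model.impulse_width_s
            amp = model.impulse_amplitude * subject_scale
            centers = (np.arange(int(math.ceil(duration_s * model.fundamental_hz))) + 0.80) * period + tau
            half = 4.0 * sigma
            for c in centers:
                lo, hi = max(0, int((c - half) * rate_hz)), min(n, int((c + half) * rate_hz) + 1)
                if lo < hi:
                    osc[lo:hi] -= amp * np.exp(-0.5 * ((t[lo:hi] - c) / sigma) ** 2)
        body[:, 2] += 0.8 * osc
        body[:, 0] += 0.30 * osc

    rotation = orientation if orientation is not None else np.eye(3)
    samples = body @ np.asarray(rotation, dtype=float).T
    if model.noise_sd > 0:
        samples = samples + rng.normal(scale=model.noise_sd, size=samples.shape)

    return AccelRecording(
        time_s=t,
        samples=samples,
        rate_hz=rate_hz,
        placement=placement,
        labels=[(0.0, duration_s, model.name)],
    )


def compose_session(
    plan: Sequence[Tuple[str, float]],
    rate_hz: float = 200.0,
    seed=0,
    walk_params: Optional[GaitModelParams] = None,
    activity_models: Optional[dict] = None,
    orientation: Optional[np.ndarray] = None,
    subject: Optional[str] = None,
) -> Tuple[AccelRecording, GaitGroundTruth]:
    """Concatenate activity bouts into one labeled session.

    ``plan`` is a list of ``(activity, duration_s)``. Walking bouts use
    ``walk_params`` (a fresh default if omitted) and contribute gait-cycle
    annotations, offset to session sample indices.
    """
    if not plan:
        raise ValueError("plan must be non-empty")
    rng = _as_rng(seed)
    walk_params = walk_params if walk_params is not None else GaitModelParams()
    if orientation is not None:
        walk_params = replace(walk_params, orientation=orientation)
    models = dict(DEFAULT_ACTIVITY_MODELS)
    if activity_models:
        models.update(activity_models)

    chunks: List[AccelRecording] = []
    labels: List[Tuple[float, float, str]] = []
    all_cycles: List[np.ndarray] = []
    t_off = 0.0
    i_off = 0
    for activity, dur in plan:
        if activity == "walk":
            rec, truth = simulate_walk(walk_params, dur, rate_hz, seed=rng)
            if truth.cgt:
                all_cycles.append(truth.cycles + i_off)
        else:
            if activity not in models:
                raise ValueError(f"unknown activity {activity!r}")
            rec = simulate_activity(
                models[activity], dur, rate_hz, seed=rng,
                orientation=orientation, subject_scale=walk_params.subject_scale,
                placement=walk_params.placement,
            )
        chunks.append(rec)
        labels.append((t_off, t_off + dur, activity))
        t_off += dur
        i_off += rec.n

    samples = np.vstack([c.samples for c in chunks])
    n = samples.shape[0]
    rec = AccelRecording(
        time_s=np.arange(n) / rate_hz,
        samples=samples,
        rate_hz=rate_hz,
        placement=walk_params.placement,
        subject=subject,
        labels=labels,
    )
    cycles = np.vstack(all_cycles) if all_cycles else np.empty((0, 2), dtype=np.int64)
    return rec, GaitGroundTruth(cycles)


@dataclass
class SubjectProfile:
    """Per-subject variation: one multiplicative amplitude scale, one
    preferred stride frequency, and a per-activity harmonic jitter drawn
    once per subject (personal movement signature)."""

    subject_id: str
    scale: float
    stride_hz: float
    activity_jitter: dict = field(default_factory=dict)

    def jitter_for(self, activity: str, n_harmonics: int, rng: np.random.Generator) -> np.ndarray:
        if activity not in self.activity_jitter:
            self.activity_jitter[activity] = rng.lognormal(0.0, 0.25, size=n_harmonics)
        j = self.activity_jitter[activity]
        if len(j) < n_harmonics:
            j = np.concatenate([j, rng.lognormal(0.0, 0.25, size=n_harmonics - len(j))])
            self.activity_jitter[activity] = j
        return j[:n_harmonics]


def make_subjects(
    n_subjects: int,
    rng: np.random.Generator,
    scale_range: Tuple[float, float] = (0.6, 1.6),
    stride_band: Tuple[float, float] = STRIDE_BAND_HZ,
) -> List[SubjectProfile]:
    """Draw a cohort of subject profiles (amplitude and cadence regimes)."""
    subjects = []
    for i in range(n_subjects):
        subjects.append(
            SubjectProfile(
                subject_id=f"S{i:02d}",
                scale=float(rng.uniform(*scale_range)),
                stride_hz=float(rng.uniform(*stride_band)),
            )
        )
    return subjects
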