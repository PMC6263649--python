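"""CSV/YAML interchange for recordings, labels, gait annotations,
metrics and ROC tables.

All files are plain CSV with a header row. Floating-point columns are
written with a fixed "%.17g" format, which round-trips IEEE doubles
exactly (distinct values stay distinct, e.g. ROC thresholds) and makes
repeated runs of the same seeded configuration byte-identical.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import yaml

from .types import ACTIVITIES, AccelRecording, ContextSpec, GaitGroundTruth, StrictSCMetrics

FLOAT_FMT = "%.17g"

RECORDING_COLUMNS = ("time_s", "ax", "ay", "az")
METRIC_COLUMNS = ("algorithm", "context", "ctp", "cfp", "cgt", "cest",
                  "tpr", "fpr", "loose_error_pct")


class RecordingParseError(ValueError):
    """Malformed recording file (the message names the offending row)."""


def read_recording(
    path,
    declared_rate_hz: Optional[float] = None,
    labels_path=None,
    units: str = "g",
) -> AccelRecording:
    """Read a tri-axial recording CSV (columns time_s, ax, ay, az).

    Validates strictly increasing time and, when a rate is declared,
    that the median inter-sample interval matches it within 5%.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in RECORDING_COLUMNS if c not in df.columns]
    if missing:
        raise RecordingParseError(f"{path}: missing columns {missing}")
    for col in RECORDING_COLUMNS:
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
            row = int(bad[0]) + 2 if len(bad) else "?"
            raise RecordingParseError(f"{path}: non-numeric value in column {col!r} at line {row}")
    t = df["time_s"].to_numpy(dtype=float)
    if t.size >= 2:
        dt = np.diff(t)
        bad = np.flatnonzero(dt <= 0)
        if bad.size:
            raise RecordingParseError(
                f"{path}: time not strictly increasing at data row {int(bad[0]) + 2}"
            )
    if declared_rate_hz is not None and t.size >= 2:
        nominal = 1.0 / declared_rate_hz
        med = float(np.median(np.diff(t)))
        if abs(med - nominal) / nominal >= 0.05:
            raise RecordingParseError(
                f"{path}: median interval {med:.6g}s deviates >5% from declared "
                f"rate {declared_rate_hz:g} Hz"
            )
    rate = declared_rate_hz
    if rate is None:
        rate = 1.0 / float(np.median(np.diff(t))) if t.size >= 2 else 1.0
    labels = read_labels(labels_path) if labels_path is not None else []
    return AccelRecording(
        time_s=t,
        samples=df[["ax", "ay", "az"]].to_numpy(dtype=float),
        rate_hz=float(rate),
        units=units,
        labels=labels,
    )


def write_recording(recording: AccelRecording, path) -> None:
    df = pd.DataFrame({
        "time_s": recording.time_s,
        "ax": recording.samples[:, 0],
        "ay": recording.samples[:, 1],
        "az": recording.samples[:, 2],
    })
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def read_labels(path) -> List[Tuple[float, float, str]]:
    """Read activity label segments (start_s, end_s, activity)."""
    df = pd.read_csv(path, float_precision="round_trip")
    labels = []
    prev_end = -np.inf
    for i, row in df.iterrows():
        start, end, activity = float(row["start_s"]), float(row["end_s"]), str(row["activity"])
        if activity not in ACTIVITIES:
            raise ValueError(f"{path}: unknown activity {activity!r} at data row {i + 2}")
        if not start < end:
            raise ValueError(f"{path}: empty segment at data row {i + 2}")
        if start < prev_end:
            raise ValueError(f"{path}: overlapping segment at data row {i + 2}")
        prev_end = end
        labels.append((start, end, activity))
    return labels


def write_labels(labels: Sequence[Tuple[float, float, str]], path) -> None:
    df = pd.DataFrame(labels, columns=["start_s", "end_s", "activity"])
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def read_cycles(path, n_samples: Optional[int] = None) -> GaitGroundTruth:
    """Read gait-cycle annotations (cycle_start_idx, cycle_end_idx)."""
    df = pd.read_csv(path, float_precision="round_trip")
    cycles = df[["cycle_start_idx", "cycle_end_idx"]].to_numpy(dtype=np.int64)
    if n_samples is not None and len(cycles) and cycles[:, 1].max() > n_samples:
        raise ValueError(f"{path}: cycle annotation beyond recording length")
    return GaitGroundTruth(cycles)


def write_cycles(truth: GaitGroundTruth, path) -> None:
    df = pd.DataFrame(truth.cycles, columns=["cycle_start_idx", "cycle_end_idx"])
    df.to_csv(path, index=False)


def metrics_record(
    metrics: StrictSCMetrics,
    algorithm: str = "",
    context: str = "baseline",
) -> dict:
    rec = {"algorithm": algorithm, "context": context}
    rec.update(metrics.as_dict())
    return rec


def write_metrics(records: Iterable[Union[dict, StrictSCMetrics]], path) -> None:
    """Write one metrics record per algorithm x context (CSV).

    Plain ``StrictSCMetrics`` are accepted and expanded with their
    derived rates; an empty record list yields a header-only file.
    """
    rows = []
    for r in records:
        if isinstance(r, StrictSCMetrics):
            r = metrics_record(r)
        rows.append(r)
    df = pd.DataFrame(rows, columns=METRIC_COLUMNS if not rows else None)
    if rows:
        for col in METRIC_COLUMNS:
            if col not in df.columns:
                df[col] = np.nan
        df = df[list(METRIC_COLUMNS) + [c for c in df.columns if c not in METRIC_COLUMNS]]
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def read_metrics(path) -> pd.DataFrame:
    return pd.read_csv(path, float_precision="round_trip")


def write_roc(curve, path) -> None:
    df = pd.DataFrame({"threshold": curve.thresholds, "fpr": curve.fpr, "tpr": curve.tpr})
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def read_roc(path):
    from .types import ROCCurve

    df = pd.read_csv(path, float_precision="round_trip")
    return ROCCurve(df["threshold"].to_numpy(), df["fpr"].to_numpy(), df["tpr"].to_numpy())


def write_detections(detections, rate_hz: float, path) -> None:
    df = pd.DataFrame({
        "index": detections.indices,
        "time_s": detections.indices / rate_hz,
        "score": detections.scores,
    })
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


@dataclass
class RunConfig:
    """One reproducible run: context, algorithm, simulator knobs, seed."""

    context: ContextSpec = field(default_factory=ContextSpec)
    algorithm: str = "stft"
    algorithm_params: dict = field(default_factory=dict)
    simulator_params: dict = field(default_factory=dict)
    seed: int = 0
    out_dir: str = "."

    def __post_init__(self) -> None:
        if not (isinstance(self.seed, (int, np.integer)) and self.seed >= 0):
            raise ValueError("seed must be a non-negative integer")

    def rng(self) -> np.random.Generator:
        """The single seeded generator all run randomness flows through."""
        return np.random.default_rng(self.seed)

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["context"] = asdict(self.context)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        ctx = data.pop("context", {})
        return cls(context=ContextSpec(**ctx), **data)
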