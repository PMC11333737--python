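"""Recording containers and their CSV on-disk format.

A recording is one scored action: two synchronized three-axis attitude traces
(forearm sensor S1, upper-arm sensor S2) at a common sampling rate, the action
id, and — when a clinician graded it — the 0/1/2 score.

On disk a recording is a CSV with header
``time_s,s1_roll,s1_pitch,s1_yaw,s2_roll,s2_pitch,s2_yaw`` (angles in
degrees) and a JSON sidecar ``<name>.meta.json`` carrying action_id, score
and generator metadata.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "AttitudeTrace",
    "ActionRecording",
    "read_recording_csv",
    "write_recording_csv",
    "RECORDING_COLUMNS",
]

RECORDING_COLUMNS = [
    "time_s",
    "s1_roll",
    "s1_pitch",
    "s1_yaw",
    "s2_roll",
    "s2_pitch",
    "s2_yaw",
]


@dataclass
class AttitudeTrace:
    """One sensor's roll/pitch/yaw signal: (T, 3) matrix in degrees."""

    sensor_id: str
    samples: np.ndarray
    rate_hz: float = 30.0

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != 3:
            raise ValueError("samples must have shape (T, 3)")
        if self.samples.shape[0] < 1:
            raise ValueError("trace must contain at least one sample")
        if np.any(np.abs(self.samples) > 180.0 + 1e-9):
            raise ValueError("attitude angles must lie within [-180, 180]")
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")

    def __len__(self) -> int:
        return self.samples.shape[0]


@dataclass
class ActionRecording:
    """Two-channel attitude recording of one action, optionally scored."""

    trace_s1: AttitudeTrace
    trace_s2: AttitudeTrace
    action_id: str
    score_label: Optional[int] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.trace_s1) != len(self.trace_s2):
            raise ValueError("both traces must have the same length")
        if self.trace_s1.rate_hz != self.trace_s2.rate_hz:
            raise ValueError("both traces must have the same sampling rate")
        if self.score_label is not None and self.score_label not in (0, 1, 2):
            raise ValueError("score_label must be 0, 1 or 2")

    def trace(self, sensor_id: str) -> AttitudeTrace:
        key = sensor_id.upper().lstrip("#")
        if key == "S1":
            return self.trace_s1
        if key == "S2":
            return self.trace_s2
        raise KeyError(f"unknown sensor id {sensor_id!r}")

    def __len__(self) -> int:
        return len(self.trace_s1)


def write_recording_csv(recording: ActionRecording, path) -> None:
    """Write a recording as CSV plus a ``.meta.json`` sidecar."""
    path = Path(path)
    n = len(recording)
    t = np.arange(n) / recording.trace_s1.rate_hz
    df = pd.DataFrame(
        np.column_stack([t, recording.trace_s1.samples, recording.trace_s2.samples]),
        columns=RECORDING_COLUMNS,
    )
    df.to_csv(path, index=False, float_format="%.9g")
    sidecar = {
        "action_id": recording.action_id,
        "score": recording.score_label,
        "rate_hz": recording.trace_s1.rate_hz,
        **recording.meta,
    }
    path.with_suffix(path.suffix + ".meta.json").write_text(
        json.dumps(sidecar, indent=1, sort_keys=True)
    )


def read_recording_csv(path) -> ActionRecording:
    """Read a recording written by :func:`write_recording_csv`.

    Raises ``ValueError`` naming the missing column or offending line on a
    malformed file.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"{path}: empty recording file") from exc
    missing = [c for c in RECORDING_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if len(df) == 0:
        raise ValueError(f"{path}: recording has no samples")
    bad = df[RECORDING_COLUMNS].isna().any(axis=1)
    if bad.any():
        # +2: header line plus 1-based indexing
        raise ValueError(f"{path}: malformed row at line {int(np.argmax(bad.values)) + 2}")

    meta_path = path.with_suffix(path.suffix + ".meta.json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    rate = float(meta.get("rate_hz", 30.0))
    if len(df) >= 2:
        dt = float(df["time_s"].iloc[1] - df["time_s"].iloc[0])
        if dt > 0:
            rate = 1.0 / dt
    action_id = meta.get("action_id", "A1")
    score = meta.get("score")
    extra = {
        k: v for k, v in meta.items() if k not in ("action_id", "score", "rate_hz")
    }
    return ActionRecording(
        trace_s1=AttitudeTrace("S1", df[RECORDING_COLUMNS[1:4]].to_numpy(), rate),
        trace_s2=AttitudeTrace("S2", df[RECORDING_COLUMNS[4:7]].to_numpy(), rate),
        action_id=action_id,
        score_label=None if score is None else int(score),
        meta=extra,
    )
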