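"""Trace normalization, fixed-length windowing, dataset splitting, UCI-HAR IO.

Attitude traces are min-max normalized with *fixed* bounds rather than
per-recording statistics: the default bounds are the sensor's full
measurement range (-180, 180) degrees mapped affinely onto (-1, 1), so the
shape of a weak movement is preserved instead of being stretched to full
scale.  Recordings are then linearly resampled to a fixed model input length
(default 128 samples, the window length used by the UCI-HAR human-activity
benchmark, so pretrained convolution shapes transfer).

Score labels 0-2 live in a 6-class label space; classes 3-5 are reserved
placeholders that keep the classifier head the same shape as an activity
recognition model pretrained on the six UCI-HAR activities.  No samples are
ever emitted with labels 3-5.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import List, Sequence, Tuple

import numpy as np

from .recording import (  # noqa: F401  (re-exported module surface)
    ActionRecording,
    AttitudeTrace,
    read_recording_csv,
    write_recording_csv,
)

__all__ = [
    "NormalizationParams",
    "LabeledWindow",
    "normalize",
    "resample_to_length",
    "make_window",
    "split_dataset",
    "load_ucihar",
    "read_recording_csv",
    "write_recording_csv",
    "ActionRecording",
    "AttitudeTrace",
    "N_CLASSES",
    "DEFAULT_LENGTH",
]

logger = logging.getLogger(__name__)

N_CLASSES = 6
DEFAULT_LENGTH = 128

UCIHAR_ACTIVITIES = {
    1: "WALKING",
    2: "WALKING_UPSTAIRS",
    3: "WALKING_DOWNSTAIRS",
    4: "SITTING",
    5: "STANDING",
    6: "LAYING",
}


@dataclass(frozen=True)
class NormalizationParams:
    """Fixed min-max bounds (degrees) and the target output range."""

    x_min: float = -180.0
    x_max: float = 180.0
    target_range: Tuple[float, float] = (-1.0, 1.0)

    def __post_init__(self):
        if not self.x_max > self.x_min:
            raise ValueError("x_max must exceed x_min")
        lo, hi = self.target_range
        if not hi > lo:
            raise ValueError("target_range must be increasing")


@dataclass
class LabeledWindow:
    """Fixed-length normalized (L, 3) window with a class label in 0..5."""

    values: np.ndarray
    class_label: int

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != 3:
            raise ValueError("values must have shape (L, 3)")
        if not 0 <= self.class_label < N_CLASSES:
            raise ValueError("class_label must be in 0..5")

    @property
    def length(self) -> int:
        return self.values.shape[0]


def normalize(
    values: np.ndarray,
    params: NormalizationParams | None = None,
    literal: bool = False,
) -> np.ndarray:
    """Min-max normalize with fixed bounds.

    Default mode maps ``[x_min, x_max]`` affinely onto ``target_range``
    (``(-1, 1)`` by default).  ``literal=True`` applies the plain
    ``(x - x_min) / (x_max - x_min)`` map onto ``[0, 1]`` instead.  Values
    outside the bounds are clipped; the clip count is logged.
    """
    params = NormalizationParams() if params is None else params
    x = np.asarray(values, dtype=float)
    n_clipped = int(np.sum((x < params.x_min) | (x > params.x_max)))
    if n_clipped:
        logger.warning("normalize: clipped %d values outside [%g, %g]",
                       n_clipped, params.x_min, params.x_max)
        x = np.clip(x, params.x_min, params.x_max)
    unit = (x - params.x_min) / (params.x_max - params.x_min)
    if literal:
        return unit
    lo, hi = params.target_range
    return lo + unit * (hi - lo)


def denormalize(values: np.ndarray, params: NormalizationParams | None = None) -> np.ndarray:
    """Inverse of :func:`normalize` in default mode."""
    params = NormalizationParams() if params is None else params
    lo, hi = params.target_range
    unit = (np.asarray(values, dtype=float) - lo) / (hi - lo)
    return params.x_min + unit * (params.x_max - params.x_min)


def resample_to_length(values: np.ndarray, length: int) -> np.ndarray:
    """Linearly interpolate a (T, C) signal onto ``length`` uniform points.

    Endpoints are preserved; an input already at the target length is
    returned unchanged (copy).
    """
    x = np.asarray(values, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    T = x.shape[0]
    if T < 2:
        raise ValueError("need at least 2 samples to resample")
    if length < 2:
        raise ValueError("target length must be >= 2")
    if T == length:
        return x.copy()
    src = np.linspace(0.0, 1.0, T)
    dst = np.linspace(0.0, 1.0, length)
    return np.column_stack([np.interp(dst, src, x[:, c]) for c in range(x.shape[1])])


def make_window(
    recording: ActionRecording,
    channel: str,
    params: NormalizationParams | None = None,
    length: int = DEFAULT_LENGTH,
    require_label: bool = True,
) -> LabeledWindow:
    """Select one sensor channel, normalize, resample to the model length.

    The 0-2 score is attached unchanged as the class label (classes 3-5 are
    reserved and never produced).
    """
    trace = recording.trace(channel)
    if recording.score_label is None:
        if require_label:
            raise ValueError("recording has no score label (required for training)")
        label = 0
    else:
        label = recording.score_label
    values = resample_to_length(normalize(trace.samples, params), length)
    return LabeledWindow(values=values, class_label=label)


def split_dataset(
    items: Sequence,
    labels: Sequence[int],
    ratios: Tuple[float, float, float] = (0.6, 0.2, 0.2),
    seed: int = 0,
) -> Tuple[list, list, list]:
    """Stratified train/validation/test split, deterministic given ``seed``.

    ``ratios`` must sum to 1.  Within each class, items are shuffled with a
    seeded generator and allocated by largest-remainder rounding; every class
    must land at least one item in each split, otherwise the offending class
    is named in the error.
    """
    if len(items) != len(labels):
        raise ValueError("items and labels must have equal length")
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError(f"ratios must sum to 1, got {ratios}")
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    parts: Tuple[list, list, list] = ([], [], [])
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        n = len(idx)
        raw = np.array(ratios) * n
        counts = np.floor(raw).astype(int)
        remainder = raw - counts
        for _ in range(n - counts.sum()):
            j = int(np.argmax(remainder))
            counts[j] += 1
            remainder[j] = -1
        if np.any(counts == 0):
            raise ValueError(
                f"class {cls} has too few samples ({n}) to stratify into ratios {ratios}"
            )
        bounds = np.cumsum(counts)
        chunks = np.split(idx, bounds[:-1])
        for part, chunk in zip(parts, chunks):
            part.extend(items[i] for i in chunk)
    return parts


def _read_fixed_width(path: Path) -> np.ndarray:
    if not path.exists():
        raise FileNotFoundError(f"UCI-HAR file missing: {path}")
    return np.loadtxt(path)


def load_ucihar(
    directory,
    split: str = "train",
    signals: Sequence[str] = ("body_acc_x", "body_acc_y", "body_acc_z"),
) -> List[LabeledWindow]:
    """Load UCI-HAR 128-sample windows from the standard directory layout.

    Reads the per-channel ``Inertial Signals/`` text files (whitespace
    separated, one 128-sample window per row) for the requested 3-signal
    subset (default: body acceleration x/y/z) and maps the dataset's activity
    labels 1-6 onto classes 0-5.
    """
    directory = Path(directory)
    if split not in ("train", "test"):
        raise ValueError("split must be 'train' or 'test'")
    if len(signals) != 3:
        raise ValueError("exactly 3 signal channels are required")
    sig_dir = directory / split / "Inertial Signals"
    channels = [
        _read_fixed_width(sig_dir / f"{name}_{split}.txt") for name in signals
    ]
    labels = _read_fixed_width(directory / split / f"y_{split}.txt").astype(int)
    n = len(labels)
    for name, ch in zip(signals, channels):
        if ch.shape != (n, 128):
            raise ValueError(
                f"{name}_{split}.txt: expected shape ({n}, 128), got {ch.shape}"
            )
    stacked = np.stack(channels, axis=2)  # (n, 128, 3)
    return [
        LabeledWindow(values=stacked[i], class_label=int(labels[i]) - 1)
        for i in range(n)
    ]
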