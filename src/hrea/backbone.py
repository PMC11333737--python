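"""Per-channel lightweight 1D-CNN action scorer.

Architecture (one sensor channel, input ``(L, 3)`` normalized attitude
angles):

    [Conv1D(kernel 10, valid) -> ReLU -> Dropout(0.5) -> MaxPool(stride 2)] x 2
    -> Flatten -> Dense(n_classes) -> softmax

With the defaults (L = 128, 16 filters per block) the per-filter feature
length shrinks 128 -> 119 -> 59 -> 50 -> 25, giving a 400-dim flattened
feature.  Training minimizes categorical cross-entropy with Adam; all
randomness (initialization, shuffling, dropout) derives from the config seed,
so a run is exactly reproducible.  The six output classes are the three
clinical scores 0-2 plus three reserved classes that keep the head
shape-compatible with a model pretrained on the six-activity UCI-HAR
benchmark, enabling transfer of the convolutional blocks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import List, Sequence, Tuple

import numpy as np

from ._nn import (
    Adam,
    Conv1D,
    Dense,
    Dropout,
    Flatten,
    MaxPool1D,
    ReLU,
    Sequential,
    softmax,
    softmax_cross_entropy,
)
from .preprocessing import LabeledWindow

__all__ = [
    "BackboneConfig",
    "ProbabilityVector",
    "TrainingHistory",
    "Backbone",
    "build_backbone",
    "cross_entropy",
    "train_backbone",
    "predict_proba",
    "transfer_init",
    "feature_lengths",
    "save_model",
    "load_model",
]

_LOSS_EPS = 1e-12
CHECKPOINT_FORMAT_VERSION = 1


@dataclass(frozen=True)
class BackboneConfig:
    input_length: int = 128
    in_channels: int = 3
    kernel_size: int = 10
    filters_per_block: Tuple[int, int] = (16, 16)
    dropout_rate: float = 0.5
    pool_stride: int = 2
    n_classes: int = 6
    learning_rate: float = 1e-3
    epochs: int = 120
    batch_size: int = 32
    seed: int = 0

    def __post_init__(self):
        if self.kernel_size > self.input_length:
            raise ValueError("kernel_size must not exceed input_length")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")


@dataclass(frozen=True)
class ProbabilityVector:
    """Class posterior from one channel's scorer; sums to 1."""

    probs: np.ndarray

    def __post_init__(self):
        p = np.asarray(self.probs, dtype=float)
        if p.ndim != 1:
            raise ValueError("probs must be a 1-D vector")
        if np.any(p < 0):
            raise ValueError("probabilities must be non-negative")
        if abs(p.sum() - 1.0) > 1e-6:
            raise ValueError(f"probabilities must sum to 1, got {p.sum()!r}")
        object.__setattr__(self, "probs", p)

    @property
    def predicted_class(self) -> int:
        return int(np.argmax(self.probs))

    def __len__(self) -> int:
        return len(self.probs)


@dataclass
class TrainingHistory:
    train_loss: List[float] = field(default_factory=list)
    train_accuracy: List[float] = field(default_factory=list)
    val_loss: List[float] = field(default_factory=list)
    val_accuracy: List[float] = field(default_factory=list)


def feature_lengths(config: BackboneConfig) -> List[int]:
    """Per-filter feature length after each conv/pool stage, starting at L.

    For the defaults: [128, 119, 59, 50, 25].
    """
    lengths = [config.input_length]
    L = config.input_length
    for _ in config.filters_per_block:
        L = L - config.kernel_size + 1
        if L < 1:
            raise ValueError("input too short for the convolution stack")
        lengths.append(L)
        L = L // config.pool_stride
        if L < 1:
            raise ValueError("input too short for the pooling stack")
        lengths.append(L)
    return lengths


class Backbone:
    """A configured scorer: the layer stack plus its config."""

    def __init__(self, config: BackboneConfig, net: Sequential):
        self.config = config
        self.net = net

    def n_parameters(self) -> int:
        return self.net.n_parameters()

    def conv_layers(self) -> List[Conv1D]:
        return [l for l in self.net.layers if isinstance(l, Conv1D)]

    def dense_layer(self) -> Dense:
        return next(l for l in self.net.layers if isinstance(l, Dense))


def build_backbone(config: BackboneConfig) -> Backbone:
    """Construct the two-block scorer with seeded parameter initialization."""
    lengths = feature_lengths(config)  # validates the shape chain
    rng = np.random.default_rng(config.seed)
    layers: list = []
    c_in = config.in_channels
    for n_filters in config.filters_per_block:
        layers += [
            Conv1D(config.kernel_size, c_in, n_filters, rng),
            ReLU(),
            Dropout(config.dropout_rate),
            MaxPool1D(config.pool_stride),
        ]
        c_in = n_filters
    flat = lengths[-1] * config.filters_per_block[-1]
    layers += [Flatten(), Dense(flat, config.n_classes, rng)]
    return Backbone(config, Sequential(layers))


def cross_entropy(prob: ProbabilityVector, truth_class: int) -> float:
    """Categorical cross-entropy, one-hot truth: ``-log p[truth]``."""
    if not 0 <= truth_class < len(prob):
        raise ValueError("truth_class out of range")
    return float(-np.log(max(prob.probs[truth_class], _LOSS_EPS)))


def _to_arrays(windows: Sequence[LabeledWindow]) -> Tuple[np.ndarray, np.ndarray]:
    X = np.stack([w.values for w in windows])
    y = np.array([w.class_label for w in windows], dtype=int)
    return X, y


def _eval(net: Sequential, X: np.ndarray, y: np.ndarray) -> Tuple[float, float]:
    logits = net.forward(X, train=False)
    loss, _ = softmax_cross_entropy(logits, y)
    acc = float(np.mean(np.argmax(logits, axis=1) == y))
    return loss, acc


def train_backbone(
    model: Backbone,
    train_set: Sequence[LabeledWindow],
    val_set: Sequence[LabeledWindow] | None = None,
    config: BackboneConfig | None = None,
) -> Tuple[Backbone, TrainingHistory]:
    """Mini-batch Adam on categorical cross-entropy; seeded and deterministic.

    Per-epoch history records loss/accuracy on the full training set (dropout
    disabled) and on the validation set when given.
    """
    config = model.config if config is None else config
    if len(train_set) == 0:
        raise ValueError("training set is empty")
    X, y = _to_arrays(train_set)
    Xv, yv = _to_arrays(val_set) if val_set else (None, None)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    opt = Adam(lr=config.learning_rate)
    history = TrainingHistory()
    n = len(X)
    for _ in range(config.epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            logits = model.net.forward(X[idx], train=True, rng=rng)
            _, dlogits = softmax_cross_entropy(logits, y[idx])
            model.net.backward(dlogits)
            opt.step(model.net)
        tl, ta = _eval(model.net, X, y)
        history.train_loss.append(tl)
        history.train_accuracy.append(ta)
        if Xv is not None:
            vl, va = _eval(model.net, Xv, yv)
            history.val_loss.append(vl)
            history.val_accuracy.append(va)
    return model, history


def predict_proba(model: Backbone, window) -> ProbabilityVector:
    """Class posterior for one window; dropout disabled."""
    values = window.values if isinstance(window, LabeledWindow) else np.asarray(window)
    cfg = model.config
    if values.shape != (cfg.input_length, cfg.in_channels):
        raise ValueError(
            f"window shape {values.shape} does not match "
            f"({cfg.input_length}, {cfg.in_channels})"
        )
    logits = model.net.forward(values[None], train=False)
    return ProbabilityVector(softmax(logits)[0])


def predict_proba_batch(model: Backbone, windows: Sequence[LabeledWindow]) -> np.ndarray:
    X, _ = _to_arrays(windows)
    return softmax(model.net.forward(X, train=False))


def transfer_init(
    pretrained: Backbone,
    config: BackboneConfig,
    mode: str = "conv",
) -> Backbone:
    """New scorer initialized from a pretrained one.

    ``mode="conv"`` copies the convolution blocks and re-initializes the
    dense head from the config seed (the default fine-tuning setup);
    ``mode="all"`` copies every parameter (shapes must match exactly).
    """
    if mode not in ("conv", "all"):
        raise ValueError("mode must be 'conv' or 'all'")
    src_cfg = pretrained.config
    if (src_cfg.kernel_size, src_cfg.in_channels, src_cfg.filters_per_block) != (
        config.kernel_size, config.in_channels, config.filters_per_block
    ):
        raise ValueError(
            "pretrained convolution shapes are incompatible with the config"
        )
    model = build_backbone(config)
    for dst, src in zip(model.conv_layers(), pretrained.conv_layers()):
        for name in src.params:
            dst.params[name] = src.params[name].copy()
    if mode == "all":
        src_dense, dst_dense = pretrained.dense_layer(), model.dense_layer()
        for name in src_dense.params:
            if src_dense.params[name].shape != dst_dense.params[name].shape:
                raise ValueError("dense shapes differ; copy-all mode unavailable")
            dst_dense.params[name] = src_dense.params[name].copy()
    return model


def _checkpoint_path(path) -> Path:
    path = Path(path)
    return path if path.suffix == ".npz" else Path(str(path) + ".npz")


def save_model(model: Backbone, path) -> None:
    """Serialize parameters (.npz) plus a JSON sidecar with the config."""
    path = _checkpoint_path(path)
    arrays = {
        f"{i}.{name}": layer.params[name]
        for (i, name), layer, _ in model.net.parameters()
    }
    np.savez(path, **arrays)
    sidecar = {
        "format_version": CHECKPOINT_FORMAT_VERSION,
        "config": asdict(model.config),
    }
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1))


def load_model(path) -> Backbone:
    path = _checkpoint_path(path)
    sidecar = json.loads(Path(str(path) + ".json").read_text())
    if sidecar.get("format_version") != CHECKPOINT_FORMAT_VERSION:
        raise ValueError("unsupported checkpoint format version")
    cfg_dict = sidecar["config"]
    cfg_dict["filters_per_block"] = tuple(cfg_dict["filters_per_block"])
    config = BackboneConfig(**cfg_dict)
    model = build_backbone(config)
    with np.load(path) as data:
        for (i, name), layer, _ in model.net.parameters():
            layer.params[name] = data[f"{i}.{name}"].copy()
    return model
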