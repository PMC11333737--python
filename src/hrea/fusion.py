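"""Multichannel fusion of per-sensor score posteriors.

Decision fusion (the MCDF model) combines the two sensors' class posteriors
after each channel has been scored independently:

* ``max``  — the class holding the single largest posterior in any channel;
* ``sum``  — the class with the largest posterior sum across channels;
* ``ds``   — Dempster-Shafer evidence combination: per-class product of the
  two channels' posteriors, normalized by ``K = 1 - sum_i p_i(x1) p_i(x2)``.
  ``K`` does not depend on the class, so the *decision* always equals the
  plain product rule's decision; the normalization only rescales the scores.
  When ``K`` vanishes (the channels agree with total mass on products) the
  unnormalized products are returned with a warning.
* ``nb``   — Naive Bayes: class prior times the product of per-channel
  posteriors, i.e. the product rule with a prior reweighting.

Feature fusion (the MCFF comparator) instead concatenates the two channels'
convolutional features before a single shared classifier head; it is trained
end-to-end with the same cross-entropy loss.

Ties are broken toward the lowest class index everywhere.  Products are
computed in log space when any posterior entry is tiny (< 1e-12) to avoid
underflow.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

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
from .backbone import (
    Backbone,
    BackboneConfig,
    ProbabilityVector,
    TrainingHistory,
    feature_lengths,
    predict_proba,
)
from .preprocessing import LabeledWindow, NormalizationParams, make_window

__all__ = [
    "FusionInput",
    "ClassPriors",
    "FusionResult",
    "fuse_max",
    "fuse_sum",
    "fuse_ds",
    "fuse_nb",
    "fuse",
    "estimate_priors",
    "mcdf_predict",
    "MCFF",
    "build_mcff",
    "train_mcff",
    "mcff_predict_proba",
    "FUSION_RULES",
]

logger = logging.getLogger(__name__)

_K_EPS = 1e-12
_LOG_GUARD = 1e-12
FUSION_RULES = ("max", "sum", "ds", "nb")


@dataclass(frozen=True)
class FusionInput:
    """Per-channel posteriors to be fused (two channels by default)."""

    probabilities: Tuple[ProbabilityVector, ...]
    channel_ids: Tuple[str, ...] = ()

    def __post_init__(self):
        if len(self.probabilities) == 0:
            raise ValueError("at least one channel posterior is required")
        lengths = {len(p) for p in self.probabilities}
        if len(lengths) != 1:
            raise ValueError("all channel posteriors must have equal length")
        if self.channel_ids and len(self.channel_ids) != len(self.probabilities):
            raise ValueError("channel_ids must match probabilities")

    def as_matrix(self) -> np.ndarray:
        """(n_channels, n_classes) matrix of posteriors."""
        return np.stack([p.probs for p in self.probabilities])

    @property
    def n_channels(self) -> int:
        return len(self.probabilities)


@dataclass(frozen=True)
class ClassPriors:
    priors: np.ndarray

    def __post_init__(self):
        p = np.asarray(self.priors, dtype=float)
        if np.any(p < 0):
            raise ValueError("priors must be non-negative")
        if abs(p.sum() - 1.0) > 1e-6:
            raise ValueError("priors must sum to 1")
        object.__setattr__(self, "priors", p)

    def __len__(self) -> int:
        return len(self.priors)


@dataclass(frozen=True)
class FusionResult:
    predicted_class: int
    scores: np.ndarray
    rule: str


def _argmax_lowest(scores: np.ndarray) -> int:
    # np.argmax already returns the first (lowest-index) maximum
    return int(np.argmax(scores))


def _products(P: np.ndarray) -> np.ndarray:
    """Per-class product across channels, in log space if entries are tiny."""
    if np.any(P < _LOG_GUARD):
        logp = np.sum(np.log(np.maximum(P, _LOG_GUARD)), axis=0)
        return np.exp(logp - np.max(logp))
    return np.prod(P, axis=0)


def fuse_max(inputs: FusionInput) -> FusionResult:
    """Class of the single largest posterior across all channels."""
    P = inputs.as_matrix()
    scores = P.max(axis=0)
    return FusionResult(_argmax_lowest(scores), scores, "max")


def fuse_sum(inputs: FusionInput) -> FusionResult:
    """Class with the largest posterior sum across channels."""
    P = inputs.as_matrix()
    scores = P.sum(axis=0)
    return FusionResult(_argmax_lowest(scores), scores, "sum")


def fuse_ds(inputs: FusionInput) -> FusionResult:
    """Dempster-Shafer combination of exactly two channels.

    Per-class score ``p_i(x1) p_i(x2) / K`` with
    ``K = 1 - sum_i p_i(x1) p_i(x2)``; falls back to the unnormalized
    products with a warning when ``|K|`` is below machine epsilon.
    """
    if inputs.n_channels != 2:
        raise ValueError("D-S fusion is defined for exactly 2 channels")
    P = inputs.as_matrix()
    products = _products(P)
    agreement = float(np.sum(P[0] * P[1]))
    K = 1.0 - agreement
    if abs(K) < _K_EPS:
        logger.warning("fuse_ds: normalization constant K ~ 0; "
                       "returning unnormalized products")
        scores = products
    else:
        scores = products / K
    return FusionResult(_argmax_lowest(scores), scores, "ds")


def fuse_nb(inputs: FusionInput, priors: ClassPriors) -> FusionResult:
    """Naive Bayes: prior times per-channel posterior product."""
    P = inputs.as_matrix()
    if len(priors) != P.shape[1]:
        raise ValueError("priors length must match the number of classes")
    scores = priors.priors * _products(P)
    return FusionResult(_argmax_lowest(scores), scores, "nb")


def fuse(inputs: FusionInput, rule: str, priors: Optional[ClassPriors] = None) -> FusionResult:
    """Dispatch on the rule name (``max``, ``sum``, ``ds``, ``nb``)."""
    if rule == "max":
        return fuse_max(inputs)
    if rule == "sum":
        return fuse_sum(inputs)
    if rule == "ds":
        return fuse_ds(inputs)
    if rule == "nb":
        if priors is None:
            n = len(inputs.probabilities[0])
            priors = ClassPriors(np.full(n, 1.0 / n))
        return fuse_nb(inputs, priors)
    raise ValueError(f"unknown fusion rule {rule!r}; expected one of {FUSION_RULES}")


def estimate_priors(
    training_labels: Sequence[int],
    n_classes: int = 6,
    smoothing: float = 0.0,
) -> ClassPriors:
    """Empirical class frequencies, optionally with additive smoothing."""
    labels = np.asarray(training_labels, dtype=int)
    if labels.size == 0:
        raise ValueError("training labels are empty")
    counts = np.bincount(labels, minlength=n_classes).astype(float)
    counts += smoothing
    return ClassPriors(counts / counts.sum())


def mcdf_predict(
    recording,
    model_s1: Backbone,
    model_s2: Backbone,
    rule: str = "nb",
    priors: Optional[ClassPriors] = None,
    params: Optional[NormalizationParams] = None,
) -> FusionResult:
    """Score one recording: per-channel preprocess + predict, then fuse."""
    if model_s1.config.n_classes != model_s2.config.n_classes:
        raise ValueError("channel models must share n_classes")
    w1 = make_window(recording, "S1", params, model_s1.config.input_length,
                     require_label=False)
    w2 = make_window(recording, "S2", params, model_s2.config.input_length,
                     require_label=False)
    inputs = FusionInput(
        probabilities=(predict_proba(model_s1, w1), predict_proba(model_s2, w2)),
        channel_ids=("S1", "S2"),
    )
    return fuse(inputs, rule, priors)


class MCFF:
    """Feature-fusion comparator: two conv extractors, concatenated features,
    one shared dense head."""

    def __init__(self, config: BackboneConfig, extractors: Tuple[Sequential, Sequential],
                 head: Sequential):
        self.config = config
        self.extractors = extractors
        self.head = head

    def forward(self, x1: np.ndarray, x2: np.ndarray, train: bool = False,
                rng: Optional[np.random.Generator] = None) -> np.ndarray:
        f1 = self.extractors[0].forward(x1, train=train, rng=rng)
        f2 = self.extractors[1].forward(x2, train=train, rng=rng)
        self._split = f1.shape[1]
        return self.head.forward(np.concatenate([f1, f2], axis=1), train=train, rng=rng)

    def backward(self, dout: np.ndarray) -> None:
        dfeat = self.head.backward(dout)
        self.extractors[0].backward(dfeat[:, :self._split])
        self.extractors[1].backward(dfeat[:, self._split:])

    def nets(self) -> List[Sequential]:
        return [*self.extractors, self.head]

    def n_parameters(self) -> int:
        return sum(net.n_parameters() for net in self.nets())

    @property
    def feature_length(self) -> int:
        """Flattened feature length of one channel's extractor."""
        cfg = self.config
        return feature_lengths(cfg)[-1] * cfg.filters_per_block[-1]


def _build_extractor(config: BackboneConfig, rng: np.random.Generator) -> Sequential:
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
    layers.append(Flatten())
    return Sequential(layers)


def build_mcff(config: BackboneConfig,
               pretrained: Optional[Backbone] = None) -> MCFF:
    """Construct the feature-fusion model, optionally transfer-initializing
    both extractors' convolution blocks from a pretrained scorer."""
    feature_lengths(config)  # validates shapes
    rng = np.random.default_rng(config.seed)
    ex1 = _build_extractor(config, rng)
    ex2 = _build_extractor(config, rng)
    flat = feature_lengths(config)[-1] * config.filters_per_block[-1]
    head = Sequential([Dense(2 * flat, config.n_classes, rng)])
    model = MCFF(config, (ex1, ex2), head)
    if pretrained is not None:
        src = pretrained.conv_layers()
        for extractor in model.extractors:
            dst = [l for l in extractor.layers if isinstance(l, Conv1D)]
            if len(dst) != len(src):
                raise ValueError("pretrained model has a different block count")
            for d, s in zip(dst, src):
                for name in s.params:
                    if d.params[name].shape != s.params[name].shape:
                        raise ValueError("pretrained conv shapes incompatible")
                    d.params[name] = s.params[name].copy()
    return model


def train_mcff(
    model: MCFF,
    train_pairs: Sequence[Tuple[LabeledWindow, LabeledWindow]],
    val_pairs: Sequence[Tuple[LabeledWindow, LabeledWindow]] | None = None,
    config: BackboneConfig | None = None,
) -> Tuple[MCFF, TrainingHistory]:
    """End-to-end Adam training of the feature-fusion model.

    ``train_pairs`` holds per-recording (S1 window, S2 window) pairs; the
    label is taken from the S1 window (both carry the recording's score).
    """
    config = model.config if config is None else config
    if len(train_pairs) == 0:
        raise ValueError("training set is empty")

    def to_arrays(pairs):
        X1 = np.stack([p[0].values for p in pairs])
        X2 = np.stack([p[1].values for p in pairs])
        y = np.array([p[0].class_label for p in pairs], dtype=int)
        return X1, X2, y

    X1, X2, y = to_arrays(train_pairs)
    val = to_arrays(val_pairs) if val_pairs else None
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    optimizers = [Adam(lr=config.learning_rate) for _ in model.nets()]
    history = TrainingHistory()
    n = len(y)
    for _ in range(config.epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            logits = model.forward(X1[idx], X2[idx], train=True, rng=rng)
            _, dlogits = softmax_cross_entropy(logits, y[idx])
            model.backward(dlogits)
            for net, opt in zip(model.nets(), optimizers):
                opt.step(net)
        logits = model.forward(X1, X2, train=False)
        loss, _ = softmax_cross_entropy(logits, y)
        history.train_loss.append(loss)
        history.train_accuracy.append(float(np.mean(np.argmax(logits, 1) == y)))
        if val is not None:
            vlogits = model.forward(val[0], val[1], train=False)
            vloss, _ = softmax_cross_entropy(vlogits, val[2])
            history.val_loss.append(vloss)
            history.val_accuracy.append(float(np.mean(np.argmax(vlogits, 1) == val[2])))
    return model, history


def mcff_predict_proba(model: MCFF, w1: LabeledWindow, w2: LabeledWindow) -> ProbabilityVector:
    logits = model.forward(w1.values[None], w2.values[None], train=False)
    return ProbabilityVector(softmax(logits)[0])
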