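"""Confusion matrices, weighted precision/recall/F1, paired model comparison.

Per-class precision ``TP/(TP+FP)``, recall ``TP/(TP+FN)`` and
``F1 = 2PR/(P+R)``; the weighted average weights each class by its share of
the evaluated samples (``N_i / N_total``), so zero-support classes — such as
the three reserved score labels — contribute nothing.  A zero denominator
yields 0 for that metric (logged), the usual reporting convention.

Model comparison uses a two-sided paired t-test on per-run metric values
(e.g. weighted F1 across repeated stratified splits paired by seed) at a
configurable significance level, 0.05 by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, List, Sequence, Tuple

import numpy as np
from scipy import stats

__all__ = [
    "ConfusionMatrix",
    "EvaluationReport",
    "ComparisonResult",
    "confusion",
    "per_class_metrics",
    "weighted_average",
    "paired_ttest",
    "evaluate_model",
    "evaluate_predictions",
]

logger = logging.getLogger(__name__)


@dataclass
class ConfusionMatrix:
    """Counts with rows = true class, columns = predicted class."""

    counts: np.ndarray
    class_labels: Tuple[int, ...] = ()

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("counts must be a square matrix")
        if np.any(self.counts < 0) or not np.issubdtype(self.counts.dtype, np.integer):
            raise ValueError("counts must be non-negative integers")
        if not self.class_labels:
            self.class_labels = tuple(range(self.counts.shape[0]))

    @property
    def n_classes(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def supports(self) -> np.ndarray:
        return self.counts.sum(axis=1)


@dataclass
class EvaluationReport:
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    supports: np.ndarray
    weighted_precision: float
    weighted_recall: float
    weighted_f1: float
    confusion: ConfusionMatrix

    @property
    def n_total(self) -> int:
        return int(self.supports.sum())

    def to_dict(self) -> dict:
        return {
            "per_class": {
                "precision": self.precision.tolist(),
                "recall": self.recall.tolist(),
                "f1": self.f1.tolist(),
                "support": self.supports.tolist(),
            },
            "weighted": {
                "precision": self.weighted_precision,
                "recall": self.weighted_recall,
                "f1": self.weighted_f1,
            },
            "confusion": self.confusion.counts.tolist(),
            "n_total": self.n_total,
        }

    def table(self) -> str:
        """Percentages rendered to 2 decimals, table-style."""
        lines = [f"{'class':>8} {'P (%)':>8} {'R (%)':>8} {'F1 (%)':>8} {'N':>6}"]
        for i in range(len(self.precision)):
            lines.append(
                f"{self.confusion.class_labels[i]:>8} "
                f"{100 * self.precision[i]:8.2f} {100 * self.recall[i]:8.2f} "
                f"{100 * self.f1[i]:8.2f} {self.supports[i]:>6}"
            )
        lines.append(
            f"{'weighted':>8} {100 * self.weighted_precision:8.2f} "
            f"{100 * self.weighted_recall:8.2f} {100 * self.weighted_f1:8.2f} "
            f"{self.n_total:>6}"
        )
        return "\n".join(lines)


@dataclass
class ComparisonResult:
    runs_a: np.ndarray
    runs_b: np.ndarray
    mean_difference: float
    t_statistic: float
    p_value: float
    alpha: float
    significant: bool


def confusion(true_labels: Sequence[int], predicted_labels: Sequence[int],
              n_classes: int) -> ConfusionMatrix:
    """Count (true, predicted) pairs into a ``n_classes``-square matrix."""
    t = np.asarray(true_labels, dtype=int)
    p = np.asarray(predicted_labels, dtype=int)
    if t.size == 0:
        raise ValueError("label sequences are empty")
    if t.shape != p.shape:
        raise ValueError("label sequences must have equal length")
    if t.min() < 0 or p.min() < 0 or t.max() >= n_classes or p.max() >= n_classes:
        raise ValueError(f"labels must lie in 0..{n_classes - 1}")
    counts = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(counts, (t, p), 1)
    return ConfusionMatrix(counts)


def per_class_metrics(cm: ConfusionMatrix) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-class (precision, recall, F1); zero denominators yield 0."""
    counts = cm.counts.astype(float)
    tp = np.diag(counts)
    fp = counts.sum(axis=0) - tp
    fn = counts.sum(axis=1) - tp

    with np.errstate(divide="ignore", invalid="ignore"):
        precision = np.where(tp + fp > 0, tp / (tp + fp), 0.0)
        recall = np.where(tp + fn > 0, tp / (tp + fn), 0.0)
        pr = precision + recall
        f1 = np.where(pr > 0, 2 * precision * recall / np.where(pr > 0, pr, 1.0), 0.0)
    if np.any((tp + fp == 0) | (tp + fn == 0)):
        logger.debug("per_class_metrics: zero-denominator class(es) reported as 0")
    return precision, recall, f1


def weighted_average(per_class: Tuple[np.ndarray, np.ndarray, np.ndarray],
                     supports: Sequence[float]) -> Tuple[float, float, float]:
    """Support-weighted mean of (precision, recall, F1)."""
    w = np.asarray(supports, dtype=float)
    if np.any(w < 0):
        raise ValueError("supports must be non-negative")
    total = w.sum()
    if total == 0:
        raise ValueError("all supports are zero")
    w = w / total
    return tuple(float(np.dot(w, m)) for m in per_class)


def evaluate_predictions(true_labels: Sequence[int], predicted_labels: Sequence[int],
                         n_classes: int) -> EvaluationReport:
    cm = confusion(true_labels, predicted_labels, n_classes)
    p, r, f1 = per_class_metrics(cm)
    wp, wr, wf1 = weighted_average((p, r, f1), cm.supports)
    return EvaluationReport(
        precision=p, recall=r, f1=f1, supports=cm.supports,
        weighted_precision=wp, weighted_recall=wr, weighted_f1=wf1,
        confusion=cm,
    )


def evaluate_model(predictor: Callable, test_set: Sequence, true_labels: Sequence[int],
                   n_classes: int = 6) -> EvaluationReport:
    """Run ``predictor(item) -> class`` over the test set and report metrics."""
    if len(test_set) == 0:
        raise ValueError("test set is empty")
    if len(test_set) != len(true_labels):
        raise ValueError("test set and labels must align")
    predicted = [int(predictor(item)) for item in test_set]
    return evaluate_predictions(list(true_labels), predicted, n_classes)


def paired_ttest(metric_runs_a: Sequence[float], metric_runs_b: Sequence[float],
                 alpha: float = 0.05) -> ComparisonResult:
    """Two-sided paired t-test on aligned per-run metric values.

    Degenerate all-zero differences return ``p = 1`` (no evidence of a
    difference) by convention.
    """
    a = np.asarray(metric_runs_a, dtype=float)
    b = np.asarray(metric_runs_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("runs must be aligned pairwise (equal length)")
    if a.size < 2:
        raise ValueError("need at least 2 paired runs")
    diffs = a - b
    if np.allclose(diffs, 0.0):
        t_stat, p_value = 0.0, 1.0
    else:
        t_stat, p_value = stats.ttest_rel(a, b)
        t_stat, p_value = float(t_stat), float(p_value)
    return ComparisonResult(
        runs_a=a, runs_b=b,
        mean_difference=float(diffs.mean()),
        t_statistic=t_stat, p_value=p_value,
        alpha=alpha, significant=bool(p_value < alpha),
    )
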