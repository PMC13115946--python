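"""Evaluation metrics: confusion matrix, accuracy, F1 family, McNemar test."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "ConfusionMatrix", "MetricsReport", "confusion", "accuracy",
    "f1_scores", "metrics_report", "mcnemar_exact",
]


@dataclass
class ConfusionMatrix:
    counts: np.ndarray  # (n, n) ints; rows = true class, columns = predicted

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("confusion matrix must be square")
        if np.any(self.counts < 0):
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return int(self.counts.sum())

    @property
    def tp(self) -> np.ndarray:
        return np.diag(self.counts)

    @property
    def fp(self) -> np.ndarray:
        return self.counts.sum(axis=0) - self.tp

    @property
    def fn(self) -> np.ndarray:
        return self.counts.sum(axis=1) - self.tp

    @property
    def support(self) -> np.ndarray:
        """Per-class truth counts (num_i)."""
        return self.counts.sum(axis=1)


@dataclass
class MetricsReport:
    accuracy: float
    per_class_f1: np.ndarray
    macro_f1: float
    weighted_f1: float
    n_samples: int
    n_correct: int
    empty_classes: list[int] = field(default_factory=list)
    zero_division_classes: list[int] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "per_class_f1": [float(x) for x in self.per_class_f1],
            "macro_f1": self.macro_f1,
            "weighted_f1": self.weighted_f1,
            "n_samples": self.n_samples,
            "n_correct": self.n_correct,
            "empty_classes": self.empty_classes,
            "zero_division_classes": self.zero_division_classes,
        }


def confusion(true_labels, predicted_labels, n: int) -> ConfusionMatrix:
    t = np.asarray(true_labels, dtype=np.int64)
    p = np.asarray(predicted_labels, dtype=np.int64)
    if t.shape != p.shape or t.ndim != 1:
        raise ValueError("label lists must be equal-length 1-D sequences")
    if t.size and (t.min() < 0 or t.max() >= n or p.min() < 0 or p.max() >= n):
        raise ValueError(f"labels must lie in [0, {n})")
    counts = np.zeros((n, n), dtype=np.int64)
    np.add.at(counts, (t, p), 1)
    return ConfusionMatrix(counts)


def accuracy(cm: ConfusionMatrix) -> float:
    if cm.n_samples == 0:
        raise ValueError("accuracy undefined for an empty confusion matrix")
    return float(cm.tp.sum() / cm.n_samples)


def f1_scores(cm: ConfusionMatrix) -> tuple[np.ndarray, float, float]:
    """Per-class F1 (0/0 -> 0 convention), macro mean and support-weighted mean."""
    tp, fp, fn = cm.tp.astype(float), cm.fp.astype(float), cm.fn.astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        precision = np.where(tp + fp > 0, tp / (tp + fp), 0.0)
        recall = np.where(tp + fn > 0, tp / (tp + fn), 0.0)
        f1 = np.where(precision + recall > 0,
                      2 * precision * recall / (precision + recall), 0.0)
    macro = float(f1.mean())
    support = cm.support.astype(float)
    if support.sum() == 0:
        raise ValueError("weighted F1 undefined without samples")
    weighted = float((f1 * support).sum() / support.sum())
    return f1, macro, weighted


def metrics_report(true_labels, predicted_labels, n: int) -> MetricsReport:
    cm = confusion(true_labels, predicted_labels, n)
    f1, macro, weighted = f1_scores(cm)
    support = cm.support
    zero_div = [int(i) for i in range(n)
                if f1[i] == 0.0 and (cm.tp[i] + cm.fp[i] == 0 or support[i] == 0)]
    return MetricsReport(
        accuracy=accuracy(cm),
        per_class_f1=f1,
        macro_f1=macro,
        weighted_f1=weighted,
        n_samples=cm.n_samples,
        n_correct=int(cm.tp.sum()),
        empty_classes=[int(i) for i in np.flatnonzero(support == 0)],
        zero_division_classes=zero_div,
    )


def mcnemar_exact(correct_a, correct_b) -> float:
    """Two-sided exact McNemar p-value on paired per-sample correctness.

    With b = #(A right, B wrong) and c = #(A wrong, B right),
    p = min(1, 2 * P(X <= min(b, c))) for X ~ Binomial(b + c, 1/2).
    """
    a = np.asarray(correct_a, dtype=bool)
    bb = np.asarray(correct_b, dtype=bool)
    if a.shape != bb.shape or a.ndim != 1:
        raise ValueError("correctness vectors must be equal-length 1-D")
    b = int(np.sum(a & ~bb))
    c = int(np.sum(~a & bb))
    n = b + c
    if n == 0:
        raise ValueError("McNemar test undefined with zero discordant pairs")
    p = 2.0 * stats.binom.cdf(min(b, c), n, 0.5)
    return float(min(p, 1.0))
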