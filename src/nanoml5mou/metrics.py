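"""Binary-classification evaluation: confusion counts, scalar metrics, AUROC, AUPRC.

Implemented from first principles so each quantity has a transparent
definition that tests can check against brute-force oracles:

* AUROC is the rank formulation P(score+ > score-) + 0.5 P(tie) over all
  positive-negative pairs.
* AUPRC is average precision — stepwise integration of the PR curve at each
  distinct score threshold, with no linear interpolation (linear PR
  interpolation is known to be optimistic).
* Scalar metrics with a zero denominator return 0 and are flagged as
  degenerate instead of propagating NaN into report tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields

import numpy as np
from scipy.stats import rankdata

from .errors import UsageError


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.tp + self.fp + self.tn + self.fn < 1:
            raise ValueError("confusion counts must describe at least one item")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class ScalarMetrics:
    acc: float
    precision: float
    recall: float
    f1: float
    mcc: float
    #: names of metrics whose denominator was zero (value reported as 0)
    degenerate: tuple[str, ...] = ()


def confusion(labels, scores, threshold: float = 0.5) -> ConfusionCounts:
    """Threshold scores into predictions (score >= threshold -> positive) and count."""
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape:
        raise UsageError(f"labels {labels.shape} and scores {scores.shape} length mismatch")
    if labels.size < 1:
        raise UsageError("confusion requires at least one item")
    pred = scores >= threshold
    pos = labels == 1
    return ConfusionCounts(
        tp=int(np.sum(pred & pos)),
        fp=int(np.sum(pred & ~pos)),
        tn=int(np.sum(~pred & ~pos)),
        fn=int(np.sum(~pred & pos)),
    )


def scalar_metrics(c: ConfusionCounts) -> ScalarMetrics:
    """Accuracy, precision, recall, F1 and Matthews correlation from counts."""
    degenerate = []

    def ratio(num, den, name):
        if den == 0:
            degenerate.append(name)
            return 0.0
        return num / den

    acc = (c.tp + c.tn) / c.n
    precision = ratio(c.tp, c.tp + c.fp, "precision")
    recall = ratio(c.tp, c.tp + c.fn, "recall")
    f1 = ratio(2 * precision * recall, precision + recall, "f1")
    mcc_den = math.sqrt(
        float(c.tp + c.fp) * float(c.tp + c.fn) * float(c.tn + c.fp) * float(c.tn + c.fn)
    )
    if mcc_den == 0:
        degenerate.append("mcc")
        mcc = 0.0
    else:
        mcc = (c.tp * c.tn - c.fp * c.fn) / mcc_den
    return ScalarMetrics(
        acc=acc, precision=precision, recall=recall, f1=f1, mcc=mcc,
        degenerate=tuple(degenerate),
    )


def _check_two_class(labels, scores):
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape:
        raise UsageError("labels and scores length mismatch")
    n1 = int(np.sum(labels == 1))
    n0 = int(np.sum(labels == 0))
    if n1 == 0 or n0 == 0:
        raise UsageError("metric undefined: both classes must be present")
    return labels, scores, n0, n1


def auroc(labels, scores) -> float:
    """Area under the ROC curve via ranks: P(score+ > score-) + 0.5 P(tie)."""
    labels, scores, n0, n1 = _check_two_class(labels, scores)
    ranks = rankdata(scores)
    u = np.sum(ranks[labels == 1]) - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def auprc(labels, scores) -> float:
    """Average precision: sum over thresholds of (recall step) x precision."""
    labels, scores, n0, n1 = _check_two_class(labels, scores)
    order = np.argsort(-scores, kind="mergesort")
    sorted_scores = scores[order]
    sorted_labels = labels[order]
    ap = 0.0
    tp = fp = 0
    prev_recall = 0.0
    i = 0
    n = labels.size
    while i < n:
        j = i
        while j < n and sorted_scores[j] == sorted_scores[i]:
            j += 1
        tp += int(np.sum(sorted_labels[i:j] == 1))
        fp += (j - i) - int(np.sum(sorted_labels[i:j] == 1))
        recall = tp / n1
        precision = tp / (tp + fp)
        ap += (recall - prev_recall) * precision
        prev_recall = recall
        i = j
    return float(ap)


_METRIC_NAMES = ("auroc", "auprc", "acc", "precision", "recall", "f1", "mcc")


@dataclass(frozen=True)
class MetricsReport:
    """Per-metric (mean, sd) pairs, aggregated over CV folds (sd = 0 for single runs)."""

    auroc: tuple[float, float]
    auprc: tuple[float, float]
    acc: tuple[float, float]
    precision: tuple[float, float]
    recall: tuple[float, float]
    f1: tuple[float, float]
    mcc: tuple[float, float]

    @classmethod
    def from_folds(cls, fold_metrics: list[dict[str, float]]) -> "MetricsReport":
        if not fold_metrics:
            raise UsageError("cannot build a MetricsReport from zero folds")
        vals = {}
        for name in _METRIC_NAMES:
            arr = np.array([fm[name] for fm in fold_metrics], dtype=float)
            vals[name] = (float(arr.mean()), float(arr.std(ddof=1)) if arr.size > 1 else 0.0)
        return cls(**vals)

    @classmethod
    def single(cls, metrics: dict[str, float]) -> "MetricsReport":
        return cls(**{name: (float(metrics[name]), 0.0) for name in _METRIC_NAMES})

    def to_dict(self) -> dict[str, dict[str, float]]:
        return {
            f.name: {"mean": getattr(self, f.name)[0], "sd": getattr(self, f.name)[1]}
            for f in fields(self)
        }

    def summary(self) -> str:
        parts = [f"{name}={getattr(self, name)[0]:.4f}+/-{getattr(self, name)[1]:.4f}"
                 for name in _METRIC_NAMES]
        return " ".join(parts)


def evaluate_scores(labels, scores, threshold: float = 0.5) -> dict[str, float]:
    """All seven metrics of one labelled score set, as a flat dict."""
    c = confusion(labels, scores, threshold=threshold)
    sm = scalar_metrics(c)
    return {
        "auroc": auroc(labels, scores),
        "auprc": auprc(labels, scores),
        "acc": sm.acc,
        "precision": sm.precision,
        "recall": sm.recall,
        "f1": sm.f1,
        "mcc": sm.mcc,
    }
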