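"""Confusion-matrix construction and classification metrics.

The positive class is "high" stress (the minority, clinically relevant
group).  Metrics follow the four standard formulas

    accuracy  = (TP + TN) / (TP + TN + FP + FN)
    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)
    F1        = 2 * precision * recall / (precision + recall)

When a denominator is zero the metric is reported as ``None`` (with a
warning) rather than silently coerced to 0, so degenerate classifiers do
not masquerade as merely bad ones.

``reference_confusion_matrices`` loads a small packaged fixture with the
published confusion counts of six models (naive Bayes, SVM, LSTM, DBN,
BiLSTM and the feature-attention model); the package recomputes metric
values *from those counts*.  Note that the counts of the
feature-attention row imply accuracy ~= 83.9% and precision ~= 92.4%,
which do not match the separately published headline percentages — an
internal inconsistency of the source material that this package surfaces
rather than hides.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "classify",
    "confusion",
    "metrics",
    "reference_confusion_matrices",
]

_LABELS = ("low", "high")


@dataclass(frozen=True)
class ConfusionMatrix:
    """TP/FP/FN/TN counts with "high" stress as the positive class."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"{name} must be a nonnegative integer, got {v!r}")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricsReport:
    """Accuracy, precision, recall and F1 as fractions; None = undefined."""

    accuracy: float
    precision: float | None
    recall: float | None
    f1: float | None

    def as_percent(self) -> dict[str, float | None]:
        return {
            name: (None if v is None else round(100.0 * v, 2))
            for name, v in (
                ("accuracy", self.accuracy),
                ("precision", self.precision),
                ("recall", self.recall),
                ("f1", self.f1),
            )
        }


def classify(prob: float, threshold: float = 0.5) -> str:
    """Map a high-stress probability to a label; ties go to "high"."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    if not 0.0 <= prob <= 1.0:
        raise ValueError(f"probability must be in [0, 1], got {prob}")
    return "high" if prob >= threshold else "low"


def _as_binary(values: Sequence) -> np.ndarray:
    arr = np.asarray(values)
    if arr.dtype.kind in ("U", "S", "O"):
        bad = set(np.unique(arr)) - set(_LABELS)
        if bad:
            raise ValueError(f"unknown label value(s): {sorted(bad)}")
        return (arr == "high").astype(int)
    uniq = set(np.unique(arr).tolist())
    if not uniq <= {0, 1, 0.0, 1.0, False, True}:
        raise ValueError(f"numeric labels must be 0/1, got {sorted(uniq)}")
    return arr.astype(int)


def confusion(labels: Sequence, predictions: Sequence) -> ConfusionMatrix:
    """Count the four outcomes; accepts {low, high} strings or 0/1."""
    y = _as_binary(labels)
    p = _as_binary(predictions)
    if y.shape != p.shape or y.size == 0:
        raise ValueError(
            f"labels and predictions must have equal nonzero length, got {y.size} and {p.size}"
        )
    return ConfusionMatrix(
        tp=int(np.sum((y == 1) & (p == 1))),
        fp=int(np.sum((y == 0) & (p == 1))),
        fn=int(np.sum((y == 1) & (p == 0))),
        tn=int(np.sum((y == 0) & (p == 0))),
    )


def metrics(cm: ConfusionMatrix) -> MetricsReport:
    """The four metrics from a confusion matrix."""
    if cm.total == 0:
        raise ValueError("confusion matrix is empty")
    accuracy = (cm.tp + cm.tn) / cm.total

    def ratio(num: int, den: int, name: str) -> float | None:
        if den == 0:
            warnings.warn(f"{name} undefined (zero denominator)", stacklevel=3)
            return None
        return num / den

    precision = ratio(cm.tp, cm.tp + cm.fp, "precision")
    recall = ratio(cm.tp, cm.tp + cm.fn, "recall")
    if precision is None or recall is None or precision + recall == 0.0:
        if precision is not None and recall is not None:
            warnings.warn("f1 undefined (precision + recall = 0)", stacklevel=2)
        f1 = None
    else:
        f1 = 2.0 * precision * recall / (precision + recall)
    return MetricsReport(accuracy=accuracy, precision=precision, recall=recall, f1=f1)


def reference_confusion_matrices() -> dict[str, ConfusionMatrix]:
    """Published confusion counts of the six compared models (fixture)."""
    with resources.files("stresslstm.data").joinpath("confusion_reference.csv").open() as fh:
        df = pd.read_csv(fh)
    return {
        row["model"]: ConfusionMatrix(
            tp=int(row["tp"]), fp=int(row["fp"]), fn=int(row["fn"]), tn=int(row["tn"])
        )
        for _, row in df.iterrows()
    }
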