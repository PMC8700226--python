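"""Classifier evaluation: confusion matrix, recall/precision, bands.

Conventions: confusion-matrix rows index the ACTUAL class and columns the
PREDICTED class, so row sums equal per-class validation counts.  Recall is
TP/(TP+FN), precision TP/(TP+FP); "overall" figures are macro averages —
the unweighted mean across classes.  Recall values also get a qualitative
descriptor from published sensitivity cut-offs (<20% very poor up to >90%
excellent); values are rounded to whole percent before banding so the
printed labels are reproduced exactly at the boundaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion

__all__ = [
    "ConfusionMatrix",
    "EvalReport",
    "confusion_matrix",
    "recall_precision",
    "sensitivity_band",
    "evaluate_predictions",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """K x K counts, rows = actual class, columns = predicted class."""

    classes: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        k = len(self.classes)
        if counts.shape != (k, k):
            raise ValueError(f"counts must be {k}x{k}, got {counts.shape}")
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.classes),
                            columns=list(self.classes))


@dataclass(frozen=True)
class EvalReport:
    """Per-class and macro recall/precision plus sensitivity bands."""

    matrix: ConfusionMatrix
    per_class_recall: dict[str, float]
    per_class_precision: dict[str, float]
    macro_recall: float
    macro_precision: float
    bands: dict[str, str] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "cuisine": c,
                "recall": self.per_class_recall.get(c, float("nan")),
                "precision": self.per_class_precision.get(c, float("nan")),
                "band": self.bands.get(c, ""),
            }
            for c in self.matrix.classes
        ]
        rows.append({"cuisine": "overall", "recall": self.macro_recall,
                     "precision": self.macro_precision,
                     "band": sensitivity_band(self.macro_recall)})
        return pd.DataFrame(rows)


def confusion_matrix(
    truths: Sequence[str], preds: Sequence[str], classes: Sequence[str]
) -> ConfusionMatrix:
    """Tally actual-vs-predicted counts over the fixed class order."""
    if len(truths) != len(preds):
        raise ValueError(f"{len(truths)} truths vs {len(preds)} predictions")
    known = set(classes)
    unknown = {v for v in (*truths, *preds) if v not in known}
    if unknown:
        raise ValueError(f"values {sorted(unknown)} are not in the class list")
    counts = _sk_confusion(truths, preds, labels=list(classes))
    return ConfusionMatrix(classes=tuple(classes), counts=counts)


def recall_precision(matrix: ConfusionMatrix) -> EvalReport:
    """Per-class and macro recall/precision from a confusion matrix.

    A class with no actual records has undefined recall (and one never
    predicted has undefined precision); such classes are reported as NaN
    and excluded from the macro mean, with a warning.
    """
    counts = np.asarray(matrix.counts, dtype=float)
    if counts.sum() == 0:
        raise ValueError("empty confusion matrix")
    tp = np.diag(counts)
    actual = counts.sum(axis=1)
    predicted = counts.sum(axis=0)

    recall: dict[str, float] = {}
    precision: dict[str, float] = {}
    bands: dict[str, str] = {}
    for i, cls in enumerate(matrix.classes):
        if actual[i] == 0:
            warnings.warn(f"class {cls!r} has no actual records; recall undefined")
            recall[cls] = float("nan")
        else:
            recall[cls] = tp[i] / actual[i]
            bands[cls] = sensitivity_band(recall[cls])
        if predicted[i] == 0:
            warnings.warn(f"class {cls!r} was never predicted; precision undefined")
            precision[cls] = float("nan")
        else:
            precision[cls] = tp[i] / predicted[i]
    macro_recall = float(np.nanmean(list(recall.values())))
    macro_precision = float(np.nanmean(list(precision.values())))
    return EvalReport(
        matrix=matrix,
        per_class_recall=recall,
        per_class_precision=precision,
        macro_recall=macro_recall,
        macro_precision=macro_precision,
        bands=bands,
    )


# Published sensitivity cut-offs.  The printed bands (<20, 21-30, 31-50,
# 51-70, 71-90, >90 %) leave the integer boundaries 20/21 etc. ambiguous;
# rounding to whole percent first and using half-open intervals at .5
# boundaries maps every value to exactly one published label.
_BANDS = (
    (0.205, "very poor"),
    (0.305, "poor"),
    (0.505, "fair"),
    (0.705, "moderate"),
    (0.905, "good"),
    (1.0001, "excellent"),
)


def sensitivity_band(recall: float) -> str:
    """Qualitative descriptor for a recall value in [0, 1]."""
    if not 0.0 <= recall <= 1.0:
        raise ValueError(f"recall must be in [0, 1], got {recall}")
    for upper, label in _BANDS:
        if recall < upper:
            return label
    return "excellent"


def evaluate_predictions(
    truths: Sequence[str], preds: Sequence[str], classes: Sequence[str]
) -> EvalReport:
    """Convenience: confusion matrix + recall/precision in one call."""
    return recall_precision(confusion_matrix(truths, preds, classes))
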