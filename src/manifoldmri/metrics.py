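"""Classification metrics: per-class precision/recall/F1/support, confusion
matrix, accuracy, and macro/weighted averages.

Conventions: precision = TP/(TP+FP) with a never-predicted class defined as
precision 0 (logged); recall = TP/(TP+FN); F1 is the harmonic mean; support
= TP+FN; macro averages are unweighted means and weighted averages are
support-weighted means.  The identity accuracy == weighted recall holds by
construction.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def f1_from_precision_recall(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall (0 when both vanish)."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def macro_average(values) -> float:
    """Unweighted mean over classes."""
    return float(np.mean(np.asarray(values, float)))


def weighted_average(values, supports) -> float:
    """Support-weighted mean over classes."""
    v = np.asarray(values, float)
    s = np.asarray(supports, float)
    return float(np.sum(v * s) / np.sum(s))


def accuracy_from_recalls(recalls, supports) -> float:
    """Overall accuracy recovered from per-class recalls and supports.

    Since TP_c = recall_c * support_c, accuracy = sum_c TP_c / sum_c support_c
    — i.e. the weighted recall.
    """
    return weighted_average(recalls, supports)


@dataclass
class ClassificationReport:
    class_order: list
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    support: np.ndarray
    confusion: np.ndarray
    accuracy: float
    macro_precision: float
    macro_recall: float
    macro_f1: float
    weighted_precision: float
    weighted_recall: float
    weighted_f1: float

    def to_frame(self) -> pd.DataFrame:
        """Table with per-class rows plus Accuracy / Macro Avg / Weighted Avg."""
        rows = []
        for i, c in enumerate(self.class_order):
            rows.append({"class": str(c), "precision": self.precision[i],
                         "recall": self.recall[i], "f1": self.f1[i],
                         "support": int(self.support[i])})
        total = int(self.support.sum())
        rows.append({"class": "accuracy", "precision": np.nan,
                     "recall": np.nan, "f1": self.accuracy, "support": total})
        rows.append({"class": "macro avg", "precision": self.macro_precision,
                     "recall": self.macro_recall, "f1": self.macro_f1,
                     "support": total})
        rows.append({"class": "weighted avg",
                     "precision": self.weighted_precision,
                     "recall": self.weighted_recall, "f1": self.weighted_f1,
                     "support": total})
        return pd.DataFrame(rows)

    def to_json(self, path=None) -> str:
        payload = {
            "class_order": [str(c) for c in self.class_order],
            "precision": self.precision.tolist(),
            "recall": self.recall.tolist(),
            "f1": self.f1.tolist(),
            "support": self.support.tolist(),
            "confusion": self.confusion.tolist(),
            "accuracy": self.accuracy,
            "macro": {"precision": self.macro_precision,
                      "recall": self.macro_recall, "f1": self.macro_f1},
            "weighted": {"precision": self.weighted_precision,
                         "recall": self.weighted_recall,
                         "f1": self.weighted_f1},
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text


def evaluate_classification(y_true, y_pred, class_order) -> ClassificationReport:
    """Compute the full report from true/predicted labels."""
    y_true = [str(v) for v in y_true]
    y_pred = [str(v) for v in y_pred]
    class_order = [str(c) for c in class_order]
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred must have equal length")
    index = {c: i for i, c in enumerate(class_order)}
    for v in y_true + y_pred:
        if v not in index:
            raise ValueError(f"unknown label {v!r}")
    K = len(class_order)
    confusion = np.zeros((K, K), dtype=int)
    for t, p in zip(y_true, y_pred):
        confusion[index[t], index[p]] += 1
    tp = np.diag(confusion).astype(float)
    support = confusion.sum(axis=1)
    predicted = confusion.sum(axis=0)
    never_predicted = predicted == 0
    if never_predicted.any():
        missing = [class_order[i] for i in np.flatnonzero(never_predicted)]
        logger.warning("classes never predicted (precision set to 0): %s", missing)
    precision = np.where(predicted > 0, tp / np.maximum(predicted, 1), 0.0)
    recall = np.where(support > 0, tp / np.maximum(support, 1), 0.0)
    f1 = np.array([f1_from_precision_recall(p, r)
                   for p, r in zip(precision, recall)])
    total = confusion.sum()
    accuracy = float(np.trace(confusion) / total)
    return ClassificationReport(
        class_order=class_order,
        precision=precision, recall=recall, f1=f1, support=support,
        confusion=confusion, accuracy=accuracy,
        macro_precision=macro_average(precision),
        macro_recall=macro_average(recall),
        macro_f1=macro_average(f1),
        weighted_precision=weighted_average(precision, support),
        weighted_recall=weighted_average(recall, support),
        weighted_f1=weighted_average(f1, support),
    )
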