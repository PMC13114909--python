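"""Multiclass evaluation metrics computed from the confusion matrix.

All five quantities — overall accuracy, macro precision/recall, macro F1 and
Cohen's kappa — derive from one C x C confusion matrix (rows = true labels,
columns = predictions), so per-class breakdowns and matrix exports come free.
Zero-division convention: a per-class precision, recall or F1 whose
denominator is zero is reported as 0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np


@dataclass
class MetricsReport:
    confusion: np.ndarray
    overall_accuracy: float
    per_class_precision: np.ndarray
    per_class_recall: np.ndarray
    macro_precision: float
    macro_recall: float
    f1_macro: float
    kappa: float
    observed_agreement: float
    expected_agreement: float
    n_samples: int
    n_classes: int

    def to_dict(self) -> dict:
        return {
            "confusion": self.confusion.tolist(),
            "overall_accuracy": self.overall_accuracy,
            "per_class_precision": self.per_class_precision.tolist(),
            "per_class_recall": self.per_class_recall.tolist(),
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "f1_macro": self.f1_macro,
            "kappa": self.kappa,
            "observed_agreement": self.observed_agreement,
            "expected_agreement": self.expected_agreement,
            "n_samples": self.n_samples,
            "n_classes": self.n_classes,
        }

    def save_json(self, path: str | Path):
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    def save_confusion_csv(self, path: str | Path):
        np.savetxt(path, self.confusion, fmt="%d", delimiter=",")


def confusion_matrix(y_true, y_pred, n_classes: int) -> np.ndarray:
    y_true = np.asarray(y_true, dtype=np.int64)
    y_pred = np.asarray(y_pred, dtype=np.int64)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have the same length")
    for name, y in (("y_true", y_true), ("y_pred", y_pred)):
        if y.size and (y.min() < 0 or y.max() >= n_classes):
            raise ValueError(f"{name} contains labels outside [0, {n_classes})")
    cm = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(cm, (y_true, y_pred), 1)
    return cm


def overall_accuracy(confusion: np.ndarray) -> float:
    n = confusion.sum()
    if n == 0:
        raise ValueError("confusion matrix is empty")
    return float(np.trace(confusion) / n)


def per_class_precision_recall(confusion: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    tp = np.diag(confusion).astype(np.float64)
    pred_totals = confusion.sum(axis=0).astype(np.float64)  # tp + fp
    true_totals = confusion.sum(axis=1).astype(np.float64)  # tp + fn
    precision = np.divide(tp, pred_totals, out=np.zeros_like(tp), where=pred_totals > 0)
    recall = np.divide(tp, true_totals, out=np.zeros_like(tp), where=true_totals > 0)
    return precision, recall


def macro_metrics(precision: np.ndarray, recall: np.ndarray) -> tuple[float, float, float]:
    if precision.shape != recall.shape or precision.size == 0:
        raise ValueError("precision and recall must be equal-length, non-empty vectors")
    denom = precision + recall
    f1 = np.divide(2 * precision * recall, denom,
                   out=np.zeros_like(denom), where=denom > 0)
    return float(precision.mean()), float(recall.mean()), float(f1.mean())


def cohens_kappa(confusion: np.ndarray) -> tuple[float, float, float]:
    """Return (kappa, observed agreement p0, expected agreement pe)."""
    n = confusion.sum()
    if n == 0:
        raise ValueError("confusion matrix is empty")
    p0 = np.trace(confusion) / n
    pe = float(confusion.sum(axis=1) @ confusion.sum(axis=0)) / n**2
    if pe >= 1.0:
        raise ValueError("expected agreement is 1 (single class on both axes); "
                         "kappa is undefined")
    return float((p0 - pe) / (1.0 - pe)), float(p0), float(pe)


def compute_metrics(y_true, y_pred, n_classes: int) -> MetricsReport:
    cm = confusion_matrix(y_true, y_pred, n_classes)
    oa = overall_accuracy(cm)
    precision, recall = per_class_precision_recall(cm)
    p_macro, r_macro, f1 = macro_metrics(precision, recall)
    kappa, p0, pe = cohens_kappa(cm)
    return MetricsReport(cm, oa, precision, recall, p_macro, r_macro, f1,
                         kappa, p0, pe, int(cm.sum()), n_classes)


def metrics_from_confusion(cm: np.ndarray) -> MetricsReport:
    cm = np.asarray(cm, dtype=np.int64)
    oa = overall_accuracy(cm)
    precision, recall = per_class_precision_recall(cm)
    p_macro, r_macro, f1 = macro_metrics(precision, recall)
    kappa, p0, pe = cohens_kappa(cm)
    return MetricsReport(cm, oa, precision, recall, p_macro, r_macro, f1,
                         kappa, p0, pe, int(cm.sum()), cm.shape[0])
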