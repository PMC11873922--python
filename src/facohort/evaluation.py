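"""Three-class evaluation: confusion matrices, precision/recall/F1 and
one-vs-rest ROC with macro-averaged AUC.

Both macro (unweighted) and support-weighted aggregates are always reported,
labelled explicitly, because published summaries of imbalanced three-class
problems rarely say which convention they used.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn import metrics as skm

from .prep import N_CLASSES

__all__ = [
    "EvalReport",
    "confusion_matrix",
    "classification_metrics",
    "roc_curve_ovr",
    "auc_macro",
    "evaluate_model",
]


def confusion_matrix(actual, predicted) -> np.ndarray:
    """3x3 count matrix; entry (r, c) = actual class r predicted as c."""
    actual = np.asarray(actual)
    predicted = np.asarray(predicted)
    if actual.shape != predicted.shape:
        raise ValueError("actual and predicted must have equal length")
    for name, a in (("actual", actual), ("predicted", predicted)):
        if not np.isin(a, np.arange(N_CLASSES)).all():
            raise ValueError(f"{name} labels outside {{0, 1, 2}}")
    return skm.confusion_matrix(actual, predicted, labels=np.arange(N_CLASSES))


def classification_metrics(confusion: np.ndarray) -> dict:
    """Per-class one-vs-rest precision/recall/F1 plus macro and weighted
    aggregates, from a confusion matrix.

    A class never predicted gets precision 0 with a warning (keeps the
    aggregates finite).
    """
    cm = np.asarray(confusion, dtype=float)
    if cm.sum() == 0:
        raise ValueError("empty confusion matrix")
    tp = np.diag(cm)
    pred_pos = cm.sum(axis=0)
    actual_pos = cm.sum(axis=1)
    if np.any(pred_pos == 0):
        warnings.warn(
            f"classes never predicted: {np.flatnonzero(pred_pos == 0).tolist()}; "
            "precision set to 0"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        precision = np.where(pred_pos > 0, tp / pred_pos, 0.0)
        recall = np.where(actual_pos > 0, tp / actual_pos, 0.0)
        denom = precision + recall
        f1 = np.where(denom > 0, 2 * precision * recall / denom, 0.0)
    support = actual_pos / actual_pos.sum()
    return {
        "precision": precision,
        "recall": recall,
        "f1": f1,
        "macro_precision": float(precision.mean()),
        "macro_recall": float(recall.mean()),
        "macro_f1": float(f1.mean()),
        "weighted_precision": float(precision @ support),
        "weighted_recall": float(recall @ support),
        "weighted_f1": float(f1 @ support),
    }


def roc_curve_ovr(actual, probabilities, positive_class: int):
    """One-vs-rest ROC for one class: (fpr, tpr, thresholds, auc).

    The positive class is scored by its probability column against the union
    of the other classes; AUC by the trapezoidal rule.
    """
    actual = np.asarray(actual)
    if not np.any(actual == positive_class):
        raise ValueError(
            f"class {positive_class} absent from the actual labels; AUC undefined"
        )
    scores = np.asarray(probabilities)[:, positive_class]
    fpr, tpr, thresholds = skm.roc_curve(
        (actual == positive_class).astype(int), scores
    )
    return fpr, tpr, thresholds, float(skm.auc(fpr, tpr))


def auc_macro(per_class_aucs) -> float:
    """Unweighted mean of the per-class one-vs-rest AUCs."""
    aucs = np.asarray(per_class_aucs, dtype=float)
    if not np.all(np.isfinite(aucs)):
        raise ValueError("non-finite AUC")
    return float(aucs.mean())


@dataclass
class EvalReport:
    """Full three-class evaluation of one model on one dataset."""

    confusion: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    macro_precision: float
    macro_recall: float
    macro_f1: float
    weighted_precision: float
    weighted_recall: float
    weighted_f1: float
    auc_per_class: np.ndarray
    macro_auc: float
    roc_points: dict = field(default_factory=dict, repr=False)
    model_id: str | None = None

    def to_dict(self) -> dict:
        return {
            "model_id": self.model_id,
            "confusion": np.asarray(self.confusion).astype(int).tolist(),
            "per_class": {
                "precision": np.round(self.precision, 6).tolist(),
                "recall": np.round(self.recall, 6).tolist(),
                "f1": np.round(self.f1, 6).tolist(),
                "auc": np.round(self.auc_per_class, 6).tolist(),
            },
            "macro": {
                "precision": round(self.macro_precision, 6),
                "recall": round(self.macro_recall, 6),
                "f1": round(self.macro_f1, 6),
                "auc": round(self.macro_auc, 6),
            },
            "weighted": {
                "precision": round(self.weighted_precision, 6),
                "recall": round(self.weighted_recall, 6),
                "f1": round(self.weighted_f1, 6),
            },
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def evaluate_model(model, X, actual, model_id: str | None = None) -> EvalReport:
    """Evaluate a fitted probability classifier on (X, actual labels)."""
    proba = model.predict_proba(X)
    predicted = np.argmax(proba, axis=1)
    cm = confusion_matrix(actual, predicted)
    m = classification_metrics(cm)
    aucs = []
    roc_points = {}
    for c in range(N_CLASSES):
        fpr, tpr, thr, auc_c = roc_curve_ovr(actual, proba, c)
        aucs.append(auc_c)
        roc_points[c] = {"fpr": fpr.tolist(), "tpr": tpr.tolist()}
    return EvalReport(
        confusion=cm,
        precision=m["precision"],
        recall=m["recall"],
        f1=m["f1"],
        macro_precision=m["macro_precision"],
        macro_recall=m["macro_recall"],
        macro_f1=m["macro_f1"],
        weighted_precision=m["weighted_precision"],
        weighted_recall=m["weighted_recall"],
        weighted_f1=m["weighted_f1"],
        auc_per_class=np.array(aucs),
        macro_auc=auc_macro(aucs),
        roc_points=roc_points,
        model_id=model_id,
    )
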