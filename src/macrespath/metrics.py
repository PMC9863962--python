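"""Classification and segmentation metrics.

Classification metrics are one-vs-rest per class from TP/FP/TN/FN counts:
sensitivity TP/(TP+FN), specificity TN/(TN+FP), accuracy
(TP+TN)/(TP+TN+FP+FN).  Segmentation overlap is pixelwise:
IoU = TP/(FN+TP+FP) and Dice = 2TP/(FN+2TP+FP).  Zero denominators are
reported as an explicit ``undefined`` flag (None) rather than NaN; two empty
masks count as perfect overlap (IoU = Dice = 1), a logged convention.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")


def confusion_counts(labels: np.ndarray, predictions: np.ndarray,
                     positive_class: int) -> ConfusionCounts:
    """One-vs-rest counts for ``positive_class``."""
    y = np.asarray(labels) == positive_class
    p = np.asarray(predictions) == positive_class
    return ConfusionCounts(
        tp=int((y & p).sum()), fp=int((~y & p).sum()),
        tn=int((~y & ~p).sum()), fn=int((y & ~p).sum()),
    )


def classification_metrics(counts: ConfusionCounts) -> dict[str, float | None]:
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    total = tp + tn + fp + fn

    def ratio(num: int, den: int) -> float | None:
        return num / den if den > 0 else None

    return {
        "sensitivity": ratio(tp, tp + fn),
        "specificity": ratio(tn, tn + fp),
        "accuracy": ratio(tp + tn, total),
    }


def per_class_report(labels: np.ndarray, predictions: np.ndarray,
                     n_classes: int) -> dict:
    """Overall accuracy plus one-vs-rest metrics per class."""
    labels = np.asarray(labels)
    predictions = np.asarray(predictions)
    report = {
        "overall_accuracy": float((labels == predictions).mean()),
        "per_class": {},
    }
    for c in range(n_classes):
        report["per_class"][c] = classification_metrics(
            confusion_counts(labels, predictions, c))
    return report


def segmentation_metrics(pred_mask: np.ndarray,
                         true_mask: np.ndarray) -> dict[str, float]:
    """IoU and Dice between two binary masks of equal shape."""
    pred = np.asarray(pred_mask)
    true = np.asarray(true_mask)
    if pred.shape != true.shape:
        raise ValueError("masks must share one shape")
    if not (np.isin(pred, (0, 1)).all() and np.isin(true, (0, 1)).all()):
        raise ValueError("masks must be binary")
    p = pred.astype(bool)
    t = true.astype(bool)
    tp = int((p & t).sum())
    fp = int((p & ~t).sum())
    fn = int((~p & t).sum())
    if tp + fp + fn == 0:
        logger.info("both masks empty: reporting IoU=Dice=1 by convention")
        return {"iou": 1.0, "dice": 1.0}
    return {
        "iou": tp / (fn + tp + fp),
        "dice": 2 * tp / (fn + 2 * tp + fp),
    }
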