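"""Evaluation metrics for segmentation masks and class predictions.

Segmentation quality is scored per image from pixel-level true/false
positives and negatives:

* ``precision   = TP / (TP + FP)``
* ``sensitivity = TP / (TP + FN)``
* ``DSC         = 2 TP / ((TP + FP) + (TP + FN))``

Empty-mask conventions (not implied by the formulas, fixed here): if both
masks are empty every metric is 1 (the prediction is vacuously perfect);
otherwise a zero denominator scores 0.

Classification is scored one-vs-rest per class (precision, sensitivity,
F1 = 2PS/(P+S) with F1 = 0 when P + S = 0) plus the overall accuracy and
the full confusion matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PixelCounts",
    "SegMetrics",
    "ClassReport",
    "pixel_counts",
    "segmentation_metrics",
    "classification_report",
]


@dataclass(frozen=True)
class PixelCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class SegMetrics:
    precision: float
    sensitivity: float
    dsc: float


def pixel_counts(pred, truth) -> PixelCounts:
    p = np.asarray(pred, dtype=bool)
    t = np.asarray(truth, dtype=bool)
    if p.shape != t.shape:
        raise ValueError(f"mask shapes differ: {p.shape} vs {t.shape}")
    return PixelCounts(
        tp=int(np.count_nonzero(p & t)),
        fp=int(np.count_nonzero(p & ~t)),
        fn=int(np.count_nonzero(~p & t)),
        tn=int(np.count_nonzero(~p & ~t)),
    )


def _safe_div(num: float, den: float, both_empty: bool) -> float:
    if den == 0:
        return 1.0 if both_empty else 0.0
    return num / den


def segmentation_metrics(pred, truth) -> SegMetrics:
    """Precision, sensitivity and Dice coefficient of a predicted mask."""
    c = pixel_counts(pred, truth)
    both_empty = (c.tp + c.fp == 0) and (c.tp + c.fn == 0)
    return SegMetrics(
        precision=_safe_div(c.tp, c.tp + c.fp, both_empty),
        sensitivity=_safe_div(c.tp, c.tp + c.fn, both_empty),
        dsc=_safe_div(2 * c.tp, (c.tp + c.fp) + (c.tp + c.fn), both_empty),
    )


@dataclass(frozen=True)
class ClassReport:
    """Per-class one-vs-rest metrics, overall accuracy, confusion matrix.

    ``confusion`` is indexed by true class (rows) and predicted class
    (columns); row sums equal the per-class support.
    """

    precision: dict[str, float]
    sensitivity: dict[str, float]
    f1: dict[str, float]
    accuracy: float
    confusion: pd.DataFrame

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "per_class": {
                c: {
                    "precision": self.precision[c],
                    "sensitivity": self.sensitivity[c],
                    "f1": self.f1[c],
                }
                for c in self.confusion.index
            },
            "confusion": {
                str(t): {str(p): int(self.confusion.loc[t, p]) for p in self.confusion.columns}
                for t in self.confusion.index
            },
        }


def classification_report(pred_labels, true_labels, classes) -> ClassReport:
    """Score predictions against ground-truth labels.

    Every label must come from *classes*; an unseen label raises.
    """
    pred = list(pred_labels)
    true = list(true_labels)
    if len(pred) != len(true):
        raise ValueError("prediction and truth lengths differ")
    classes = list(classes)
    cset = set(classes)
    stray = (set(pred) | set(true)) - cset
    if stray:
        raise ValueError(f"labels outside the class list: {sorted(stray)}")
    idx = {c: i for i, c in enumerate(classes)}
    conf = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(true, pred):
        conf[idx[t], idx[p]] += 1
    precision, sensitivity, f1 = {}, {}, {}
    for c in classes:
        i = idx[c]
        tp = conf[i, i]
        fp = conf[:, i].sum() - tp
        fn = conf[i, :].sum() - tp
        prec = tp / (tp + fp) if tp + fp else 0.0
        sens = tp / (tp + fn) if tp + fn else 0.0
        precision[c] = float(prec)
        sensitivity[c] = float(sens)
        f1[c] = float(2 * prec * sens / (prec + sens)) if prec + sens else 0.0
    accuracy = float(np.trace(conf) / len(true)) if true else 0.0
    confusion = pd.DataFrame(conf, index=classes, columns=classes)
    return ClassReport(
        precision=precision,
        sensitivity=sensitivity,
        f1=f1,
        accuracy=accuracy,
        confusion=confusion,
    )
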