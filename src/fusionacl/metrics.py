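"""Binary diagnostic evaluation: confusion counts, accuracy/recall, ROC/AUC.

Standard definitions throughout: accuracy = (TP+TN)/(TP+FP+TN+FN),
recall = sensitivity = TP/(TP+FN), specificity = TN/(TN+FP).  A metric
whose denominator is zero is reported as NaN (a flagged missing value)
rather than raising.  The ROC curve is the empirical one over all score
thresholds and AUC is its trapezoidal area, which equals the Mann-Whitney
pair statistic P(score+ > score-) + 0.5 P(tie).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_curve as _sk_roc_curve


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")
        if self.total < 1:
            raise ValueError("confusion matrix must contain at least one sample")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class ROCCurve:
    """Empirical ROC: (FPR, TPR) points at strictly decreasing thresholds."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray


def confusion(calls, labels) -> ConfusionMatrix:
    """Cross-tabulate binary calls against binary reference labels."""
    calls = np.asarray(calls, int)
    labels = np.asarray(labels, int)
    if calls.shape != labels.shape:
        raise ValueError(f"length mismatch: {calls.shape} vs {labels.shape}")
    if calls.size < 1:
        raise ValueError("need at least one call/label pair")
    return ConfusionMatrix(
        tp=int(np.sum((calls == 1) & (labels == 1))),
        fp=int(np.sum((calls == 1) & (labels == 0))),
        tn=int(np.sum((calls == 0) & (labels == 0))),
        fn=int(np.sum((calls == 0) & (labels == 1))),
    )


def _ratio(num: int, den: int) -> float:
    return num / den if den > 0 else float("nan")


def accuracy(cm: ConfusionMatrix) -> float:
    return _ratio(cm.tp + cm.tn, cm.total)


def recall(cm: ConfusionMatrix) -> float:
    return _ratio(cm.tp, cm.tp + cm.fn)


def sensitivity(cm: ConfusionMatrix) -> float:
    return recall(cm)


def specificity(cm: ConfusionMatrix) -> float:
    return _ratio(cm.tn, cm.tn + cm.fp)


def roc_auc(scores, labels) -> tuple[ROCCurve, float]:
    """Empirical ROC curve and its trapezoidal area.

    Requires both classes to be present; unclamped, so a worse-than-chance
    ranker yields AUC < 0.5.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    if len(set(labels.tolist())) < 2:
        raise ValueError("ROC requires both classes present")
    fpr, tpr, thr = _sk_roc_curve(labels, scores)
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(fpr=fpr, tpr=tpr, thresholds=thr), auc
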