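"""Confusion-matrix statistics, ROC curves and AUC.

Sensitivity SE = TP/(TP+FN), specificity SP = TN/(TN+FP), total accuracy
Q = (TP+TN)/N (all in percent) and the Matthews correlation coefficient

    MCC = (TP*TN - FN*FP) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

with the standard four marginal factors in the denominator.  The ROC curve
sweeps the score threshold downward, plotting SE against 1-SP; tied scores
move as one threshold step (a diagonal segment), so the trapezoidal AUC
equals the Mann–Whitney pair statistic with half credit for ties.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.tn + self.fp


def confusion(preds, truth) -> ConfusionMatrix:
    preds = np.asarray(preds, dtype=int)
    truth = np.asarray(truth, dtype=int)
    if preds.shape != truth.shape:
        raise ValueError("prediction/truth length mismatch")
    for arr in (preds, truth):
        if not set(np.unique(arr)) <= {1, -1}:
            raise ValueError("labels must lie in {+1, -1}")
    return ConfusionMatrix(
        tp=int(np.sum((preds == 1) & (truth == 1))),
        fn=int(np.sum((preds == -1) & (truth == 1))),
        tn=int(np.sum((preds == -1) & (truth == -1))),
        fp=int(np.sum((preds == 1) & (truth == -1))),
    )


def _masked(name: str) -> None:
    warnings.warn(f"{name}: zero marginal, value masked")


def se(cm: ConfusionMatrix) -> float | None:
    """Sensitivity in percent; None when there are no actual positives."""
    if cm.tp + cm.fn == 0:
        _masked("SE")
        return None
    return 100.0 * cm.tp / (cm.tp + cm.fn)


def sp(cm: ConfusionMatrix) -> float | None:
    """Specificity in percent; None when there are no actual negatives."""
    if cm.tn + cm.fp == 0:
        _masked("SP")
        return None
    return 100.0 * cm.tn / (cm.tn + cm.fp)


def q(cm: ConfusionMatrix) -> float | None:
    """Total prediction accuracy in percent."""
    if cm.total == 0:
        _masked("Q")
        return None
    return 100.0 * (cm.tp + cm.tn) / cm.total


def mcc(cm: ConfusionMatrix) -> float | None:
    """Matthews correlation coefficient in [-1, 1]."""
    denom = (
        (cm.tp + cm.fp) * (cm.tp + cm.fn) * (cm.tn + cm.fp) * (cm.tn + cm.fn)
    )
    if denom == 0:
        _masked("MCC")
        return None
    return (cm.tp * cm.tn - cm.fn * cm.fp) / math.sqrt(denom)


def metrics_report(cm: ConfusionMatrix, ndigits: int = 2) -> dict:
    """SE/SP/Q (percent, rounded half-up style via round) and MCC (4 d.p.)."""
    out = {}
    for name, fn in (("SE", se), ("SP", sp), ("Q", q)):
        v = fn(cm)
        out[name] = None if v is None else round(v, ndigits)
    v = mcc(cm)
    out["MCC"] = None if v is None else round(v, 4)
    out.update(TP=cm.tp, FN=cm.fn, TN=cm.tn, FP=cm.fp)
    return out


@dataclass(frozen=True)
class ROCCurve:
    points: np.ndarray  # (k, 2): (1-SP, SE) from (0,0) to (1,1)
    auc: float


def roc_curve(scores, truth) -> ROCCurve:
    """Threshold sweep over unique scores, descending; ties step diagonally."""
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth, dtype=int)
    n_pos = int(np.sum(truth == 1))
    n_neg = int(np.sum(truth == -1))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires both classes in the truth labels")
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    t = truth[order]
    pts = [(0.0, 0.0)]
    tp = fp = 0
    i = 0
    while i < len(s):
        j = i
        while j < len(s) and s[j] == s[i]:
            j += 1
        tp += int(np.sum(t[i:j] == 1))
        fp += int(np.sum(t[i:j] == -1))
        pts.append((fp / n_neg, tp / n_pos))
        i = j
    points = np.asarray(pts)
    area = float(np.trapezoid(points[:, 1], points[:, 0]))
    return ROCCurve(points, area)


def auc(curve: ROCCurve) -> float:
    return curve.auc


def roc_points_frame(curve: ROCCurve) -> pd.DataFrame:
    return pd.DataFrame(curve.points, columns=["fpr", "se"])
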