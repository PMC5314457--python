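"""Threshold-based evaluation of continuous classifier scores.

All model adapters emit scores oriented so that *higher means IL-10
inducing*; a peptide is predicted positive iff its score >= the decision
threshold. Performance is summarised by sensitivity, specificity and
accuracy (percent) and the Matthews correlation coefficient:

    Sn  = 100 * TP / (TP + FN)
    Sp  = 100 * TN / (TN + FP)
    Acc = 100 * (TP + TN) / (TP + TN + FP + FN)
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

MCC with a zero denominator (degenerate confusion) is defined as 0.

Two sweep grids mirror the two score scales in use: signed SVM margins
(-2.0 ... 2.0, step 0.1) and positive-class probability fractions
(0.0 ... 1.0, step 0.05).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve

#: Threshold grid for margin-scaled scores (SVM decision values).
MARGIN_GRID = np.round(np.arange(-2.0, 2.0 + 1e-9, 0.1), 10)
#: Threshold grid for probability-scaled scores (vote / neighbour fractions).
PROB_GRID = np.round(np.arange(0.0, 1.0 + 1e-9, 0.05), 10)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n_pos(self) -> int:
        return self.tp + self.fn

    @property
    def n_neg(self) -> int:
        return self.tn + self.fp


def confusion_at_threshold(
    scores: np.ndarray, labels: np.ndarray, threshold: float
) -> ConfusionCounts:
    """Confusion counts with predicted-positive defined as score >= threshold."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    pred = scores >= threshold
    pos = labels == 1
    return ConfusionCounts(
        tp=int(np.sum(pred & pos)),
        fp=int(np.sum(pred & ~pos)),
        tn=int(np.sum(~pred & ~pos)),
        fn=int(np.sum(~pred & pos)),
    )


def sens_spec_acc_mcc(c: ConfusionCounts) -> tuple[float, float, float, float]:
    """(Sn %, Sp %, Acc %, MCC) from confusion counts.

    Requires at least one true positive-class and one true negative-class
    instance; an all-degenerate MCC denominator yields MCC = 0.
    """
    if c.n_pos == 0 or c.n_neg == 0:
        raise ValueError("both classes must be present to compute Sn/Sp")
    sn = 100.0 * c.tp / c.n_pos
    sp = 100.0 * c.tn / c.n_neg
    acc = 100.0 * (c.tp + c.tn) / (c.n_pos + c.n_neg)
    denom = (
        (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    mcc = 0.0 if denom == 0 else (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom)
    return sn, sp, acc, mcc


def counts_from_rates(
    sn_pct: float, sp_pct: float, n_pos: int, n_neg: int
) -> ConfusionCounts:
    """Reconstruct integer confusion counts from printed Sn/Sp and class sizes.

    TP = round(Sn/100 * n_pos), TN = round(Sp/100 * n_neg). Useful for
    checking that a published (Sn, Sp) operating point is consistent with
    its published accuracy and MCC.
    """
    tp = round(sn_pct / 100.0 * n_pos)
    tn = round(sp_pct / 100.0 * n_neg)
    return ConfusionCounts(tp=tp, fp=n_neg - tn, tn=tn, fn=n_pos - tp)


def roc_auc(scores, labels) -> tuple[float, np.ndarray, np.ndarray]:
    """Trapezoidal ROC AUC plus the ROC points (fpr, tpr).

    Thresholds at every distinct score; tied scores contribute the averaged
    (diagonal) segment, which the trapezoid integrates as half-credit.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC/AUC requires both classes to be present")
    fpr, tpr, _ = roc_curve(labels, scores)
    auc = float(np.trapezoid(tpr, fpr))
    return auc, fpr, tpr


def threshold_sweep(
    scores,
    labels,
    grid,
    criterion: str = "mcc",
) -> tuple[pd.DataFrame, float]:
    """Evaluate every grid threshold; return the table and the best threshold.

    ``criterion`` picks the operating point: ``"mcc"`` (default) maximises
    MCC, ``"accuracy"`` maximises Acc, ``"balance"`` minimises |Sn - Sp|.
    Ties are broken toward the smaller |Sn - Sp| and then the smaller
    threshold.
    """
    grid = np.asarray(list(grid), dtype=float)
    if grid.size == 0:
        raise ValueError("threshold grid must be non-empty")
    rows = []
    for thr in grid:
        sn, sp, acc, mcc = sens_spec_acc_mcc(
            confusion_at_threshold(scores, labels, thr)
        )
        rows.append((thr, sn, sp, acc, mcc))
    table = pd.DataFrame(
        rows, columns=["Threshold", "Sensitivity", "Specificity", "Accuracy", "MCC"]
    )
    key = {"mcc": "MCC", "accuracy": "Accuracy"}.get(criterion)
    if criterion == "balance":
        primary = -(table["Sensitivity"] - table["Specificity"]).abs()
    elif key is not None:
        primary = table[key]
    else:
        raise ValueError(f"unknown criterion {criterion!r}")
    balance = -(table["Sensitivity"] - table["Specificity"]).abs()
    order = sorted(
        range(len(table)),
        key=lambda i: (-primary.iloc[i], -balance.iloc[i], table["Threshold"].iloc[i]),
    )
    best = float(table["Threshold"].iloc[order[0]])
    return table, best
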