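"""Figures of merit for the selection and designation stages.

Confusion-count rates (TPR/FPR), dataset fractions of false calls,
appearance-time mean absolute error as a percentage of the pulse duration,
P2/P1 ratio MAE, and the accuracy of ratio > 1 detection.  Report rounding
is half-up to match conventional table formatting; internal values are
never rounded.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .networks import PULSE_LEN


@dataclass
class ConfusionCounts:
    """Binary confusion counts for the pulse-selection task."""
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("counts must be nonnegative")
        if self.total == 0:
            raise ValueError("empty confusion matrix")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion(labels, predicted) -> ConfusionCounts:
    """Confusion counts from boolean label/prediction masks."""
    y = np.asarray(labels).astype(bool)
    p = np.asarray(predicted).astype(bool)
    if y.shape != p.shape:
        raise ValueError("labels and predictions must align")
    return ConfusionCounts(tp=int((y & p).sum()), fp=int((~y & p).sum()),
                           tn=int((~y & ~p).sum()), fn=int((y & ~p).sum()))


def rates(c: ConfusionCounts) -> tuple[float, float]:
    """(TPR, FPR) in percent: 100*tp/(tp+fn), 100*fp/(fp+tn)."""
    if c.tp + c.fn == 0 or c.fp + c.tn == 0:
        raise ValueError("rates undefined: an outcome class is empty")
    return 100.0 * c.tp / (c.tp + c.fn), 100.0 * c.fp / (c.fp + c.tn)


def dataset_fractions(c: ConfusionCounts) -> tuple[float, float]:
    """Percent of all pulses that are false positives / false negatives."""
    return 100.0 * c.fp / c.total, 100.0 * c.fn / c.total


def appearance_mae(true_labels, predicted) -> tuple[float, float]:
    """Mean absolute P1/P2 appearance-time error, % of pulse duration.

    Inputs are aligned (n, 2) integer arrays of subpeak indices in the
    180-point frame, restricted to pulses where both truth and prediction
    are calculable.
    """
    t = np.asarray(true_labels, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if t.shape != p.shape or t.ndim != 2 or t.shape[1] != 2:
        raise ValueError("need aligned (n, 2) index arrays")
    if len(t) == 0:
        raise ValueError("no pulses to evaluate")
    mae = np.mean(np.abs(t - p), axis=0) / PULSE_LEN * 100.0
    return float(mae[0]), float(mae[1])


def ratio_eval(true_ratios, predicted_ratios) -> tuple[float, float]:
    """(ratio MAE, accuracy of ratio > 1 detection).

    A ratio of exactly 1 belongs to the "-" class (strict >), so a pulse is
    correctly classified iff (pred > 1) == (true > 1).
    """
    t = np.asarray(true_ratios, dtype=float)
    p = np.asarray(predicted_ratios, dtype=float)
    if t.shape != p.shape or len(t) == 0:
        raise ValueError("need aligned nonempty ratio arrays")
    mae = float(np.mean(np.abs(t - p)))
    acc = float(np.mean((t > 1) == (p > 1)))
    return mae, acc


@dataclass
class DesignationEval:
    """Designation metrics over a labeled test set."""
    p1_mae_pct: float
    p2_mae_pct: float
    ratio_mae: float
    gt1_accuracy: float


def evaluate_designation(true_labels, predicted, true_ratios,
                         predicted_ratios) -> DesignationEval:
    p1_mae, p2_mae = appearance_mae(true_labels, predicted)
    ratio_mae, acc = ratio_eval(true_ratios, predicted_ratios)
    return DesignationEval(p1_mae_pct=p1_mae, p2_mae_pct=p2_mae,
                           ratio_mae=ratio_mae, gt1_accuracy=acc)


def round_half_up(x: float, decimals: int = 1) -> float:
    """Half-up rounding for report tables (numpy rounds half to even)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def selection_report(counts: dict[str, ConfusionCounts]) -> pd.DataFrame:
    """Tabular report of confusion counts and rates per architecture."""
    rows = {}
    for name, c in counts.items():
        tpr, fpr = rates(c)
        fp_pct, fn_pct = dataset_fractions(c)
        rows[name] = {
            "tp": c.tp, "fp": c.fp, "tn": c.tn, "fn": c.fn,
            "tpr_pct": round_half_up(tpr), "fpr_pct": round_half_up(fpr),
            "fp_pct_of_total": round_half_up(fp_pct),
            "fn_pct_of_total": round_half_up(fn_pct),
        }
    return pd.DataFrame(rows).T
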