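"""Screening metrics and confusion-matrix reconstruction.

Malignant is the positive class throughout: sensitivity is the true-
positive rate on malignant masses, specificity the true-negative rate on
benign ones.  Cohen's kappa corrects accuracy for chance agreement:
``kappa = (Po - Pe) / (1 - Pe)`` with ``Po`` the observed accuracy and
``Pe`` the expected agreement of independent marginals.

Percentages are reported rounded half-up to 2 decimals; raw fractions
are retained on the report object.  ``reconstruct_confusion`` inverts
printed sensitivity/specificity percentages and class counts back to an
integer confusion matrix, which makes published result rows auditable:
recomputing all metrics from the reconstructed matrix must reproduce the
printed row.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from sklearn.metrics import roc_auc_score

__all__ = [
    "ConfusionMatrix", "MetricsReport", "compute_metrics",
    "reconstruct_confusion", "confusion_from_predictions", "roc_auc",
    "round2",
]


def round2(x: float) -> float:
    """Round half-up to 2 decimals (printed-table convention)."""
    return math.floor(x * 100 + 0.5) / 100


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 counts; positive class = malignant."""

    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValueError("confusion-matrix counts must be non-negative")

    @property
    def n_malignant(self) -> int:
        return self.tp + self.fn

    @property
    def n_benign(self) -> int:
        return self.tn + self.fp

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.tn + self.fp


@dataclass
class MetricsReport:
    """All headline metrics as percentages (None where undefined)."""

    sensitivity: Optional[float]
    specificity: Optional[float]
    accuracy: Optional[float]
    kappa: Optional[float]
    f1: Optional[float]
    po: float
    pe: float
    auc: Optional[float] = None  # fraction in [0, 1], set separately

    def as_dict(self) -> dict:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "kappa": self.kappa,
            "f1": self.f1,
            "po": self.po,
            "pe": self.pe,
            "auc": self.auc,
        }


def compute_metrics(cm: ConfusionMatrix, f1_from_sen_spe: bool = False) -> MetricsReport:
    """Sensitivity, specificity, accuracy, Cohen's kappa and F1 from counts.

    F1 defaults to the precision/recall harmonic mean; with
    ``f1_from_sen_spe=True`` it is the harmonic mean of sensitivity and
    specificity instead.  Zero-denominator metrics are ``None``.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    tp, fn, tn, fp = cm.tp, cm.fn, cm.tn, cm.fp
    total = cm.total

    sen = tp / (tp + fn) if tp + fn else None
    spe = tn / (tn + fp) if tn + fp else None
    acc = (tp + tn) / total
    po = acc
    pe = ((tp + fn) * (tp + fp) + (fp + tn) * (fn + tn)) / total**2
    kappa = (po - pe) / (1 - pe) if pe != 1 else None

    if f1_from_sen_spe:
        f1 = (
            2 * sen * spe / (sen + spe)
            if sen is not None and spe is not None and (sen + spe) > 0
            else None
        )
    else:
        prec = tp / (tp + fp) if tp + fp else None
        rec = sen
        f1 = (
            2 * prec * rec / (prec + rec)
            if prec is not None and rec is not None and (prec + rec) > 0
            else None
        )

    pct = lambda v: None if v is None else round2(100 * v)
    return MetricsReport(
        sensitivity=pct(sen),
        specificity=pct(spe),
        accuracy=pct(acc),
        kappa=pct(kappa),
        f1=pct(f1),
        po=po,
        pe=pe,
    )


def reconstruct_confusion(
    n_malignant: int, n_benign: int, sen_percent: float, spe_percent: float
) -> ConfusionMatrix:
    """Integer confusion matrix implied by printed sensitivity/specificity
    percentages and the test-set class counts (rounding half-up)."""
    if n_malignant <= 0 or n_benign <= 0:
        raise ValueError("class counts must be positive")
    if not (0 <= sen_percent <= 100 and 0 <= spe_percent <= 100):
        raise ValueError("percentages must lie in [0, 100]")
    tp = _round_half_up(sen_percent * n_malignant / 100)
    tn = _round_half_up(spe_percent * n_benign / 100)
    return ConfusionMatrix(tp=tp, fn=n_malignant - tp, tn=tn, fp=n_benign - tn)


def confusion_from_predictions(
    y_true: Sequence[int], y_pred: Sequence[int]
) -> ConfusionMatrix:
    """Counts from 0/1 label arrays (1 = malignant = positive)."""
    t = np.asarray(y_true, dtype=int)
    p = np.asarray(y_pred, dtype=int)
    if t.shape != p.shape:
        raise ValueError("y_true and y_pred differ in length")
    return ConfusionMatrix(
        tp=int(((t == 1) & (p == 1)).sum()),
        fn=int(((t == 1) & (p == 0)).sum()),
        tn=int(((t == 0) & (p == 0)).sum()),
        fp=int(((t == 0) & (p == 1)).sum()),
    )


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Trapezoidal AUC of malignant scores (midrank tie handling)."""
    y = np.asarray(labels, dtype=int)
    if np.unique(y).size < 2:
        raise ValueError("AUC requires both classes")
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))
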