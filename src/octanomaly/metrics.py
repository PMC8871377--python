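"""Confusion-matrix evaluation suite for the binary AMD/NORMAL task.

AMD is the positive class.  For a confusion matrix with counts TP (AMD
called AMD), FN (AMD called NORMAL), FP (NORMAL called AMD) and TN:

    accuracy    = (TP + TN) / (TP + TN + FP + FN)        (global)
    sensitivity = TP / (TP + FN)
    precision   = TP / (TP + FP)
    F1          = 2 * precision * sensitivity / (precision + sensitivity)

Reports follow the per-class convention common in screening studies:
each class's row lists its own recall under the "accuracy" column (for
the NORMAL row the positive/negative roles are swapped), and the
"weighted average" row is the support-weighted mean of the per-class
values — which, for recall, coincides with global accuracy in the binary
case.  Percentages are rounded half-up to 2 decimals and AUC to 4, at
the reporting layer only; internal values stay exact.

ROC curves come from a threshold sweep over the unique scores (higher
score = more AMD-like, the LOF convention); AUC is the trapezoidal area,
which equals the tie-corrected normalized Mann-Whitney U statistic.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction
from typing import Optional, Sequence

import numpy as np

from .data import BinaryLabel

_METRIC_NAMES = ("accuracy", "sensitivity", "precision", "f1")


def round_half_up(x: float, ndigits: int) -> float:
    """Decimal round-half-up (0.005 -> 0.01), as printed metric tables use."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionMatrix:
    """Binary confusion counts; rows = true label, columns = predicted."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fn", "fp", "tn"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def amd_support(self) -> int:
        return self.tp + self.fn

    @property
    def normal_support(self) -> int:
        return self.fp + self.tn

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    def swapped(self) -> "ConfusionMatrix":
        """The same matrix with NORMAL treated as the positive class."""
        return ConfusionMatrix(tp=self.tn, fn=self.fp, fp=self.fn, tn=self.tp)


def confusion(
    true_labels: Sequence[BinaryLabel | str],
    predicted_labels: Sequence[BinaryLabel | str],
) -> ConfusionMatrix:
    """Count the four cells from paired label sequences over {AMD, NORMAL}."""
    if len(true_labels) != len(predicted_labels):
        raise ValueError("true and predicted label sequences differ in length")
    counts = {"tp": 0, "fn": 0, "fp": 0, "tn": 0}
    for t, p in zip(true_labels, predicted_labels):
        t, p = BinaryLabel(t), BinaryLabel(p)
        if t is BinaryLabel.AMD:
            counts["tp" if p is BinaryLabel.AMD else "fn"] += 1
        else:
            counts["fp" if p is BinaryLabel.AMD else "tn"] += 1
    return ConfusionMatrix(**counts)


def _positive_class_metrics(cm: ConfusionMatrix) -> dict[str, Optional[Fraction]]:
    """Recall/precision/F1 of the positive class, exact rationals; None when undefined."""
    recall = Fraction(cm.tp, cm.tp + cm.fn) if cm.tp + cm.fn > 0 else None
    precision = Fraction(cm.tp, cm.tp + cm.fp) if cm.tp + cm.fp > 0 else None
    f1 = None
    if precision is not None and recall is not None and precision + recall > 0:
        f1 = 2 * precision * recall / (precision + recall)
    return {"accuracy": recall, "sensitivity": recall, "precision": precision, "f1": f1}


def class_metrics(cm: ConfusionMatrix) -> dict[str, dict[str, Optional[float]]]:
    """Per-class metric block as percentages (unrounded floats; None = undefined).

    The AMD block uses AMD as positive; the NORMAL block swaps the roles.
    Per-class "accuracy" is the class's recall, matching the screening
    convention for per-class table rows.
    """
    out = {}
    for name, mat in (("AMD", cm), ("NORMAL", cm.swapped())):
        block = _positive_class_metrics(mat)
        out[name] = {k: (None if v is None else 100.0 * float(v)) for k, v in block.items()}
    return out


def weighted_metrics(cm: ConfusionMatrix) -> dict[str, Optional[float]]:
    """Support-weighted average of the per-class metrics, as percentages."""
    if cm.amd_support == 0 or cm.normal_support == 0:
        raise ValueError("weighted metrics require both class supports > 0")
    amd = _positive_class_metrics(cm)
    nrm = _positive_class_metrics(cm.swapped())
    out: dict[str, Optional[float]] = {}
    for name in _METRIC_NAMES:
        a, n = amd[name], nrm[name]
        if a is None or n is None:
            out[name] = None
        else:
            w = (cm.amd_support * a + cm.normal_support * n) / cm.total
            out[name] = 100.0 * float(w)
    return out


def global_accuracy(cm: ConfusionMatrix) -> float:
    """(TP + TN) / total, as a percentage."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return 100.0 * float(Fraction(cm.tp + cm.tn, cm.total))


def roc_curve(
    scores: Sequence[float], true_labels: Sequence[BinaryLabel | str]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(fpr, tpr, thresholds) from a sweep over the unique scores, descending.

    Tied scores collapse onto a single operating point.  The first point
    is (0, 0) at threshold +inf and the last is (1, 1).
    """
    s = np.asarray(scores, dtype=np.float64)
    y = np.array([BinaryLabel(t) is BinaryLabel.AMD for t in true_labels])
    if len(s) != len(y):
        raise ValueError("scores and labels differ in length")
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires both classes present")
    order = np.argsort(-s, kind="stable")
    s, y = s[order], y[order]
    distinct = np.r_[np.flatnonzero(np.diff(s)), len(s) - 1]
    tps = np.cumsum(y)[distinct]
    fps = np.cumsum(~y)[distinct]
    tpr = np.r_[0.0, tps / n_pos]
    fpr = np.r_[0.0, fps / n_neg]
    thresholds = np.r_[np.inf, s[distinct]]
    return fpr, tpr, thresholds


def roc_auc(
    scores: Sequence[float], true_labels: Sequence[BinaryLabel | str]
) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC points plus the trapezoidal AUC (tie-corrected: ties earn half credit)."""
    fpr, tpr, _ = roc_curve(scores, true_labels)
    auc = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, auc


@dataclass
class MetricsReport:
    """Full evaluation block: counts, per-class and weighted percentages, AUC."""

    cm: ConfusionMatrix
    per_class: dict[str, dict[str, Optional[float]]]
    weighted: dict[str, Optional[float]]
    global_accuracy: float
    auc: Optional[float] = None

    @classmethod
    def from_predictions(
        cls,
        true_labels: Sequence[BinaryLabel | str],
        predicted_labels: Sequence[BinaryLabel | str],
        scores: Optional[Sequence[float]] = None,
    ) -> "MetricsReport":
        cm = confusion(true_labels, predicted_labels)
        auc = None
        if scores is not None:
            try:
                _, _, auc = roc_auc(scores, true_labels)
            except ValueError:
                auc = None  # single-class test set: AUC undefined, reported absent
        return cls(
            cm=cm,
            per_class=class_metrics(cm),
            weighted=weighted_metrics(cm) if cm.amd_support and cm.normal_support else {},
            global_accuracy=global_accuracy(cm),
            auc=auc,
        )

    def rounded(self) -> dict:
        """Reporting view: percentages at 2 decimals (half-up), AUC at 4."""
        def r2(v):
            return None if v is None else round_half_up(v, 2)

        return {
            "confusion": {"tp": self.cm.tp, "fn": self.cm.fn,
                          "fp": self.cm.fp, "tn": self.cm.tn},
            "per_class": {c: {k: r2(v) for k, v in block.items()}
                          for c, block in self.per_class.items()},
            "weighted": {k: r2(v) for k, v in self.weighted.items()},
            "global_accuracy": r2(self.global_accuracy),
            "auc": None if self.auc is None else round_half_up(self.auc, 4),
        }
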