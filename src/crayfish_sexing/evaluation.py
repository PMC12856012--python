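"""Confusion matrices, the six-metric report, and table aggregation.

Positive class is male throughout: predicting a male animal as male is a
true positive, a female as male a false positive. The metric suite is
accuracy, sensitivity (recall), specificity, precision, F1 and Matthews
correlation coefficient; displayed values are rounded half-away-from-zero
at three decimals, matching the benchmark tables, while internal values
keep full precision.

``reconstruct_cm`` inverts printed recall/specificity rows back to integer
confusion matrices (with a round-trip consistency check), which lets the
published metric rows be re-derived from the Table 2 formulas exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ConfusionMatrix",
    "MetricReport",
    "confusion",
    "metrics",
    "reconstruct_cm",
    "sum_accuracy",
    "round_display",
]


def round_display(x: float, decimals: int = 3) -> float:
    """Round half away from zero (table presentation convention)."""
    factor = 10**decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.total == 0:
            raise ValueError("confusion matrix must contain at least one sample")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricReport:
    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    f1: float
    mcc: float
    degenerate: tuple[str, ...] = ()  # metrics whose denominator was zero
    rounding: int = 3

    def rounded(self) -> dict[str, float]:
        return {
            name: round_display(getattr(self, name), self.rounding)
            for name in ("accuracy", "sensitivity", "specificity",
                         "precision", "f1", "mcc")
        }


def confusion(
    true_labels: np.ndarray, predicted_labels: np.ndarray, positive: str = "M"
) -> ConfusionMatrix:
    """Count TP/FP/FN/TN with male as the positive class."""
    t = np.asarray(true_labels)
    p = np.asarray(predicted_labels)
    if t.shape != p.shape:
        raise ValueError(f"length mismatch: {t.shape} vs {p.shape}")
    valid = {"F", "M"}
    bad = (set(np.unique(t)) | set(np.unique(p))) - valid
    if bad:
        raise ValueError(f"unknown labels {sorted(bad)}; expected F/M")
    tpos = t == positive
    ppos = p == positive
    return ConfusionMatrix(
        tp=int(np.sum(tpos & ppos)),
        fp=int(np.sum(~tpos & ppos)),
        fn=int(np.sum(tpos & ~ppos)),
        tn=int(np.sum(~tpos & ~ppos)),
    )


def _ratio(num: float, den: float, name: str, degenerate: list[str]) -> float:
    if den == 0:
        degenerate.append(name)
        return 0.0
    return num / den


def metrics(cm: ConfusionMatrix) -> MetricReport:
    """The six-metric suite; zero-denominator metrics report 0, flagged."""
    degenerate: list[str] = []
    tp, fp, fn, tn = cm.tp, cm.fp, cm.fn, cm.tn
    accuracy = (tp + tn) / cm.total
    sensitivity = _ratio(tp, tp + fn, "sensitivity", degenerate)
    specificity = _ratio(tn, tn + fp, "specificity", degenerate)
    precision = _ratio(tp, tp + fp, "precision", degenerate)
    f1 = _ratio(2 * precision * sensitivity, precision + sensitivity, "f1",
                degenerate)
    mcc_den = math.sqrt(
        float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    )
    mcc = _ratio(tp * tn - fp * fn, mcc_den, "mcc", degenerate)
    return MetricReport(accuracy, sensitivity, specificity, precision, f1,
                        mcc, tuple(degenerate))


def reconstruct_cm(
    recall: float, specificity: float, n_pos: int, n_neg: int, decimals: int = 3
) -> ConfusionMatrix:
    """Integer confusion matrix consistent with printed recall/specificity.

    TP = round(recall * n_pos), TN = round(specificity * n_neg); the result
    is returned only when re-deriving the two rates from the integers and
    rounding reproduces the inputs, else the printed row is inconsistent.
    """
    if not (0.0 <= recall <= 1.0 and 0.0 <= specificity <= 1.0):
        raise ValueError("recall and specificity must lie in [0, 1]")
    if n_pos < 1 or n_neg < 1:
        raise ValueError("class sizes must be positive")
    tp = int(round_display(recall * n_pos, 0))
    tn = int(round_display(specificity * n_neg, 0))
    cm = ConfusionMatrix(tp=tp, fp=n_neg - tn, fn=n_pos - tp, tn=tn)

    def consistent(rate: float, printed: float) -> bool:
        # benchmark tables occasionally round in two steps (e.g. 50/62 =
        # 0.80645 -> 0.8065 -> 0.807), so accept the double-rounded form too
        target = round_display(printed, decimals)
        return (round_display(rate, decimals) == target
                or round_display(round_display(rate, decimals + 1), decimals)
                == target)

    if not (consistent(cm.tp / n_pos, recall)
            and consistent(cm.tn / n_neg, specificity)):
        raise ValueError(
            f"no integer matrix with n_pos={n_pos}, n_neg={n_neg} reproduces "
            f"recall={recall} and specificity={specificity} at "
            f"{decimals} decimals"
        )
    return cm


def sum_accuracy(reports: list, decimals: int = 3) -> float:
    """Sum of display-rounded accuracies (table column totals).

    Accepts MetricReport objects or raw accuracy floats.
    """
    if not reports:
        raise ValueError("need at least one report")
    total = 0.0
    for r in reports:
        acc = r.accuracy if isinstance(r, MetricReport) else float(r)
        total += round_display(acc, decimals)
    return round_display(total, decimals)
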