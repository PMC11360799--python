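"""Confusion matrix and pooled multi-class sensitivity/specificity/accuracy.

The headline metrics pool one-vs-rest counts over all C classes of a C x C
confusion matrix M (rows = true class, columns = predicted class):

* TP = trace(M)
* FP = sum over classes of (column sum - diagonal)
* FN = sum over classes of (row sum - diagonal)
* TN = sum over classes of (grand total - row sum - column sum + diagonal)

and report, as percentages,

* sensitivity = TP / (TP + FN) * 100
* specificity = TN / (TN + FP) * 100
* accuracy    = (TP + TN) / (TP + TN + FP + FN) * 100

Macro (per-class averaged) values and the plain accuracy trace/total are
reported alongside for transparency.  Class ordering is fixed (numeric sleep
stages first, then W, R, M, then anything else sorted) so confusion matrices
are comparable across runs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion

__all__ = [
    "STAGE_ORDER",
    "ConfusionMatrix",
    "EvalReport",
    "confusion",
    "aggregate_counts",
    "report",
    "class_sort_key",
]

#: canonical display order for sleep-stage labels
STAGE_ORDER = ("S1", "S2", "S3", "S4", "W", "R", "M")


def class_sort_key(label) -> tuple:
    s = str(label)
    if s in STAGE_ORDER:
        return (0, STAGE_ORDER.index(s), "")
    return (1, 0, s)


@dataclass(frozen=True)
class ConfusionMatrix:
    """C x C counts, rows = true class, columns = predicted class."""

    M: np.ndarray
    classes: tuple

    def __post_init__(self) -> None:
        M = np.asarray(self.M)
        if M.ndim != 2 or M.shape[0] != M.shape[1]:
            raise ValueError("confusion matrix must be square")
        if M.shape[0] != len(self.classes):
            raise ValueError("class names must match the matrix dimension")
        if np.any(M < 0):
            raise ValueError("confusion counts must be non-negative")
        object.__setattr__(self, "M", M.astype(np.int64))
        object.__setattr__(self, "classes", tuple(self.classes))

    @property
    def total(self) -> int:
        return int(self.M.sum())


@dataclass(frozen=True)
class EvalReport:
    """Pooled percentages plus per-class breakdown and macro alternatives."""

    sensitivity_pct: float
    specificity_pct: float
    accuracy_pct: float
    pooled: dict
    per_class: dict
    macro_sensitivity_pct: float
    macro_specificity_pct: float
    plain_accuracy_pct: float
    confusion: ConfusionMatrix | None = field(default=None, repr=False)

    def to_dict(self) -> dict:
        d = {
            "sensitivity_pct": self.sensitivity_pct,
            "specificity_pct": self.specificity_pct,
            "accuracy_pct": self.accuracy_pct,
            "pooled": dict(self.pooled),
            "per_class": {k: dict(v) for k, v in self.per_class.items()},
            "macro_sensitivity_pct": self.macro_sensitivity_pct,
            "macro_specificity_pct": self.macro_specificity_pct,
            "plain_accuracy_pct": self.plain_accuracy_pct,
        }
        if self.confusion is not None:
            d["confusion"] = {
                "classes": [str(c) for c in self.confusion.classes],
                "matrix": self.confusion.M.tolist(),
            }
        return d


def confusion(y_true, y_pred, classes=None) -> ConfusionMatrix:
    """Count (true, predicted) pairs into a deterministic-order matrix."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size != y_pred.size:
        raise ValueError(
            f"length mismatch: {y_true.size} true vs {y_pred.size} predicted"
        )
    if classes is None:
        observed = set(map(str, y_true)) | set(map(str, y_pred))
        classes = sorted(observed, key=class_sort_key)
    M = _sk_confusion(
        y_true.astype(str), y_pred.astype(str), labels=[str(c) for c in classes]
    )
    return ConfusionMatrix(M, tuple(classes))


def aggregate_counts(cm: ConfusionMatrix) -> tuple[int, int, int, int]:
    """Pooled (TP, TN, FP, FN) over all classes of the confusion matrix."""
    M = cm.M
    if M.shape[0] < 2:
        raise ValueError("pooled counts need at least 2 classes")
    diag = np.diag(M)
    rows = M.sum(axis=1)
    cols = M.sum(axis=0)
    total = M.sum()
    tp = int(diag.sum())
    fp = int((cols - diag).sum())
    fn = int((rows - diag).sum())
    tn = int((total - rows - cols + diag).sum())
    return tp, tn, fp, fn


def _pct(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name}: zero denominator; value undefined")
        return float("nan")
    return 100.0 * num / den


def report(cm: ConfusionMatrix) -> EvalReport:
    """Pooled sensitivity/specificity/accuracy report from a confusion matrix."""
    tp, tn, fp, fn = aggregate_counts(cm)
    M = cm.M
    diag = np.diag(M)
    rows = M.sum(axis=1)
    cols = M.sum(axis=0)
    total = M.sum()

    per_class = {}
    sens_c, spec_c = [], []
    for i, c in enumerate(cm.classes):
        ctp = int(diag[i])
        cfn = int(rows[i] - diag[i])
        cfp = int(cols[i] - diag[i])
        ctn = int(total - rows[i] - cols[i] + diag[i])
        per_class[str(c)] = {"TP": ctp, "TN": ctn, "FP": cfp, "FN": cfn}
        sens_c.append(ctp / (ctp + cfn) if ctp + cfn else np.nan)
        spec_c.append(ctn / (ctn + cfp) if ctn + cfp else np.nan)

    return EvalReport(
        sensitivity_pct=_pct(tp, tp + fn, "sensitivity"),
        specificity_pct=_pct(tn, tn + fp, "specificity"),
        accuracy_pct=_pct(tp + tn, tp + tn + fp + fn, "accuracy"),
        pooled={"TP": tp, "TN": tn, "FP": fp, "FN": fn},
        per_class=per_class,
        macro_sensitivity_pct=float(100.0 * np.nanmean(sens_c)),
        macro_specificity_pct=float(100.0 * np.nanmean(spec_c)),
        plain_accuracy_pct=_pct(int(diag.sum()), int(total), "plain accuracy"),
        confusion=cm,
    )
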