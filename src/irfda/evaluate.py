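"""Classification evaluation: confusion matrices, FPR/FNR, ROC/AUC, the
joint nine-class labeling, and the misclassification taxonomy.

Binary predictions for the four functional groups are assessed per group
and then combined: each compound's four flags map to one of nine mutually
exclusive composition classes (four single groups, four observed pairs,
or none); flag combinations outside those nine are reported verbatim as
``other_combo`` rather than coerced.  Misclassifications are partitioned
into partial / missed / spurious / disjoint errors by comparing the true
and predicted group sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve as _sk_roc_curve

from .io import GROUPS

#: Composition classes in canonical (table) order.
JOINT_CLASSES = (
    "amide_only",
    "aniline_only",
    "benzene_only",
    "piperidine_only",
    "amide_aniline",
    "amide_benzene",
    "aniline_benzene",
    "benzene_piperidine",
    "none",
)

_FLAGS_TO_CLASS = {
    (True, False, False, False): "amide_only",
    (False, True, False, False): "aniline_only",
    (False, False, True, False): "benzene_only",
    (False, False, False, True): "piperidine_only",
    (True, True, False, False): "amide_aniline",
    (True, False, True, False): "amide_benzene",
    (False, True, True, False): "aniline_benzene",
    (False, False, True, True): "benzene_piperidine",
    (False, False, False, False): "none",
}

_CLASS_TO_FLAGS = {v: k for k, v in _FLAGS_TO_CLASS.items()}


@dataclass(frozen=True)
class BinaryConfusion:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


class Rates(NamedTuple):
    fpr: float | None
    fnr: float | None
    accuracy: float


@dataclass(frozen=True)
class RocCurve:
    """ROC curve: sensitivity (1-FNR) against FPR over descending thresholds."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    one_minus_specificity: np.ndarray
    auc: float


@dataclass(frozen=True)
class JointLabel:
    """One of the nine composition classes, or a raw out-of-table combo."""

    value: str
    flags: tuple[bool, bool, bool, bool]

    @property
    def group_set(self) -> frozenset[str]:
        return frozenset(g for g, f in zip(GROUPS, self.flags) if f)


@dataclass(frozen=True)
class JointConfusion:
    """Truth-by-prediction cross-tabulation of joint labels.

    Rows are true classes, columns predicted classes; out-of-table
    predicted combinations appear as extra ``other_combo:...`` columns.
    """

    table: pd.DataFrame
    accuracy: float
    n: int

    @property
    def diagonal_total(self) -> int:
        return int(
            sum(
                self.table.at[c, c]
                for c in self.table.index
                if c in self.table.columns
            )
        )


def confusion(pred: Sequence[bool], truth: Sequence[bool]) -> BinaryConfusion:
    """Tally TP/FP/FN/TN (prediction vs ground truth)."""
    p = np.asarray(pred, dtype=bool)
    t = np.asarray(truth, dtype=bool)
    if p.shape != t.shape or p.size == 0:
        raise ValueError("pred and truth must be equal-length and non-empty")
    return BinaryConfusion(
        tp=int(np.sum(p & t)),
        fp=int(np.sum(p & ~t)),
        fn=int(np.sum(~p & t)),
        tn=int(np.sum(~p & ~t)),
    )


def rates(cm: BinaryConfusion) -> Rates:
    """FPR = FP/(FP+TN), FNR = FN/(FN+TP), accuracy = (TP+TN)/total.

    A rate with zero denominator is reported as None rather than raising.
    """
    fpr = cm.fp / (cm.fp + cm.tn) if (cm.fp + cm.tn) > 0 else None
    fnr = cm.fn / (cm.fn + cm.tp) if (cm.fn + cm.tp) > 0 else None
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return Rates(fpr, fnr, (cm.tp + cm.tn) / cm.total)


def roc_auc(probabilities: Sequence[float], truth: Sequence[bool]) -> RocCurve:
    """ROC curve over every distinct probability cut, with trapezoid AUC.

    The curve starts at (0, 0) and ends at (1, 1); the AUC equals the
    Mann-Whitney concordance probability with ties counted one half.
    """
    p = np.asarray(probabilities, dtype=float)
    t = np.asarray(truth, dtype=bool)
    if p.shape != t.shape:
        raise ValueError("probabilities and truth must be equal-length")
    if t.all() or (~t).all():
        raise ValueError("ROC requires both classes present")
    fpr, tpr, thr = _sk_roc_curve(t.astype(int), p, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(thresholds=thr, sensitivity=tpr, one_minus_specificity=fpr, auc=auc)


def derive_joint_label(flags: Sequence[bool]) -> JointLabel:
    """Map four group flags to the composition class (or other_combo)."""
    key = tuple(bool(f) for f in flags)
    if len(key) != 4:
        raise ValueError("expected four flags")
    name = _FLAGS_TO_CLASS.get(key)
    if name is None:
        combo = "+".join(g for g, f in zip(GROUPS, key) if f)
        name = f"other_combo:{combo}"
    return JointLabel(name, key)


def class_flags(name: str) -> tuple[bool, bool, bool, bool]:
    """Flags of a named composition class (inverse of derive_joint_label)."""
    return _CLASS_TO_FLAGS[name]


def joint_confusion(
    pred_flags: Sequence[Sequence[bool]],
    truth_flags: Sequence[Sequence[bool]],
) -> JointConfusion:
    """Cross-tabulate derived joint labels; accuracy is exact flag match."""
    if len(pred_flags) != len(truth_flags):
        raise ValueError("pred and truth must be equal-length")
    pred_labels = [derive_joint_label(f).value for f in pred_flags]
    truth_labels = [derive_joint_label(f).value for f in truth_flags]
    extra_pred = sorted(set(pred_labels) - set(JOINT_CLASSES))
    extra_truth = sorted(set(truth_labels) - set(JOINT_CLASSES))
    cols = list(JOINT_CLASSES) + extra_pred
    rows = list(JOINT_CLASSES) + extra_truth
    table = pd.DataFrame(0, index=rows, columns=cols, dtype=int)
    for t, p in zip(truth_labels, pred_labels):
        table.at[t, p] += 1
    n = len(pred_labels)
    exact = sum(t == p for t, p in zip(truth_labels, pred_labels))
    return JointConfusion(table=table, accuracy=exact / n, n=n)


def error_taxonomy(
    pred_flags: Sequence[Sequence[bool]],
    truth_flags: Sequence[Sequence[bool]],
) -> dict[str, int]:
    """Partition compounds by how the predicted group set relates to truth.

    exact: P == T; partial: P != T with a common group; missed: T nonempty,
    P empty; spurious: T empty, P nonempty; disjoint: both nonempty, no
    common group.  The five counts always sum to n.
    """
    if len(pred_flags) != len(truth_flags):
        raise ValueError("pred and truth must be equal-length")
    counts = {"exact": 0, "partial": 0, "missed": 0, "spurious": 0, "disjoint": 0}
    for pf, tf in zip(pred_flags, truth_flags):
        p = derive_joint_label(pf).group_set
        t = derive_joint_label(tf).group_set
        if p == t:
            counts["exact"] += 1
        elif t and not p:
            counts["missed"] += 1
        elif p and not t:
            counts["spurious"] += 1
        elif p & t:
            counts["partial"] += 1
        else:
            counts["disjoint"] += 1
    return counts
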