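"""Confusion-matrix metrics, proportion-active summaries, group comparisons.

Sensitivity = TP/(TP+FN), specificity = TN/(TN+FP), accuracy =
(TP+TN)/(TP+TN+FP+FN), counted against lidocaine (or simulated) ground
truth.  Ambiguous neurons are excluded everywhere.  Group-level proportions
of active neurons are compared with an unpaired Student t test
(pooled variance; Welch available), reported as mean ± SEM.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .trace import ACTIVE, INACTIVE, LabelSet

__all__ = [
    "ConfusionCounts",
    "EvaluationReport",
    "confusion",
    "binary_confusion",
    "metrics",
    "proportion_active",
    "compare_groups",
    "GroupComparison",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class EvaluationReport:
    """Core detection metrics; NaN plus a flag marks undefined ratios."""

    sensitivity: float
    specificity: float
    accuracy: float
    counts: ConfusionCounts
    undefined: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "tp": self.counts.tp, "fp": self.counts.fp,
            "tn": self.counts.tn, "fn": self.counts.fn,
            "undefined": list(self.undefined),
        }


def confusion(truth: LabelSet, predicted: LabelSet) -> ConfusionCounts:
    """Count TP/FP/TN/FN over neurons present and unambiguous in both sets.

    TP = truly active predicted active; FP = truly inactive predicted
    active; TN = truly inactive predicted inactive; FN = truly active
    predicted inactive.
    """
    t = truth.unambiguous()
    p = predicted.unambiguous()
    shared = [nid for nid in t if nid in p]
    if not shared:
        raise ValueError("truth and prediction share no unambiguous neurons")
    tp = fp = tn = fn = 0
    for nid in shared:
        truly_active = t[nid] == ACTIVE
        pred_active = p[nid] == ACTIVE
        if truly_active and pred_active:
            tp += 1
        elif truly_active:
            fn += 1
        elif pred_active:
            fp += 1
        else:
            tn += 1
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def binary_confusion(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionCounts:
    """Confusion counts from aligned binary vectors (1 = active)."""
    y_true = np.asarray(y_true).astype(bool)
    y_pred = np.asarray(y_pred).astype(bool)
    if y_true.shape != y_pred.shape:
        raise ValueError("shape mismatch")
    return ConfusionCounts(
        tp=int(np.sum(y_true & y_pred)),
        fp=int(np.sum(~y_true & y_pred)),
        tn=int(np.sum(~y_true & ~y_pred)),
        fn=int(np.sum(y_true & ~y_pred)),
    )


def metrics(counts: ConfusionCounts) -> EvaluationReport:
    """Sensitivity, specificity and accuracy from confusion counts.

    A ratio with a zero denominator is reported as NaN and named in
    ``undefined`` — never silently coerced to 0 or 1.
    """
    if counts.total == 0:
        raise ValueError("cannot compute metrics from all-zero counts")
    undefined: list[str] = []

    def ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            undefined.append(name)
            return math.nan
        return num / den

    sens = ratio(counts.tp, counts.tp + counts.fn, "sensitivity")
    spec = ratio(counts.tn, counts.tn + counts.fp, "specificity")
    acc = (counts.tp + counts.tn) / counts.total
    return EvaluationReport(sensitivity=sens, specificity=spec, accuracy=acc,
                            counts=counts, undefined=undefined)


def proportion_active(labels: LabelSet) -> tuple[float, int, int]:
    """Fraction of unambiguous neurons labeled active: (proportion, n_active,
    n_unambiguous)."""
    unamb = labels.unambiguous()
    if not unamb:
        raise ValueError("no unambiguous neurons to summarize")
    n_active = sum(1 for v in unamb.values() if v == ACTIVE)
    return n_active / len(unamb), n_active, len(unamb)


@dataclass
class GroupComparison:
    t_statistic: float
    p_value: float
    mean_a: float
    sem_a: float
    mean_b: float
    sem_b: float
    n_a: int
    n_b: int
    test: str
    degenerate: bool = False


def _sem(x: np.ndarray) -> float:
    return float(np.std(x, ddof=1) / math.sqrt(len(x))) if len(x) > 1 else math.nan


def compare_groups(group_a, group_b, welch: bool = False) -> GroupComparison:
    """Unpaired two-sample t test on per-recording proportions.

    Default is the Student (pooled-variance) test; ``welch=True`` drops the
    equal-variance assumption.  When both groups have zero variance and
    equal means the comparison is degenerate: t = 0, p = 1, flagged.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 recordings")
    degenerate = False
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
        t_stat, p = 0.0, 1.0
        degenerate = True
    else:
        t_stat, p = stats.ttest_ind(a, b, equal_var=not welch)
        t_stat, p = float(t_stat), float(p)
    return GroupComparison(
        t_statistic=t_stat, p_value=p,
        mean_a=float(np.mean(a)), sem_a=_sem(a),
        mean_b=float(np.mean(b)), sem_b=_sem(b),
        n_a=len(a), n_b=len(b),
        test="welch" if welch else "student",
        degenerate=degenerate,
    )
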