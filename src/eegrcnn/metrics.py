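"""Confusion counting and the sensitivity/specificity/accuracy scores.

Per-class counts are one-vs-rest. The scores are

    Sen = TP / (TP + FN)
    Spe = TN / (TN + FP)
    Acc = (TP + TN) / (TP + FN + TN + FP)

exactly as used in clinical seizure-detection reporting. A zero denominator
makes the corresponding score *undefined*: it is flagged and reported as NaN,
never silently set to 0. For multi-class tasks, Sen/Spe are macro-averaged
one-vs-rest and Acc is the fraction of correctly classified windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion_matrix

from .exceptions import ValidationError


@dataclass(frozen=True)
class ConfusionCounts:
    """One-vs-rest counts for a single positive class."""

    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValidationError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.tn + self.fp


@dataclass(frozen=True)
class Metrics:
    """Sen/Spe/Acc on [0, 1]; undefined scores are NaN and named in ``undefined``."""

    sen: float
    spe: float
    acc: float
    undefined: frozenset[str] = frozenset()

    def as_percent(self) -> tuple[float, float, float]:
        return 100.0 * self.sen, 100.0 * self.spe, 100.0 * self.acc


def compute_metrics(counts: ConfusionCounts) -> Metrics:
    """Score one confusion quadruple; flags undefined ratios."""
    undefined: set[str] = set()
    if counts.tp + counts.fn > 0:
        sen = counts.tp / (counts.tp + counts.fn)
    else:
        sen = float("nan")
        undefined.add("sen")
    if counts.tn + counts.fp > 0:
        spe = counts.tn / (counts.tn + counts.fp)
    else:
        spe = float("nan")
        undefined.add("spe")
    if counts.total > 0:
        acc = (counts.tp + counts.tn) / counts.total
    else:
        acc = float("nan")
        undefined.add("acc")
    return Metrics(sen, spe, acc, frozenset(undefined))


def confusion_matrix(y_true: np.ndarray, y_pred: np.ndarray, n_class: int) -> np.ndarray:
    """Raw confusion matrix, rows = true class, columns = predicted class."""
    return _sk_confusion_matrix(y_true, y_pred, labels=np.arange(n_class))


def counts_from_matrix(cm: np.ndarray, positive: int) -> ConfusionCounts:
    """One-vs-rest counts for class ``positive`` from a confusion matrix."""
    tp = int(cm[positive, positive])
    fn = int(cm[positive].sum() - tp)
    fp = int(cm[:, positive].sum() - tp)
    tn = int(cm.sum() - tp - fn - fp)
    return ConfusionCounts(tp=tp, fn=fn, tn=tn, fp=fp)


#: labels recognized as the "positive" (seizure-side) class of a binary
#: task, in priority order
SEIZURE_LABELS = ("ictal", "epileptic", "seizure", "preictal")


def positive_class_index(class_names) -> int:
    """Index of the seizure-side class for binary scoring.

    Falls back to the second class when no name matches, matching the
    convention that class 1 is the positive one.
    """
    names = [str(c).lower() for c in class_names]
    for label in SEIZURE_LABELS:
        if label in names:
            return names.index(label)
    return min(1, len(names) - 1)


def score_confusion(cm: np.ndarray, positive_class: int | None = None) -> Metrics:
    """Sen/Spe/Acc of a confusion matrix.

    Binary tasks score the designated positive class (default: class 1, the
    seizure class by convention). Multi-class tasks macro-average the
    one-vs-rest Sen/Spe and use overall accuracy.
    """
    cm = np.asarray(cm)
    n = cm.shape[0]
    total = cm.sum()
    if n == 2:
        pos = 1 if positive_class is None else positive_class
        return compute_metrics(counts_from_matrix(cm, pos))
    sens, spes, undefined = [], [], set()
    for k in range(n):
        m = compute_metrics(counts_from_matrix(cm, k))
        sens.append(m.sen)
        spes.append(m.spe)
        undefined |= set(m.undefined)
    acc = float(np.trace(cm) / total) if total > 0 else float("nan")
    if total == 0:
        undefined.add("acc")
    return Metrics(
        float(np.mean(sens)), float(np.mean(spes)), acc, frozenset(undefined)
    )
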