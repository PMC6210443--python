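"""Multi-class evaluation: confusion matrices, OSR, one-vs-rest ROC parameters.

The confusion matrix is oriented predicted-rows x actual-columns with classes
in listed order (2, 3, 7 by default).  The overall success rate (OSR) is the
trace divided by the total number of classified instances — a symmetric
multi-class score in [0, 1].  Per-class ROC point parameters come from the
one-vs-rest binarization of the matrix:

    TP = diagonal cell          FP = rest of the predicted row
    FN = rest of the actual col TN = everything else

    ACC = (TP+TN)/N   TPR = TP/(TP+FN)   TNR = TN/(TN+FP)
    PPV = TP/(TP+FP)  NPV = TN/(TN+FN)

A zero denominator makes the corresponding parameter undefined (NaN), never
silently 0.  Tabulated values are rounded half-up to 4 decimals; aggregate
standard deviations use the sample (n-1) convention.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np

from .io import CLASS_SET, Session


def round_half_up(x: float, places: int = 4) -> float:
    """Decimal half-up rounding, as used in tabulated reports."""
    if not np.isfinite(x):
        return x
    q = Decimal(1).scaleb(-places)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class ConfusionMatrix:
    """K x K counts; rows = predicted class, columns = actual class."""

    counts: np.ndarray
    class_order: tuple[int, ...] = CLASS_SET

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        k = len(self.class_order)
        if self.counts.shape != (k, k):
            raise ValueError(f"expected {k}x{k} counts, got {self.counts.shape}")
        if np.any(self.counts < 0):
            raise ValueError("negative counts")
        if self.counts.sum() == 0:
            raise ValueError("empty confusion matrix")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def index(self, cls: int) -> int:
        try:
            return self.class_order.index(cls)
        except ValueError:
            raise ValueError(f"class {cls} not in {self.class_order}") from None


@dataclass
class BinaryConfusion:
    """One-vs-rest counts for a single class."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class ROCParams:
    """Point ROC parameters of a one-vs-rest binarization."""

    acc: float
    tpr: float
    tnr: float
    ppv: float
    npv: float

    def rounded(self, places: int = 4) -> "ROCParams":
        return ROCParams(*(round_half_up(getattr(self, f.name), places) for f in fields(self)))

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def confusion_matrix(
    predicted: Sequence[int],
    actual: Sequence[int],
    class_order: tuple[int, ...] = CLASS_SET,
) -> ConfusionMatrix:
    """Tally predictions: entry (r, c) counts instances predicted
    class_order[r] whose actual class is class_order[c]."""
    predicted = np.asarray(predicted, dtype=int)
    actual = np.asarray(actual, dtype=int)
    if predicted.shape != actual.shape:
        raise ValueError("predicted and actual label sequences differ in length")
    index = {c: k for k, c in enumerate(class_order)}
    k = len(class_order)
    counts = np.zeros((k, k), dtype=int)
    for p, a in zip(predicted, actual):
        if int(p) not in index or int(a) not in index:
            raise ValueError(f"label outside class order {class_order}: ({p}, {a})")
        counts[index[int(p)], index[int(a)]] += 1
    return ConfusionMatrix(counts, class_order)


def osr(cm: ConfusionMatrix) -> float:
    """Overall success rate: trace / total instances."""
    return float(np.trace(cm.counts)) / cm.total


def binarize_one_vs_rest(cm: ConfusionMatrix, cls: int) -> BinaryConfusion:
    """Collapse the K-class matrix to class-vs-rest counts for ``cls``."""
    i = cm.index(cls)
    tp = int(cm.counts[i, i])
    fp = int(cm.counts[i, :].sum() - tp)
    fn = int(cm.counts[:, i].sum() - tp)
    tn = cm.total - tp - fp - fn
    return BinaryConfusion(tp, fp, fn, tn)


def _ratio(num: int, den: int) -> float:
    return num / den if den > 0 else float("nan")


def roc_params(b: BinaryConfusion) -> ROCParams:
    """ACC/TPR/TNR/PPV/NPV of a binary confusion; undefined ratios are NaN."""
    return ROCParams(
        acc=_ratio(b.tp + b.tn, b.total),
        tpr=_ratio(b.tp, b.tp + b.fn),
        tnr=_ratio(b.tn, b.tn + b.fp),
        ppv=_ratio(b.tp, b.tp + b.fp),
        npv=_ratio(b.tn, b.tn + b.fn),
    )


def aggregate(values: Sequence[float]) -> tuple[float, float]:
    """Arithmetic mean and sample (n-1) standard deviation."""
    arr = np.asarray(values, dtype=float)
    mean = float(arr.mean())
    std = float(arr.std(ddof=1)) if len(arr) >= 2 else float("nan")
    return mean, std


@dataclass
class Effectiveness:
    """Per-frame classification score against a labelled test session."""

    percent: float
    n_scored: int
    n_excluded: int


def effectiveness(
    predicted: Sequence[int], test_session: Session, window: int = 16
) -> Effectiveness:
    """Percent of frames classified correctly against the session's labels.

    One prediction per scored frame; the first ``window - 1`` frames have no
    full preceding window and are excluded (the exclusion count is reported).
    """
    if not test_session.labelled:
        raise ValueError("test session must be labelled")
    predicted = np.asarray(predicted, dtype=int)
    excluded = window - 1
    expected = len(test_session) - excluded
    if len(predicted) != expected:
        raise ValueError(
            f"expected {expected} predictions for {len(test_session)} frames "
            f"with window {window}, got {len(predicted)}"
        )
    actual = test_session.labels[excluded:]
    correct = int(np.sum(predicted == actual))
    return Effectiveness(100.0 * correct / expected, expected, excluded)


def generalization_error(train_accuracy: float, test_accuracy: float) -> float:
    """Training-phase accuracy minus test accuracy, in percentage points."""
    for v in (train_accuracy, test_accuracy):
        if not 0.0 <= v <= 100.0:
            raise ValueError("accuracies must be percentages in [0, 100]")
    return train_accuracy - test_accuracy


def subject_report(cm: ConfusionMatrix) -> dict:
    """Full per-subject evaluation block: matrix, OSR, per-class ROC rows."""
    per_class = {}
    for cls in cm.class_order:
        params = roc_params(binarize_one_vs_rest(cm, cls)).rounded()
        per_class[cls] = params.as_dict()
    return {
        "class_order": list(cm.class_order),
        "confusion_matrix": cm.counts.tolist(),
        "osr": round_half_up(osr(cm)),
        "per_class": per_class,
    }
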