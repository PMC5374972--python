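"""Single- and multi-label performance metrics over the six EC classes.

Single-label evaluation is based on the 6 x 6 confusion matrix C(x, y)
(true class x, predicted class y): overall accuracy is trace / total and
balanced accuracy is the mean per-class recall over the classes present.

Multi-label evaluation treats each enzyme's labels as a subset of {1..6}
encoded as a 6-bit vector and reports, with N enzymes and Delta the
symmetric difference:

* Hamming-loss  = (1/N) sum_i |pred_i Delta true_i| / 6 (and its complement)
* Accuracy      = mean Jaccard similarity |pred & true| / |pred | true|
* Precision / Recall / F1, sample-averaged
* Subset accuracy = fraction of exact label-set matches
* Macro precision/recall/F1 (per-class, then averaged over the 6 classes)
* Micro precision/recall/F1 (from class-summed TP/FP/FN counts)
* Per-class 1-Hamming-loss (per-column binary accuracy)

Zero-denominator conventions: a per-sample precision term with an empty
prediction set contributes 0, and a macro per-class ratio with a zero
denominator contributes 0 to its mean. These cases cannot arise for the
predictors in this package (predictions are never all-zero) but the
conventions keep the metrics total and deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .sequence_similarity import N_CLASSES

__all__ = [
    "ConfusionMatrix",
    "MultiLabelEvalResult",
    "confusion_and_accuracies",
    "multilabel_metrics",
]


@dataclass
class ConfusionMatrix:
    """counts[x-1, y-1] = number of enzymes of true class x predicted as y."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (N_CLASSES, N_CLASSES):
            raise ValueError(f"expected 6x6 counts, got {self.counts.shape}")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def overall_accuracy(self) -> float:
        return float(np.trace(self.counts) / self.total)

    @property
    def balanced_accuracy(self) -> float:
        """Mean per-class recall over classes with at least one true member."""
        row_sums = self.counts.sum(axis=1)
        present = row_sums > 0
        recalls = np.diag(self.counts)[present] / row_sums[present]
        return float(recalls.mean())


def confusion_and_accuracies(
    y_true: np.ndarray, y_pred: np.ndarray
) -> tuple[ConfusionMatrix, float, float]:
    """Confusion matrix plus overall and balanced accuracy for classes 1..6."""
    y_true = np.asarray(y_true, dtype=int).ravel()
    y_pred = np.asarray(y_pred, dtype=int).ravel()
    if y_true.size == 0:
        raise ValueError("empty evaluation input")
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    for arr, name in ((y_true, "y_true"), (y_pred, "y_pred")):
        if arr.min() < 1 or arr.max() > N_CLASSES:
            raise ValueError(f"{name} labels must lie in 1..{N_CLASSES}")
    counts = np.zeros((N_CLASSES, N_CLASSES), dtype=int)
    np.add.at(counts, (y_true - 1, y_pred - 1), 1)
    cm = ConfusionMatrix(counts)
    return cm, cm.overall_accuracy, cm.balanced_accuracy


@dataclass
class MultiLabelEvalResult:
    """The full multi-label metric suite; every scalar lies in [0, 1]."""

    hamming_loss: float
    one_minus_hamming: float
    accuracy: float  # sample-averaged Jaccard
    precision: float
    recall: float
    f1: float
    subset_accuracy: float
    macro_precision: float
    macro_recall: float
    macro_f1: float
    micro_precision: float
    micro_recall: float
    micro_f1: float
    tp: np.ndarray = field(repr=False)
    fp: np.ndarray = field(repr=False)
    fn: np.ndarray = field(repr=False)
    per_class_one_minus_hamming: np.ndarray = field(repr=False)

    def as_dict(self) -> dict[str, float]:
        scalars = (
            "hamming_loss one_minus_hamming accuracy precision recall f1 "
            "subset_accuracy macro_precision macro_recall macro_f1 "
            "micro_precision micro_recall micro_f1"
        ).split()
        return {k: float(getattr(self, k)) for k in scalars}


def _safe_div(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    """Elementwise num/den with 0 where the denominator is 0."""
    num = np.asarray(num, dtype=float)
    den = np.asarray(den, dtype=float)
    out = np.zeros_like(num)
    np.divide(num, den, out=out, where=den > 0)
    return out


def multilabel_metrics(Y_true: np.ndarray, Y_pred: np.ndarray) -> MultiLabelEvalResult:
    """Compute the full multi-label metric suite on (n, 6) binary matrices.

    Raises
    ------
    ValueError
        On shape mismatch, non-binary entries, or a true row without any
        positive label.
    """
    Y_true = np.asarray(Y_true, dtype=int)
    Y_pred = np.asarray(Y_pred, dtype=int)
    if Y_true.shape != Y_pred.shape:
        raise ValueError(f"shape mismatch: {Y_true.shape} vs {Y_pred.shape}")
    if Y_true.ndim != 2 or Y_true.shape[1] != N_CLASSES or len(Y_true) == 0:
        raise ValueError(f"expected non-empty (n, {N_CLASSES}) matrices")
    for Y, name in ((Y_true, "Y_true"), (Y_pred, "Y_pred")):
        if not np.isin(Y, (0, 1)).all():
            raise ValueError(f"{name} must be binary")
    if (Y_true.sum(axis=1) == 0).any():
        raise ValueError("a true label vector has no positive entry")

    n = len(Y_true)
    inter = (Y_true & Y_pred).sum(axis=1)
    union = (Y_true | Y_pred).sum(axis=1)
    sym_diff = (Y_true ^ Y_pred).sum(axis=1)
    n_true = Y_true.sum(axis=1)
    n_pred = Y_pred.sum(axis=1)

    hamming = float(np.mean(sym_diff / N_CLASSES))
    jaccard = float(np.mean(_safe_div(inter, union)))
    precision = float(np.mean(_safe_div(inter, n_pred)))
    recall = float(np.mean(_safe_div(inter, n_true)))
    f1 = float(np.mean(2.0 * _safe_div(inter, n_pred + n_true)))
    subset = float(np.mean(sym_diff == 0))

    tp = (Y_true & Y_pred).sum(axis=0)
    fp = ((1 - Y_true) & Y_pred).sum(axis=0)
    fn = (Y_true & (1 - Y_pred)).sum(axis=0)
    prec_j = _safe_div(tp, tp + fp)
    rec_j = _safe_div(tp, tp + fn)
    macro_precision = float(prec_j.mean())
    macro_recall = float(rec_j.mean())
    macro_f1 = float(np.mean(2.0 * _safe_div(prec_j * rec_j, prec_j + rec_j)))
    micro_precision = float(_safe_div(tp.sum(), tp.sum() + fp.sum()))
    micro_recall = float(_safe_div(tp.sum(), tp.sum() + fn.sum()))
    micro_f1 = float(
        _safe_div(2.0 * micro_precision * micro_recall, micro_precision + micro_recall)
    )
    per_class_omh = 1.0 - (Y_true != Y_pred).mean(axis=0)

    return MultiLabelEvalResult(
        hamming_loss=hamming,
        one_minus_hamming=1.0 - hamming,
        accuracy=jaccard,
        precision=precision,
        recall=recall,
        f1=f1,
        subset_accuracy=subset,
        macro_precision=macro_precision,
        macro_recall=macro_recall,
        macro_f1=macro_f1,
        micro_precision=micro_precision,
        micro_recall=micro_recall,
        micro_f1=micro_f1,
        tp=tp,
        fp=fp,
        fn=fn,
        per_class_one_minus_hamming=per_class_omh,
    )
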