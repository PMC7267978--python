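"""Classification metrics for the decoder, implemented from their defining
formulas.

Per-label tallies follow the one-vs-rest reading in which, for a given label,
TP is the diagonal entry, FP/FN are the off-diagonal column/row sums — and TN
is *the sum of the TPs of the rest of the labels*. That TN convention is the
one the decoder's reference analysis uses; the usual convention (all correct
rejections, i.e. everything outside the label's row and column... plus the
rest of the diagonal) is available behind ``tn_convention="standard"`` and
both are reported in the metrics dict.

F1 = 2TP / (2TP + FP + FN); sensitivity = TP/(TP+FN);
specificity = TN/(TN+FP); accuracy = (TP+TN)/(TP+FP+TN+FN).
Degenerate denominators yield 0 with a warning so fold aggregation never
crashes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ConfusionMatrix", "LabelTally", "RocCurve",
    "confusion_matrix", "tally_label", "f1_score",
    "sensitivity_specificity_accuracy", "roc_one_vs_rest",
    "chance_level", "multiclass_accuracy", "metrics_report",
]


@dataclass
class ConfusionMatrix:
    counts: np.ndarray  # square, (true, predicted)
    labels: list[str]

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=int)
        n = len(self.labels)
        if self.counts.shape != (n, n):
            raise ValueError("confusion matrix must be square and match labels")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def normalized(self) -> np.ndarray:
        """Rows divided by row sums (per-label instance counts)."""
        sums = self.counts.sum(axis=1, keepdims=True).astype(float)
        sums[sums == 0] = 1.0
        return self.counts / sums


@dataclass(frozen=True)
class LabelTally:
    tp: int
    fp: int
    fn: int
    tn: int


@dataclass
class RocCurve:
    fpr: np.ndarray  # 1 - specificity, non-decreasing
    tpr: np.ndarray  # sensitivity, non-decreasing
    auc: float


def confusion_matrix(y_true, y_pred, labels=None) -> ConfusionMatrix:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if labels is None:
        labels = sorted(set(y_true.tolist()) | set(y_pred.tolist()))
    index = {l: i for i, l in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=int)
    for t, p in zip(y_true, y_pred):
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts, [str(l) for l in labels])


def tally_label(cm: ConfusionMatrix, label, tn_convention: str = "tp_rest") -> LabelTally:
    """Per-label TP/FP/FN/TN from a confusion matrix.

    ``tn_convention="tp_rest"`` defines TN as the summed TPs of the other
    labels; ``"standard"`` counts every sample that is neither in the label's
    row nor its column.
    """
    label = str(label)
    if label not in cm.labels:
        raise KeyError(f"unknown label {label!r}")
    i = cm.labels.index(label)
    tp = int(cm.counts[i, i])
    fp = int(cm.counts[:, i].sum() - tp)
    fn = int(cm.counts[i, :].sum() - tp)
    if tn_convention == "tp_rest":
        tn = int(np.trace(cm.counts) - tp)
    elif tn_convention == "standard":
        tn = int(cm.total - tp - fp - fn)
    else:
        raise ValueError(f"unknown tn_convention {tn_convention!r}")
    return LabelTally(tp=tp, fp=fp, fn=fn, tn=tn)


def _safe_div(num, den, what):
    if den == 0:
        warnings.warn(f"degenerate denominator in {what}; returning 0", stacklevel=3)
        return 0.0
    return num / den


def f1_score(t: LabelTally) -> float:
    return _safe_div(2 * t.tp, 2 * t.tp + t.fp + t.fn, "F1")


def sensitivity_specificity_accuracy(t: LabelTally) -> tuple[float, float, float]:
    sens = _safe_div(t.tp, t.tp + t.fn, "sensitivity")
    spec = _safe_div(t.tn, t.tn + t.fp, "specificity")
    acc = _safe_div(t.tp + t.tn, t.tp + t.fp + t.tn + t.fn, "accuracy")
    return sens, spec, acc


def multiclass_accuracy(cm: ConfusionMatrix) -> float:
    return _safe_div(int(np.trace(cm.counts)), cm.total, "accuracy")


def chance_level(n_classes: int) -> float:
    """Chance accuracy in percent, to two decimals (e.g. 7 classes -> 14.29)."""
    if n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    return round(100.0 / n_classes, 2)


def roc_one_vs_rest(scores: np.ndarray, y_true, target_label) -> RocCurve:
    """One-vs-rest ROC over the target class's score column.

    ``scores`` is (n_samples, n_classes) (or a 1-D score vector for the
    target class). Tied scores are grouped — the curve moves through each
    distinct threshold once — making the trapezoidal AUC equal the
    Mann-Whitney U statistic / (n_pos * n_neg) with the midpoint tie rule.
    """
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=float)
    if scores.ndim == 2:
        s = scores[:, int(target_label)]
    else:
        s = scores
    pos = y_true == target_label
    n_pos = int(pos.sum())
    n_neg = int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs at least one positive and one negative sample")
    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    pos_sorted = pos[order]
    # group ties: cumulative counts at each distinct-threshold boundary
    distinct = np.r_[np.nonzero(np.diff(s_sorted))[0], len(s_sorted) - 1]
    tp_cum = np.cumsum(pos_sorted)[distinct]
    fp_cum = np.cumsum(~pos_sorted)[distinct]
    tpr = np.r_[0.0, tp_cum / n_pos]
    fpr = np.r_[0.0, fp_cum / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(fpr=fpr, tpr=tpr, auc=auc)


def metrics_report(y_true, y_pred, scores=None, labels=None) -> dict:
    """Full per-label report: F1, sensitivity, specificity, accuracy (under
    both TN conventions) and one-vs-rest AUC when scores are given."""
    cm = confusion_matrix(y_true, y_pred, labels=labels)
    report = {
        "labels": cm.labels,
        "confusion": cm.counts.tolist(),
        "confusion_normalized": cm.normalized().tolist(),
        "accuracy": multiclass_accuracy(cm),
        "chance_level_percent": chance_level(len(cm.labels)),
        "per_label": {},
    }
    for i, lab in enumerate(cm.labels):
        t = tally_label(cm, lab)
        t_std = tally_label(cm, lab, tn_convention="standard")
        sens, spec, acc = sensitivity_specificity_accuracy(t)
        sens_s, spec_s, acc_s = sensitivity_specificity_accuracy(t_std)
        entry = {
            "f1": f1_score(t),
            "sensitivity": sens,
            "specificity": spec,
            "accuracy": acc,
            "specificity_standard_tn": spec_s,
            "accuracy_standard_tn": acc_s,
        }
        if scores is not None:
            index = {l: j for j, l in enumerate(cm.labels)}
            y_idx = np.array([index[str(t)] for t in np.asarray(y_true)])
            entry["auc"] = roc_one_vs_rest(np.asarray(scores), y_idx, i).auc
        report["per_label"][lab] = entry
    return report
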