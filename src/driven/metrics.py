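"""Evaluation metrics: window-level classification scores, threshold-free
curves, and the patient-level four-class severity agreement."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

SEVERITY_ORDER = ("healthy", "mild", "moderate", "severe")


@dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @classmethod
    def from_predictions(cls, y_true, y_pred) -> "ConfusionCounts":
        t = np.asarray(y_true).astype(bool)
        p = np.asarray(y_pred).astype(bool)
        return cls(
            tp=int((t & p).sum()),
            tn=int((~t & ~p).sum()),
            fp=int((~t & p).sum()),
            fn=int((t & ~p).sum()),
        )


def _ratio(num: float, den: float, flags: list[str], name: str) -> float:
    if den == 0:
        flags.append(name)
        return 0.0
    return num / den


def binary_metrics(counts: ConfusionCounts) -> dict:
    """Accuracy, recall, specificity, precision and F1 from counts.

    Ratios with a zero denominator are reported as 0 and listed under
    ``undefined``.
    """
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    flags: list[str] = []
    precision = _ratio(tp, tp + fp, flags, "precision")
    recall = _ratio(tp, tp + fn, flags, "recall")
    return {
        "accuracy": _ratio(tp + tn, tp + tn + fp + fn, flags, "accuracy"),
        "recall": recall,
        "specificity": _ratio(tn, tn + fp, flags, "specificity"),
        "precision": precision,
        "f1": _ratio(2 * precision * recall, precision + recall, flags, "f1"),
        "undefined": flags,
    }


def _check_two_classes(labels: np.ndarray):
    if labels.min() == labels.max():
        raise ValueError("both classes must be present")


def roc_auc(scores, labels) -> float:
    """AUROC via the rank (Mann-Whitney) statistic; ties count half."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    _check_two_classes(y)
    order = np.argsort(s, kind="mergesort")
    ranks = np.empty(len(s))
    sorted_s = s[order]
    # midranks for ties
    i = 0
    while i < len(s):
        j = i
        while j + 1 < len(s) and sorted_s[j + 1] == sorted_s[i]:
            j += 1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def pr_auc(scores, labels) -> float:
    """Area under the precision-recall curve by step-wise integration.

    Sum over thresholds of precision x recall increment (no linear
    interpolation between operating points, which would be optimistic).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    _check_two_classes(y)
    order = np.argsort(-s, kind="mergesort")
    y_sorted = y[order]
    s_sorted = s[order]
    tp = np.cumsum(y_sorted)
    n = np.arange(1, len(y) + 1)
    # evaluate only at distinct-threshold boundaries
    boundary = np.concatenate([s_sorted[1:] != s_sorted[:-1], [True]])
    precision = tp[boundary] / n[boundary]
    recall = tp[boundary] / y.sum()
    prev_recall = np.concatenate([[0.0], recall[:-1]])
    return float(np.sum((recall - prev_recall) * precision))


def curve_points(scores, labels) -> dict:
    """Threshold sweep: (threshold, precision, recall, TPR, FPR) arrays."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    _check_two_classes(y)
    thresholds = np.unique(s)[::-1]
    rows = []
    p_total, n_total = y.sum(), len(y) - y.sum()
    for thr in thresholds:
        pred = s >= thr
        tp = int((pred & (y == 1)).sum())
        fp = int((pred & (y == 0)).sum())
        prec = tp / max(tp + fp, 1)
        rows.append((thr, prec, tp / p_total, tp / p_total, fp / n_total))
    arr = np.array(rows)
    return {
        "threshold": arr[:, 0],
        "precision": arr[:, 1],
        "recall": arr[:, 2],
        "tpr": arr[:, 3],
        "fpr": arr[:, 4],
    }


def f1_ahi(true_classes, predicted_classes) -> dict:
    """Macro F1 over the four severity classes plus agreement statistics.

    Reports per-class one-vs-rest F1, their unweighted mean, the 4x4
    confusion matrix, the exact-agreement fraction and the fraction of
    patients classified within one class of the truth (classes ordered
    healthy < mild < moderate < severe).
    """
    idx = {c: i for i, c in enumerate(SEVERITY_ORDER)}
    t = [idx[c] if c in idx else -1 for c in true_classes]
    p = [idx[c] if c in idx else -1 for c in predicted_classes]
    if -1 in t or -1 in p:
        raise ValueError(f"labels must come from {SEVERITY_ORDER}")
    t = np.asarray(t)
    p = np.asarray(p)
    confusion = np.zeros((4, 4), dtype=int)
    for a, b in zip(t, p):
        confusion[a, b] += 1
    per_class = {}
    present = set(t) | set(p)
    for c, name in enumerate(SEVERITY_ORDER):
        m = binary_metrics(ConfusionCounts.from_predictions(t == c, p == c))
        per_class[name] = m["f1"]
    macro = float(np.mean([per_class[SEVERITY_ORDER[c]] for c in sorted(present)]))
    return {
        "per_class_f1": per_class,
        "macro_f1": macro,
        "confusion": confusion,
        "exact_agreement": float(np.mean(t == p)),
        "within_one_class": float(np.mean(np.abs(t - p) <= 1)),
    }
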