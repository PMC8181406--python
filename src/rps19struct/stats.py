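"""Group-comparison statistics and classifier performance metrics.

The disease/neutral group comparisons use the one-tailed Mann-Whitney U test:
exact-enumeration p-values for small tie-free samples (min(n) <= 8), and the
normal approximation with tie and continuity corrections otherwise.
Classifier performance is summarized by accuracy, F1, Matthews correlation
coefficient (MCC, the model-selection objective) and false-positive rate.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "GroupComparison",
    "ConfusionMetrics",
    "mann_whitney_one_tailed",
    "confusion_metrics",
]


@dataclass
class GroupComparison:
    median_a: float
    median_b: float
    u_statistic: float
    p_value: float
    n_a: int
    n_b: int
    alternative: str
    method: str


def _has_ties(x, y) -> bool:
    pooled = list(x) + list(y)
    return len(set(pooled)) < len(pooled)


def mann_whitney_one_tailed(x, y, alternative: str = "less") -> GroupComparison:
    """One-tailed Mann-Whitney U test of sample x against sample y.

    ``alternative="less"`` tests whether x is stochastically smaller than y.
    Exact enumeration is used when the smaller sample has at most 8 values and
    there are no ties; otherwise the normal approximation with tie correction
    and continuity correction.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if alternative not in ("less", "greater"):
        raise ValueError("alternative must be 'less' or 'greater'")
    exact = min(x.size, y.size) <= 8 and not _has_ties(x, y)
    method = "exact" if exact else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative=alternative, method=method,
                           use_continuity=True)
    return GroupComparison(
        median_a=float(np.median(x)),
        median_b=float(np.median(y)),
        u_statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n_a=int(x.size),
        n_b=int(y.size),
        alternative=alternative,
        method=method,
    )


@dataclass
class ConfusionMetrics:
    tp: int
    fp: int
    tn: int
    fn: int
    acc: float
    f1: float
    mcc: float
    fpr: float


def confusion_metrics(tp: int, fp: int, tn: int, fn: int) -> ConfusionMetrics:
    """Standard binary-classification metrics from a confusion matrix.

    MCC is defined as 0 when any marginal is empty; FPR = fp / (fp + tn).
    """
    if min(tp, fp, tn, fn) < 0:
        raise ValueError("confusion counts must be non-negative")
    total = tp + fp + tn + fn
    if total == 0:
        raise ValueError("empty confusion matrix")
    acc = (tp + tn) / total
    f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) > 0 else 0.0
    denom = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = ((tp * tn - fp * fn) / denom) if denom > 0 else 0.0
    fpr = fp / (fp + tn) if (fp + tn) > 0 else 0.0
    return ConfusionMetrics(tp=tp, fp=fp, tn=tn, fn=fn, acc=acc, f1=f1,
                            mcc=mcc, fpr=fpr)
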