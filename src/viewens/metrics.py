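"""Screening metrics, ROC/AUC, the NPV-constrained operating point, and the
exact Wilcoxon signed-ranks test.

Conventions.  Abnormal is the positive class: Se = TP/(TP+FN) over
abnormals, Sp = TN/(TN+FP) over normals, GMean = sqrt(Sp*Se), NPV =
TN/(TN+FN).  The ROC curve uses the screening convention TPR = Sp on the
vertical axis and FPR = 1 - Se on the horizontal axis: the "rate of
normals passed through" against the "rate of abnormals missed".  The
area under that curve equals the conventional AUC (the curve is the
standard one reflected through both axes).

The NPV-constrained point answers: among all thresholds whose NPV is at
least the target (95% by default — at most 5% of records called normal
are actually abnormal), how many normals can be filtered out?  When no
threshold qualifies the sentinel (0, 0) is returned.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "PairedTestResult",
    "confusion",
    "basic_metrics",
    "evaluate",
    "roc_curve_auc",
    "tpr_at_npv",
    "wilcoxon_exact",
    "summarize",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricsReport:
    """Screening metrics as fractions; fields with empty denominators are NaN."""

    sp: float
    se: float
    gmean: float
    acc: float
    npv: float
    auc: float = float("nan")
    tpr_at_npv: float = float("nan")
    fpr_at_npv: float = float("nan")
    threshold_used: float = 0.5
    npv_target: float = 0.95

    def to_dict(self, percent: bool = False) -> dict:
        d = self.__dict__.copy()
        if percent:
            for k in ("sp", "se", "gmean", "acc", "npv", "tpr_at_npv", "fpr_at_npv"):
                d[k] = round(d[k] * 100, 2) if math.isfinite(d[k]) else d[k]
        return d


@dataclass(frozen=True)
class PairedTestResult:
    n_effective: int
    w_statistic: float
    p_two_sided: float


def _check_labels_probs(labels, probs):
    labels = np.asarray(labels, dtype=int)
    probs = np.asarray(probs, dtype=float)
    if labels.size == 0:
        raise ValueError("empty input")
    if labels.shape != probs.shape:
        raise ValueError("labels and probs must have equal length")
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be 0 (normal) or 1 (abnormal)")
    return labels, probs


def confusion(labels, probs, threshold: float = 0.5) -> ConfusionCounts:
    """Counts with the abnormal call made when prob >= threshold."""
    labels, probs = _check_labels_probs(labels, probs)
    pred = (probs >= threshold).astype(int)
    return ConfusionCounts(
        tp=int(np.sum((pred == 1) & (labels == 1))),
        tn=int(np.sum((pred == 0) & (labels == 0))),
        fp=int(np.sum((pred == 1) & (labels == 0))),
        fn=int(np.sum((pred == 0) & (labels == 1))),
    )


def _ratio(num: int, den: int) -> float:
    return num / den if den > 0 else float("nan")


def basic_metrics(c: ConfusionCounts, threshold: float = 0.5) -> MetricsReport:
    """Sp, Se, GMean, Acc and NPV from a confusion table."""
    if c.total == 0:
        raise ValueError("cannot compute metrics from all-zero counts")
    sp = _ratio(c.tn, c.tn + c.fp)
    se = _ratio(c.tp, c.tp + c.fn)
    gmean = math.sqrt(sp * se) if math.isfinite(sp) and math.isfinite(se) else float("nan")
    acc = (c.tp + c.tn) / c.total
    npv = _ratio(c.tn, c.tn + c.fn)
    return MetricsReport(sp=sp, se=se, gmean=gmean, acc=acc, npv=npv, threshold_used=threshold)


def roc_curve_auc(labels, probs) -> tuple[np.ndarray, float]:
    """ROC points (FPR = 1-Se, TPR = Sp) over all distinct thresholds.

    The returned array has rows (fpr, tpr, threshold) from (0, 0) to
    (1, 1); thresholds at the endpoints are +inf / -inf.  AUC is the
    trapezoidal area, identical to the conventional definition.
    """
    labels, probs = _check_labels_probs(labels, probs)
    if labels.min() == labels.max():
        raise ValueError("ROC needs both classes present")
    n_pos = int(labels.sum())          # abnormals
    n_neg = labels.size - n_pos        # normals
    order = np.argsort(probs, kind="stable")  # ascending: low score = normal call
    sorted_labels = labels[order]
    sorted_probs = probs[order]
    # the abnormal call is prob >= t; records strictly below t are "normal"
    distinct, first_idx = np.unique(sorted_probs, return_index=True)
    cum_neg = np.cumsum(sorted_labels == 0)
    cum_pos = np.cumsum(sorted_labels == 1)
    rows = [(0.0, 0.0, float("-inf"))]  # t = -inf: everything called abnormal
    for t, i in zip(distinct, first_idx):
        below = i  # count of records with score strictly below t
        tn = int(cum_neg[below - 1]) if below > 0 else 0
        fn = int(cum_pos[below - 1]) if below > 0 else 0
        rows.append((fn / n_pos, tn / n_neg, float(t)))  # (1-Se, Sp)
    rows.append((1.0, 1.0, float("inf")))  # t = +inf: everything called normal
    curve = np.asarray(rows)
    auc = float(np.trapezoid(curve[:, 1], curve[:, 0]))
    return curve, auc


def tpr_at_npv(labels, probs, npv_target: float = 0.95) -> tuple[float, float]:
    """Best screening pass-through rate at a guaranteed miss bound.

    Sweeps every distinct threshold; among operating points with
    NPV >= npv_target returns the one maximizing TPR (= Sp) together
    with its FPR (= 1 - Se).  Returns the sentinel (0, 0) when the NPV
    constraint cannot be met at any threshold.
    """
    labels, probs = _check_labels_probs(labels, probs)
    if not (0 < npv_target < 1):
        raise ValueError("npv_target must lie strictly between 0 and 1")
    if labels.min() == labels.max():
        raise ValueError("needs both classes present")
    best = None
    thresholds = np.unique(probs)
    for t in list(thresholds) + [float(np.max(probs)) + 1.0]:
        c = confusion(labels, probs, threshold=t)
        if c.tn + c.fn == 0:
            continue
        npv = c.tn / (c.tn + c.fn)
        if npv >= npv_target:
            tpr = _ratio(c.tn, c.tn + c.fp)   # Sp
            fpr = _ratio(c.fn, c.fn + c.tp)   # 1 - Se
            if best is None or tpr > best[0]:
                best = (tpr, fpr)
    return best if best is not None else (0.0, 0.0)


def _exact_signed_rank_distribution(ranks: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Distribution of the positive-rank sum over all 2^n sign assignments.

    Ranks may be midranks (half-integers); they are doubled to integers
    and the distribution is built by dynamic programming (polynomial
    convolution), so n up to ~20 is instant.  Returns (support, counts)
    on the doubled scale.
    """
    doubled = np.rint(ranks * 2).astype(int)
    total = int(doubled.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in doubled:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    return np.arange(total + 1), counts


def wilcoxon_exact(x, y) -> PairedTestResult:
    """Two-sided exact Wilcoxon signed-ranks test on paired values.

    Differences d = y - x; zero differences are dropped; |d| are ranked
    with midranks for ties; W = min(positive-rank sum, negative-rank
    sum); the two-sided p enumerates all 2^n sign assignments of the
    realized (mid)ranks.  All differences zero gives p = 1, n = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    if x.size > 20:
        raise ValueError("exact enumeration is limited to n <= 20 pairs")
    d = y - x
    d = d[d != 0]
    n = d.size
    if n == 0:
        return PairedTestResult(0, 0.0, 1.0)
    from scipy.stats import rankdata

    ranks = rankdata(np.abs(d))  # midranks for ties
    w_pos = float(ranks[d > 0].sum())
    w_neg = float(ranks[d < 0].sum())
    w = min(w_pos, w_neg)
    support, counts = _exact_signed_rank_distribution(ranks)
    total_sum = support[-1]
    w2 = int(round(w * 2))
    # two-sided: P(W+ <= w) + P(W+ >= total - w), exact under H0 symmetry
    p = (counts[: w2 + 1].sum() + counts[total_sum - w2 :].sum()) / counts.sum()
    return PairedTestResult(n, w, min(1.0, float(p)))


def summarize(values) -> tuple[float, float]:
    """Arithmetic mean and sample standard deviation (n-1 denominator)."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot summarize an empty list")
    mean = float(values.mean())
    sd = float(values.std(ddof=1)) if values.size >= 2 else float("nan")
    return mean, sd


def evaluate(
    labels, probs, threshold: float = 0.5, npv_target: float = 0.95
) -> MetricsReport:
    """Full report: thresholded metrics plus AUC and the NPV-constrained point."""
    rep = basic_metrics(confusion(labels, probs, threshold), threshold)
    labels_arr = np.asarray(labels)
    if labels_arr.min() != labels_arr.max():
        _, rep.auc = roc_curve_auc(labels, probs)
        rep.tpr_at_npv, rep.fpr_at_npv = tpr_at_npv(labels, probs, npv_target)
    rep.npv_target = npv_target
    return rep
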