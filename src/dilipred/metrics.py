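"""Confusion-matrix performance metrics and the V model-selection score.

Every metric is computed from raw TP/TN/FP/FN counts.  The V score,

    V = (MCC + c) * specificity,        c = 0.05 by default,

is the selection statistic used to rank hyperparameter combinations during
Monte Carlo cross-validation: multiplying by specificity penalises the
majority-class ("everything is hepatotoxic") solutions that plain MCC or
accuracy tolerate on a positive-heavy drug panel.

AUC is computed as the Mann-Whitney rank statistic -- the fraction of
(positive, negative) score pairs ranked correctly, ties counted 1/2 -- which
is exactly the area under the empirical ROC curve and is invariant to any
monotone transform of the scores.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields

import numpy as np
from scipy.stats import rankdata

from .exceptions import UndefinedMetricError

#: Default additive constant c of the V score.
V_ADDITIVE_CONSTANT = 0.05

METRIC_NAMES = (
    "auc",
    "mcc",
    "f1",
    "cohens_kappa",
    "accuracy",
    "balanced_accuracy",
    "sensitivity",
    "specificity",
)


@dataclass(frozen=True)
class ConfusionCounts:
    """True/false positive/negative counts of a binary prediction."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if int(v) != v or v < 0:
                raise ValueError(f"{f.name} must be a non-negative integer, got {v!r}")
            object.__setattr__(self, f.name, int(v))

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricsReport:
    """One row of performance metrics for a single evaluated model/split."""

    auc: float
    mcc: float
    f1: float
    cohens_kappa: float
    accuracy: float
    balanced_accuracy: float
    sensitivity: float
    specificity: float
    v_score: float
    counts: ConfusionCounts | None = field(default=None, compare=False)

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in METRIC_NAMES + ("v_score",)}


def confusion(true_labels, predicted_labels) -> ConfusionCounts:
    """Tally TP/TN/FP/FN from two equal-length binary vectors."""
    y = np.asarray(true_labels)
    p = np.asarray(predicted_labels)
    if y.shape != p.shape or y.ndim != 1:
        raise ValueError(f"label vectors must be 1-d and equal length, got {y.shape} vs {p.shape}")
    for name, v in (("true", y), ("predicted", p)):
        if not np.isin(v, (0, 1)).all():
            bad = v[~np.isin(v, (0, 1))][:5]
            raise ValueError(f"{name} labels must be binary 0/1, found {bad.tolist()}")
    y = y.astype(int)
    p = p.astype(int)
    return ConfusionCounts(
        tp=int(((y == 1) & (p == 1)).sum()),
        tn=int(((y == 0) & (p == 0)).sum()),
        fp=int(((y == 0) & (p == 1)).sum()),
        fn=int(((y == 1) & (p == 0)).sum()),
    )


def _ratio(num: float, den: float) -> float:
    """num/den with the zero-denominator convention: undefined -> 0."""
    return num / den if den != 0 else 0.0


def sensitivity(c: ConfusionCounts) -> float:
    return _ratio(c.tp, c.tp + c.fn)


def specificity(c: ConfusionCounts) -> float:
    return _ratio(c.tn, c.tn + c.fp)


def accuracy(c: ConfusionCounts) -> float:
    return _ratio(c.tp + c.tn, c.total)


def balanced_accuracy(c: ConfusionCounts) -> float:
    return (sensitivity(c) + specificity(c)) / 2.0


def f1(c: ConfusionCounts) -> float:
    return _ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn)


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient; 0 when any marginal is empty."""
    den = (
        (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    if den == 0:
        return 0.0
    return (c.tp * c.tn - c.fp * c.fn) / math.sqrt(den)


def cohens_kappa(c: ConfusionCounts) -> float:
    """Cohen's kappa (P(o) - P(e)) / (1 - P(e)); 0 when P(e) = 1."""
    n = c.total
    if n == 0:
        return 0.0
    p_o = (c.tp + c.tn) / n
    p_e = ((c.tp + c.fp) * (c.tp + c.fn) + (c.fn + c.tn) * (c.fp + c.tn)) / (n * n)
    if p_e == 1.0:
        return 0.0
    return (p_o - p_e) / (1.0 - p_e)


def v_from_components(mcc_value: float, specificity_value: float,
                      additive_constant: float = V_ADDITIVE_CONSTANT) -> float:
    """V = (MCC + c) * specificity from already-computed components."""
    return (mcc_value + additive_constant) * specificity_value


def v_score(c: ConfusionCounts, additive_constant: float = V_ADDITIVE_CONSTANT) -> float:
    """The V selection score of a confusion table."""
    return v_from_components(mcc(c), specificity(c), additive_constant)


def roc_auc(true_labels, scores) -> float:
    """Area under the ROC curve via the Mann-Whitney rank statistic.

    Equals the fraction of (positive, negative) pairs with score_pos >
    score_neg, counting ties as 1/2.  Raises if only one class is present.
    """
    y = np.asarray(true_labels)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape or y.ndim != 1:
        raise ValueError("labels and scores must be 1-d and equal length")
    if not np.isin(y, (0, 1)).all():
        raise ValueError("true labels must be binary 0/1")
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError(
            f"AUC undefined: {n_pos} positives and {n_neg} negatives in truth"
        )
    ranks = rankdata(s)
    rank_sum_pos = ranks[y == 1].sum()
    return float((rank_sum_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def compute_metrics(c: ConfusionCounts, auc: float = float("nan"),
                    additive_constant: float = V_ADDITIVE_CONSTANT) -> MetricsReport:
    """Evaluate every confusion-based metric; AUC is supplied by the caller
    (it needs continuous scores, not thresholded labels)."""
    if c.total == 0:
        raise ValueError("cannot compute metrics of an empty confusion table")
    return MetricsReport(
        auc=float(auc),
        mcc=mcc(c),
        f1=f1(c),
        cohens_kappa=cohens_kappa(c),
        accuracy=accuracy(c),
        balanced_accuracy=balanced_accuracy(c),
        sensitivity=sensitivity(c),
        specificity=specificity(c),
        v_score=v_score(c, additive_constant),
        counts=c,
    )


def evaluate_predictions(true_labels, scores, threshold: float = 0.5,
                         additive_constant: float = V_ADDITIVE_CONSTANT) -> MetricsReport:
    """Full report from continuous scores: threshold, tally, compute, add AUC."""
    from .classifiers import classify  # local import to avoid a cycle

    labels = classify(scores, threshold=threshold)
    c = confusion(true_labels, labels)
    return compute_metrics(c, auc=roc_auc(true_labels, scores),
                           additive_constant=additive_constant)
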