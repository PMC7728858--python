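"""Confusion-based metrics, the V score and rank-based AUC against
independent oracles (exact rational transcription, exhaustive pair counting,
and sklearn)."""

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import cohen_kappa_score, matthews_corrcoef, roc_auc_score

from dilipred import metrics as M
from dilipred.exceptions import UndefinedMetricError


# ----------------------------------------------------------------------
# Exact-rational transcription of the metric formulas (test-side oracle)
# ----------------------------------------------------------------------

def rational_metrics(tp, tn, fp, fn):
    tp, tn, fp, fn = (Fraction(v) for v in (tp, tn, fp, fn))
    n = tp + tn + fp + fn
    out = {}
    den = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    # numerator/denominator kept exact; the final square root is the only float
    out["mcc"] = 0.0 if den == 0 else float(tp * tn - fp * fn) / float(den) ** 0.5
    out["f1"] = 0.0 if 2 * tp + fp + fn == 0 else float(2 * tp / (2 * tp + fp + fn))
    out["accuracy"] = float((tp + tn) / n)
    sens = Fraction(0) if tp + fn == 0 else tp / (tp + fn)
    spec = Fraction(0) if tn + fp == 0 else tn / (tn + fp)
    out["sensitivity"] = float(sens)
    out["specificity"] = float(spec)
    out["balanced_accuracy"] = float((sens + spec) / 2)
    p_o = (tp + tn) / n
    p_e = ((tp + fp) * (tp + fn) + (fn + tn) * (fp + tn)) / (n * n)
    out["cohens_kappa"] = 0.0 if p_e == 1 else float((p_o - p_e) / (1 - p_e))
    return out


def pair_count_auc(y, scores):
    """Exhaustive (positive, negative) pair enumeration with half-ties."""
    pos = [s for s, t in zip(scores, y) if t == 1]
    neg = [s for s, t in zip(scores, y) if t == 0]
    wins = sum(1.0 if p > q else 0.5 if p == q else 0.0 for p in pos for q in neg)
    return wins / (len(pos) * len(neg))


counts_strategy = st.tuples(
    st.integers(0, 500), st.integers(0, 500), st.integers(0, 500), st.integers(0, 500)
).filter(lambda t: sum(t) > 0)


@settings(max_examples=1000, deadline=None, derandomize=True)
@given(counts_strategy)
def test_metrics_match_exact_rational_transcription(counts):
    tp, tn, fp, fn = counts
    c = M.ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)
    rep = M.compute_metrics(c)
    expected = rational_metrics(tp, tn, fp, fn)
    for name, val in expected.items():
        assert getattr(rep, name) == pytest.approx(val, abs=1e-12), name
    assert rep.v_score == pytest.approx((expected["mcc"] + 0.05) * expected["specificity"])


@settings(max_examples=300, deadline=None, derandomize=True)
@given(counts_strategy.filter(lambda t: t[0] + t[3] > 0 and t[1] + t[2] > 0))
def test_mcc_and_kappa_agree_with_sklearn(counts):
    tp, tn, fp, fn = counts
    y = [1] * (tp + fn) + [0] * (tn + fp)
    p = [1] * tp + [0] * fn + [0] * tn + [1] * fp
    c = M.confusion(y, p)
    assert M.mcc(c) == pytest.approx(matthews_corrcoef(y, p), abs=1e-12)
    assert M.cohens_kappa(c) == pytest.approx(cohen_kappa_score(y, p), abs=1e-12)


def test_confusion_tally_examples():
    assert M.confusion((1, 1, 0, 0), (1, 1, 0, 0)) == M.ConfusionCounts(2, 2, 0, 0)
    assert M.confusion((1, 0), (0, 1)) == M.ConfusionCounts(tp=0, tn=0, fp=1, fn=1)


def test_confusion_matches_bruteforce_tally_on_random_vectors():
    rng = np.random.default_rng(0)
    y = rng.integers(0, 2, 100)
    p = rng.integers(0, 2, 100)
    c = M.confusion(y, p)
    tally = {"tp": 0, "tn": 0, "fp": 0, "fn": 0}
    for t, q in zip(y, p):
        tally[{(1, 1): "tp", (0, 0): "tn", (0, 1): "fp", (1, 0): "fn"}[(t, q)]] += 1
    assert (c.tp, c.tn, c.fp, c.fn) == tuple(tally.values())


def test_confusion_rejects_non_binary():
    with pytest.raises(ValueError, match="binary"):
        M.confusion((1, 2), (0, 1))


def test_balanced_accuracy_reproduces_printed_rounding():
    """sens 0.851 / spec 0.630 average to 0.7405, printing as 0.741."""
    ba = (0.851 + 0.630) / 2
    assert ba == pytest.approx(0.7405)
    assert round(ba + 1e-12, 3) == 0.741  # half-up at the printed precision


def test_perfect_classifier_metrics():
    rep = M.compute_metrics(M.ConfusionCounts(tp=5, tn=5, fp=0, fn=0))
    for m in ("mcc", "f1", "cohens_kappa", "accuracy", "balanced_accuracy"):
        assert getattr(rep, m) == 1.0


def test_all_positive_predictor_on_validation_class_sizes():
    rep = M.compute_metrics(M.ConfusionCounts(tp=714, fp=486, tn=0, fn=0))
    assert rep.sensitivity == 1.0
    assert rep.specificity == 0.0
    assert rep.balanced_accuracy == 0.5
    assert rep.accuracy == pytest.approx(714 / 1200)
    assert rep.mcc == 0.0  # zero-denominator convention


def test_v_score_identity_and_examples():
    assert M.v_from_components(0.422, 0.625) == pytest.approx(0.295, abs=5e-4)
    perfect = M.ConfusionCounts(tp=5, tn=5, fp=0, fn=0)
    assert M.v_score(perfect) == pytest.approx(1.05)
    no_spec = M.ConfusionCounts(tp=3, tn=0, fp=2, fn=1)
    assert M.v_score(no_spec) == 0.0  # specificity 0 kills any MCC


@settings(max_examples=200, deadline=None, derandomize=True)
@given(counts_strategy, st.floats(0.0, 1.0))
def test_v_score_is_shifted_mcc_times_specificity(counts, k):
    c = M.ConfusionCounts(*counts)
    assert M.v_score(c, k) == pytest.approx((M.mcc(c) + k) * M.specificity(c))


@settings(max_examples=400, deadline=None, derandomize=True)
@given(
    st.lists(st.tuples(st.integers(0, 1), st.integers(0, 5)), min_size=2, max_size=12)
    .filter(lambda rows: {t for t, _ in rows} == {0, 1})
)
def test_auc_matches_exhaustive_pair_counting(rows):
    y = [t for t, _ in rows]
    scores = [s / 5 for _, s in rows]  # coarse grid forces ties
    assert M.roc_auc(y, scores) == pytest.approx(pair_count_auc(y, scores), abs=1e-12)


def test_auc_examples_and_sklearn_agreement():
    assert M.roc_auc((1, 0, 1, 0), (0.9, 0.8, 0.7, 0.1)) == pytest.approx(0.75)
    assert M.roc_auc((0, 0, 1, 1), (0.1, 0.2, 0.8, 0.9)) == 1.0
    assert M.roc_auc((0, 1, 0, 1), (0.4, 0.4, 0.4, 0.4)) == 0.5  # all ties
    rng = np.random.default_rng(3)
    y = rng.integers(0, 2, 50)
    s = rng.random(50).round(1)
    assert M.roc_auc(y, s) == pytest.approx(roc_auc_score(y, s), abs=1e-12)


def test_auc_single_class_is_an_error():
    with pytest.raises(UndefinedMetricError):
        M.roc_auc((1, 1, 1), (0.1, 0.2, 0.3))


def test_metric_report_ranges_fuzzed():
    rng = np.random.default_rng(1)
    for _ in range(200):
        tp, tn, fp, fn = rng.integers(0, 30, 4)
        if tp + tn + fp + fn == 0:
            continue
        rep = M.compute_metrics(M.ConfusionCounts(tp, tn, fp, fn))
        for m in ("f1", "accuracy", "balanced_accuracy", "sensitivity", "specificity"):
            assert 0.0 <= getattr(rep, m) <= 1.0
        assert -1.0 <= rep.mcc <= 1.0
        assert -1.0 <= rep.cohens_kappa <= 1.0
        assert rep.balanced_accuracy == pytest.approx(
            (rep.sensitivity + rep.specificity) / 2
        )
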