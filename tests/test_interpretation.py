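"""Signature extraction, high-frequency gene ranking and ATC stratification."""

from collections import Counter

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

import dilipred as dp
from dilipred.exceptions import SignatureError
from dilipred.interpretation import validate_atc_table

from .conftest import knn, make_profile_set


def test_hand_ordered_signature():
    ps = make_profile_set(np.array([[3.0], [2.0], [1.0], [-1.0], [-2.0]]),
                          gene_ids=list("abcde"), labels=[1])
    sigs = dp.extract_signatures(ps, predictions=[1], k=2)
    assert len(sigs) == 1
    assert sigs[0].up == ("a", "b")      # values 3, 2
    assert sigs[0].down == ("e", "d")    # values -2, -1
    assert set(sigs[0].up).isdisjoint(sigs[0].down)


def test_incorrect_predictions_contribute_nothing():
    ps = make_profile_set(np.random.default_rng(0).normal(size=(10, 4)),
                          labels=[1, 0, 1, 0])
    sigs = dp.extract_signatures(ps, predictions=[1, 1, 0, 0], k=3)
    assert [s.profile_id for s in sigs] == [ps.profile_ids[0], ps.profile_ids[3]]


def test_signature_k_too_large_is_an_error():
    ps = make_profile_set(np.zeros((5, 1)), labels=[1])
    with pytest.raises(SignatureError):
        dp.extract_signatures(ps, predictions=[1], k=3)


def test_ties_broken_by_lexical_gene_id():
    ps = make_profile_set(np.array([[1.0], [1.0], [0.0], [-1.0], [-1.0], [0.0]]),
                          gene_ids=["gb", "ga", "gc", "ge", "gd", "gf"],
                          labels=[1])
    sigs = dp.extract_signatures(ps, predictions=[1], k=2)
    assert sigs[0].up == ("ga", "gb")
    assert sigs[0].down == ("gd", "ge")


def test_gene_row_permutation_does_not_change_sets(signal_profiles):
    pred = signal_profiles.labels  # all correct
    sigs = dp.extract_signatures(signal_profiles, pred, k=10)
    perm = np.random.default_rng(2).permutation(signal_profiles.n_genes)
    shuffled = make_profile_set(signal_profiles.values[perm],
                                gene_ids=[signal_profiles.gene_ids[i] for i in perm],
                                profile_ids=list(signal_profiles.profile_ids),
                                labels=signal_profiles.labels,
                                drug_ids=list(signal_profiles.drug_ids))
    sigs2 = dp.extract_signatures(shuffled, pred, k=10)
    for a, b in zip(sigs, sigs2):
        assert set(a.up) == set(b.up) and set(a.down) == set(b.down)


def test_high_frequency_ranking_matches_bruteforce_tally(signal_profiles):
    pred = signal_profiles.labels
    sigs = dp.extract_signatures(signal_profiles, pred, k=8)
    summary = dp.high_frequency_genes(sigs, top_n=20)
    oracle = Counter()
    for s in sigs:
        oracle.update(s.up)
        oracle.update(s.down)
    counts = dict(zip(summary.frequencies["gene_id"], summary.frequencies["count"]))
    assert counts == dict(oracle)
    # counts non-increasing down the ranked list
    ranked = summary.frequencies["count"].to_numpy()
    assert np.all(np.diff(ranked) <= 0)
    assert len(summary.top_genes) == 20


def test_single_signature_deterministic_tie_order():
    ps = make_profile_set(np.array([[4.0], [3.0], [-3.0], [-4.0]]),
                          gene_ids=["g1", "g2", "g3", "g4"], labels=[1])
    sigs = dp.extract_signatures(ps, predictions=[1], k=2)
    summary = dp.high_frequency_genes(sigs, top_n=10)
    assert list(summary.frequencies["count"]) == [1, 1, 1, 1]
    # all counts tie -> larger |Z| first, then lexical
    assert list(summary.frequencies["gene_id"]) == ["g1", "g4", "g2", "g3"]


def test_top_n_truncation_exact():
    rng = np.random.default_rng(3)
    ps = make_profile_set(rng.normal(size=(500, 30)), labels=[1] * 30)
    sigs = dp.extract_signatures(ps, predictions=[1] * 30, k=100)
    summary = dp.high_frequency_genes(sigs, top_n=200)
    assert len(summary.top_genes) == 200


def test_signal_genes_enriched_in_high_frequency_list():
    cfg = dp.SyntheticConfig(n_genes=300, n_drugs=60, positive_fraction=0.5,
                             profiles_per_drug=3, n_signal_genes=30,
                             effect_size=2.0, cell_line_sd=0.2, seed=17)
    cat = dp.generate_drug_catalog(cfg)
    ps = dp.simulate_profiles(cat, cfg)
    plan = dp.stratified_split_profiles(ps, 0.8, 1)
    train, valid = ps.subset(plan.train_ids), ps.subset(plan.validation_ids)
    model = dp.train_classifier(knn(3), train)
    pred = dp.classify(dp.predict_scores(model, valid))
    sigs = dp.extract_signatures(valid, pred, k=20)
    summary = dp.high_frequency_genes(sigs, top_n=60)
    planted = {valid.gene_ids[i] for i in cat.signal_genes}
    overlap = len(planted & set(summary.top_genes))
    p = hypergeom.sf(overlap - 1, cfg.n_genes, len(planted), 60)
    assert p < 0.01


# ----------------------------------------------------------------------
# ATC stratification
# ----------------------------------------------------------------------

def atc_fixture():
    ps = make_profile_set(np.random.default_rng(4).normal(size=(6, 8)),
                          drug_ids=["d1", "d1", "d2", "d2", "d3", "d3", "d4", "d4"],
                          labels=[1, 1, 0, 0, 1, 1, 0, 0])
    atc = pd.DataFrame({
        "drug_id": ["d1", "d2", "d3", "d3", "d4"],
        "atc_first_level": ["L", "L", "N", "L", "N"],
    })
    return ps, atc


def test_atc_groups_multiclass_drugs_into_each_class():
    ps, atc = atc_fixture()
    pred = ps.labels  # perfect predictions
    table, report = dp.atc_stratified_metrics(ps, pred, atc)
    table = table.set_index("atc_class")
    assert table.loc["L", "n_profiles"] == 6  # d1, d2 and multi-class d3
    assert table.loc["N", "n_profiles"] == 4
    assert table.loc["L", "balanced_accuracy"] == 1.0
    assert report["n_unmapped_drugs"] == 0


def test_atc_degenerate_stratum_reports_partial_metrics():
    ps, _ = atc_fixture()
    atc = pd.DataFrame({"drug_id": ["d1"], "atc_first_level": ["A"]})
    pred = ps.labels
    table, report = dp.atc_stratified_metrics(ps, pred, atc)
    row = table.set_index("atc_class").loc["A"]
    assert row["sensitivity"] == 1.0       # only positives present
    assert np.isnan(row["specificity"])
    assert np.isnan(row["balanced_accuracy"])
    assert report["n_unmapped_drugs"] == 3


def test_atc_class_with_planted_double_effect_outperforms_pool():
    aucs_special, aucs_pool = [], []
    for seed in range(8):
        cfg = dp.SyntheticConfig(n_genes=100, n_drugs=60, positive_fraction=0.5,
                                 profiles_per_drug=3, n_signal_genes=20,
                                 effect_size=0.6, cell_line_sd=0.2, seed=seed)
        cat = dp.generate_drug_catalog(cfg)
        ps = dp.simulate_profiles(cat, cfg)
        # drugs in class "L" get their planted shift doubled
        drugs = sorted(set(ps.drug_ids))
        special = set(drugs[: len(drugs) // 3])
        for j, d in enumerate(ps.drug_ids):
            if d in special and d in cat.directions.index:
                ps.values[cat.signal_genes, j] *= 1.0
                ps.values[cat.signal_genes, j] += (
                    cfg.effect_size * cat.directions.loc[d].to_numpy())
        atc = pd.DataFrame({
            "drug_id": drugs,
            "atc_first_level": ["L" if d in special else "N" for d in drugs]})
        plan = dp.stratified_split_profiles(ps, 0.8, seed)
        train, valid = ps.subset(plan.train_ids), ps.subset(plan.validation_ids)
        model = dp.train_classifier(knn(3), train)
        scores = dp.predict_scores(model, valid)
        pred = dp.classify(scores)
        table, _ = dp.atc_stratified_metrics(valid, pred, atc, scores=scores)
        table = table.set_index("atc_class")
        if "L" in table.index and not np.isnan(table.loc["L", "auc"]):
            aucs_special.append(table.loc["L", "auc"])
            aucs_pool.append(dp.roc_auc(valid.labels, scores))
    diff = np.array(aucs_special) - np.array(aucs_pool)
    se = diff.std(ddof=1) / np.sqrt(len(diff))
    assert diff.mean() > 0
    assert diff.mean() > -3 * se  # strictly better on average, within noise


def test_atc_table_validation():
    with pytest.raises(ValueError):
        validate_atc_table(pd.DataFrame({"drug_id": ["d"], "atc_first_level": ["Z"]}))
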