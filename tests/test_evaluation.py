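"""Evaluation harness: split contracts, metric brute-force oracles,
similarity, leakage filtering, and the CV driver."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rsmanet import (MoleculeRecord, RNARecord, SyntheticSpec,
                     classification_metrics, evaluate_predictions,
                     generate_dataset, independent_filter, make_splits,
                     morgan_fingerprint, regression_metrics, rna_identity,
                     run_cv, tanimoto)
from rsmanet.data_io import AffinityPair, Dataset

from conftest import providers_for, tiny_config

RNG = np.random.default_rng(31)


# ---------------------------------------------------------------- splits --

def test_stratified_partition_sizes():
    syn = generate_dataset(SyntheticSpec(n_rnas=10, n_mols=12, n_pairs=100,
                                         seed=0, rna_len_range=(15, 25)))
    plan = make_splits(syn.dataset, "stratified_kfold", 5, seed=0)
    sizes = [len(plan.fold_indices(f)) for f in range(5)]
    assert sum(sizes) == 100
    assert all(abs(s - 20) <= 1 for s in sizes)


def test_stratified_beats_sorted_sequential_on_balance():
    """Per-fold mean pKd stays near the global mean under stratification but
    not under sorted-sequential chunking."""
    syn = generate_dataset(SyntheticSpec(n_rnas=12, n_mols=15, n_pairs=150,
                                         seed=3, rna_len_range=(15, 25)))
    y = syn.dataset.affinities
    plan = make_splits(syn.dataset, "stratified_kfold", 5, seed=1)
    strat_dev = max(abs(y[plan.fold_indices(f)].mean() - y.mean())
                    for f in range(5))
    assert strat_dev < 0.2
    order = np.argsort(y)
    seq_dev = max(abs(y[order[f * 30:(f + 1) * 30]].mean() - y.mean())
                  for f in range(5))
    assert seq_dev > strat_dev


@pytest.mark.parametrize("mode,attr", [("blind_rna", "rna_id"),
                                       ("blind_mol", "mol_id")])
def test_blind_modes_entity_disjoint(mode, attr):
    syn = generate_dataset(SyntheticSpec(n_rnas=10, n_mols=12, n_pairs=80,
                                         seed=5, rna_len_range=(15, 25)))
    plan = make_splits(syn.dataset, mode, 5, seed=2)
    folds = [{getattr(syn.dataset.pairs[i], attr)
              for i in plan.fold_indices(f)} for f in range(5)]
    for a in range(5):
        for b in range(a + 1, 5):
            assert not folds[a] & folds[b]


def test_all_blind_joint_disjointness():
    syn = generate_dataset(SyntheticSpec(n_rnas=10, n_mols=12, n_pairs=80,
                                         seed=6, rna_len_range=(15, 25)))
    plan = make_splits(syn.dataset, "all_blind", 4, seed=3)
    kept = plan.assignment >= 0
    assert kept.any()
    for attr in ("rna_id", "mol_id"):
        folds = [{getattr(syn.dataset.pairs[i], attr)
                  for i in plan.fold_indices(f)} for f in range(4)]
        for a in range(4):
            for b in range(a + 1, 4):
                assert not folds[a] & folds[b]


def test_blind_mode_needs_enough_entities():
    rnas = {f"r{i}": RNARecord(f"r{i}", "ACGU") for i in range(2)}
    mols = {"m0": MoleculeRecord("m0", "C")}
    pairs = [AffinityPair("r0", "m0", 4.0), AffinityPair("r1", "m0", 5.0)]
    ds = Dataset(rnas, mols, pairs).validate()
    with pytest.raises(ValueError, match="blind folds"):
        make_splits(ds, "blind_rna", 5, seed=0)


# --------------------------------------------------------------- metrics --

def pearson_oracle(a, b):
    am, bm = a - a.mean(), b - b.mean()
    return float((am * bm).sum() / np.sqrt((am ** 2).sum() * (bm ** 2).sum()))


def rank_average_ties(v):
    order = np.argsort(v, kind="stable")
    ranks = np.empty(len(v))
    i = 0
    sv = v[order]
    while i < len(v):
        j = i
        while j < len(v) and sv[j] == sv[i]:
            j += 1
        ranks[order[i:j]] = (i + j - 1) / 2 + 1
        i = j
    return ranks


def auc_pair_counting(labels, scores):
    pos = scores[labels]
    neg = scores[~labels]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return float(wins / (len(pos) * len(neg)))


def test_regression_metrics_identity_and_sign():
    y = RNG.normal(5, 1, 30)
    pcc, scc, rmse = regression_metrics(y, y)
    assert pcc == pytest.approx(1.0) and scc == pytest.approx(1.0)
    assert rmse == pytest.approx(0.0)
    pcc_neg, _, _ = regression_metrics(y, -(y - y.mean()))
    assert pcc_neg == pytest.approx(-1.0)


def test_regression_metrics_match_brute_force():
    for _ in range(20):
        yt = RNG.normal(5, 1.5, 50)
        yp = yt + RNG.normal(0, 1, 50)
        pcc, scc, rmse = regression_metrics(yt, yp)
        assert pcc == pytest.approx(pearson_oracle(yt, yp), abs=1e-10)
        assert scc == pytest.approx(
            pearson_oracle(rank_average_ties(yt), rank_average_ties(yp)),
            abs=1e-10)
        assert rmse == pytest.approx(
            float(np.sqrt(sum((a - b) ** 2 for a, b in zip(yt, yp)) / 50)),
            abs=1e-12)


def test_constant_truth_rejected():
    with pytest.raises(ValueError, match="constant"):
        regression_metrics([4.0, 4.0, 4.0], [1.0, 2.0, 3.0])


def test_classification_metrics_perfect_separation():
    yt = np.array([6.0, 5.5, 3.0, 2.0])
    spec, bacc, auc = classification_metrics(yt, yt, threshold=4.0)
    assert spec == 1.0 and bacc == 1.0 and auc == 1.0


def test_auc_matches_pair_counting_with_ties():
    labels = np.array([True, True, False, False])
    scores = np.array([0.9, 0.4, 0.6, 0.1])
    yt = np.where(labels, 5.0, 3.0)
    _, _, auc = classification_metrics(yt, scores, threshold=4.0)
    assert auc == pytest.approx(auc_pair_counting(labels, scores), abs=1e-12)
    # ties get half credit
    tied = np.array([0.5, 0.5, 0.5, 0.1])
    _, _, auc_t = classification_metrics(yt, tied, threshold=4.0)
    assert auc_t == pytest.approx(auc_pair_counting(labels, tied), abs=1e-12)


def test_single_class_rejected():
    with pytest.raises(ValueError, match="classes"):
        classification_metrics([5.0, 6.0], [5.0, 6.0], threshold=4.0)


@given(st.lists(st.floats(-5, 5).map(lambda v: round(v, 3)),
                min_size=6, max_size=30).map(np.array))
@settings(max_examples=50, derandomize=True, deadline=None)
def test_auc_invariant_under_monotone_transform(scores):
    labels = np.arange(len(scores)) % 2 == 0
    yt = np.where(labels, 5.0, 3.0)
    _, _, auc1 = classification_metrics(yt, scores, threshold=4.0)
    _, _, auc2 = classification_metrics(yt, np.exp(scores / 2), threshold=4.0)
    assert auc1 == pytest.approx(auc2, abs=1e-12)


# ------------------------------------------------------------ similarity --

def test_tanimoto_set_arithmetic():
    assert tanimoto(frozenset({1, 2}), frozenset({1, 2})) == 1.0
    assert tanimoto(frozenset({1}), frozenset({2})) == 0.0
    assert tanimoto(frozenset({1, 2, 3}), frozenset({2, 3, 4})) == 0.5
    assert tanimoto(frozenset(), frozenset()) == 0.0


def test_rna_identity_near_duplicate():
    a = "ACGUACGUACGUACGUACGU"
    b = a[:10] + "C" + a[11:]           # one substitution in 20 nt
    assert rna_identity(a, a) == 1.0
    assert rna_identity(a, b) == pytest.approx(0.95)


def test_independent_filter_removes_leaky_entities():
    train_rnas = {"r1": RNARecord("r1", "ACGUACGUACGUACGUACGU"),
                  "r2": RNARecord("r2", "GGGGCCCCGGGGCCCCAAAA")}
    test_rnas = {"t1": RNARecord(
        "t1", "ACGUACGUACCUACGUACGU")}   # identity 0.95 with r1
    train_mols = {"m1": MoleculeRecord("m1", "c1ccccc1O"),
                  "m2": MoleculeRecord("m2", "CCCCCCCC")}
    test_mols = {"x1": MoleculeRecord("x1", "c1ccccc1O")}   # identical to m1
    train_ds = Dataset(train_rnas, train_mols,
                       [AffinityPair("r1", "m1", 5.0),
                        AffinityPair("r1", "m2", 4.0),
                        AffinityPair("r2", "m1", 6.0),
                        AffinityPair("r2", "m2", 3.0)]).validate()
    test_ds = Dataset(test_rnas, test_mols,
                      [AffinityPair("t1", "x1", 5.0)]).validate()
    filtered, report = independent_filter(train_ds, test_ds, 0.8, 0.8)
    assert report.removed_rnas == ["r1"]
    assert report.removed_mols == ["m1"]
    assert [(p.rna_id, p.mol_id) for p in filtered.pairs] == [("r2", "m2")]


def test_independent_filter_keeps_dissimilar_training_set():
    train_ds = Dataset({"r1": RNARecord("r1", "AAAAAAAAAAUUUUUUUUUU")},
                       {"m1": MoleculeRecord("m1", "CCCCCCCC")},
                       [AffinityPair("r1", "m1", 5.0)]).validate()
    test_ds = Dataset({"t1": RNARecord("t1", "GCGCGCGCGCGCGCGCGCGC")},
                      {"x1": MoleculeRecord("x1", "c1ccc2ccccc2c1")},
                      [AffinityPair("t1", "x1", 5.0)]).validate()
    filtered, report = independent_filter(train_ds, test_ds, 0.8, 0.8)
    assert not report.removed_rnas and not report.removed_mols
    assert len(filtered.pairs) == 1


def test_morgan_fingerprint_identity():
    a = morgan_fingerprint(MoleculeRecord("a", "c1ccccc1O"))
    b = morgan_fingerprint(MoleculeRecord("b", "Oc1ccccc1"))
    assert tanimoto(a, b) == 1.0        # same molecule, different SMILES


# ------------------------------------------------------------------- CV --

def test_run_cv_smoke_and_aggregate(tiny_synthetic):
    syn = generate_dataset(SyntheticSpec(n_rnas=8, n_mols=10, n_pairs=40,
                                         seed=9, rna_len_range=(12, 20)))
    cfg = tiny_config(epochs=2)
    plan = make_splits(syn.dataset, "stratified_kfold", 2, seed=4)
    result = run_cv(syn.dataset, cfg, plan, providers_for(syn))
    assert len(result.fold_reports) == 2
    assert result.aggregate_mean["pcc"] == pytest.approx(
        np.mean([r.pcc for r in result.fold_reports]))
    # identical seed list reproduces the aggregate exactly
    result2 = run_cv(syn.dataset, cfg, plan, providers_for(syn))
    assert result.aggregate_mean == result2.aggregate_mean


def test_evaluate_predictions_bundles_both_tasks():
    yt = np.array([5.0, 6.0, 3.0, 2.5, 4.5])
    yp = yt + 0.1
    rep = evaluate_predictions(yt, yp)
    assert rep.n == 5 and rep.auc == 1.0 and rep.rmse == pytest.approx(0.1)
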