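"""Fold plans, metric correctness against brute force, and CV behavior."""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from opnote.cascade import train_ovr
from opnote.evaluate import (
    auprc,
    f1_scores,
    feature_importance,
    grouped_kfold,
    hamming_loss,
    roc_auc,
    stratified_note_kfold,
)
from opnote.featurize import TokenStream, fit_tfidf, transform_corpus


# ---------------------------------------------------------------------------
# brute-force oracles (independent of the implementations under test)


def auc_oracle(scores, labels):
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def ap_oracle(scores, labels):
    """Average precision: sum over recall steps of delta-recall x precision,
    thresholding at each distinct score (descending)."""
    n_pos = sum(labels)
    ap, prev_recall = 0.0, 0.0
    for t in sorted(set(scores), reverse=True):
        pred = [s >= t for s in scores]
        tp = sum(1 for p, l in zip(pred, labels) if p and l)
        fp = sum(1 for p, l in zip(pred, labels) if p and not l)
        recall = tp / n_pos
        precision = tp / (tp + fp) if tp + fp else 0.0
        ap += (recall - prev_recall) * precision
        prev_recall = recall
    return ap


def f1_oracle(pred, true):
    n, k = true.shape
    per_class = []
    for j in range(k):
        tp = int(np.sum((pred[:, j] == 1) & (true[:, j] == 1)))
        fp = int(np.sum((pred[:, j] == 1) & (true[:, j] == 0)))
        fn = int(np.sum((pred[:, j] == 0) & (true[:, j] == 1)))
        per_class.append(2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0)
    tp = int(np.sum((pred == 1) & (true == 1)))
    fp = int(np.sum((pred == 1) & (true == 0)))
    fn = int(np.sum((pred == 0) & (true == 1)))
    micro = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0
    return micro, float(np.mean(per_class)), per_class


class TestRocAuc:
    def test_perfect(self):
        assert roc_auc([0.1, 0.9], [0, 1]) == 1.0

    def test_tie_contributes_half(self):
        assert roc_auc([0.5, 0.5], [0, 1]) == 0.5

    def test_reversed(self):
        assert roc_auc([0.9, 0.1], [0, 1]) == 0.0

    def test_one_class_error(self):
        with pytest.raises(ValueError):
            roc_auc([0.2, 0.3], [1, 1])


class TestAuprc:
    def test_perfect_any_prevalence(self):
        assert auprc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == pytest.approx(1.0)

    def test_interleaved(self):
        assert auprc([0.9, 0.8, 0.7], [1, 0, 1]) == pytest.approx(1 * 0.5 + (2 / 3) * 0.5)

    def test_constant_scores_give_prevalence(self):
        assert auprc([0.4] * 8, [1, 0, 0, 1, 0, 0, 0, 0]) == pytest.approx(0.25)

    def test_no_positives_error(self):
        with pytest.raises(ValueError):
            auprc([0.2, 0.3], [0, 0])


class TestF1AndHamming:
    def test_hand_confusion_counts(self):
        true = [[1, 0], [0, 1]]
        pred = [[1, 0], [1, 1]]
        micro, macro, per_class = f1_scores(pred, true)
        assert per_class[0] == pytest.approx(2 / 3)
        assert per_class[1] == pytest.approx(1.0)
        assert macro == pytest.approx(5 / 6)
        assert micro == pytest.approx(0.8)

    def test_perfect_prediction(self):
        true = [[1, 0, 1], [0, 1, 0]]
        micro, macro, per_class = f1_scores(true, true)
        assert micro == macro == 1.0
        assert np.all(per_class == 1.0)

    def test_all_negative_prediction(self):
        true = [[1, 0], [1, 1]]
        pred = [[0, 0], [0, 0]]
        micro, _, _ = f1_scores(pred, true)
        assert micro == 0.0

    def test_hamming_examples(self):
        assert hamming_loss([[1, 0, 0], [0, 1, 0]], [[1, 0, 0], [0, 0, 0]]) == pytest.approx(1 / 6)
        assert hamming_loss([[1, 0]], [[1, 0]]) == 0.0
        assert hamming_loss([[1, 0]], [[0, 1]]) == 1.0

    def test_micro_f1_is_not_one_minus_hamming_in_general(self):
        # guard against conflating the two metrics
        true = np.array([[1, 0]])
        pred = np.array([[0, 0]])
        micro, _, _ = f1_scores(pred, true)
        assert micro != pytest.approx(1 - hamming_loss(pred, true))

    def test_macro_invariant_to_class_relabeling(self):
        rng = np.random.default_rng(0)
        true = rng.integers(0, 2, size=(10, 4))
        pred = rng.integers(0, 2, size=(10, 4))
        perm = [2, 0, 3, 1]
        _, macro_a, _ = f1_scores(pred, true)
        _, macro_b, _ = f1_scores(pred[:, perm], true[:, perm])
        assert macro_a == pytest.approx(macro_b)


@st.composite
def scored_instance(draw):
    n = draw(st.integers(2, 12))
    labels = draw(
        st.lists(st.integers(0, 1), min_size=n, max_size=n).filter(
            lambda l: 0 < sum(l) < len(l)
        )
    )
    # mix of tied and distinct scores
    scores = draw(
        st.lists(st.sampled_from([0.0, 0.1, 0.25, 0.5, 0.5, 0.75, 0.9, 1.0]),
                 min_size=n, max_size=n)
    )
    return scores, labels


class TestOracleProperties:
    @given(scored_instance())
    @settings(max_examples=150, derandomize=True, deadline=None)
    def test_auc_and_ap_match_brute_force(self, inst):
        scores, labels = inst
        assert roc_auc(scores, labels) == pytest.approx(auc_oracle(scores, labels), abs=1e-9)
        assert auprc(scores, labels) == pytest.approx(ap_oracle(scores, labels), abs=1e-9)

    @given(st.integers(1, 12), st.integers(1, 4), st.integers(0, 2**31 - 1))
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_f1_and_hamming_match_brute_force(self, n, k, seed):
        rng = np.random.default_rng(seed)
        true = rng.integers(0, 2, size=(n, k))
        pred = rng.integers(0, 2, size=(n, k))
        micro, macro, per_class = f1_scores(pred, true)
        micro_o, macro_o, per_o = f1_oracle(pred, true)
        assert micro == pytest.approx(micro_o, abs=1e-9)
        assert macro == pytest.approx(macro_o, abs=1e-9)
        np.testing.assert_allclose(per_class, per_o, atol=1e-9)
        expected_hamming = np.mean(pred != true)
        assert hamming_loss(pred, true) == pytest.approx(expected_hamming, abs=1e-9)


class TestGroupedKfold:
    def test_ten_patients_five_folds(self):
        plan = grouped_kfold([f"p{i}" for i in range(10)], k=5, seed=0)
        sizes = [len(plan.test_units(f)) for f in range(5)]
        assert sizes == [2, 2, 2, 2, 2]

    def test_patient_notes_share_fold(self):
        patients = ["a", "a", "a", "b", "c", "d", "e"]
        plan = grouped_kfold(patients, k=3, seed=1)
        folds_of_a = {plan.assignments[i] for i, p in enumerate(patients) if p == "a"}
        assert len(folds_of_a) == 1

    def test_too_few_patients_error(self):
        with pytest.raises(ValueError):
            grouped_kfold(["a", "b", "c", "d"], k=5, seed=0)

    def test_deterministic(self):
        patients = [f"p{i % 7}" for i in range(20)]
        a = grouped_kfold(patients, k=3, seed=5)
        b = grouped_kfold(patients, k=3, seed=5)
        assert a.assignments == b.assignments

    def test_always_train_units_never_tested(self):
        patients = [f"p{i}" for i in range(8)] + ["s1", "s2"]
        units = list(range(10))
        plan = grouped_kfold(patients, k=4, seed=2, unit_ids=units, always_train=[8, 9])
        assert plan.assignments[8] == -1 and plan.assignments[9] == -1
        for fold in range(4):
            assert 8 not in plan.test_units(fold)

    def test_no_patient_spans_folds_random(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            n = int(rng.integers(10, 60))
            patients = [f"p{int(rng.integers(0, n // 2 + 2))}" for _ in range(n)]
            k = int(rng.integers(2, min(5, len(set(patients))) + 1))
            plan = grouped_kfold(patients, k=k, seed=int(rng.integers(0, 1000)))
            by_patient = {}
            for i, p in enumerate(patients):
                by_patient.setdefault(p, set()).add(plan.assignments[i])
            assert all(len(folds) == 1 for folds in by_patient.values())


class TestStratifiedKfold:
    def test_round_robin_balance(self):
        labels = ["A"] * 6 + ["B"] * 3
        plan = stratified_note_kfold(labels, k=3, seed=0)
        for fold in range(3):
            test = plan.test_units(fold)
            assert sum(1 for u in test if labels[u] == "A") == 2
            assert sum(1 for u in test if labels[u] == "B") == 1

    def test_rare_class_warns_and_misses_folds(self, caplog):
        labels = ["A"] * 6 + ["B"]
        with caplog.at_level(logging.WARNING, logger="opnote.evaluate"):
            plan = stratified_note_kfold(labels, k=3, seed=0)
        assert any("unstable" in rec.message for rec in caplog.records)
        b_folds = {plan.assignments[6]}
        assert len(b_folds) == 1  # B appears in exactly one test fold

    def test_deterministic(self):
        labels = ["A", "B", "A", "C", "B", "A"]
        assert (
            stratified_note_kfold(labels, k=2, seed=3).assignments
            == stratified_note_kfold(labels, k=2, seed=3).assignments
        )

    def test_folds_partition_units(self):
        labels = ["A"] * 7 + ["B"] * 5 + ["C"] * 2
        plan = stratified_note_kfold(labels, k=3, seed=1)
        all_units = list(itertools.chain.from_iterable(plan.test_units(f) for f in range(3)))
        assert sorted(all_units) == list(range(14))


class TestFeatureImportance:
    def _separable_model(self):
        # three classes so the class-A token is the unique best A-vs-rest
        # split (in a two-class setup either class's token separates both)
        rng = np.random.default_rng(0)
        marker = {"A": "cheiloplasty", "B": "pharyngoplasty", "C": "palatoplasty"}
        docs, labels = [], []
        filler = ["patient", "procedure", "anesthesia", "well"]
        for i in range(12):
            for cls, token in marker.items():
                docs.append(
                    TokenStream(f"{cls}{i}", tuple([token] + list(rng.permutation(filler))))
                )
                labels.append(frozenset({cls}))
        tfidf = fit_tfidf(docs, max_features=50)
        X = transform_corpus(docs, tfidf)
        ovr = train_ovr(X, labels, ("A", "B", "C"), seed=1, n_trees=80)
        return ovr, tfidf.feature_names()

    def test_driving_term_ranks_first(self):
        ovr, names = self._separable_model()
        report = feature_importance(ovr, names, top_k=10)
        assert "cheiloplasty" in report["A"][0][0]
        assert report["A"][0][1] == pytest.approx(1.0)  # normalized to max 1

    def test_top_k_larger_than_vocabulary(self):
        ovr, names = self._separable_model()
        report = feature_importance(ovr, names, top_k=10_000)
        assert len(report["A"]) == len(names)

    def test_duplicate_features_share_importance_contiguously(self):
        rng = np.random.default_rng(7)
        n = 40
        informative = np.repeat([0.0, 1.0], n // 2)
        X = np.column_stack([
            informative, informative,  # identical duplicated columns
            rng.normal(size=n) * 0.01,
        ])
        labels = [frozenset({"P"}) if v else frozenset() for v in informative]
        labels = [l if l else frozenset({"N"}) for l in labels]
        ovr = train_ovr(X, labels, ("P",), seed=2, n_trees=100)
        report = feature_importance(ovr, ["dup1", "dup2", "noise"], top_k=3)
        top_names = [t for t, _ in report["P"]]
        assert set(top_names[:2]) == {"dup1", "dup2"}
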