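"""Decomposition schemes, bagged-OVO voting, metrics and nested CV."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.linear_model import LogisticRegression
from sklearn.svm import LinearSVC

from necsuff import (
    BaggedOvoModel,
    ConfigurationError,
    ContractError,
    OvoModel,
    balanced_accuracy,
    compare_classifiers_ttest,
    decompose_ova,
    decompose_ovo,
    fit_bagged_ovo,
    fit_ovo,
    nested_cv,
    predict_vote,
    split_majority,
    weighted_f1,
)
from necsuff.ensemble import BinaryTask

from .conftest import imbalanced_gaussians


def _blobs(seed=0, n=30, sep=8.0):
    rng = np.random.default_rng(seed)
    X = np.vstack(
        [rng.normal((i * sep, 0), 1.0, size=(n, 2)) for i in range(3)]
    )
    y = np.repeat(["AD", "CN", "MCI"], n)
    return X, y


class TestDecomposition:
    @pytest.mark.parametrize(
        "classes, expected",
        [({"CN", "MCI", "AD"}, 3), ({"A", "B"}, 1), (set("ABCDE"), 10)],
    )
    def test_ovo_task_count_is_m_choose_2(self, classes, expected):
        tasks = decompose_ovo(classes)
        assert len(tasks) == expected
        pairs = {(t.negative, t.positive) for t in tasks}
        assert len(pairs) == expected  # each unordered pair once

    def test_ova_tasks_one_per_class_with_rest_pooled(self):
        labels = np.repeat(["CN", "MCI", "AD"], [4, 7, 3])
        tasks = decompose_ova({"CN", "MCI", "AD"}, labels=labels)
        assert [t.positive for t in tasks] == ["AD", "CN", "MCI"]
        assert all(t.negative is None for t in tasks)
        for t in tasks:
            n_k = np.sum(labels == t.positive)
            assert len(t.rows) - n_k == len(labels) - n_k  # rest = n - n_k

    def test_two_classes(self):
        assert len(decompose_ovo({"A", "B"})) == 1
        assert len(decompose_ova({"A", "B"})) == 2

    def test_fewer_than_two_classes_rejected(self):
        with pytest.raises(ContractError):
            decompose_ovo({"A"})
        with pytest.raises(ContractError):
            decompose_ova({"A"})


class TestSplitMajority:
    def test_reference_majority_740_splits_370_370(self):
        labels = np.repeat(["CN", "MCI", "AD"], [449, 740, 274])
        a, b = split_majority(labels, "MCI", seed=0)
        assert np.sum(labels[a] == "MCI") == 370
        assert np.sum(labels[b] == "MCI") == 370
        # both halves keep every minority row
        assert np.sum(labels[a] != "MCI") == 449 + 274
        assert np.sum(labels[b] != "MCI") == 449 + 274

    @given(n_maj=st.integers(1, 40), seed=st.integers(0, 100))
    @settings(max_examples=30, deadline=None)
    def test_partition_property(self, n_maj, seed):
        labels = np.array(["m"] * n_maj + ["x"] * 5)
        a, b = split_majority(labels, "m", seed=seed)
        maj_a = set(np.flatnonzero(labels == "m")) & set(a)
        maj_b = set(np.flatnonzero(labels == "m")) & set(b)
        assert maj_a | maj_b == set(range(n_maj))
        assert not (maj_a & maj_b)
        assert abs(len(maj_a) - len(maj_b)) <= 1

    def test_absent_majority_rejected(self):
        with pytest.raises(ContractError):
            split_majority(np.array(["a", "b"]), "z")


class _FixedPairClf:
    """Stub binary classifier emitting fixed per-class probabilities."""

    def __init__(self, classes, prob_of_first):
        self.classes_ = np.asarray(classes)
        self.p = prob_of_first

    def predict_proba(self, X):
        n = np.atleast_2d(X).shape[0]
        return np.tile([self.p, 1.0 - self.p], (n, 1))


def _manual_ovo(probs):
    """OvoModel over {AD, CN, MCI} with fixed pairwise probabilities."""
    classes = ["AD", "CN", "MCI"]
    tasks, ests = [], []
    for (a, b), p in probs.items():
        tasks.append(BinaryTask(positive=b, negative=a))
        ests.append(_FixedPairClf([a, b], p))
    return OvoModel(classes_=classes, tasks_=tasks, estimators_=ests)


class TestVoting:
    def test_unanimous_probabilities_elect_that_class(self):
        # every pair containing AD gives AD probability 1
        ovo = _manual_ovo({("AD", "CN"): 1.0, ("AD", "MCI"): 1.0, ("CN", "MCI"): 0.5})
        model = BaggedOvoModel(classes_=ovo.classes_, majority_="MCI",
                               bags_=[ovo, ovo])
        labels, scores = predict_vote(model, np.zeros((2, 2)))
        assert list(labels) == ["AD", "AD"]
        assert scores[0, 0] == scores.max()

    def test_exact_tie_broken_by_alphabetical_order(self):
        # symmetric probabilities: every class scores identically
        ovo = _manual_ovo({("AD", "CN"): 0.5, ("AD", "MCI"): 0.5, ("CN", "MCI"): 0.5})
        model = BaggedOvoModel(classes_=ovo.classes_, majority_="MCI",
                               bags_=[ovo, ovo])
        labels, scores = predict_vote(model, np.zeros((1, 2)))
        assert np.allclose(scores[0], scores[0, 0])
        assert labels[0] == "AD"  # earliest in the fixed alphabetical order

    def test_vote_invariant_to_task_order(self):
        probs = {("AD", "CN"): 0.8, ("AD", "MCI"): 0.3, ("CN", "MCI"): 0.6}
        ovo1 = _manual_ovo(probs)
        ovo2 = _manual_ovo(dict(reversed(list(probs.items()))))
        X = np.zeros((3, 2))
        np.testing.assert_array_equal(
            ovo1.predict_scores(X), ovo2.predict_scores(X)
        )

    def test_identical_bags_equal_plain_ovo(self):
        X, y = _blobs(seed=3)
        ovo = fit_ovo(X, y, LogisticRegression(max_iter=1000))
        bagged = BaggedOvoModel(classes_=ovo.classes_, majority_="CN",
                                bags_=[ovo, ovo])
        Xte = np.random.default_rng(0).normal(4, 3, size=(40, 2))
        np.testing.assert_array_equal(bagged.predict(Xte), ovo.predict(Xte))


class TestFitBaggedOvo:
    def test_three_classes_give_six_binary_classifiers(self):
        X, y = _blobs()
        model = fit_bagged_ovo(X, y, LogisticRegression(max_iter=1000), seed=0)
        assert len(model.bags_) == 2
        assert model.n_binary_classifiers == 6

    def test_separable_blobs_perfect_training_accuracy(self):
        X, y = _blobs(sep=10.0)
        model = fit_bagged_ovo(X, y, LogisticRegression(max_iter=1000), seed=0)
        assert balanced_accuracy(y, model.predict(X)) == 1.0

    def test_deterministic_given_seed(self):
        X, y = imbalanced_gaussians(2)
        Xte, _ = imbalanced_gaussians(3)
        a = fit_bagged_ovo(X, y, LogisticRegression(max_iter=1000), seed=5)
        b = fit_bagged_ovo(X, y, LogisticRegression(max_iter=1000), seed=5)
        np.testing.assert_array_equal(a.predict(Xte), b.predict(Xte))

    def test_margin_only_learner_is_calibrated(self):
        X, y = _blobs()
        model = fit_bagged_ovo(X, y, LinearSVC(), seed=0)
        scores = model.predict_scores(X[:5])
        assert scores.shape == (5, 3)

    def test_unusable_learner_rejected(self):
        class NoProb:
            def fit(self, X, y):
                return self

            def get_params(self, deep=True):
                return {}

        X, y = _blobs()
        with pytest.raises(ConfigurationError, match="calibration"):
            fit_bagged_ovo(X, y, NoProb(), seed=0)

    def test_each_bag_flattens_imbalance(self):
        X, y = imbalanced_gaussians(0)
        raw_ratio = np.mean(y == "B")
        for rows in split_majority(y, "B", seed=0):
            assert np.mean(y[rows] == "B") < raw_ratio


class TestMetrics:
    def test_perfect_predictions(self):
        y = np.repeat(["a", "b", "c"], 5)
        assert balanced_accuracy(y, y) == 1.0
        assert weighted_f1(y, y) == 1.0

    def test_balanced_accuracy_hand_computed_binary(self):
        # TP=8 FN=2 TN=9 FP=1 -> (0.8 + 0.9)/2
        y_true = ["p"] * 10 + ["n"] * 10
        y_pred = ["p"] * 8 + ["n"] * 2 + ["n"] * 9 + ["p"] * 1
        assert balanced_accuracy(y_true, y_pred) == pytest.approx(0.85)

    def test_constant_predictor_three_classes(self):
        y = np.repeat(["a", "b", "c"], 4)
        assert balanced_accuracy(y, ["a"] * 12) == pytest.approx(1 / 3)

    def test_all_wrong_binary_f1_zero(self):
        y = ["a"] * 5 + ["b"] * 5
        flipped = ["b"] * 5 + ["a"] * 5
        assert weighted_f1(y, flipped) == 0.0

    def test_weighted_f1_hand_computed_three_class(self):
        # confusion: a: 3 right / 1 as b; b: 2 right / 2 as c; c: 2 right
        y_true = ["a"] * 4 + ["b"] * 4 + ["c"] * 2
        y_pred = ["a", "a", "a", "b", "b", "b", "c", "c", "c", "c"]
        prec_a, rec_a = 3 / 3, 3 / 4
        prec_b, rec_b = 2 / 3, 2 / 4
        prec_c, rec_c = 2 / 4, 2 / 2
        f1 = lambda p, r: 2 * p * r / (p + r)
        expected = (4 * f1(prec_a, rec_a) + 4 * f1(prec_b, rec_b)
                    + 2 * f1(prec_c, rec_c)) / 10
        assert weighted_f1(y_true, y_pred) == pytest.approx(expected)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ContractError):
            balanced_accuracy(["a"], ["a", "b"])


class TestPairedTTest:
    def test_identical_vectors_degenerate_p_one(self):
        assert compare_classifiers_ttest([0.8, 0.9, 0.85], [0.8, 0.9, 0.85]) == (0.0, 1.0)

    def test_hand_computed_paired_t(self):
        d = np.array([0.02, 0.03, 0.025, 0.015, 0.02])
        b = np.full(5, 0.8)
        t, p = compare_classifiers_ttest(b + d, b)
        expected_t = d.mean() / (d.std(ddof=1) / np.sqrt(5))
        assert t == pytest.approx(expected_t)
        assert 0 < p < 0.05

    def test_antisymmetry(self):
        a = [0.8, 0.82, 0.78, 0.85, 0.9]
        b = [0.75, 0.8, 0.8, 0.8, 0.84]
        t1, p1 = compare_classifiers_ttest(a, b)
        t2, p2 = compare_classifiers_ttest(b, a)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ContractError):
            compare_classifiers_ttest([1.0], [1.0, 2.0])


class TestNestedCV:
    def test_five_outer_records_and_summary(self):
        X, y = imbalanced_gaussians(1, n_min=30)
        res = nested_cv(X, y, LogisticRegression(max_iter=1000),
                        {"C": [1.0]}, seed=0)
        assert len(res.folds) == 5
        for metric in ("balanced_accuracy", "weighted_f1"):
            assert set(res.summary[metric]) == {"mean", "max", "sd"}
            vals = [f[metric] for f in res.folds]
            assert res.summary[metric]["mean"] == pytest.approx(np.mean(vals))
            assert res.summary[metric]["max"] == pytest.approx(np.max(vals))

    def test_separable_data_high_balanced_accuracy(self):
        X, y = _blobs(n=40, sep=10.0)
        res = nested_cv(X, y, LogisticRegression(max_iter=1000), {}, seed=0)
        assert res.summary["balanced_accuracy"]["mean"] > 0.95

    def test_tiny_class_rejected(self):
        X = np.zeros((8, 2))
        y = np.array(["a"] * 3 + ["b"] * 5)
        with pytest.raises(ContractError, match="stratified"):
            nested_cv(X, y, LogisticRegression(), {}, outer=5)
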