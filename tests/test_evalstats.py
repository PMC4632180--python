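import itertools

import numpy as np
import pytest
from scipy import stats

from cpemm.evalstats import (ConfusionMatrix, accuracy, compare_base_classifiers,
                             kfold_cv, ovr_accuracy, precision, press_q, recall,
                             roc_auc_ovr, train_test_eval)
from cpemm.synthgen import SyntheticSpec, generate

from conftest import make_dataset


def cm(counts, classes=("A", "B")):
    return ConfusionMatrix(np.array(counts, dtype=float), tuple(classes))


class TestConfusionMetrics:
    def test_accuracy_cases(self):
        assert accuracy(cm([[10, 0], [0, 5]])) == 1.0
        assert accuracy(cm([[40, 10], [10, 40]])) == 0.8
        assert accuracy(cm([[0, 3], [4, 0]])) == 0.0

    def test_accuracy_conservation(self):
        c = cm([[12, 3, 1], [2, 20, 4], [0, 5, 9]], classes=("A", "B", "C"))
        off = c.total - np.trace(c.counts)
        assert accuracy(c) == pytest.approx(1 - off / c.total)

    def test_precision_cases(self):
        c = cm([[50, 0], [10, 40]])        # TP_A=50, FP_A=10
        assert precision(c, "A") == pytest.approx(50 / 60)
        c2 = cm([[50, 5], [0, 40]])        # FP_A=0
        assert precision(c2, "A") == 1.0
        c3 = cm([[0, 5], [0, 40]])         # TP=FP=0
        assert precision(c3, "A") == 0.0

    def test_recall_cases(self):
        c = cm([[45, 5], [0, 50]])
        assert recall(c, "A") == pytest.approx(0.9)
        assert recall(cm([[50, 0], [3, 40]]), "A") == 1.0
        assert recall(cm([[0, 0], [10, 40]]), "A") == 0.0

    def test_ovr_accuracy(self):
        c = cm([[40, 10], [10, 40]])
        assert ovr_accuracy(c, "A") == pytest.approx(0.8)

    def test_unknown_class_rejected(self):
        with pytest.raises(KeyError):
            precision(cm([[1, 0], [0, 1]]), "Z")

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            accuracy(cm([[0, 0], [0, 0]]))


def brute_force_auc(pos, neg):
    """Mann-Whitney pair counting: independent oracle."""
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0
               for p, n in itertools.product(pos, neg))
    return wins / (len(pos) * len(neg))


def _score_matrix(pos, neg):
    s = np.array(list(pos) + list(neg))
    scores = np.column_stack([s, 1 - s])
    y = np.array(["P"] * len(pos) + ["N"] * len(neg), dtype=object)
    return scores, y


class TestRocAuc:
    def test_perfect_separation(self):
        scores, y = _score_matrix([0.9, 0.8], [0.7, 0.6])
        assert roc_auc_ovr(scores, y, "P", ("P", "N")) == 1.0

    def test_pair_counting_example(self):
        scores, y = _score_matrix([0.9, 0.4], [0.6, 0.2])
        assert roc_auc_ovr(scores, y, "P", ("P", "N")) == 0.75

    def test_all_ties_give_half(self):
        scores, y = _score_matrix([0.5, 0.5], [0.5, 0.5, 0.5])
        assert roc_auc_ovr(scores, y, "P", ("P", "N")) == 0.5

    def test_matches_brute_force_and_sklearn(self):
        from sklearn.metrics import roc_auc_score
        rng = np.random.default_rng(4)
        for _ in range(20):
            pos = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], size=rng.integers(2, 6))
            neg = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], size=rng.integers(2, 6))
            scores, y = _score_matrix(pos, neg)
            ours = roc_auc_ovr(scores, y, "P", ("P", "N"))
            assert ours == pytest.approx(brute_force_auc(pos, neg), abs=1e-12)
            assert ours == pytest.approx(
                roc_auc_score((y == "P").astype(int), scores[:, 0]), abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(5)
        pos, neg = rng.random(8), rng.random(6)
        a = brute_force_auc(pos, neg)
        scores, y = _score_matrix(np.exp(3 * pos) / 60, np.exp(3 * neg) / 60)
        assert roc_auc_ovr(scores, y, "P", ("P", "N")) == pytest.approx(a, abs=1e-12)

    def test_two_class_ovr_symmetry(self):
        rng = np.random.default_rng(6)
        scores, y = _score_matrix(rng.random(10), rng.random(12))
        a_p = roc_auc_ovr(scores, y, "P", ("P", "N"))
        a_n = roc_auc_ovr(scores, y, "N", ("P", "N"))
        assert a_p == pytest.approx(a_n, abs=1e-12)

    def test_one_class_rejected(self):
        scores = np.array([[1.0, 0.0]])
        with pytest.raises(ValueError):
            roc_auc_ovr(scores, np.array(["P"]), "P", ("P", "N"))


class TestPressQ:
    def test_printed_example(self):
        r = press_q(100, 90, 3)
        assert r.Q == pytest.approx(144.5, abs=1e-12)

    def test_chance_level_gives_zero(self):
        assert press_q(99, 33, 3).Q == 0.0

    def test_p_value_at_chi2_boundary(self):
        # Q = 3.841 is the 5% critical value of chi-square with 1 df;
        # find (m, n, p) hitting close to it and cross-check the tail
        q = press_q(160, 93, 2)           # Q = (160-186)^2/160 = 4.225
        assert q.p_value == pytest.approx(stats.chi2.sf(4.225, 1), abs=1e-12)
        assert stats.chi2.sf(3.841, 1) == pytest.approx(0.05, abs=5e-4)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            press_q(10, 5, 1)
        with pytest.raises(ValueError):
            press_q(0, 0, 2)
        with pytest.raises(ValueError):
            press_q(10, 11, 2)


def perfect_memoriser(train, X_test):
    """Callback that looks the answers up from the generating rule."""
    labels = np.where(X_test[:, 0] > 0, "hi", "lo").astype(object)
    scores = np.column_stack([X_test[:, 0] > 0, X_test[:, 0] <= 0]).astype(float)
    return labels, scores


@pytest.fixture
def threshold_data():
    rng = np.random.default_rng(8)
    X = rng.normal(size=(60, 2))
    X[:, 0] = np.where(np.arange(60) % 2 == 0, 1.0, -1.0) * (1 + rng.random(60))
    y = np.where(X[:, 0] > 0, "hi", "lo").astype(object)
    return make_dataset(X, y, classes=("hi", "lo"))


class TestProtocols:
    def test_kfold_partition_and_stratification(self, threshold_data):
        d = threshold_data
        seen = np.zeros(d.n_instances, dtype=int)

        def fp(train, X_test):
            labels, scores = perfect_memoriser(train, X_test)
            return labels, scores

        from cpemm.evalstats import stratified_fold_indices
        folds = stratified_fold_indices(d.y, 5, seed=1)
        for _, te in folds:
            seen[te] += 1
        assert (seen == 1).all()
        for c in d.classes:
            sizes = [np.sum(d.y[te] == c) for _, te in folds]
            assert max(sizes) - min(sizes) <= 1
        rep = kfold_cv(d, 5, fp, seed=1)
        assert rep.overall_accuracy == 1.0
        assert rep.macro_auc == 1.0

    def test_kfold_small_class_rejected(self):
        d = make_dataset(np.zeros((6, 1)), ["a", "a", "a", "a", "b", "b"])
        with pytest.raises(ValueError, match="class"):
            kfold_cv(d, 5, perfect_memoriser, seed=0)

    def test_train_test_split_sizes_and_determinism(self, threshold_data):
        d = threshold_data
        rep1 = train_test_eval(d, 0.3, perfect_memoriser, seed=4)
        rep2 = train_test_eval(d, 0.3, perfect_memoriser, seed=4)
        assert rep1.confusion.total == 18
        np.testing.assert_array_equal(rep1.confusion.counts, rep2.confusion.counts)

    def test_constant_prediction_accuracy_is_prevalence(self, threshold_data):
        d = threshold_data

        def constant(train, X_test):
            return np.array(["hi"] * len(X_test), dtype=object), None

        rep = train_test_eval(d, 0.3, constant, seed=4)
        prevalence = np.mean(d.y == "hi")  # stratified split keeps the class mix
        assert rep.overall_accuracy == pytest.approx(prevalence, abs=0.05)


class TestCompare:
    def test_shape_without_ablation(self, threshold_data):
        table, winner = compare_base_classifiers(threshold_data, ["c45"], seed=0)
        assert len(table) == 2
        full = table[table.condition == "full"].accuracy.iloc[0]
        ablated = table[table.condition == "ablated"].accuracy.iloc[0]
        assert full == ablated
        assert winner == "c45"

    def test_ablating_dominant_feature_hurts_every_kind(self):
        spec = SyntheticSpec(class_counts=(("NL", 60), ("MCI", 60), ("AD", 60)),
                             n_informative=1, n_redundant=0, n_noise=5,
                             effect=6.0, missing_rate=0.0, seed=3)
        d, gt = generate(spec)
        kinds = ["c45", "nb"]
        table, _ = compare_base_classifiers(d, kinds, ablate=["inf_00"], seed=0)
        assert len(table) == len(kinds) * 2
        for k in kinds:
            sub = table[table.kind == k]
            assert (sub[sub.condition == "full"].accuracy.iloc[0]
                    > sub[sub.condition == "ablated"].accuracy.iloc[0])

    def test_missing_ablation_column_rejected(self, threshold_data):
        with pytest.raises(KeyError):
            compare_base_classifiers(threshold_data, ["c45"], ablate=["nope"])

    def test_empty_kinds_rejected(self, threshold_data):
        with pytest.raises(ValueError):
            compare_base_classifiers(threshold_data, [])
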