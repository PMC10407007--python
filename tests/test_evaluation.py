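"""The classifier roster, the repeated stratified evaluation protocol and
the metric calculus."""

import numpy as np
import pytest

from myotex.evaluation import (METRIC_NAMES, MODEL_NAMES, MetricDistribution,
                               ModelSpec, build_classifier,
                               compare_distributions, per_class_metrics,
                               repeated_eval, roc_curve)
from myotex.selection import FeatureTable, zscore


class TestRoster:
    def test_all_seven_construct_and_fit(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((30, 5))
        y = np.repeat([1, 2, 3], 10)
        for name in MODEL_NAMES:
            model = build_classifier(ModelSpec(name, seed=1))
            model.fit(X, y)
            assert model.predict(X).shape == (30,)
            assert model.predict_proba(X).shape == (30, 3)

    def test_unknown_name_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec("extra_trees")

    def test_fine_knn_memorizes_training_set(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((30, 4))
        y = rng.integers(1, 4, 30)
        model = build_classifier(ModelSpec("fine_knn"))
        model.fit(X, y)
        assert (model.predict(X) == y).all()


class TestROC:
    def test_perfect_and_reversed(self):
        y = np.array([0, 0, 0, 1, 1])
        assert roc_curve([0.1, 0.2, 0.3, 0.8, 0.9], y)[2] == 1.0
        assert roc_curve([0.9, 0.8, 0.7, 0.2, 0.1], y)[2] == 0.0

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(3)
        aucs = [roc_curve(rng.random(200), rng.random(200) > 0.5)[2]
                for _ in range(40)]
        assert np.mean(np.abs(np.array(aucs) - 0.5) <= 0.08) >= 0.95

    def test_ties_give_rank_statistic(self):
        scores = np.array([0.5, 0.5, 0.5, 0.5])
        labels = np.array([1, 0, 1, 0])
        assert roc_curve(scores, labels)[2] == pytest.approx(0.5)

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            roc_curve([0.1, 0.2], [1, 1])


class TestPerClassMetrics:
    def test_perfect_diagonal(self):
        df = per_class_metrics(np.diag([2, 2, 2]))
        for m in ("accuracy", "sensitivity", "specificity", "precision",
                  "fscore"):
            assert (df[m] == 1.0).all()

    def test_hand_counted_confusion(self):
        C = np.array([[3, 1, 0], [0, 2, 0], [1, 0, 3]])
        df = per_class_metrics(C)
        assert df.loc[1, "sensitivity"] == pytest.approx(0.75)
        assert df.loc[1, "precision"] == pytest.approx(0.75)
        assert df.loc[1, "specificity"] == pytest.approx(5 / 6)

    def test_all_wrong_zero_sensitivity(self):
        C = np.array([[0, 2, 0], [0, 0, 2], [2, 0, 0]])
        df = per_class_metrics(C)
        assert (df["sensitivity"] == 0.0).all()

    def test_zero_denominator_flagged(self):
        C = np.array([[2, 0, 0], [2, 0, 0], [2, 0, 0]])
        df = per_class_metrics(C)
        assert df.loc[2, "precision"] == 0.0 and df.loc[2, "flagged"]


class TestRepeatedEval:
    def test_holdout_protocol_sizes(self, planted_gauss_table):
        """With class sizes 24/12/16 and 2-per-class stratified holdout,
        every repetition trains on 46 and validates on 6."""
        res, _ = repeated_eval(planted_gauss_table, ModelSpec("fine_knn"),
                               n_reps=5, seed=0)
        assert res.train_size == 46 and res.val_size == 6
        assert res.confusion.sum() == pytest.approx(6.0)
        np.testing.assert_allclose(res.confusion.sum(axis=1), 2.0)

    def test_deterministic_under_seed(self, planted_gauss_table):
        r1, d1 = repeated_eval(planted_gauss_table, ModelSpec("random_forest"),
                               n_reps=5, seed=7)
        r2, d2 = repeated_eval(planted_gauss_table, ModelSpec("random_forest"),
                               n_reps=5, seed=7)
        np.testing.assert_array_equal(r1.confusion, r2.confusion)
        np.testing.assert_array_equal(d1["auc"].values, d2["auc"].values)

    def test_planted_cohort_reaches_high_auc(self, planted_gauss_table):
        zt = zscore(planted_gauss_table)
        res, _ = repeated_eval(zt, ModelSpec("fine_knn"), n_reps=25, seed=1)
        assert res.macro_mean["auc"] >= 0.8

    def test_full_coverage_confusion_rows_are_class_sizes(self,
                                                          planted_gauss_table):
        res, _ = repeated_eval(planted_gauss_table, ModelSpec("fine_knn"),
                               n_reps=3, scheme="full-coverage", seed=0,
                               n_folds=4)
        np.testing.assert_allclose(res.confusion.sum(axis=1), [24, 12, 16])

    def test_label_permutation_null_accuracy(self):
        """Chance-level holdout hit rate on permuted labels.

        The repetition variance within one fixed labeling understates the
        labeling-to-labeling variance, so the null is averaged over several
        independent label permutations.
        """
        rng = np.random.default_rng(11)
        X = rng.standard_normal((52, 8))
        y = np.repeat([1, 2, 3], [24, 12, 16])
        per_rep = []
        for p in range(10):
            table = FeatureTable(X, [f"f{i}" for i in range(8)],
                                 rng.permutation(y))
            _, dists = repeated_eval(table, ModelSpec("fine_knn"), n_reps=8,
                                     seed=p)
            per_rep.extend(dists["sensitivity"].values)
        per_rep = np.array(per_rep)
        se = per_rep.std() / np.sqrt(len(per_rep))
        assert abs(per_rep.mean() - 1 / 3) <= 3 * se + 0.02

    def test_too_small_class_rejected(self):
        X = np.zeros((6, 2))
        y = np.array([1, 1, 2, 2, 3, 3])
        with pytest.raises(ValueError):
            repeated_eval(FeatureTable(X, ["a", "b"], y), ModelSpec("fine_knn"))


class TestCompareDistributions:
    def test_identical_distributions(self):
        a = MetricDistribution("auc", np.array([0.7, 0.8, 0.9]))
        b = MetricDistribution("auc", np.array([0.7, 0.8, 0.9]))
        assert compare_distributions(a, b) == 1.0

    def test_fully_separated_exact_minimum(self):
        from math import comb

        a = MetricDistribution("auc", np.linspace(0.1, 0.2, 10))
        b = MetricDistribution("auc", np.linspace(0.8, 0.9, 10))
        p = compare_distributions(a, b)
        assert p == pytest.approx(2.0 / comb(20, 10))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            compare_distributions(MetricDistribution("x", np.array([])),
                                  MetricDistribution("x", np.array([])))
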