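"""z-scoring, the three selectors and the Wilcoxon screen."""

import numpy as np
import pytest

from myotex.selection import (FeatureTable, lasso_select, mrmr_rank, nca_rank,
                              pairwise_wilcoxon, ranksum_p, select_top_k,
                              zscore)


def _planted(n=60, noise_dim=20, sep=0.3, seed=0):
    rng = np.random.default_rng(seed)
    y = np.repeat([1, 2, 3], n // 3)
    X = rng.standard_normal((n, noise_dim + 1))
    X[:, 0] = y + sep * rng.standard_normal(n)
    names = ["planted"] + [f"noise{i:02d}" for i in range(noise_dim)]
    return X, y, names


class TestZscore:
    def test_mean_zero_sd_one(self):
        X, y, names = _planted()
        zt = zscore(FeatureTable(X, names, y))
        np.testing.assert_allclose(zt.values.mean(axis=0), 0, atol=1e-12)
        np.testing.assert_allclose(zt.values.std(axis=0), 1, atol=1e-12)

    def test_constant_column_dropped_with_warning(self):
        X, y, names = _planted()
        X[:, 3] = 7.0
        with pytest.warns(UserWarning, match="zero-variance"):
            zt = zscore(FeatureTable(X, names, y))
        assert names[3] not in zt.feature_names
        assert zt.values.shape[1] == X.shape[1] - 1

    def test_affine_invariance(self):
        X, y, names = _planted()
        X2 = X.copy()
        X2[:, 0] = 4.0 * X[:, 0] - 11.0
        z1 = zscore(FeatureTable(X, names, y))
        z2 = zscore(FeatureTable(X2, names, y))
        np.testing.assert_allclose(z1.values[:, 0], z2.values[:, 0],
                                   atol=1e-10)


class TestNCA:
    def test_planted_feature_ranked_first_across_seeds(self):
        X, y, names = _planted()
        zt = zscore(FeatureTable(X, names, y))
        top = [nca_rank(zt.values, zt.labels, zt.feature_names,
                        seed=s).ranked_names[0] for s in range(10)]
        assert top.count("planted") >= 9

    def test_top_importance_is_one(self):
        X, y, names = _planted()
        res = nca_rank(X, y, names, seed=1)
        assert res.importance[0] == 1.0
        assert np.all((res.importance >= 0) & (res.importance <= 1))

    def test_permuted_labels_destroy_the_signal(self):
        X, y, names = _planted(sep=0.2)
        zt = zscore(FeatureTable(X, names, y))
        res_sig = nca_rank(zt.values, zt.labels, zt.feature_names, seed=0)
        assert res_sig.ranked_names[0] == "planted"
        rng = np.random.default_rng(0)
        null_top, null_max = [], []
        for s in range(8):
            yp = rng.permutation(zt.labels)
            res = nca_rank(zt.values, yp, zt.feature_names, seed=s)
            null_top.append(res.ranked_names[0])
            null_max.append(res.raw_weights.max())
        # the planted feature loses its privileged rank under the null
        assert null_top.count("planted") <= 2
        # and typical null weights sit below the planted-case weight
        assert np.median(null_max) < res_sig.raw_weights.max()

    def test_nonfinite_rejected(self):
        X, y, names = _planted()
        X[0, 0] = np.nan
        with pytest.raises(ValueError):
            nca_rank(X, y, names)


class TestMRMR:
    def test_first_pick_maximizes_mi_on_discrete_toy(self):
        # 3 discrete features with known MI ordering, verified by brute force
        rng = np.random.default_rng(0)
        y = np.repeat([1, 2, 3], 30)
        f_strong = y.astype(float)                       # MI = H(y)
        f_weak = np.where(rng.random(90) < 0.5, y, 1).astype(float)
        f_null = rng.integers(0, 3, 90).astype(float)
        X = np.column_stack([f_null, f_weak, f_strong])

        def mi_brute(a, b):
            mi = 0.0
            for av in np.unique(a):
                for bv in np.unique(b):
                    p_ab = np.mean((a == av) & (b == bv))
                    if p_ab > 0:
                        mi += p_ab * np.log(p_ab / (np.mean(a == av)
                                                    * np.mean(b == bv)))
            return mi

        mis = [mi_brute(np.digitize(X[:, j], np.quantile(X[:, j],
                                                         [1/8*i for i in range(1, 8)])), y)
               for j in range(3)]
        assert np.argmax(mis) == 2
        res = mrmr_rank(X, y, ["null", "weak", "strong"], n_bins=8)
        assert res.ranked_names[0] == "strong"

    def test_duplicate_feature_penalized(self):
        X, y, names = _planted(noise_dim=5)
        X = np.column_stack([X, X[:, 0]])  # exact duplicate of planted
        names = names + ["planted_copy"]
        res = mrmr_rank(X, y, names)
        first = res.ranked_names[0]
        assert first in ("planted", "planted_copy")
        # the duplicate cannot be picked immediately after the original
        assert res.ranked_names[1] not in ("planted", "planted_copy")

    def test_deterministic(self):
        X, y, names = _planted()
        r1 = mrmr_rank(X, y, names)
        r2 = mrmr_rank(X, y, names)
        assert r1.ranked_names == r2.ranked_names

    def test_invalid_bins(self):
        X, y, names = _planted()
        with pytest.raises(ValueError):
            mrmr_rank(X, y, names, n_bins=1)


class TestLasso:
    def test_reaches_target_k_and_finds_planted(self):
        X, y, names = _planted(n=60, noise_dim=30, sep=0.5)
        zt = zscore(FeatureTable(X, names, y))
        res = lasso_select(zt.values, zt.labels, zt.feature_names, target_k=7)
        assert res.k == 7
        assert "planted" in res.selected

    def test_planted_enters_path_first(self):
        X, y, names = _planted(n=60, noise_dim=10, sep=0.3)
        zt = zscore(FeatureTable(X, names, y))
        res = lasso_select(zt.values, zt.labels, zt.feature_names, target_k=1)
        assert res.selected == ["planted"]


class TestSelectTopK:
    def test_identity_and_range(self):
        res = nca_rank(*_planted()[:2], seed=0)
        assert select_top_k(res, len(res.ranked_names)) == res.ranked_names
        with pytest.raises(ValueError):
            select_top_k(res, 0)
        with pytest.raises(ValueError):
            select_top_k(res, len(res.ranked_names) + 1)

    def test_tie_break_alphabetical(self):
        # equal importances: the ranking is built with name-order tie-break
        imp = np.array([0.5, 0.5, 0.5])
        names = ["b", "a", "c"]
        order = np.lexsort((names, -imp))
        assert [names[i] for i in order] == ["a", "b", "c"]


class TestWilcoxon:
    def test_exact_small_sample(self):
        assert ranksum_p([1, 2, 3], [10, 11, 12]) == pytest.approx(0.1)

    def test_identical_groups(self):
        assert ranksum_p([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_pairwise_structure(self):
        X, y, names = _planted()
        res = pairwise_wilcoxon(X, y, names)
        assert list(res.p_values.columns) == ["C1C2", "C1C3", "C2C3"]
        assert res.p_values.shape == (len(names), 3)
        assert ((res.p_values > 0) & (res.p_values <= 1)).all().all()
        # the planted feature separates the extreme classes decisively
        assert res.p_values.loc["planted", "C1C3"] < 1e-4

    def test_small_class_rejected(self):
        X = np.zeros((5, 2))
        y = np.array([1, 1, 2, 2, 3])
        with pytest.raises(ValueError):
            pairwise_wilcoxon(X, y)

    def test_null_false_positive_rate(self):
        rng = np.random.default_rng(12)
        X = rng.standard_normal((60, 100))
        y = np.repeat([1, 2, 3], 20)
        res = pairwise_wilcoxon(X, y)
        fpr = (res.p_values.values < 0.05).mean()
        assert 0.012 <= fpr <= 0.088  # 0.05 +/- 3 binomial sd on 300 tests
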