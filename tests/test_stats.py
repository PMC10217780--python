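"""Splitting, weighting, AUC, bootstrap and feature screening vs brute-force oracles."""

import numpy as np
import pytest
from scipy import stats as sps

from kgprodromal.stats import (AUCDistribution, SplitSpec, bootstrap_auc,
                               class_weights, compare_auc_distributions,
                               feature_mannwhitney, importance_percentiles,
                               roc_auc, split_train_test, top_features_by_type,
                               train_classifier)


def pair_counting_auc(scores, labels):
    """Brute-force oracle: P(case > control) + ½·P(tie) over all pairs."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestSplit:
    def test_stratification_arithmetic(self):
        y = np.array([1] * 10 + [0] * 90)
        train, test = split_train_test(100, y, SplitSpec(0.8, True, seed=4))
        assert len(train) == 80 and y[train].sum() == 8

    def test_deterministic_and_partitioning(self):
        y = np.array([1] * 20 + [0] * 30)
        a = split_train_test(50, y, SplitSpec(seed=7))
        b = split_train_test(50, y, SplitSpec(seed=7))
        np.testing.assert_array_equal(a[0], b[0])
        assert sorted(np.concatenate(a)) == list(range(50))
        assert not set(a[0]) & set(a[1])

    def test_tiny_class_rejected(self):
        with pytest.raises(ValueError):
            split_train_test(5, np.array([1, 0, 0, 0, 0]))


class TestClassWeights:
    def test_imbalanced_formula(self):
        y = np.array([1] * 10 + [0] * 990)
        w = class_weights(y)
        assert w[1] == pytest.approx(50.0)
        assert w[0] == pytest.approx(1000 / 1980)

    def test_balanced_gives_unit_weights(self):
        w = class_weights(np.array([0, 1, 0, 1]))
        assert w[0] == w[1] == 1.0

    def test_invariant_to_label_encoding(self):
        a = class_weights(np.array(["case"] * 3 + ["ctrl"] * 9))
        b = class_weights(np.array(["ctrl"] * 9 + ["case"] * 3))
        assert a == b

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            class_weights(np.zeros(5))


class TestTrainClassifier:
    @pytest.mark.parametrize("model", ["forest", "logistic"])
    def test_separable_data_perfect_training_auc(self, model):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(0, 0.1, (20, 2)), rng.normal(5, 0.1, (20, 2))])
        y = np.array([0] * 20 + [1] * 20)
        scorer = train_classifier(X, y, model=model, seed=1)
        assert roc_auc(scorer.scores(X), y) == 1.0
        assert scorer.importances.shape == (2,)

    def test_permuted_labels_give_chance_auc(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(200, 10))
        y = rng.permutation([1] * 100 + [0] * 100)
        tr, te = split_train_test(200, y, SplitSpec(seed=2))
        scorer = train_classifier(X[tr], y[tr], seed=3)
        assert 0.35 <= roc_auc(scorer.scores(X[te]), y[te]) <= 0.65

    def test_nan_features_rejected(self):
        X = np.array([[1.0, np.nan], [0.0, 1.0], [1.0, 0.0], [0.0, 0.0]])
        with pytest.raises(ValueError, match="NaN"):
            train_classifier(X, np.array([1, 0, 1, 0]))

    def test_reproducible_under_seed(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(60, 5))
        y = rng.integers(0, 2, 60)
        y[:2] = [0, 1]
        s1 = train_classifier(X, y, seed=11).scores(X)
        s2 = train_classifier(X, y, seed=11).scores(X)
        np.testing.assert_array_equal(s1, s2)


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_all_tied_scores(self):
        assert roc_auc([0.5] * 6, [0, 1, 0, 1, 0, 1]) == 0.5

    def test_worked_example(self):
        assert roc_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == pytest.approx(0.75)

    def test_matches_pair_counting_on_random_sets(self):
        rng = np.random.default_rng(12)
        for _ in range(100):
            n = int(rng.integers(4, 30))
            scores = rng.choice(np.linspace(0, 1, 7), size=n)  # force ties
            labels = rng.integers(0, 2, n)
            if len(np.unique(labels)) < 2:
                continue
            assert roc_auc(scores, labels) == pytest.approx(
                pair_counting_auc(scores, labels), abs=1e-12)

    def test_score_negation_symmetry(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(size=40)  # tie-free almost surely
        labels = rng.permutation([1] * 15 + [0] * 25)
        assert roc_auc(scores, labels) == pytest.approx(1 - roc_auc(-scores, labels))

    def test_mann_whitney_u_relation(self):
        rng = np.random.default_rng(4)
        scores = rng.normal(size=30)
        labels = rng.permutation([1] * 10 + [0] * 20)
        u = sps.mannwhitneyu(scores[labels == 1], scores[labels == 0]).statistic
        assert roc_auc(scores, labels) == pytest.approx(u / (10 * 20))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])


class TestBootstrapAuc:
    def test_perfect_scorer_degenerate_at_one(self):
        scores = np.array([0.1] * 30 + [0.9] * 30)
        labels = np.array([0] * 30 + [1] * 30)
        dist = bootstrap_auc(scores, labels, seed=5)
        assert dist.ci95 == (1.0, 1.0) and dist.mean == 1.0

    def test_constant_scores_degenerate_at_half(self):
        labels = np.array([0, 1] * 30)
        dist = bootstrap_auc(np.full(60, 0.5), labels, seed=5)
        assert dist.mean == 0.5 and dist.sd == 0.0

    def test_mean_tracks_full_sample_auc(self):
        rng = np.random.default_rng(9)
        labels = np.array([1] * 100 + [0] * 100)
        scores = np.concatenate([rng.normal(0.7, 0.3, 100), rng.normal(0.3, 0.3, 100)])
        dist = bootstrap_auc(scores, labels, n_boot=100, sample_size=50, seed=6)
        assert abs(dist.mean - roc_auc(scores, labels)) < 0.05

    def test_ci_within_replicate_range(self):
        rng = np.random.default_rng(10)
        labels = rng.permutation([1] * 40 + [0] * 40)
        dist = bootstrap_auc(rng.normal(size=80), labels, seed=7)
        assert dist.values.min() <= dist.ci95[0] <= dist.ci95[1] <= dist.values.max()
        assert np.all((dist.values >= 0) & (dist.values <= 1))


class TestFeatureMannWhitney:
    def test_identical_distributions_half_u(self):
        vals = np.tile(np.array([[1.0], [2.0], [3.0]]), (2, 1))
        labels = np.array([1, 1, 1, 0, 0, 0])
        df = feature_mannwhitney(vals, labels, ["f"])
        assert df.u_statistic.iloc[0] == pytest.approx(4.5)  # n1*n2/2

    def test_fully_separated_exact_p(self):
        vals = np.array([[1.0], [2.0], [3.0], [10.0], [11.0], [12.0]])
        labels = np.array([1, 1, 1, 0, 0, 0])
        df = feature_mannwhitney(vals, labels, ["f"])
        assert df.u_statistic.iloc[0] == 0.0
        assert df.p_value.iloc[0] == pytest.approx(0.1)  # 2/C(6,3) two-sided
        assert df.direction.iloc[0] == -1

    def test_label_identical_column_is_most_significant(self):
        rng = np.random.default_rng(2)
        labels = np.array([1] * 15 + [0] * 15)
        vals = rng.normal(size=(30, 4))
        vals[:, 2] = labels
        df = feature_mannwhitney(vals, labels, list("abcd"))
        assert df.p_value.idxmin() == 2

    def test_constant_column_flagged_p_one(self):
        vals = np.column_stack([np.ones(10), np.arange(10.0)])
        labels = np.array([1] * 5 + [0] * 5)
        df = feature_mannwhitney(vals, labels, ["const", "var"])
        row = df[df.node_id == "const"].iloc[0]
        assert row.p_value == 1.0 and row.constant

    def test_ranks_permute_within_type(self):
        rng = np.random.default_rng(6)
        labels = np.array([1] * 10 + [0] * 10)
        vals = rng.normal(size=(20, 6))
        types = {f: ("Disease" if i < 3 else "Symptom") for i, f in enumerate("abcdef")}
        df = feature_mannwhitney(vals, labels, list("abcdef"), types)
        for t in ("Disease", "Symptom"):
            assert sorted(df[df.node_type == t]["rank"]) == [1, 2, 3]


class TestImportanceReport:
    def test_all_equal_importances_sit_at_50(self):
        rep = importance_percentiles(np.ones(8), [f"f{i}" for i in range(8)])
        assert np.allclose(rep.percentile, 50.0)

    def test_unique_maximum_convention(self):
        rep = importance_percentiles(np.array([0.1, 0.2, 0.9, 0.3]),
                                     list("abcd"))
        # midrank convention: 100*(N-0.5)/N for the unique max
        assert rep.percentile.max() == pytest.approx(100 * 3.5 / 4)

    def test_top_k_truncated_and_sorted(self):
        rng = np.random.default_rng(1)
        ids = [f"f{i}" for i in range(40)]
        types = {f: "Disease" for f in ids}
        rep = importance_percentiles(rng.random(40), ids, types)
        top = top_features_by_type(rep, "Disease", k=15)
        assert len(top) == 15
        assert list(top.importance) == sorted(top.importance, reverse=True)


class TestCompareDistributions:
    def test_identical_distributions_zero_ks(self):
        a = AUCDistribution(np.linspace(0.6, 0.8, 100))
        stat, p = compare_auc_distributions(a, a, test="ks")
        assert stat == 0.0 and p == 1.0

    def test_shifted_distributions_detected(self):
        rng = np.random.default_rng(0)
        a = AUCDistribution(rng.normal(0.6, 0.05, 100))
        b = AUCDistribution(a.values + 0.2)
        _, p = compare_auc_distributions(a, b, test="t")
        assert p < 1e-3

    def test_symmetric_p_value(self):
        rng = np.random.default_rng(1)
        a = AUCDistribution(rng.normal(0.6, 0.05, 100))
        b = AUCDistribution(rng.normal(0.65, 0.05, 100))
        _, p_ab = compare_auc_distributions(a, b)
        _, p_ba = compare_auc_distributions(b, a)
        assert p_ab == pytest.approx(p_ba)

    def test_mismatched_lengths_rejected(self):
        a = AUCDistribution(np.full(100, 0.6))
        b = AUCDistribution(np.full(50, 0.6))
        with pytest.raises(ValueError):
            compare_auc_distributions(a, b)
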