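import numpy as np
import pytest

from miresponse.classifier import (
    ConfusionCounts,
    ModelSpec,
    compare_auc,
    covariate_auc,
    ddct_fold_change,
    kfold_cv,
    metrics,
    predict,
    roc_auc,
    scale_features,
    train_svm_rbf,
)

from oracles import pair_count_auc, qp_svm_rbf


class TestScaling:
    def test_zscore_population_sd(self):
        train = np.array([[1.0], [2.0], [3.0]])
        scaled, _, _ = scale_features(train, mode="zscore")
        assert np.allclose(scaled.ravel(), [-1.2247448, 0.0, 1.2247448],
                           atol=1e-6)

    def test_none_is_identity(self):
        train = np.arange(6.0).reshape(3, 2)
        scaled, test, _ = scale_features(train, train.copy(), mode="none")
        assert np.array_equal(scaled, train)
        assert np.array_equal(test, train)

    def test_statistics_come_from_train_only(self):
        train = np.array([[0.0], [1.0]])
        test = np.array([[2.0]])
        _, test_s, _ = scale_features(train, test, mode="minmax")
        # outside the training range: allowed to exceed [0, 1]
        assert test_s[0, 0] == pytest.approx(2.0)

    def test_zero_variance_feature_warns_and_zeroes(self):
        train = np.array([[1.0, 5.0], [1.0, 6.0]])
        with pytest.warns(UserWarning):
            scaled, _, _ = scale_features(train, mode="zscore")
        assert np.allclose(scaled[:, 0], 0.0)


class TestSVM:
    def _separated(self, rng, gap=5.0, sd=0.1, n=6):
        x = np.vstack([rng.normal(gap, sd, (n, 2)),
                       rng.normal(-gap, sd, (n, 2))])
        y = np.array([1] * n + [-1] * n)
        return x, y

    def test_separable_clusters_fit_perfectly(self):
        x, y = self._separated(np.random.default_rng(0))
        model = train_svm_rbf(x, y, ModelSpec(c=1.0, gamma=1.0,
                                              scale_mode="none"))
        pred, _ = predict(model, x)
        assert np.array_equal(pred, y)

    def test_xor_pattern_separable_with_rbf(self):
        x = np.array([[0.0, 0.0], [1.0, 1.0], [0.0, 1.0], [1.0, 0.0]])
        y = np.array([1, 1, -1, -1])
        model = train_svm_rbf(x, y, ModelSpec(c=1e3, gamma=1.0,
                                              scale_mode="none"))
        pred, _ = predict(model, x)
        assert np.array_equal(pred, y)

    def test_decision_matches_qp_oracle(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(14, 3))
        y = np.where(x[:, 0] + 0.5 * x[:, 1] + rng.normal(0, 0.3, 14) > 0, 1, -1)
        if len(np.unique(y)) < 2:
            pytest.skip("degenerate draw")
        spec = ModelSpec(c=2.0, gamma=0.7, scale_mode="none")
        model = train_svm_rbf(x, y, spec)
        _, _, oracle_decision = qp_svm_rbf(x, y, c=2.0, gamma=0.7)
        grid = rng.normal(size=(20, 3))
        assert np.allclose(model.decision_function(grid),
                           oracle_decision(grid), atol=1e-3)

    def test_duplicating_training_points_keeps_decision(self):
        rng = np.random.default_rng(4)
        x, y = self._separated(rng, gap=2.0, sd=0.5)
        spec = ModelSpec(c=1.0, gamma=0.5, scale_mode="none")
        m1 = train_svm_rbf(x, y, spec)
        # duplicating every point doubles each alpha bound's usage but the
        # optimal separating function is unchanged
        m2 = train_svm_rbf(np.vstack([x, x]), np.hstack([y, y]),
                           ModelSpec(c=0.5, gamma=0.5, scale_mode="none"))
        grid = rng.normal(0, 2.5, size=(25, 2))
        assert np.allclose(m1.decision_function(grid),
                           m2.decision_function(grid), atol=1e-4)

    def test_mirrored_point_gets_opposite_label(self):
        x = np.array([[1.0, 0.0], [-1.0, 0.0]])
        y = np.array([1, -1])
        model = train_svm_rbf(x, y, ModelSpec(c=10.0, gamma=1.0,
                                              scale_mode="none"))
        la, _ = predict(model, np.array([[2.0, 0.0]]))
        lb, _ = predict(model, np.array([[-2.0, 0.0]]))
        assert la[0] == 1 and lb[0] == -1

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            train_svm_rbf(np.zeros((4, 2)), np.ones(4, dtype=int))

    def test_dimension_mismatch_rejected(self):
        x, y = self._separated(np.random.default_rng(0))
        model = train_svm_rbf(x, y)
        with pytest.raises(ValueError):
            predict(model, np.zeros((2, 5)))


class TestMetrics:
    def test_hand_confusion_table(self):
        sens, spec, acc = metrics(ConfusionCounts(tp=3, tn=4, fp=0, fn=1))
        assert sens == 0.75
        assert spec == 1.0
        assert acc == 7 / 8

    def test_all_positive_all_correct(self):
        with pytest.warns(UserWarning):
            sens, spec, acc = metrics(ConfusionCounts(tp=5, tn=0, fp=0, fn=0))
        assert acc == 1.0 and sens == 1.0
        assert np.isnan(spec)

    def test_class_swap_swaps_sensitivity_and_specificity(self):
        c = ConfusionCounts(tp=3, tn=5, fp=2, fn=1)
        swapped = ConfusionCounts(tp=c.tn, tn=c.tp, fp=c.fn, fn=c.fp)
        s1, p1, a1 = metrics(c)
        s2, p2, a2 = metrics(swapped)
        assert (s1, p1) == (p2, s2) and a1 == a2

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(tp=-1, tn=0, fp=0, fn=0)


class TestROC:
    def test_perfect_ranking(self):
        _, auc = roc_auc(np.array([0.9, 0.8, 0.2, 0.1]),
                         np.array([1, 1, -1, -1]))
        assert auc == 1.0

    def test_hand_case_three_quarters(self):
        _, auc = roc_auc(np.array([0.9, 0.4, 0.8, 0.1]),
                         np.array([1, 1, -1, -1]))
        assert auc == pytest.approx(0.75)

    def test_matches_pair_counting_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            n = int(rng.integers(6, 30))
            y = np.array([1] * (n // 2) + [-1] * (n - n // 2))
            s = rng.choice(np.linspace(0, 1, 7), size=n)  # force ties
            _, auc = roc_auc(s, y)
            assert auc == pytest.approx(pair_count_auc(s, y), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc(np.array([0.1, 0.2]), np.array([1, 1]))


class TestCrossValidation:
    def test_separable_cohort_is_perfect(self):
        rng = np.random.default_rng(1)
        x = np.vstack([rng.normal(5, 0.1, (6, 4)), rng.normal(-5, 0.1, (6, 4))])
        y = np.array([1] * 6 + [-1] * 6)
        rep = kfold_cv(x, y, k=5, repeats=5, seed=0)
        assert rep.mean_accuracy == 1.0
        assert rep.mean_auc == 1.0
        assert np.allclose(rep.repeats["accuracy"], 1.0)

    def test_same_seed_reproduces_folds_and_metrics(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(12, 4))
        y = np.array([1] * 6 + [-1] * 6)
        r1 = kfold_cv(x, y, seed=5)
        r2 = kfold_cv(x, y, seed=5)
        assert r1.repeats.equals(r2.repeats)
        assert all(f1.test_index == f2.test_index
                   for f1, f2 in zip(r1.folds, r2.folds))

    def test_metrics_recomputable_from_stored_counts(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(12, 3))
        y = np.array([1] * 6 + [-1] * 6)
        rep = kfold_cv(x, y, k=5, repeats=2, seed=1)
        for r in range(2):
            counts = ConfusionCounts(0, 0, 0, 0)
            for f in rep.folds:
                if f.repeat == r:
                    counts = counts + f.counts
            _, _, acc = metrics(counts)
            assert acc == pytest.approx(rep.repeats.loc[r, "accuracy"])

    def test_label_permutation_null_accuracy_near_half(self):
        rng = np.random.default_rng(42)
        accs = []
        for i in range(200):
            x = rng.normal(size=(12, 4))
            y = np.array([1] * 6 + [-1] * 6)
            accs.append(kfold_cv(x, y, k=5, repeats=1, seed=i).mean_accuracy)
        assert 0.35 <= float(np.mean(accs)) <= 0.65

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            kfold_cv(np.zeros((3, 2)), np.array([1, -1, 1]), k=5)


class TestCompareAUC:
    def _scores(self, rng, n=40, gap=1.0):
        y = np.array([1] * (n // 2) + [-1] * (n // 2))
        a = rng.normal(0, 1, n) + gap * (y == 1)
        return y, a

    def test_identical_scores_give_p_one(self):
        y, a = self._scores(np.random.default_rng(0))
        out = compare_auc(a, a.copy(), y)
        assert out["p_value"] == 1.0

    def test_symmetry_in_argument_order(self):
        rng = np.random.default_rng(1)
        y, a = self._scores(rng)
        b = a + rng.normal(0, 0.8, len(a))
        assert (compare_auc(a, b, y)["p_value"]
                == pytest.approx(compare_auc(b, a, y)["p_value"], rel=1e-12))

    def test_power_against_a_large_auc_gap(self):
        rng = np.random.default_rng(7)
        rejections = 0
        n_sim = 100
        for _ in range(n_sim):
            n = 120
            y = np.array([1] * 60 + [-1] * 60)
            informative = rng.normal(0, 1, n) + 1.3 * (y == 1)  # AUC ~ 0.82
            noise = rng.normal(0, 1, n) + 0.2 * (y == 1)        # AUC ~ 0.56
            if compare_auc(informative, noise, y)["p_value"] < 0.05:
                rejections += 1
        assert rejections / n_sim > 0.8

    def test_degenerate_variance_not_computable(self):
        y = np.array([1, 1, -1, -1])
        a = np.array([1.0, 1.0, 0.0, 0.0])   # AUC 1, zero variance
        b = np.array([0.0, 0.0, 1.0, 1.0])   # AUC 0
        with pytest.warns(UserWarning):
            out = compare_auc(a, b, y)
        assert np.isnan(out["p_value"])


class TestCovariateAUC:
    def test_orientation_flipped_to_at_least_half(self):
        y = np.array([1, 1, -1, -1])
        auc, sign = covariate_auc(np.array([0.1, 0.2, 0.8, 0.9]), y)
        assert auc == 1.0 and sign == -1


class TestDdCt:
    def test_hand_case(self):
        assert ddct_fold_change(20, 18, 22, 18) == pytest.approx(4.0)

    def test_equal_dct_gives_unity(self):
        assert ddct_fold_change(21, 19, 23, 21) == pytest.approx(1.0)

    def test_one_cycle_halves_fold(self):
        f1 = ddct_fold_change(20, 18, 22, 18)
        f2 = ddct_fold_change(21, 18, 22, 18)
        assert f2 == pytest.approx(f1 / 2)

    def test_nonpositive_ct_rejected(self):
        with pytest.raises(ValueError):
            ddct_fold_change(0, 18, 22, 18)
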