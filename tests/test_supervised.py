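"""Model fitting contract, metrics, VIP scores and panel selection."""

import numpy as np
import pytest

from metabotype import (
    ConfusionMatrix,
    ModelSpec,
    PLSDAClassifier,
    balanced_accuracy,
    fit_model,
    predict_confusion,
    random_undersample,
    regression_metrics,
    select_vip,
    vip_scores,
)
from metabotype.supervised import _tally


def separable_toy(n=60, p=4, gap=8.0, seed=0):
    rng = np.random.default_rng(seed)
    half = n // 2
    X = rng.normal(size=(n, p))
    X[:half, 0] += gap
    y = np.array(["A"] * half + ["B"] * (n - half), dtype=object)
    return X, y


class TestFitModel:
    @pytest.mark.parametrize("kind,grid", [
        ("plsda", {"n_components": [1, 2]}),
        ("svm_linear", {"C": [1.0, 10.0]}),
        ("random_forest", {"n_estimators": [50], "max_features": ["sqrt"]}),
    ])
    def test_separable_training_accuracy_perfect(self, kind, grid):
        X, y = separable_toy()
        assert X[y == "A", 0].min() > X[y == "B", 0].max()  # genuinely separable
        model = fit_model(X, y, ModelSpec(kind, grid, 7, 0))
        cm = predict_confusion(model, X, y)
        assert balanced_accuracy(cm) == 1.0

    def test_single_class_rejected(self):
        X = np.random.default_rng(0).normal(size=(20, 3))
        y = np.array(["A"] * 20, dtype=object)
        with pytest.raises(ValueError, match="degenerate"):
            fit_model(X, y, ModelSpec("plsda", {"n_components": [1]}, 7, 0))

    def test_too_few_samples_for_folds(self):
        X, y = separable_toy(n=6)
        with pytest.raises(ValueError, match="cv_folds"):
            fit_model(X, y, ModelSpec("plsda", {"n_components": [1, 2]}, 7, 0))

    def test_rank_one_signal_selects_few_components(self):
        """Grid search on a rank-1 class signal prefers compact models."""
        small = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            n = 70
            latent = rng.normal(size=n)
            y = np.where(latent > 0, "A", "B").astype(object)
            X = np.outer(latent, rng.normal(size=10)) + 0.5 * rng.normal(size=(n, 10))
            model = fit_model(
                X, y, ModelSpec("plsda", {"n_components": list(range(1, 8))}, 7, seed)
            )
            small += model.chosen_params["n_components"] <= 2
        assert small >= 90

    def test_deterministic_given_seed(self):
        X, y = separable_toy(gap=1.0)
        m1 = fit_model(X, y, ModelSpec("plsda", {"n_components": [1, 2, 3]}, 7, 5))
        m2 = fit_model(X, y, ModelSpec("plsda", {"n_components": [1, 2, 3]}, 7, 5))
        assert m1.chosen_params == m2.chosen_params
        assert m1.cv_score == m2.cv_score


class TestConfusionAndBalancedAccuracy:
    def test_perfect_predictor(self):
        X, y = separable_toy(n=20, gap=5.0)
        model = fit_model(X, y, ModelSpec("plsda", {"n_components": [1]}, 5, 0))
        cm = predict_confusion(model, X, y, class_names=("A", "B"))
        assert cm.counts.tolist() == [[10, 0], [0, 10]]

    def test_constant_predictor_tally_and_ba(self):
        pred = np.array(["A"] * 20, dtype=object)
        actual = np.array(["A"] * 10 + ["B"] * 10, dtype=object)
        cm = _tally(pred, actual, ("A", "B"))
        assert cm.counts.tolist() == [[10, 10], [0, 0]]
        assert balanced_accuracy(cm) == pytest.approx(0.5)

    def test_hand_built_tally(self):
        pred = np.array(["A", "B", "A", "B", "A", "A"], dtype=object)
        actual = np.array(["A", "A", "B", "B", "A", "B"], dtype=object)
        cm = _tally(pred, actual, ("A", "B"))
        # manual count: TP=2 (pos predicted pos), FP=2, FN=1, TN=1
        assert cm.counts.tolist() == [[2, 2], [1, 1]]
        assert cm.total == 6

    @pytest.mark.parametrize("counts,expected", [
        ([[50, 0], [0, 50]], 1.0),
        ([[40, 20], [10, 30]], 0.7),
        ([[10, 10], [0, 0]], 0.5),
    ])
    def test_balanced_accuracy_values(self, counts, expected):
        cm = ConfusionMatrix(np.array(counts), ("A", "B"))
        assert balanced_accuracy(cm) == pytest.approx(expected)

    def test_rebalancing_invariance(self):
        """Scaling each actual class's column leaves balanced accuracy fixed."""
        cm1 = ConfusionMatrix(np.array([[40, 20], [10, 30]]), ("A", "B"))
        cm2 = ConfusionMatrix(np.array([[400, 2], [100, 3]]), ("A", "B"))
        assert balanced_accuracy(cm1) == pytest.approx(balanced_accuracy(cm2))

    def test_absent_class_raises(self):
        cm = ConfusionMatrix(np.array([[5, 0], [3, 0]]), ("A", "B"))
        with pytest.raises(ValueError):
            balanced_accuracy(cm)


class TestRandomUndersample:
    def test_majority_reduced_to_minority_size(self):
        labels = np.array(["young"] * 524 + ["old"] * 148, dtype=object)
        idx = random_undersample(labels, seed=0)
        assert len(idx) == 296
        assert (labels[idx] == "old").sum() == 148
        assert (labels[idx] == "young").sum() == 148

    def test_balanced_input_untouched(self):
        labels = np.array(["A"] * 50 + ["B"] * 50, dtype=object)
        assert len(random_undersample(labels, seed=1)) == 100

    def test_seeds_differ_minority_kept(self):
        labels = np.array(["A"] * 20 + ["B"] * 5, dtype=object)
        i1 = random_undersample(labels, seed=1)
        i2 = random_undersample(labels, seed=2)
        assert len(i1) == len(i2) == 10
        assert set(np.where(labels == "B")[0]) <= set(i1)
        assert not np.array_equal(i1, i2)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            random_undersample(np.array(["A", "A"]), seed=0)


class TestRegressionMetrics:
    def test_perfect_prediction(self):
        y = np.array([1.0, 2.0, 3.0])
        m = regression_metrics(y, y)
        assert m.q2 == pytest.approx(1.0) and m.rmsep == pytest.approx(0.0)

    def test_mean_prediction_gives_zero_q2(self):
        y = np.array([1.0, 2.0, 3.0, 6.0])
        m = regression_metrics(y, np.full(4, y.mean()))
        assert m.q2 == pytest.approx(0.0)

    def test_constant_truth_q2_undefined(self):
        m = regression_metrics([0.0, 0.0], [3.0, 4.0])
        assert m.rmsep == pytest.approx(np.sqrt(25 / 2))
        assert m.q2 is None

    def test_negative_q2_attainable(self):
        y = np.array([1.0, 2.0, 3.0])
        m = regression_metrics(y, y[::-1] * 3)
        assert m.q2 < 0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            regression_metrics([1.0], [1.0, 2.0])


def fit_pls_toy(X, y, ncomp):
    return fit_model(
        np.asarray(X, dtype=float),
        np.asarray(y),
        ModelSpec("plsr", {"n_components": [ncomp]}, 2, 0),
    )


class TestVIP:
    def test_equal_weights_all_one(self):
        """One component with symmetric informative features: VIP all 1."""
        rng = np.random.default_rng(0)
        t = rng.normal(size=200)
        X = np.column_stack([t, t, t, t]) + 0.01 * rng.normal(size=(200, 4))
        model = fit_pls_toy(X, t, 1)
        vips = vip_scores(model)
        assert np.allclose([v.vip for v in vips], 1.0, atol=1e-2)

    def test_single_informative_feature_closed_form(self):
        """Weight concentrated on one of p features gives VIP = (sqrt(p), 0...)."""
        rng = np.random.default_rng(1)
        t = rng.normal(size=300)
        X = np.column_stack([t] + [rng.normal(size=300) * 1e-8 for _ in range(4)])
        model = fit_pls_toy(X, t, 1)
        vips = np.array([v.vip for v in vip_scores(model)])
        assert vips[0] == pytest.approx(np.sqrt(5), rel=1e-3)
        assert np.all(vips[1:] < 1e-3)

    def test_mean_square_is_one(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(80, 12))
        y = X @ rng.normal(size=12) + rng.normal(size=80)
        for ncomp in (1, 2, 4):
            vips = np.array([v.vip for v in vip_scores(fit_pls_toy(X, y, ncomp))])
            assert np.mean(vips**2) == pytest.approx(1.0, abs=1e-8)

    def test_matches_brute_force_formula(self):
        """VIP from the fitted model equals a from-scratch recomputation."""
        rng = np.random.default_rng(3)
        X = rng.normal(size=(50, 6))
        y = X[:, 0] + 0.5 * X[:, 3] + 0.2 * rng.normal(size=50)
        model = fit_pls_toy(X, y, 3)
        pls = model.estimator
        W, T, Q = pls.x_weights_, pls.x_scores_, pls.y_loadings_
        p, A = W.shape
        expected = np.zeros(p)
        ss = [float(Q[0, a] ** 2 * T[:, a] @ T[:, a]) for a in range(A)]
        for j in range(p):
            acc = sum(
                ss[a] * (W[j, a] / np.linalg.norm(W[:, a])) ** 2 for a in range(A)
            )
            expected[j] = np.sqrt(p * acc / sum(ss))
        got = np.array([v.vip for v in vip_scores(model)])
        assert np.allclose(got, expected, atol=1e-10)

    def test_planted_feature_maximal(self):
        wins = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(100, 8))
            y = np.where(X[:, 5] + 0.7 * rng.normal(size=100) > 0, "A", "B").astype(object)
            model = fit_model(X, y, ModelSpec("plsda", {"n_components": [2]}, 5, seed))
            vips = vip_scores(model)
            wins += int(np.argmax([v.vip for v in vips]) == 5)
        assert wins >= 95

    def test_non_pls_rejected(self):
        X, y = separable_toy(n=30)
        model = fit_model(X, y, ModelSpec("svm_linear", {"C": [1.0]}, 5, 0))
        with pytest.raises(ValueError, match="PLS"):
            vip_scores(model)

    def test_plsda_exposes_vip(self):
        X, y = separable_toy(n=40, gap=2.0)
        clf = PLSDAClassifier(n_components=2).fit(X, y)
        vips = np.array([v.vip for v in vip_scores(clf)])
        assert np.mean(vips**2) == pytest.approx(1.0, abs=1e-8)
        assert np.argmax(vips) == 0


class TestSelectVIP:
    def test_strictly_greater_than_rule(self):
        from metabotype.supervised import VIPScore

        vips = [VIPScore("a", 1.0, False), VIPScore("b", 1.2, True), VIPScore("c", 0.8, False)]
        assert select_vip(vips) == ["b"]
        assert select_vip([VIPScore("a", 1.0, False)]) == []

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            select_vip([])
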