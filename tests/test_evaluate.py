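import numpy as np
import pandas as pd
import pytest

from gliomics.evaluate import (
    AveragedCurve,
    average_curves,
    best_slice,
    class_weights,
    fit_weighted_logistic,
    optimal_cutoff,
    repeated_split_evaluate,
    select_exemplars,
    u_test_and_top_third,
    zscore_columns,
)


class TestZScore:
    def test_closed_form(self):
        out = zscore_columns(np.array([[1.0], [2.0], [3.0]]))
        np.testing.assert_allclose(out[:, 0], [-1.2247, 0.0, 1.2247], atol=1e-4)

    def test_idempotent(self, rng):
        X = rng.normal(3, 5, (40, 4))
        once = zscore_columns(X)
        twice = zscore_columns(once)
        np.testing.assert_allclose(once, twice, atol=1e-12)

    def test_postcondition(self, rng):
        X = rng.normal(-2, 7, (50, 6))
        out = zscore_columns(X)
        np.testing.assert_allclose(out.mean(0), 0.0, atol=1e-12)
        np.testing.assert_allclose(out.std(0), 1.0, atol=1e-12)

    def test_zero_variance_column_named(self):
        X = pd.DataFrame({"good": [1.0, 2.0], "flat": [3.0, 3.0]})
        with pytest.raises(ValueError, match="flat"):
            zscore_columns(X)


class TestClassWeights:
    def test_formula(self):
        y = [1] * 4 + [0] * 12
        w = class_weights(y)
        assert w[1] == pytest.approx(2.0)
        assert w[0] == pytest.approx(16 / 24)

    def test_balanced_gives_ones(self):
        w = class_weights([0, 0, 1, 1])
        assert w[0] == w[1] == 1.0

    def test_weighted_masses_equal(self, rng):
        y = (rng.random(100) < 0.3).astype(int)
        w = class_weights(y)
        n1, n0 = y.sum(), (1 - y).sum()
        assert w[1] * n1 == pytest.approx(w[0] * n0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            class_weights([1, 1, 1])


class TestWeightedLogistic:
    def test_separable_boundary(self):
        X = np.linspace(-2, 2, 40).reshape(-1, 1)
        y = (X[:, 0] > 0).astype(int)
        model = fit_weighted_logistic(X, y)
        assert model.predict_proba(np.array([[-0.5]]))[0] < 0.5
        assert model.predict_proba(np.array([[0.5]]))[0] > 0.5

    def test_balanced_weights_match_unweighted(self, rng):
        X = rng.normal(0, 1, (100, 3))
        y = np.repeat([0, 1], 50)
        m1 = fit_weighted_logistic(X, y, weights=class_weights(y))
        m2 = fit_weighted_logistic(X, y, weights=None)
        np.testing.assert_allclose(m1.coefficients, m2.coefficients, atol=1e-6)

    def test_parameter_recovery(self):
        rng = np.random.default_rng(0)
        theta = np.array([1.5, -2.0])
        X = rng.normal(0, 1, (2000, 2))
        p = 1 / (1 + np.exp(-(X @ theta)))
        y = (rng.random(2000) < p).astype(int)
        model = fit_weighted_logistic(X, y)
        np.testing.assert_allclose(model.coefficients, theta, rtol=0.15)

    def test_duplicate_balancing_equivalence(self, rng):
        # weighting an imbalanced design == physically duplicating the
        # minority class to balance
        X = rng.normal(0, 1, (30, 2))
        y = np.array([1] * 10 + [0] * 20)
        m_w = fit_weighted_logistic(X, y, weights=class_weights(y))
        X_dup = np.vstack([X, X[:10]])
        y_dup = np.concatenate([y, np.ones(10, dtype=int)])
        m_dup = fit_weighted_logistic(X_dup, y_dup, weights=None)
        np.testing.assert_allclose(m_w.coefficients, m_dup.coefficients, atol=5e-3)


class TestAveragedCurves:
    def test_identity_on_copies(self):
        x = np.array([0.0, 0.5, 1.0])
        y = np.array([0.0, 0.8, 1.0])
        t = np.array([0.9, 0.5, 0.1])
        avg = average_curves([(x, y, t)] * 5, "ROC", grid_points=3)
        np.testing.assert_allclose(avg.y, y)

    def test_pointwise_mean(self):
        grid = np.linspace(0, 1, 101)
        c1 = (grid, grid.copy(), np.zeros(101))
        c2 = (grid, np.ones(101), np.zeros(101))
        avg = average_curves([c1, c2], "ROC")
        np.testing.assert_allclose(avg.y, (grid + 1) / 2)

    def test_grid_refinement_stable(self, rng):
        curves = []
        for _ in range(20):
            fpr = np.sort(np.concatenate([[0.0], rng.random(10), [1.0]]))
            tpr = np.sort(np.concatenate([[0.0], rng.random(10), [1.0]]))
            thr = np.linspace(1, 0, 12)
            curves.append((fpr, tpr, thr))
        a101 = average_curves(curves, "ROC", 101).auc()
        a1001 = average_curves(curves, "ROC", 1001).auc()
        assert abs(a101 - a1001) < 0.005

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            average_curves([], "ROC")


class TestOptimalCutoff:
    def test_forced_arithmetic(self):
        curve = AveragedCurve(
            "ROC",
            x=np.array([0.0, 0.2, 1.0]),
            y=np.array([0.0, 0.9, 1.0]),
            thresholds=np.array([1.0, 0.5, 0.0]),
        )
        thr, point = optimal_cutoff(curve)
        assert point == (0.2, 0.9)
        assert thr == 0.5

    def test_perfect_classifier(self):
        curve = AveragedCurve(
            "ROC",
            x=np.array([0.0, 0.0, 1.0]),
            y=np.array([0.0, 1.0, 1.0]),
            thresholds=np.array([1.0, 0.6, 0.0]),
        )
        _, point = optimal_cutoff(curve)
        assert point == (0.0, 1.0)

    def test_brute_force_scan_agrees(self, rng):
        for kind in ("ROC", "PR"):
            x = np.sort(rng.random(50))
            y = rng.random(50)
            t = rng.random(50)
            curve = AveragedCurve(kind, x, y, t)
            thr, point = optimal_cutoff(curve)
            corner = (0.0, 1.0) if kind == "ROC" else (1.0, 1.0)
            dists = [np.hypot(a - corner[0], b - corner[1]) for a, b in zip(x, y)]
            assert np.hypot(point[0] - corner[0], point[1] - corner[1]) == pytest.approx(
                min(dists)
            )


class TestRepeatedSplit:
    def test_perfectly_separable(self, rng):
        X = np.concatenate([rng.normal(-5, 0.1, 40), rng.normal(5, 0.1, 40)])
        y = np.repeat([0, 1], 40)
        res = repeated_split_evaluate(X.reshape(-1, 1), y, repetitions=50)
        assert res.summary["accuracy"]["mean"] == 1.0
        assert res.summary["roc_auc"]["mean"] == 1.0

    def test_null_auc_half(self, rng):
        # a single finite dataset can sit ~1 SD from 0.5; average the
        # null AUC over a few independent label permutations
        X = rng.normal(0, 1, (120, 5))
        y = (rng.random(120) < 0.3).astype(int)
        aucs = []
        for _ in range(5):
            y_perm = rng.permutation(y)
            res = repeated_split_evaluate(X, y_perm, repetitions=60, master_seed=5)
            aucs.append(res.summary["roc_auc"]["mean"])
        assert abs(np.mean(aucs) - 0.5) < 0.05

    def test_ci_brackets_mean(self, rng):
        X = rng.normal(0, 1, (60, 3))
        y = (rng.random(60) < 0.4).astype(int)
        res = repeated_split_evaluate(X, y, repetitions=30)
        for metric in res.summary.values():
            lo, hi = metric["ci95"]
            assert lo <= metric["mean"] <= hi

    def test_deterministic(self, rng):
        X = rng.normal(0, 1, (50, 3))
        y = (X[:, 0] > 0).astype(int)
        r1 = repeated_split_evaluate(X, y, repetitions=20, master_seed=3)
        r2 = repeated_split_evaluate(X, y, repetitions=20, master_seed=3)
        assert r1.metrics.equals(r2.metrics)
        np.testing.assert_array_equal(r1.importance, r2.importance)
        np.testing.assert_array_equal(
            r1.mean_probability.fillna(-1), r2.mean_probability.fillna(-1)
        )

    def test_label_permutation_accuracy_near_majority(self):
        rng = np.random.default_rng(9)
        X = rng.normal(0, 1, (100, 4))
        y = np.array([1] * 30 + [0] * 70)
        y_perm = rng.permutation(y)
        res = repeated_split_evaluate(X, y_perm, repetitions=100, master_seed=2)
        # class weighting pushes decisions toward chance on null data;
        # accuracy must not be meaningfully above the no-information rate
        assert res.summary["accuracy"]["mean"] < 0.7 + 0.05

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            repeated_split_evaluate(np.zeros((10, 1)), np.ones(10, dtype=int))


class TestHighlighting:
    @pytest.mark.parametrize("k,quota", [(11, 3), (6, 2)])
    def test_top_third_quota(self, k, quota, rng):
        X = pd.DataFrame(
            rng.normal(0, 1, (400, k)), columns=[f"f{j}" for j in range(k)]
        )
        y = (rng.random(400) < 0.5).astype(int)
        # make the top-|importance| features strongly label-dependent
        importances = pd.Series(
            np.linspace(10, 1, k), index=X.columns
        )
        for feat in X.columns[:quota]:
            X.loc[y == 1, feat] += 3.0
        out = u_test_and_top_third(importances, X, y)
        assert set(out) == set(X.columns[:quota])

    def test_null_features_rarely_highlighted(self, rng):
        hits = 0
        for trial in range(20):
            X = pd.DataFrame(
                rng.normal(0, 1, (60, 6)), columns=[f"f{j}" for j in range(6)]
            )
            y = (rng.random(60) < 0.5).astype(int)
            importances = pd.Series(rng.normal(0, 1, 6), index=X.columns)
            hits += len(u_test_and_top_third(importances, X, y))
        # expected false highlights per trial <= alpha * quota = 0.1
        assert hits <= 10


class TestExemplars:
    def test_single_patient_is_both_extremes(self):
        features = pd.DataFrame({"f": [1.0]}, index=["P1"])
        probs = pd.Series([0.7], index=["P1"])
        masks = {"P1": np.ones((4, 4, 3), dtype=bool)}
        out = select_exemplars(features, ["f"], probs, masks)
        assert out["features"]["f"]["max"]["patient_id"] == "P1"
        assert out["features"]["f"]["min"]["patient_id"] == "P1"
        assert out["model"]["max"]["patient_id"] == "P1"

    def test_single_slice_mask(self):
        mask = np.zeros((5, 5, 4), dtype=bool)
        mask[:, :, 2] = True
        assert best_slice(mask) == 2

    def test_slice_argmax_matches_bruteforce(self, rng):
        mask = rng.random((6, 6, 8)) < 0.3
        areas = [int(mask[:, :, k].sum()) for k in range(8)]
        assert best_slice(mask) == int(np.argmax(areas))

    def test_tie_takes_lowest_slice(self):
        mask = np.zeros((4, 4, 5), dtype=bool)
        mask[0, 0, 1] = True
        mask[0, 0, 3] = True
        assert best_slice(mask) == 1
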