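import warnings

import numpy as np
import pandas as pd
import pytest

from microclim.tree import (cv_plan, evaluate, fit_cart, gini, grow,
                            grow_regression, one_se_select, predict,
                            predict_regression, prune_path,
                            rolling_origin_cv, temporal_holdout)


class TestGini:
    @pytest.mark.parametrize("counts,expected", [
        ((10, 0), 0.0), ((5, 5), 0.5), ((2, 1, 1), 0.625)])
    def test_values(self, counts, expected):
        assert gini(counts) == pytest.approx(expected)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            gini((0, 0))


def _brute_force_root(X, y, min_leaf=1):
    """Exhaustive best root split over all feature/midpoint pairs."""
    n, p = X.shape
    classes = list(pd.unique(y))
    best, best_score = None, np.inf
    for j in range(p):
        xs = np.unique(X[:, j])
        for a, b in zip(xs[:-1], xs[1:]):
            thr = (a + b) / 2
            left, right = y[X[:, j] <= thr], y[X[:, j] > thr]
            if len(left) < min_leaf or len(right) < min_leaf:
                continue
            score = sum(
                len(part) * gini([np.sum(part == c) for c in classes])
                for part in (left, right)) / n
            if score < best_score - 1e-12:
                best_score, best = score, (j, thr)
    return best


class TestGrow:
    def test_single_class_yields_single_leaf(self):
        X = np.arange(10.0).reshape(-1, 1)
        root, order = grow(X, np.array(["a"] * 10), min_split=2,
                           min_leaf=1)
        assert root.is_leaf
        assert predict(root, X, order).tolist() == ["a"] * 10

    def test_perfectly_separable_1d(self):
        x = np.concatenate([np.linspace(-2, -0.1, 10),
                            np.linspace(0.1, 2, 10)])
        y = np.array(["A"] * 10 + ["B"] * 10)
        root, order = grow(x.reshape(-1, 1), y, min_split=2, min_leaf=1)
        assert root.depth() == 1
        assert (predict(root, x.reshape(-1, 1), order) == y).all()

    def test_root_split_matches_exhaustive_search(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            n = int(rng.integers(10, 41))
            p = int(rng.integers(1, 4))
            X = rng.normal(size=(n, p)).round(2)
            y = rng.choice(["a", "b", "c"], size=n)
            root, _ = grow(X, y, min_split=2, min_leaf=1, max_depth=1)
            expected = _brute_force_root(X, y)
            if expected is None:
                assert root.is_leaf
            else:
                assert (root.feature, root.threshold) == \
                    pytest.approx(expected)

    def test_reference_implementation_agreement(self):
        """Predictions agree with scikit-learn's tree on >=90% of rows
        for matched hyperparameters."""
        sklearn_tree = pytest.importorskip("sklearn.tree")
        rng = np.random.default_rng(3)
        n = 300
        X = rng.normal(size=(n, 4))
        y = np.where(X[:, 0] + 0.5 * X[:, 1] ** 2 > 0.3, "pos", "neg")
        flip = rng.random(n) < 0.05
        y = np.where(flip, np.where(y == "pos", "neg", "pos"), y)
        root, order = grow(X, y, min_split=20, min_leaf=7, max_depth=5)
        ref = sklearn_tree.DecisionTreeClassifier(
            criterion="gini", min_samples_split=20, min_samples_leaf=7,
            max_depth=5, random_state=0).fit(X, y)
        ours = predict(root, X, order)
        agreement = np.mean(ours == ref.predict(X))
        assert agreement >= 0.9


class TestPruning:
    def _grown(self, seed=1, n=200):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, 3))
        y = np.where(X[:, 0] > 0, "a", np.where(X[:, 1] > 0.5, "b", "a"))
        noise = rng.random(n) < 0.1
        y = np.where(noise, "b", y)
        return grow(X, y, min_split=10, min_leaf=4, max_depth=6)

    def test_single_leaf_path(self):
        root, _ = grow(np.zeros((10, 1)), np.array(["a"] * 10))
        path = prune_path(root)
        assert len(path.alphas) == 1 and path.n_leaves == [1]

    def test_alphas_increase_and_sizes_shrink_to_root(self):
        root, _ = self._grown()
        path = prune_path(root)
        assert all(b > a for a, b in zip(path.alphas, path.alphas[1:]))
        assert all(b <= a for a, b in zip(path.n_leaves, path.n_leaves[1:]))
        assert path.n_leaves[0] == root.leaves()
        assert path.n_leaves[-1] == 1

    def test_subtrees_nested(self):
        root, _ = self._grown(seed=2)
        path = prune_path(root)
        for earlier, later in zip(path.collapsed, path.collapsed[1:]):
            assert earlier <= later

    def test_depth1_collapse_alpha_is_error_reduction(self):
        # perfectly separating stump: collapsing costs the full risk
        # reduction R(root-as-leaf) - 0 at its recorded alpha
        x = np.array([-1.0] * 6 + [1.0] * 4).reshape(-1, 1)
        y = np.array(["A"] * 6 + ["B"] * 4)
        root, _ = grow(x, y, min_split=2, min_leaf=1)
        path = prune_path(root)
        assert path.n_leaves == [2, 1]
        # root risk = 4/10 misclassified; stump risk = 0; one extra leaf
        assert path.alphas[1] == pytest.approx(0.4)
        assert path.root_risk == pytest.approx(0.4)


class TestCvPlan:
    def test_expanding_origin_boundaries(self):
        plan = cv_plan(100, k=5, initial_fraction=0.5)
        assert [p[0] for p in plan] == [50, 60, 70, 80, 90]
        # validation blocks partition the tail
        assert plan[0][1] == 50 and plan[-1][2] == 100
        for (_, _, e), (_, s, _) in zip(plan, plan[1:]):
            assert e == s

    def test_too_small_raises(self):
        with pytest.raises(ValueError):
            cv_plan(8, k=5, initial_fraction=0.5)

    def test_shuffled_timestamps_warn(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(60, 2))
        y = rng.choice(["a", "b"], size=60)
        ts = pd.date_range("2024-03-14", periods=60, freq="D")
        shuffled = ts.to_numpy()[rng.permutation(60)]
        with pytest.warns(UserWarning, match="timestamp order"):
            rolling_origin_cv(X, y, k=3, cp_grid=[0.0],
                              timestamps=shuffled, min_split=5,
                              min_leaf=2)

    def test_large_cp_gives_majority_class_error(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(100, 2))
        y = np.array(["a"] * 70 + ["b"] * 30)
        res = rolling_origin_cv(X, y, k=5, cp_grid=[10.0], min_split=5,
                                min_leaf=2)
        # root-only tree predicts the training majority in each fold
        plan = cv_plan(100, 5, 0.5)
        expected = np.mean([
            np.mean(y[v0:v1] != pd.Series(y[:te]).mode()[0])
            for te, v0, v1 in plan])
        assert res["mean_error"].iloc[0] == pytest.approx(expected)


class TestOneSeRule:
    def test_identical_errors_pick_largest_cp(self):
        cv = pd.DataFrame({"cp": [0.0, 0.01, 0.1],
                           "mean_error": [0.2, 0.2, 0.2],
                           "se": [0.02, 0.02, 0.02]})
        assert one_se_select(cv) == pytest.approx(0.1)

    def test_single_cp(self):
        cv = pd.DataFrame({"cp": [0.05], "mean_error": [0.3],
                           "se": [0.1]})
        assert one_se_select(cv) == pytest.approx(0.05)

    def test_rule_arithmetic(self):
        cv = pd.DataFrame({"cp": [0.0, 0.01, 0.1],
                           "mean_error": [0.10, 0.11, 0.20],
                           "se": [0.02, 0.02, 0.02]})
        # bound = 0.12: second cp qualifies, third does not
        assert one_se_select(cv) == pytest.approx(0.01)


class TestTemporalHoldout:
    @pytest.mark.parametrize("n,n_train,n_test", [(10, 7, 3),
                                                  (100, 70, 30)])
    def test_split_sizes(self, n, n_train, n_test):
        tr, te = temporal_holdout(n)
        assert len(tr) == n_train and len(te) == n_test

    def test_test_rows_after_train_rows(self):
        frame = pd.DataFrame({
            "t": pd.date_range("2024-03-14", periods=50, freq="D"),
            "x": range(50)})
        tr, te = temporal_holdout(frame)
        assert te["t"].min() > tr["t"].max()

    def test_tiny_input_rejected(self):
        with pytest.raises(ValueError):
            temporal_holdout(3)


class TestEvaluate:
    def test_perfect_predictions(self):
        y = ["a", "b", "a", "c"]
        r = evaluate(y, y, ["a", "b", "c"])
        assert r.accuracy == 1.0 and r.kappa == pytest.approx(1.0)
        assert r.balanced_accuracy == 1.0 and r.macro_f1 == 1.0

    def test_kappa_hand_case(self):
        truth = ["A"] * 60 + ["B"] * 40
        pred = ["A"] * 45 + ["B"] * 15 + ["A"] * 25 + ["B"] * 15
        r = evaluate(truth, pred, ["A", "B"])
        assert r.confusion.tolist() == [[45, 15], [25, 15]]
        assert r.accuracy == pytest.approx(0.60)
        assert r.kappa == pytest.approx(0.130, abs=5e-4)

    def test_single_class_truth_kappa_undefined(self):
        with pytest.warns(UserWarning, match="kappa undefined"):
            r = evaluate(["a", "a"], ["a", "a"], ["a"])
        assert np.isnan(r.kappa)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            evaluate(["a"], ["a", "b"], ["a", "b"])


class TestRegressionTree:
    def test_fits_smooth_signal(self):
        rng = np.random.default_rng(0)
        x = np.linspace(0, 10, 400).reshape(-1, 1)
        y = np.sin(x[:, 0]) + rng.normal(0, 0.05, 400)
        tree = grow_regression(x, y, min_split=10, min_leaf=5,
                               max_depth=8)
        pred = predict_regression(tree, x)
        assert np.sqrt(np.mean((pred - y) ** 2)) < 0.2

    def test_mtry_subsampling_deterministic_with_rng(self):
        rng1 = np.random.default_rng(7)
        rng2 = np.random.default_rng(7)
        X = np.random.default_rng(0).normal(size=(100, 5))
        y = X[:, 0] + X[:, 3]
        t1 = grow_regression(X, y, mtry=2, rng=rng1)
        t2 = grow_regression(X, y, mtry=2, rng=rng2)
        assert np.allclose(predict_regression(t1, X),
                           predict_regression(t2, X))


class TestEndToEnd:
    def test_planted_rule_recovery(self):
        """A 2-rule daily-status structure is recovered with holdout
        balanced accuracy >= 0.9 at n=400 days."""
        rng = np.random.default_rng(5)
        n = 400
        cols = [f"pct_{c}_{v}" for v in ("T", "RH", "VPD")
                for c in ("optimal", "suboptimal", "critical")]
        X = pd.DataFrame({c: rng.uniform(0, 100, n) for c in cols})
        y = np.where((X["pct_critical_RH"] > 50)
                     | (X["pct_critical_VPD"] > 60), "critical",
                     "optimal")
        res = fit_cart(X.to_numpy(), y,
                       class_order=["optimal", "suboptimal", "critical"])
        assert res.holdout_report.balanced_accuracy >= 0.9
        assert res.n_test == 120
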