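"""Regression trees, the bootstrap forest, importance and serialization."""

import numpy as np
import pytest

import folscan as fs
from folscan.cohort import SizeHistogram
from folscan.forest import (
    fit_forest,
    fit_tree,
    forest_from_json,
    forest_to_json,
    importance,
    predict_interval,
    predict_matrix,
    predict_tree,
)


def _tree_sse(node, X, y, idx):
    yv = y[idx]
    sse = float(((yv - yv.mean()) ** 2).sum())
    leaves_sse = 0.0
    internal_dec = 0.0
    stack = [(node, idx)]
    while stack:
        nd, ii = stack.pop()
        if nd.is_leaf:
            yy = y[ii]
            leaves_sse += float(((yy - yy.mean()) ** 2).sum()) if ii.size else 0.0
        else:
            internal_dec += nd.node_sse_decrease
            m = X[ii, nd.split_feature] <= nd.split_threshold
            stack.append((nd.left, ii[m]))
            stack.append((nd.right, ii[~m]))
    return sse, leaves_sse, internal_dec


class TestTree:
    def test_constant_outcome_single_leaf(self, rng):
        X = rng.integers(0, 5, size=(30, 18)).astype(float)
        y = np.full(30, 7.0)
        t = fit_tree(X, y, mtry=18, min_leaf=1, rng=rng)
        assert t.is_leaf
        assert t.leaf_value == 7.0

    def test_memorization_at_min_leaf_one(self, rng):
        X = rng.normal(size=(40, 18))  # distinct rows almost surely
        y = rng.normal(size=40)
        t = fit_tree(X, y, mtry=18, min_leaf=1, rng=rng)
        assert np.allclose(predict_tree(t, X), y, atol=1e-12)

    def test_planted_split_recovered(self):
        """y = 10·1[count14 >= 2] + noise: the root splits on 14 mm with a
        threshold between 1 and 2."""
        hits = 0
        for seed in range(100):
            r = np.random.default_rng(seed)
            X = r.integers(0, 5, size=(120, 18)).astype(float)
            y = 10.0 * (X[:, 6] >= 2) + r.normal(0, 1, 120)
            t = fit_tree(X, y, mtry=18, min_leaf=5, rng=r)
            hits += (t.split_feature == 6) and (1.0 < t.split_threshold < 2.0)
        assert hits >= 95

    def test_sse_decrease_bookkeeping(self, rng):
        X = rng.integers(0, 6, size=(100, 18)).astype(float)
        y = X[:, 4] * 2.0 + rng.normal(0, 1, 100)
        t = fit_tree(X, y, mtry=6, min_leaf=5, rng=rng)
        idx = np.arange(100)
        sse_root, sse_leaves, dec = _tree_sse(t, X, y, idx)
        assert dec == pytest.approx(sse_root - sse_leaves, abs=1e-8)


class TestForest:
    def test_reduces_to_single_tree_without_bootstrap(self, rng):
        X = rng.integers(0, 6, size=(50, 18)).astype(float)
        y = X[:, 3] + rng.normal(0, 0.5, 50)
        f = fit_forest(X, y, n_trees=1, mtry=6, min_leaf=5, seed=4, bootstrap=False)
        t = fit_tree(
            X, y, mtry=6, min_leaf=5,
            rng=np.random.default_rng(np.random.SeedSequence(4).spawn(1)[0]),
        )
        assert np.array_equal(predict_tree(f.trees[0], X), predict_tree(t, X))

    def test_determinism_and_serialization_round_trip(self, rng):
        X = rng.integers(0, 6, size=(60, 18)).astype(float)
        y = X[:, 7] + rng.normal(0, 0.5, 60)
        f1 = fit_forest(X, y, n_trees=20, seed=9)
        f2 = fit_forest(X, y, n_trees=20, seed=9)
        s1, s2 = forest_to_json(f1), forest_to_json(f2)
        assert s1 == s2
        back = forest_from_json(s1)
        assert np.allclose(predict_matrix(back, X), predict_matrix(f1, X), atol=0)
        assert fit_forest(X, y, n_trees=20, seed=10).trees[0].split_feature is not None
        assert forest_to_json(fit_forest(X, y, n_trees=20, seed=10)) != s1

    def test_beats_global_mean_on_held_out_data(self, step_cohort, step_curve):
        cohort, _, cfg = step_cohort
        f = fs.fit_forest_cohort(cohort, "oocytes", n_trees=200, seed=1)
        test_cohort, _ = fs.generate_cohort(
            fs.preset("hcg_like", n_patients=200, seed=777, yield_curve=step_curve)
        )
        Xt = test_cohort.design_matrix()
        yt = test_cohort.outcome_vector("oocytes")
        mse_forest = np.mean((predict_matrix(f, Xt) - yt) ** 2)
        mse_null = np.mean((cohort.outcome_vector("oocytes").mean() - yt) ** 2)
        assert mse_forest < mse_null

    def test_prediction_is_tree_mean_and_order_invariant(self, step_cohort):
        cohort, _, _ = step_cohort
        f = fs.fit_forest_cohort(cohort, "oocytes", n_trees=30, seed=2)
        X = cohort.design_matrix()[:100]
        brute = np.mean([predict_tree(t, X.astype(float)) for t in f.trees], axis=0)
        assert np.allclose(predict_matrix(f, X), brute, atol=1e-12)
        f.trees.reverse()
        assert np.allclose(predict_matrix(f, X), brute, atol=1e-12)

    def test_interval_brackets_mean(self, step_cohort):
        cohort, _, _ = step_cohort
        f = fs.fit_forest_cohort(cohort, "oocytes", n_trees=50, seed=3)
        for r in cohort.records[:10]:
            lo, hi = predict_interval(f, r.histogram)
            point = fs.predict(f, r.histogram)
            assert lo <= hi
            per_tree = predict_matrix(
                f, r.histogram.as_array()[None, :], per_tree=True
            )[:, 0]
            assert lo >= per_tree.min() and hi <= per_tree.max()
            assert per_tree.mean() == pytest.approx(point, abs=1e-12)

    def test_constant_forest_interval(self):
        X = np.ones((20, 18))
        y = np.full(20, 3.0)
        f = fit_forest(X, y, n_trees=10, seed=0)
        h = SizeHistogram(np.ones(18, dtype=np.int64))
        assert fs.predict(f, h) == 3.0
        assert predict_interval(f, h) == (3.0, 3.0)

    def test_min_leaf_regularizes_monotonically(self, step_cohort):
        cohort, _, _ = step_cohort
        X = cohort.design_matrix()
        y = cohort.outcome_vector("oocytes")
        fits = []
        for ml in (1, 5, 25):
            f = fit_forest(X, y, n_trees=40, min_leaf=ml, seed=5, bootstrap=False)
            fits.append(np.mean((predict_matrix(f, X) - y) ** 2))
        assert fits[0] <= fits[1] <= fits[2]


class TestImportance:
    def test_never_split_feature_scores_zero(self, rng):
        X = rng.integers(0, 6, size=(80, 18)).astype(float)
        X[:, 17] = 0.0  # constant column can never be split on
        y = X[:, 4] + rng.normal(0, 0.3, 80)
        f = fit_forest(X, y, n_trees=30, seed=6)
        imp = importance(f)
        assert imp.importance[25] == 0.0
        assert all(v >= 0 for v in imp.importance.values())

    def test_impurity_sums_to_mean_total_decrease(self, rng):
        X = rng.integers(0, 6, size=(60, 18)).astype(float)
        y = X[:, 4] + rng.normal(0, 0.3, 60)
        f = fit_forest(X, y, n_trees=25, seed=7)
        imp = importance(f)
        total = 0.0
        for t in f.trees:
            stack = [t]
            while stack:
                nd = stack.pop()
                if not nd.is_leaf:
                    total += nd.node_sse_decrease
                    stack.extend([nd.left, nd.right])
        assert sum(imp.importance.values()) == pytest.approx(total / 25, rel=1e-10)

    def test_shift_invariance(self, rng):
        X = rng.integers(0, 6, size=(60, 18)).astype(float)
        y = X[:, 9] * 2 + rng.normal(0, 0.5, 60)
        i1 = importance(fit_forest(X, y, n_trees=15, seed=8)).importance
        i2 = importance(fit_forest(X, y + 100.0, n_trees=15, seed=8)).importance
        for d in i1:
            assert i1[d] == pytest.approx(i2[d], rel=1e-9, abs=1e-9)

    def test_in_window_diameters_rank_higher(self, step_cohort):
        cohort, _, _ = step_cohort
        f = fs.fit_forest_cohort(cohort, "mature", n_trees=200, seed=11)
        for method in ("impurity", "permutation"):
            imp = importance(f, method).importance
            in_mean = np.mean([imp[d] for d in range(12, 20)])
            out_mean = np.mean([imp[d] for d in (8, 9, 10, 21, 22, 23, 24, 25)])
            assert in_mean > out_mean, method

    def test_permutation_requires_oob(self, rng):
        X = rng.integers(0, 6, size=(40, 18)).astype(float)
        y = X[:, 3] + rng.normal(0, 0.3, 40)
        f = fit_forest(X, y, n_trees=5, seed=1)
        f.X_train = None
        with pytest.raises(fs.ValidationError, match="out-of-bag"):
            importance(f, "permutation")


def test_cross_check_against_sklearn(step_cohort):
    """Independent oracle: scikit-learn's forest, fitted on the same cohort,
    agrees on which half of the diameter axis matters."""
    from sklearn.ensemble import RandomForestRegressor

    cohort, _, _ = step_cohort
    X = cohort.design_matrix()
    y = cohort.outcome_vector("oocytes")
    ours = importance(fs.fit_forest_cohort(cohort, "oocytes", n_trees=200, seed=13))
    theirs = RandomForestRegressor(
        n_estimators=200, max_features=6, min_samples_leaf=5, random_state=13
    ).fit(X, y)
    ours_in = sum(v for d, v in ours.importance.items() if 12 <= d <= 19)
    ours_total = sum(ours.importance.values())
    theirs_in = theirs.feature_importances_[4:12].sum()
    assert ours_in / ours_total == pytest.approx(theirs_in, abs=0.15)
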