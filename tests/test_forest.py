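"""Honest causal forest: pseudo-outcome algebra, split-search oracle,
honesty, the forest-weight CATE ratio, variable importance and tuning."""

import numpy as np
import pytest

from causalhurdle.forest import (CausalForest, CausalTree, ForestParams,
                                 _leaf_statistics, best_split, grow_tree,
                                 node_pseudo_outcomes, tune_params)


def single_leaf_forest(d, y, e, m, w=None):
    """Forest with one tree whose only leaf holds every row (oracle device)."""
    n = len(d)
    w = np.ones(n) if w is None else np.asarray(w, float)
    cf = CausalForest(ForestParams(num_trees=1, min_node_size=1))
    cf.X_ = np.zeros((n, 1))
    cf.d_ = np.asarray(d, np.int64)
    cf.w_ = w
    cf.d_res_ = np.asarray(d, float) - np.asarray(e, float)
    cf.y_res_ = np.asarray(y, float) - np.asarray(m, float)
    tree = CausalTree(feature=np.array([-1]), threshold=np.array([np.nan]),
                      left=np.array([-1]), right=np.array([-1]),
                      depth=np.array([0]), split_sample=np.arange(0),
                      estimation_sample=np.arange(n),
                      term_rows={0: np.arange(n)})
    _leaf_statistics(tree, cf.d_res_, cf.y_res_, cf.w_)
    cf.trees_ = [tree]
    cf._split_records = []
    cf.variable_importance_ = np.zeros(1)
    return cf


class TestPseudoOutcomes:
    def test_exact_linear_node_has_zero_rho(self):
        d_res = np.array([0.6, -0.4, 0.6, -0.4])
        y_res = 3.0 * d_res + 1.0
        rho, beta = node_pseudo_outcomes(d_res, y_res)
        assert beta == pytest.approx(3.0)
        assert np.allclose(rho, 0.0, atol=1e-12)

    def test_hand_example_slope_two(self):
        rho, beta = node_pseudo_outcomes(np.array([0.5, 0.5, -0.5, -0.5]),
                                         np.array([3.0, 1.0, 1.0, -1.0]))
        assert beta == pytest.approx(2.0)

    def test_weighted_rho_sums_vanish_on_random_nodes(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = rng.integers(4, 40)
            d_res = rng.integers(0, 2, n) - rng.random()
            y_res = rng.normal(size=n)
            w = rng.integers(1, 5, n).astype(float)
            rho, _ = node_pseudo_outcomes(d_res, y_res, w)
            assert abs(np.dot(w, rho)) < 1e-10

    def test_degenerate_node_not_splittable(self):
        with pytest.raises(ValueError, match="variance"):
            node_pseudo_outcomes(np.zeros(5), np.arange(5.0))


def brute_force_split(X, rho, w, d, min_node_size, alpha, penalty):
    """Exhaustive oracle over every feature and midpoint threshold."""
    best = None
    w_tot = w.sum()
    for f in range(X.shape[1]):
        vals = np.unique(X[:, f])
        for lo, hi in zip(vals[:-1], vals[1:]):
            thr = (lo + hi) / 2
            L = X[:, f] <= thr
            R = ~L
            if (d[L].sum() < min_node_size or (1 - d[L]).sum() < min_node_size
                    or d[R].sum() < min_node_size or (1 - d[R]).sum() < min_node_size):
                continue
            wl, wr = w[L].sum(), w[R].sum()
            if wl < alpha * w_tot or wr < alpha * w_tot:
                continue
            delta = (np.dot(w[L], rho[L]) ** 2 / wl + np.dot(w[R], rho[R]) ** 2 / wr
                     - penalty * (1 / wl + 1 / wr))
            if delta > 1e-12 and (best is None or delta > best[0] + 1e-12):
                best = (delta, f, thr)
    return None if best is None else (best[1], best[2])


class TestBestSplit:
    def test_separating_feature_chosen(self):
        n = 20
        x = np.r_[np.zeros(10), np.ones(10)]
        X = np.column_stack([x, np.arange(n, dtype=float)])
        rho = np.r_[np.ones(10), -np.ones(10)]
        w = np.ones(n)
        d = np.tile([0, 1], 10)
        got = best_split(X, rho, w, d, np.array([0, 1]), 1, 0.0, 0.0)
        assert got is not None and got[0] == 0
        assert got[1] == pytest.approx(0.5)

    def test_alpha_near_half_forces_median_splits(self):
        rng = np.random.default_rng(1)
        n = 40
        X = rng.normal(size=(n, 1))
        rho = rng.normal(size=n)
        w = np.ones(n)
        d = np.tile([0, 1], 20)
        got = best_split(X, rho, w, d, np.array([0]), 1, 0.49, 0.0)
        if got is not None:
            left = (X[:, 0] <= got[1]).sum()
            assert 0.49 * n <= left <= 0.51 * n + 1

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(10, 30)
        p = rng.integers(1, 4)
        X = np.round(rng.normal(size=(n, p)), 1)
        d = rng.integers(0, 2, n)
        if d.sum() < 2 or (1 - d).sum() < 2:
            d[:2] = [0, 1]
        rho = rng.normal(size=n)
        rho -= rho.mean()
        w = rng.integers(1, 4, n).astype(float)
        args = (1, 0.05, 0.5)
        got = best_split(X, rho, w, d, np.arange(p), *args)
        want = brute_force_split(X, rho, w, d, *args)
        if want is None:
            assert got is None
        else:
            assert got is not None
            # equal scores may pick different (feature, threshold); compare scores
            def score(f, thr):
                L = X[:, f] <= thr
                wl, wr = w[L].sum(), w[~L].sum()
                return (np.dot(w[L], rho[L]) ** 2 / wl
                        + np.dot(w[~L], rho[~L]) ** 2 / wr
                        - args[2] * (1 / wl + 1 / wr))
            assert score(*got) == pytest.approx(score(*want), rel=1e-9)


class TestGrowTree:
    def _data(self, n=200, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, 3))
        d = rng.integers(0, 2, n)
        tau = np.where(X[:, 0] > 0, 2.0, -1.0)
        y = d * tau + rng.normal(size=n)
        return X, d.astype(np.int64), y, np.full(n, 0.5), np.zeros(n), np.ones(n)

    def test_large_min_node_size_gives_single_leaf(self):
        X, d, y, e, m, w = self._data()
        params = ForestParams(num_trees=1, min_node_size=500)
        tree = grow_tree(X, d - e, y - m, d, w, params, np.random.default_rng(0))
        assert (tree.feature == -1).all()

    def test_honesty_structure_independent_of_estimation_outcomes(self):
        X, d, y, e, m, w = self._data()
        params = ForestParams(num_trees=1, min_node_size=5, seed=3)
        t1 = grow_tree(X, d - e, y - m, d, w, params, np.random.default_rng(42))
        y2 = y.copy()
        y2[t1.estimation_sample] += np.random.default_rng(1).normal(
            size=len(t1.estimation_sample)) * 10
        t2 = grow_tree(X, d - e, y2 - m, d, w, params, np.random.default_rng(42))
        assert np.array_equal(t1.feature, t2.feature)
        assert np.array_equal(t1.threshold, t2.threshold, equal_nan=True)

    def test_split_and_estimation_samples_disjoint(self):
        X, d, y, e, m, w = self._data()
        params = ForestParams(num_trees=1, min_node_size=5)
        tree = grow_tree(X, d - e, y - m, d, w, params, np.random.default_rng(7))
        assert len(np.intersect1d(tree.split_sample, tree.estimation_sample)) == 0

    def test_pruned_leaves_all_nonempty(self):
        X, d, y, e, m, w = self._data(n=300, seed=5)
        params = ForestParams(num_trees=1, min_node_size=2, honesty_prune_leaves=True)
        tree = grow_tree(X, d - e, y - m, d, w, params, np.random.default_rng(11))
        assert tree.term_rows
        for rows in tree.term_rows.values():
            assert len(rows) > 0


class TestCatePrediction:
    def test_hand_example_ratio_two(self):
        # uniform weights, e = 0.5, m = 0, D = (1,1,0,0), Y = (3,1,1,-1)
        cf = single_leaf_forest([1, 1, 0, 0], [3.0, 1.0, 1.0, -1.0],
                                np.full(4, 0.5), np.zeros(4))
        tau = cf.predict(np.zeros((1, 1)))
        assert tau[0] == pytest.approx(2.0)

    def test_single_leaf_equals_residual_regression_slope(self):
        rng = np.random.default_rng(2)
        n = 80
        d = rng.integers(0, 2, n)
        e = rng.uniform(0.3, 0.7, n)
        m = rng.normal(size=n)
        y = m + d * 1.5 + rng.normal(size=n)
        w = rng.integers(1, 4, n).astype(float)
        cf = single_leaf_forest(d, y, e, m, w)
        tau = cf.predict(np.zeros((1, 1)))[0]
        dr, yr = d - e, y - m
        slope = np.dot(w, dr * yr) / np.dot(w, dr**2)
        assert tau == pytest.approx(slope, abs=1e-8)

    def test_forest_weights_uniform_on_single_leaf(self):
        cf = single_leaf_forest([1, 0, 1, 0], [1.0, 0.0, 2.0, 1.0],
                                np.full(4, 0.5), np.zeros(4))
        wv = cf.forest_weights(np.zeros(1))
        assert np.allclose(wv, 0.25)
        assert wv.sum() == pytest.approx(1.0)

    def test_weights_sum_to_one_and_exclude_split_rows(self):
        rng = np.random.default_rng(3)
        n = 150
        X = rng.normal(size=(n, 2))
        d = rng.integers(0, 2, n)
        y = rng.normal(size=n) + d
        cf = CausalForest(ForestParams(num_trees=20, min_node_size=3, seed=5))
        cf.fit(X, d, y, np.full(n, 0.5), np.zeros(n))
        wv = cf.forest_weights(X[0])
        assert wv.sum() == pytest.approx(1.0)
        est_union = set()
        for t in cf.trees_:
            est_union.update(t.estimation_sample.tolist())
        never_est = np.setdiff1d(np.arange(n), sorted(est_union))
        assert np.allclose(wv[never_est], 0.0)

    def test_constant_shift_of_treated_outcomes_shifts_cate(self):
        rng = np.random.default_rng(4)
        n = 2000
        X = rng.normal(size=(n, 3))
        d = rng.integers(0, 2, n)
        noise = rng.normal(size=n)
        e = np.full(n, 0.5)
        m = np.zeros(n)
        params = ForestParams(num_trees=50, min_node_size=10, seed=9)
        t0 = CausalForest(params).fit(X, d, noise, e, m).predict(X).mean()
        t1 = CausalForest(params).fit(X, d, noise + 3.0 * d, e, m).predict(X).mean()
        se = 3 * noise.std() / np.sqrt(n) * 2
        assert abs((t1 - t0) - 3.0) < 3 * se + 0.15


class TestVariableImportance:
    def test_single_driver_ranks_first(self):
        rng = np.random.default_rng(5)
        n = 3000
        X = rng.normal(size=(n, 4))
        d = rng.integers(0, 2, n)
        y = d * np.where(X[:, 1] > 0, 3.0, -3.0) + rng.normal(size=n)
        cf = CausalForest(ForestParams(num_trees=40, min_node_size=10, seed=6))
        cf.fit(X, d, y, np.full(n, 0.5), np.zeros(n))
        vi = cf.variable_importance
        assert vi.sum() == pytest.approx(1.0)
        assert (vi >= 0).all()
        assert np.argmax(vi) == 1

    def test_no_splits_gives_zeros(self):
        rng = np.random.default_rng(6)
        n = 30
        X = rng.normal(size=(n, 2))
        d = np.tile([0, 1], 15)
        cf = CausalForest(ForestParams(num_trees=3, min_node_size=50, seed=1))
        cf.fit(X, d, rng.normal(size=n), np.full(n, 0.5), np.zeros(n))
        assert np.allclose(cf.variable_importance, 0.0)


class TestSerialisation:
    def test_json_dump_round_trips_structure(self):
        import json
        rng = np.random.default_rng(21)
        n = 120
        X = rng.normal(size=(n, 2))
        d = rng.integers(0, 2, n)
        y = rng.normal(size=n) + d * (X[:, 0] > 0)
        cf = CausalForest(ForestParams(num_trees=5, min_node_size=3, seed=2))
        cf.fit(X, d, y, np.full(n, 0.5), np.zeros(n))
        dump = json.loads(cf.to_json())
        assert len(dump["trees"]) == 5
        assert dump["params"]["num_trees"] == 5
        t0 = dump["trees"][0]
        assert len(t0["feature"]) == len(t0["threshold"]) == len(t0["left"])
        assert set(map(int, t0["term_rows"])) <= set(range(len(t0["feature"])))


class TestTuning:
    def _data(self, n=600, seed=8):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, 3))
        d = rng.integers(0, 2, n)
        y = d * (1.0 + X[:, 0]) + rng.normal(size=n)
        return X, d, y, np.full(n, 0.5), np.zeros(n)

    def test_single_candidate_returned_unchanged(self):
        X, d, y, e, m = self._data()
        cand = ForestParams(num_trees=10, min_node_size=7)
        assert tune_params(X, d, y, e, m, candidates=[cand]) is cand

    def test_deterministic_selection(self):
        X, d, y, e, m = self._data()
        a = tune_params(X, d, y, e, m, n_draws=3, tune_trees=10, seed=4)
        b = tune_params(X, d, y, e, m, n_draws=3, tune_trees=10, seed=4)
        assert a == b

    def test_tuned_not_worse_than_default(self):
        from dataclasses import replace
        X, d, y, e, m = self._data()
        tuned = tune_params(X, d, y, e, m, n_draws=4, tune_trees=20, seed=2)
        loss_tuned = CausalForest(replace(tuned, num_trees=20, seed=1)).fit(
            X, d, y, e, m).r_loss()
        loss_default = CausalForest(ForestParams(num_trees=20, seed=1)).fit(
            X, d, y, e, m).r_loss()
        assert loss_tuned <= loss_default + 0.1
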