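"""Quintile machinery, sorted GATEs, Romano-Wolf stepdown, classification
analysis, subgroup GATEs and the best linear projection."""

import numpy as np
import pandas as pd
import pytest

from causalhurdle.data import ObservationTable
from causalhurdle.effects import aiptw_ate
from causalhurdle.heterogeneity import (assign_quintiles, blp,
                                        classification_analysis,
                                        quintile_difference_tests, sorted_gates,
                                        subgroup_gates)


class TestQuintiles:
    def test_simple_ranks(self):
        qa = assign_quintiles(np.arange(1, 11, dtype=float))
        assert np.array_equal(qa.labels, np.repeat([1, 2, 3, 4, 5], 2))

    def test_weight_scale_invariance(self):
        rng = np.random.default_rng(0)
        tau = rng.normal(size=100)
        w = rng.uniform(0.5, 3.0, 100)
        a = assign_quintiles(tau, w).labels
        b = assign_quintiles(tau, 2.0 * w).labels
        assert np.array_equal(a, b)

    def test_integer_weights_match_replication_oracle(self):
        rng = np.random.default_rng(1)
        tau = rng.normal(size=40)
        w = rng.integers(1, 5, 40)
        qa = assign_quintiles(tau, w.astype(float))
        rep = np.repeat(np.arange(40), w)
        qa_rep = assign_quintiles(tau[rep])
        # replicated copies of a row are contiguous in the stable ordering, so
        # compare weighted group shares
        for q in range(1, 6):
            share_w = w[qa.labels == q].sum() / w.sum()
            share_r = (qa_rep.labels == q).mean()
            # a boundary row's copies may straddle a cut in the replicated data
            assert share_w == pytest.approx(share_r, abs=2 * w.max() / w.sum())

    def test_all_identical_collapses_to_q1(self):
        qa = assign_quintiles(np.ones(10))
        assert (qa.labels == 1).all()

    def test_labels_monotone_in_tau(self):
        rng = np.random.default_rng(2)
        tau = rng.normal(size=200)
        qa = assign_quintiles(tau)
        order = np.argsort(tau, kind="stable")
        assert (np.diff(qa.labels[order]) >= 0).all()


class TestSortedGates:
    def test_reaggregation_identity(self):
        rng = np.random.default_rng(3)
        gamma = rng.normal(size=300)
        w = rng.uniform(0.5, 2.0, 300)
        tau = rng.normal(size=300)
        qa = assign_quintiles(tau, w)
        gates = sorted_gates(gamma, qa, w)
        shares = np.array([w[qa.labels == q].sum() for q in range(1, 6)])
        recombined = np.dot(gates["estimate"], shares) / shares.sum()
        assert recombined == pytest.approx(aiptw_ate(gamma, w).estimate, abs=1e-8)

    def test_homogeneous_scores_give_flat_gates(self):
        rng = np.random.default_rng(4)
        n = 4000
        gamma = 0.7 + rng.normal(size=n)  # tau* = 0.7 everywhere
        tau = rng.normal(size=n)  # ranking independent of gamma
        gates = sorted_gates(gamma, assign_quintiles(tau), None)
        for _, r in gates.iterrows():
            assert abs(r["estimate"] - 0.7) < 3 * r["se"]


class TestRomanoWolf:
    def _panel(self, n=1500, shift=0.0, seed=0):
        rng = np.random.default_rng(seed)
        tau = rng.normal(size=n)
        gamma = rng.normal(size=n) * 2 + shift * (tau > np.quantile(tau, 0.8))
        return gamma, assign_quintiles(tau)

    def test_adjusted_at_least_unadjusted(self):
        gamma, qa = self._panel(shift=1.0, seed=5)
        out = quintile_difference_tests(gamma, qa, n_boot=300, seed=1)
        assert (out["p_adjusted"] >= out["p_unadjusted"] - 1e-12).all()
        assert len(out) == 4

    def test_single_contrast_adjusted_equals_unadjusted(self):
        rng = np.random.default_rng(6)
        tau = rng.normal(size=400)
        gamma = rng.normal(size=400)
        qa = assign_quintiles(tau, n_groups=2)
        out = quintile_difference_tests(gamma, qa, n_boot=300, seed=2)
        assert len(out) == 1
        assert out["p_adjusted"].iloc[0] == pytest.approx(out["p_unadjusted"].iloc[0])

    def test_small_b_rejected(self):
        gamma, qa = self._panel()
        with pytest.raises(ValueError):
            quintile_difference_tests(gamma, qa, n_boot=50)

    def test_fwer_under_global_null(self):
        # 300 replicate panels with no heterogeneity: family-wise error rate
        # of the adjusted tests stays near the nominal 5% level
        reps, alpha = 300, 0.05
        rejections = 0
        for r in range(reps):
            gamma, qa = self._panel(n=600, shift=0.0, seed=1000 + r)
            out = quintile_difference_tests(gamma, qa, n_boot=200, seed=r)
            rejections += int((out["p_adjusted"] < alpha).any())
        fwer = rejections / reps
        assert fwer <= alpha + 2 * np.sqrt(alpha * (1 - alpha) / reps)


def _table_with(tau, seed=0, extra=None):
    rng = np.random.default_rng(seed)
    n = len(tau)
    cov = {"x_noise": rng.normal(size=n), "b_noise": rng.integers(0, 2, n).astype(float)}
    if extra:
        cov.update(extra)
    return ObservationTable(pd.DataFrame(cov), rng.integers(0, 2, n),
                            {"y": rng.poisson(1.0, n)})


class TestClassification:
    def test_oracle_covariate_ranks_first(self):
        rng = np.random.default_rng(7)
        n = 2000
        tau = rng.normal(size=n)
        ranks = np.argsort(np.argsort(tau)).astype(float)
        table = _table_with(tau, seed=7, extra={"tau_rank": ranks})
        res = classification_analysis(table, assign_quintiles(tau))
        assert res.ranking.iloc[0]["covariate"] == "tau_rank"
        assert res.top_modifiers[0] == "tau_rank"

    def test_independent_covariate_near_zero_distance(self):
        rng = np.random.default_rng(8)
        n = 5000
        tau = rng.normal(size=n)
        table = _table_with(tau, seed=88)  # covariates independent of tau
        res = classification_analysis(table, assign_quintiles(tau))
        dist = res.table[res.table["covariate"] == "x_noise"]["distance"]
        assert (dist < 0.1).all()
        assert (res.table["distance"] >= 0).all()

    def test_zero_variance_excluded_from_ranking(self):
        tau = np.arange(100, dtype=float)
        table = _table_with(tau, extra={"const_col": np.ones(100)})
        res = classification_analysis(table, assign_quintiles(tau))
        row = res.ranking[res.ranking["covariate"] == "const_col"].iloc[0]
        assert row["excluded"]
        assert np.isnan(row["rank"]) or row["rank"] > 0

    def test_hand_check_on_toy_table(self):
        # 20 rows, one binary covariate perfectly aligned with tau quintiles
        tau = np.arange(20, dtype=float)
        top = (tau >= 16).astype(float)  # = 1 exactly in Q5
        table = _table_with(tau, extra={"top_flag": top})
        res = classification_analysis(table, assign_quintiles(tau))
        sub = res.table[res.table["covariate"] == "top_flag"].set_index("group")
        overall_mean, overall_sd = 0.2, np.sqrt(20 / 19 * 0.2 * 0.8)
        assert sub.loc["Q5", "mean"] == pytest.approx(1.0)
        assert sub.loc["Q5", "distance"] == pytest.approx((1 - overall_mean) / overall_sd)
        assert sub.loc["Q1", "distance"] == pytest.approx(overall_mean / overall_sd)


class TestSubgroupGates:
    def test_reaggregation_identity(self):
        rng = np.random.default_rng(9)
        n = 500
        gamma = rng.normal(size=n)
        table = _table_with(np.zeros(n), seed=9)
        out = subgroup_gates(gamma, table, ["b_noise"])
        shares = np.array([ (table.covariates["b_noise"] == int(lv)).sum()
                            for lv in out["level"]])
        recombined = np.dot(out["estimate"], shares) / shares.sum()
        assert recombined == pytest.approx(gamma.mean(), abs=1e-8)

    def test_oracle_modifier_orders_levels(self):
        rng = np.random.default_rng(10)
        n = 3000
        tau_star = rng.normal(size=n)
        gamma = tau_star + rng.normal(size=n) * 0.5
        flag = (tau_star > np.median(tau_star)).astype(float)
        table = _table_with(tau_star, seed=10, extra={"high_tau": flag})
        out = subgroup_gates(gamma, table, ["high_tau"]).set_index("level")
        assert out.loc["1", "estimate"] > out.loc["0", "estimate"]

    def test_independent_binary_levels_agree(self):
        rng = np.random.default_rng(11)
        n = 4000
        gamma = 0.4 + rng.normal(size=n)
        table = _table_with(np.zeros(n), seed=11)
        out = subgroup_gates(gamma, table, ["b_noise"])
        diff = out["estimate"].iloc[1] - out["estimate"].iloc[0]
        se = np.hypot(out["se"].iloc[0], out["se"].iloc[1])
        assert abs(diff) < 3 * se

    def test_continuous_modifier_median_split(self):
        rng = np.random.default_rng(12)
        n = 300
        gamma = rng.normal(size=n)
        table = _table_with(np.zeros(n), seed=12)
        out = subgroup_gates(gamma, table, ["x_noise"])
        assert len(out) == 2
        assert out["n_effective"].sum() == pytest.approx(n)


class TestBlp:
    def test_intercept_only_equals_aiptw_ate(self):
        rng = np.random.default_rng(13)
        gamma = rng.normal(size=400) + 1.2
        w = rng.uniform(0.5, 2.0, 400)
        res = blp(gamma, pd.DataFrame(index=range(400)), w)
        assert res.intercept == pytest.approx(aiptw_ate(gamma, w).estimate, abs=1e-10)

    def test_parameter_recovery_linear_tau(self):
        rng = np.random.default_rng(14)
        n = 20_000
        x1 = rng.integers(0, 2, n).astype(float)
        tau_star = 0.5 + 1.0 * x1
        gamma = tau_star + rng.normal(size=n) * 3  # DR-score-like noise
        res = blp(gamma, pd.DataFrame({"x1": x1}))
        c = res.coefficients.set_index("term")
        assert abs(c.loc["x1", "estimate"] - 1.0) < 3 * c.loc["x1", "se"]
        assert abs(c.loc["const", "estimate"] - 0.5) < 3 * c.loc["const", "se"]

    def test_orthogonal_regressor_has_zero_coefficient(self):
        rng = np.random.default_rng(15)
        n = 20_000
        x1 = rng.integers(0, 2, n).astype(float)
        x2 = rng.normal(size=n)  # unrelated to tau*
        gamma = (0.5 + x1) + rng.normal(size=n) * 2
        res = blp(gamma, pd.DataFrame({"x1": x1, "x2": x2}))
        c = res.coefficients.set_index("term")
        assert abs(c.loc["x2", "estimate"]) < 3 * c.loc["x2", "se"]

    def test_reports_both_se_flavours(self):
        rng = np.random.default_rng(16)
        res = blp(rng.normal(size=100), pd.DataFrame({"z": rng.normal(size=100)}))
        assert {"se", "se_conventional", "p", "p_conventional"} <= set(res.coefficients)
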