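"""Tests for covariate-adjusted permutation inference, FDR, NBS and
Spearman partial correlation."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import oracles as orc
from dfcstates import stats as ds


def make_design(n=30, seed=0):
    rng = np.random.default_rng(seed)
    groups = np.array(["A"] * (n // 2) + ["B"] * (n - n // 2))
    covs = pd.DataFrame(
        {"age": rng.normal(60, 8, n), "gender": rng.integers(0, 2, n)}
    )
    return groups, covs, rng


class TestCovariateAdjust:
    def test_orthogonal_covariates_center_only(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        covs = np.array([1.0, -1.0, 1.0, -1.0]) * 0.5  # orthogonal to the trend? no:
        # use a covariate exactly orthogonal to the centered outcome
        covs = np.array([1.0, -1.0, -1.0, 1.0])
        resid = ds.covariate_adjust(y, covs)
        assert np.allclose(resid, y - y.mean(), atol=1e-10)

    def test_outcome_linear_in_age_gives_zero_residuals(self):
        age = np.array([40.0, 50.0, 55.0, 70.0, 62.0])
        y = 3.0 + 0.5 * age
        assert np.allclose(ds.covariate_adjust(y, age), 0.0, atol=1e-10)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(1)
        y = rng.normal(size=25)
        covs = rng.normal(size=(25, 2))
        x = np.column_stack([np.ones(25), covs])
        assert np.allclose(
            ds.covariate_adjust(y, covs), orc.ols_residuals_oracle(y, x), atol=1e-10
        )

    def test_collinear_covariate_named(self):
        covs = pd.DataFrame({"age": np.arange(10.0), "age2": 2 * np.arange(10.0)})
        with pytest.raises(ds.StatsInputError, match="age"):
            ds.covariate_adjust(np.random.default_rng(0).normal(size=10), covs)


class TestPermutationTest:
    def test_constant_outcome_p_is_one(self):
        groups, covs, _ = make_design()
        res = ds.permutation_test(np.ones(30), groups, covs, n_perm=200, seed=0)
        assert res.p_value == 1.0

    def test_saturated_effect_reaches_minimal_p(self):
        groups, covs, rng = make_design(seed=2)
        y = rng.normal(0, 1, 30)
        y[groups == "A"] += 5.0  # 5-SD separation
        res = ds.permutation_test(y, groups, covs, n_perm=500, seed=1)
        assert res.p_value == pytest.approx(1 / 501)

    def test_affine_invariance(self):
        groups, covs, rng = make_design(seed=3)
        y = rng.normal(size=30)
        p1 = ds.permutation_test(y, groups, covs, n_perm=300, seed=7).p_value
        p2 = ds.permutation_test(3.7 * y - 11.0, groups, covs, n_perm=300, seed=7).p_value
        assert p1 == p2

    def test_p_value_bounds(self):
        groups, covs, rng = make_design(seed=4)
        res = ds.permutation_test(rng.normal(size=30), groups, covs, n_perm=99, seed=0)
        assert 1 / 100 <= res.p_value <= 1.0

    def test_many_matches_single_outcome(self):
        groups, covs, rng = make_design(seed=5)
        y = rng.normal(size=(30, 4))
        obs, p = ds.permutation_test_many(y, groups, covs, n_perm=200, seed=9)
        for j in range(4):
            single = ds.permutation_test(y[:, j], groups, covs, n_perm=200, seed=9)
            assert obs[j] == pytest.approx(single.observed_stat, abs=1e-12)
            assert p[j] == pytest.approx(single.p_value)

    def test_unadjusted_and_adjusted_agree_without_covariate_effect(self):
        # with no true covariate effect the two tests reject at similar rates
        rng = np.random.default_rng(6)
        n_sim, alpha = 300, 0.05
        rej = {"adj": 0, "raw": 0}
        groups = np.array(["A"] * 10 + ["B"] * 10)
        for _ in range(n_sim):
            y = rng.normal(size=20)
            covs = rng.normal(size=(20, 2))
            seed = int(rng.integers(2**31))
            rej["adj"] += ds.permutation_test(y, groups, covs, 200, seed).p_value < alpha
            rej["raw"] += ds.permutation_test(y, groups, None, 200, seed).p_value < alpha
        assert abs(rej["adj"] - rej["raw"]) / n_sim < 0.05


class TestFdrBH:
    def test_hand_worked_step_up(self):
        res = ds.fdr_bh([0.01, 0.02, 0.5], q=0.05)
        assert np.allclose(res.adjusted_p, [0.03, 0.03, 0.5])
        assert res.rejected.tolist() == [True, True, False]

    def test_all_ones_no_rejections(self):
        res = ds.fdr_bh([1.0, 1.0, 1.0])
        assert not res.rejected.any()
        assert np.all(res.adjusted_p == 1.0)

    def test_single_p_identity(self):
        res = ds.fdr_bh([0.04])
        assert res.adjusted_p[0] == pytest.approx(0.04)
        assert res.rejected[0]

    def test_adjusted_dominates_raw_and_is_monotone(self):
        rng = np.random.default_rng(7)
        p = rng.uniform(size=50)
        res = ds.fdr_bh(p)
        assert np.all(res.adjusted_p >= res.raw_p - 1e-15)
        order = np.argsort(p)
        assert np.all(np.diff(res.adjusted_p[order]) >= -1e-15)


class TestNBS:
    def edge_data(self, n_nodes=10, n_subj=24, seed=0):
        rng = np.random.default_rng(seed)
        m = n_nodes * (n_nodes - 1) // 2
        y = rng.normal(size=(n_subj, m))
        groups = np.array(["A"] * (n_subj // 2) + ["B"] * (n_subj // 2))
        covs = pd.DataFrame({"age": rng.normal(60, 5, n_subj),
                             "gender": rng.integers(0, 2, n_subj)})
        return y, groups, covs

    def test_single_planted_edge_is_one_component(self):
        y, groups, covs = self.edge_data(seed=1)
        y[groups == "A", 5] += 6.0
        res = ds.nbs(y, groups, covs, n_iter=100, seed=0)
        assert len(res.components) == 1
        assert res.components[0]["n_edges"] == 1

    def test_null_data_gives_empty_result(self):
        y, groups, covs = self.edge_data(seed=2)
        res = ds.nbs(y, groups, covs, n_iter=50, seed=0)
        # with edge alpha 0.001 and 45 null edges, suprathreshold hits are rare
        assert len(res.suprathreshold_edges) <= 1

    def test_null_calibration(self):
        """Familywise false-positive rate of NBS on pure-noise data ~ alpha."""
        rng = np.random.default_rng(3)
        hits = 0
        n_rep = 200
        for _ in range(n_rep):
            y, groups, covs = self.edge_data(
                n_nodes=15, n_subj=24, seed=int(rng.integers(2**31))
            )
            res = ds.nbs(y, groups, covs, edge_alpha=0.01, comp_alpha=0.05,
                         n_iter=100, seed=int(rng.integers(2**31)))
            hits += bool(res.significant_components)
        # binomial(200, 0.05): 3-sigma band around 10 is roughly [1, 19]
        assert 1 <= hits <= 19

    def test_component_p_monotone_in_size(self):
        y, groups, covs = self.edge_data(n_nodes=12, seed=4)
        # plant two effects: a 4-edge path and a single edge
        path_edges = [(0, 1), (1, 2), (2, 3), (3, 4)]
        iu = np.column_stack(np.triu_indices(12, 1))
        idx = {tuple(e): i for i, e in enumerate(iu)}
        for e in path_edges:
            y[groups == "A", idx[e]] += 6.0
        y[groups == "A", idx[(8, 9)]] += 6.0
        res = ds.nbs(y, groups, covs, n_iter=100, seed=0)
        sizes = [c["n_edges"] for c in res.components]
        ps = [c["p_corrected"] for c in res.components]
        assert sizes == sorted(sizes, reverse=True)
        assert all(ps[i] <= ps[i + 1] + 1e-12 for i in range(len(ps) - 1))


class TestSpearmanPartial:
    def test_constant_covariates_reduce_to_plain_spearman(self):
        rng = np.random.default_rng(8)
        x, y = rng.normal(size=20), rng.normal(size=20)
        res = ds.spearman_partial(x, y, np.ones((20, 1)))
        rho, _ = sps.spearmanr(x, y)
        assert res.rho == pytest.approx(rho, abs=1e-10)

    def test_monotone_relation_gives_rho_one(self):
        x = np.linspace(0, 5, 15)
        res = ds.spearman_partial(x, np.exp(x), None)
        assert res.rho == pytest.approx(1.0)
        assert res.p_value < 1e-12

    def test_matches_recursive_formula_oracle(self):
        rng = np.random.default_rng(9)
        x, y = rng.normal(size=25), rng.normal(size=25)
        covs = rng.normal(size=(25, 2))
        res = ds.spearman_partial(x, y, covs)
        expected = orc.partial_corr_recursive(
            sps.rankdata(x), sps.rankdata(y), sps.rankdata(covs, axis=0)
        )
        # the oracle partials out ranked covariates; ranking the covariates
        # is a monotone reparametrization the residual method must match on
        # rank-transformed inputs
        res_ranked = ds.spearman_partial(x, y, sps.rankdata(covs, axis=0))
        assert res_ranked.rho == pytest.approx(expected, abs=1e-10)
        assert -1.0 <= res.rho <= 1.0

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(10)
        df = pd.DataFrame(
            {
                "x": rng.normal(size=30),
                "y": rng.normal(size=30),
                "age": rng.normal(60, 10, 30),
                "gender": rng.integers(0, 2, 30).astype(float),
            }
        )
        # pingouin ranks the covariates as well, so hand it covariates that
        # are already ranks to put both methods on the same design
        df[["age", "gender"]] = sps.rankdata(df[["age", "gender"]], axis=0)
        res = ds.spearman_partial(
            df["x"].to_numpy(), df["y"].to_numpy(), df[["age", "gender"]]
        )
        ref = pg.partial_corr(df, x="x", y="y", covar=["age", "gender"],
                              method="spearman")
        assert res.rho == pytest.approx(float(ref["r"].iloc[0]), abs=1e-8)
        assert res.p_value == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-6)

    def test_degenerate_inputs_raise(self):
        # constant x: zero residual variance after ranking
        with pytest.raises(ds.StatsInputError):
            ds.spearman_partial(np.ones(10), np.arange(10.0), None)
        # too few observations for n > covariates + 2
        with pytest.raises(ds.StatsInputError):
            ds.spearman_partial(np.arange(2.0), np.arange(2.0), None)


class TestDemographics:
    def cohort_table(self):
        rng = np.random.default_rng(11)
        rows = []
        for g, n in (("HC", 27), ("HZ", 37), ("PHN", 18)):
            for _ in range(n):
                rows.append(
                    {
                        "group": g,
                        "age": rng.normal(60, 9),
                        "gender": int(rng.random() < 0.5),
                        "nrs": np.nan if g == "HC" else rng.normal(6.5, 1.8),
                    }
                )
        return pd.DataFrame(rows)

    def test_gender_chi2_matches_hand_formula(self):
        # the three-group gender split 14/13, 18/19, 10/8 as a 2x3 table
        table = np.array([[14, 18, 10], [13, 19, 8]])
        expected = orc.chi2_oracle(table)
        rows = []
        for g, (male, female) in zip(["HC", "HZ", "PHN"], [(14, 13), (18, 19), (10, 8)]):
            rows += [{"group": g, "gender": 1, "age": 60.0}] * male
            rows += [{"group": g, "gender": 0, "age": 60.0}] * female
        out = ds.demographics_tests(pd.DataFrame(rows))
        assert out["gender_chi2"]["statistic"] == pytest.approx(expected, abs=1e-10)
        assert out["gender_chi2"]["dof"] == 2

    def test_identical_samples_mannwhitney_nonsignificant(self):
        table = self.cohort_table()
        table.loc[table["group"] == "PHN", "nrs"] = (
            table.loc[table["group"] == "HZ", "nrs"].iloc[:18].to_numpy()
        )
        out = ds.demographics_tests(table)
        assert out["nrs_mannwhitney"]["p_value"] > 0.2

    def test_report_structure_and_missing_columns(self):
        out = ds.demographics_tests(self.cohort_table())
        assert {"age_kruskal", "gender_chi2", "nrs_mannwhitney"} <= set(out)
        for v in out.values():
            assert np.isfinite(v["statistic"]) and 0 <= v["p_value"] <= 1
        with pytest.raises(ds.StatsInputError, match="missing"):
            ds.demographics_tests(pd.DataFrame({"group": ["A"], "age": [1.0]}))
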