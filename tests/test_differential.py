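"""Per-antigen OLS, empirical-Bayes variance moderation, significance calls."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from abarray import differential as de
from abarray.core import AntigenMatrix


def _matrix(values, stage="batch_corrected", antigens=None, samples=None):
    antigens = antigens or [f"A{i}" for i in range(values.shape[0])]
    samples = samples or [f"S{i}" for i in range(values.shape[1])]
    vals = pd.DataFrame(values, index=antigens, columns=samples)
    return AntigenMatrix(vals, pd.DataFrame(True, index=vals.index, columns=vals.columns), stage)


def _manifest(groups, age=None, sex=None, diabetes=None):
    n = len(groups)
    return pd.DataFrame(
        {
            "sample_id": [f"S{i}" for i in range(n)],
            "group": groups,
            "age": age if age is not None else 70.0,
            "sex": sex if sex is not None else "F",
            "diabetes": diabetes if diabetes is not None else False,
            "batch": "2021",
            "moca_raw": 25,
            "low_education": False,
        }
    ).set_index("sample_id", drop=False)


class TestFitLinearModels:
    def test_two_group_coef_is_mean_difference(self):
        rng = np.random.default_rng(0)
        groups = ["control"] * 6 + ["dementia"] * 6
        manifest = _manifest(groups)
        vals = rng.normal(8, 1, (20, 12))
        m = _matrix(vals)
        design = de.build_design(manifest, ("dementia", "control"), covariates=())
        fit = de.fit_linear_models(m, design)
        expected = vals[:, 6:].mean(axis=1) - vals[:, :6].mean(axis=1)
        np.testing.assert_allclose(fit["coef"].to_numpy(), expected, atol=1e-10)

    def test_balanced_covariate_leaves_coef_unchanged(self):
        rng = np.random.default_rng(1)
        groups = ["control"] * 8 + ["dementia"] * 8
        # diabetes perfectly balanced within each group => orthogonal to contrast
        diabetes = [True, False] * 8
        manifest = _manifest(groups, diabetes=diabetes)
        vals = rng.normal(8, 1, (15, 16))
        m = _matrix(vals)
        d0 = de.build_design(manifest, ("dementia", "control"), covariates=())
        d1 = de.build_design(manifest, ("dementia", "control"), covariates=("diabetes",))
        f0 = de.fit_linear_models(m, d0)
        f1 = de.fit_linear_models(m, d1)
        np.testing.assert_allclose(f0["coef"], f1["coef"], atol=1e-10)

    def test_planted_effect_recovered_across_seeds(self):
        # Δ = 1.0, n = 30/30, σ = 0.5: se = 0.129, so ±0.25 = ±1.94 se and
        # the sampling distribution of the mean difference gives coverage
        # 2Φ(1.94)−1 ≈ 0.947; assert with binomial slack over 40 seeds
        hits = 0
        n_seeds = 40
        for seed in range(n_seeds):
            rng = np.random.default_rng(100 + seed)
            y = np.concatenate([rng.normal(8, 0.5, 30), rng.normal(9, 0.5, 30)])
            manifest = _manifest(["control"] * 30 + ["dementia"] * 30)
            m = _matrix(y[None, :])
            design = de.build_design(manifest, ("dementia", "control"), covariates=())
            coef = de.fit_linear_models(m, design)["coef"].iloc[0]
            hits += abs(coef - 1.0) <= 0.25
        assert hits / n_seeds >= 0.85

    def test_masked_cells_recompute_df(self):
        rng = np.random.default_rng(2)
        manifest = _manifest(["control"] * 10 + ["dementia"] * 10)
        vals = rng.normal(8, 1, (5, 20))
        m = _matrix(vals)
        m.valid.iloc[0, :4] = False
        design = de.build_design(manifest, ("dementia", "control"), covariates=())
        fit = de.fit_linear_models(m, design)
        assert fit.loc["A0", "n_used"] == 16
        assert fit.loc["A0", "df"] == 14
        assert fit.loc["A1", "df"] == 18


class TestModerateVariances:
    def test_equal_variances_degenerate_prior(self):
        # identical variances: infinite prior df, one common variance equal
        # to the log-moment-matched estimate s²·exp(log(df/2) − ψ(df/2))
        from scipy.special import digamma

        s2 = np.full(50, 0.25)
        df = np.full(50, 28.0)
        d0, s0_2, s2_tilde = de.moderate_variances(s2, df)
        assert np.isinf(d0)
        expected = 0.25 * np.exp(np.log(14.0) - digamma(14.0))
        np.testing.assert_allclose(s2_tilde, expected, rtol=1e-10)
        np.testing.assert_allclose(s2_tilde, 0.25, rtol=0.05)  # bias factor is small

    def test_prior_parameters_recovered(self):
        # true variances ~ s0² * d0 / chi²(d0): scaled inverse chi-square
        recovered_d0, recovered_s0 = [], []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            d0_true, s0_true, dfg = 4.0, 0.04, 30
            true_var = s0_true * d0_true / rng.chisquare(d0_true, 200)
            s2 = true_var * rng.chisquare(dfg, 200) / dfg
            d0, s0_2, _ = de.moderate_variances(s2, np.full(200, float(dfg)))
            recovered_d0.append(d0)
            recovered_s0.append(s0_2)
        assert all(2.0 <= d <= 8.0 for d in recovered_d0)
        assert all(0.02 <= s <= 0.08 for s in recovered_s0)

    def test_shrinkage_formula(self):
        rng = np.random.default_rng(3)
        s2 = rng.chisquare(10, 40) / 10 * 0.3
        df = np.full(40, 10.0)
        d0, s0_2, s2_tilde = de.moderate_variances(s2, df)
        np.testing.assert_allclose(
            s2_tilde, (d0 * s0_2 + df * s2) / (d0 + df), rtol=1e-10
        )


class TestCallDifferential:
    def _null_fit(self, n_ag=400, n=40, seed=0):
        rng = np.random.default_rng(seed)
        vals = rng.normal(8, 0.5, (n_ag, n))
        manifest = _manifest(["control"] * (n // 2) + ["dementia"] * (n // 2))
        m = _matrix(vals)
        design = de.build_design(manifest, ("dementia", "control"))
        return de.fit_linear_models(m, design)

    def test_zero_prior_df_equals_ordinary_t(self):
        fit = self._null_fit()
        table = de.call_differential(fit, d0=0.0, s2_tilde=fit["s2"].to_numpy())
        se = fit["se_unit"] * np.sqrt(fit["s2"])
        t_ord = (fit["coef"] / se).to_numpy()
        p_ord = 2 * stats.t.sf(np.abs(t_ord), fit["df"].to_numpy())
        table = table.loc[fit.index]
        np.testing.assert_allclose(table["t_mod"].to_numpy(), t_ord, rtol=1e-12)
        np.testing.assert_allclose(table["p"].to_numpy(), p_ord, rtol=1e-10)

    def test_null_p_uniform(self):
        fit = self._null_fit(n_ag=1000, seed=1)
        d0, _, s2_tilde = de.moderate_variances(fit["s2"].to_numpy(), fit["df"].to_numpy())
        table = de.call_differential(fit, d0, s2_tilde)
        ks = stats.kstest(table["p"].to_numpy(), "uniform")
        assert ks.pvalue > 0.01

    def test_up_down_partition(self):
        fit = self._null_fit(seed=2)
        d0, _, s2_tilde = de.moderate_variances(fit["s2"].to_numpy(), fit["df"].to_numpy())
        table = de.call_differential(fit, d0, s2_tilde)
        sig = table[table["significant"]]
        assert len(sig) == (sig["direction"] == "up").sum() + (sig["direction"] == "down").sum()
        assert ((table["log2fc"] > 0) == (table["direction"] == "up")).all()

    def test_alpha_zero_yields_nothing(self):
        fit = self._null_fit(seed=3)
        table = de.call_differential(fit, 0.0, fit["s2"].to_numpy(), alpha=0.0)
        assert not table["significant"].any()

    def test_bh_adjustment_is_more_conservative(self):
        fit = self._null_fit(seed=4)
        raw = de.call_differential(fit, 0.0, fit["s2"].to_numpy(), adjust="none")
        bh = de.call_differential(fit, 0.0, fit["s2"].to_numpy(), adjust="BH")
        assert bh["significant"].sum() <= raw["significant"].sum()
        assert (bh["fdr"] >= bh["p"] - 1e-15).all()


class TestOrderingInvariance:
    def test_results_invariant_to_sample_and_antigen_order(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(8, 0.6, (30, 24))
        groups = ["control"] * 12 + ["dementia"] * 12
        manifest = _manifest(groups)
        manifest["age"] = rng.normal(70, 5, 24)
        m1 = _matrix(vals)
        t1 = de.run_contrast(m1, manifest, ("dementia", "control"))

        perm_s = rng.permutation(24)
        perm_a = rng.permutation(30)
        m2 = _matrix(
            vals[np.ix_(perm_a, perm_s)],
            antigens=[f"A{i}" for i in perm_a],
            samples=[f"S{i}" for i in perm_s],
        )
        t2 = de.run_contrast(m2, manifest.iloc[perm_s], ("dementia", "control"))
        t2 = t2.loc[t1.index]
        np.testing.assert_allclose(t1["t_mod"], t2["t_mod"], rtol=1e-9)
        np.testing.assert_allclose(t1["p"], t2["p"], rtol=1e-9)


def test_overlap_table_intersects_significant_sets():
    a = pd.DataFrame({"significant": [True, True, False]}, index=["X", "Y", "Z"])
    b = pd.DataFrame({"significant": [True, False, True]}, index=["X", "Y", "Z"])
    out = de.overlap_table({"c1": a, "c2": b})
    assert out["antigen_id"].tolist() == ["X"]
    assert out["n_contrasts"].tolist() == [2]
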