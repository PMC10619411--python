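"""Linear models, effect sizes, mixed model, partial correlations, node scan."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from memnet.stats import (
    cohens_d_from_t,
    covariate_variants,
    fit_ols,
    fit_random_intercept_lmm,
    node_level_scan,
    partial_correlation,
    reml_log_likelihood_profile,
)


def _frame(rng, n=200):
    df = pd.DataFrame(
        {
            "male": rng.integers(0, 2, n),
            "age": rng.normal(23, 3, n),
            "icv": rng.normal(16, 1.5, n),
        }
    )
    df["y"] = 0.4 * df.male + 0.05 * df.age - 0.1 * df.icv + rng.normal(0, 1, n)
    return df


class TestFitOls:
    def test_coefficients_match_normal_equations(self):
        rng = np.random.default_rng(0)
        df = _frame(rng, 120)
        res = fit_ols(df, "y", ["male", "age", "icv"])
        x = np.column_stack([np.ones(120), df.male, df.age, df.icv])
        beta = np.linalg.pinv(x) @ df.y.to_numpy()
        assert np.allclose(res.coef.to_numpy(), beta)

    def test_matches_statsmodels_type2_anova(self):
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        rng = np.random.default_rng(1)
        df = _frame(rng, 150)
        df["y"] = df["y"] + 0.2 * df.male * df.icv
        res = fit_ols(df, "y", ["male", "icv", "male:icv", "age"])
        an = sm.stats.anova_lm(smf.ols("y ~ male + icv + male:icv + age", df).fit(), typ=2)
        for term, sm_term in [("male", "male"), ("icv", "icv"),
                              ("male:icv", "male:icv"), ("age", "age")]:
            assert res[term].f == pytest.approx(an.loc[sm_term, "F"], rel=1e-8)
            assert res[term].p == pytest.approx(an.loc[sm_term, "PR(>F)"], rel=1e-6)

    def test_binary_predictor_f_equals_t_squared(self):
        rng = np.random.default_rng(2)
        df = _frame(rng, 100)
        res = fit_ols(df, "y", ["male"])
        t, _ = sps.ttest_ind(df.y[df.male == 1], df.y[df.male == 0])
        assert res["male"].f == pytest.approx(t**2, rel=1e-10)

    def test_constant_response_gives_zero_f(self):
        rng = np.random.default_rng(3)
        df = _frame(rng, 50)
        df["y"] = 3.0
        res = fit_ols(df, "y", ["male", "age"])
        assert res["male"].f == pytest.approx(0.0, abs=1e-6)
        assert res["age"].f == pytest.approx(0.0, abs=1e-6)

    def test_rank_deficiency_names_collinear_columns(self):
        rng = np.random.default_rng(4)
        df = _frame(rng, 80)
        df["gmv"] = 2.0 * df["icv"]  # perfectly collinear
        with pytest.raises(ValueError, match="collinear"):
            fit_ols(df, "y", ["male", "icv", "gmv"])

    def test_d_consistent_with_raw_standardized_difference(self):
        # no covariates: d from t within 3% of the direct mean difference / SD
        rng = np.random.default_rng(5)
        n = 4000
        male = rng.integers(0, 2, n)
        y = 0.5 * male + rng.normal(0, 1, n)
        df = pd.DataFrame({"male": male, "y": y})
        res = fit_ols(df, "y", ["male"])
        pooled = np.sqrt(
            ((y[male == 1].var(ddof=1) * (sum(male == 1) - 1))
             + (y[male == 0].var(ddof=1) * (sum(male == 0) - 1)))
            / (n - 2)
        )
        direct = (y[male == 1].mean() - y[male == 0].mean()) / pooled
        assert res["male"].cohens_d == pytest.approx(direct, rel=0.03)

    def test_sign_convention_male_higher_positive_d(self):
        rng = np.random.default_rng(6)
        df = _frame(rng, 300)
        assert fit_ols(df, "y", ["male", "age", "icv"])["male"].cohens_d > 0


class TestCohensD:
    def test_reproduces_printed_effect_size(self):
        # F = 27.11 with groups 264/391 and residual df 651 -> d = 0.42
        d = cohens_d_from_t(np.sqrt(27.11), 264, 391, 651)
        assert round(d, 2) == 0.42

    def test_zero_t_zero_d(self):
        assert cohens_d_from_t(0.0, 50, 50, 98) == 0.0

    def test_equal_groups_reduces_to_classic_formula(self):
        t, n = 2.5, 60
        assert cohens_d_from_t(t, n, n, 2 * n - 2) == pytest.approx(
            2 * t / np.sqrt(2 * n - 2)
        )

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            cohens_d_from_t(1.0, 0, 10, 8)


class TestPartialCorrelation:
    def test_orthogonal_covariates_equal_plain_pearson(self):
        rng = np.random.default_rng(7)
        n = 500
        x, y = rng.normal(size=(2, n))
        z = rng.normal(size=n)
        z -= np.polyval(np.polyfit(x, z, 1), x) * 0  # independent anyway
        r_plain = np.corrcoef(x, y)[0, 1]
        r_part, _ = partial_correlation(x, y, z)
        assert r_part == pytest.approx(r_plain, abs=0.01)

    def test_identical_variables_r_one(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=50)
        r, p = partial_correlation(x, x.copy(), None)
        assert r == pytest.approx(1.0)

    def test_matches_pingouin(self):
        import pingouin as pg

        rng = np.random.default_rng(9)
        n = 300
        z1, z2 = rng.normal(size=(2, n))
        x = 0.5 * z1 + rng.normal(size=n)
        y = -0.3 * z1 + 0.2 * x + rng.normal(size=n)
        df = pd.DataFrame({"x": x, "y": y, "z1": z1, "z2": z2})
        ours_r, ours_p = partial_correlation(x, y, np.column_stack([z1, z2]))
        ref = pg.partial_corr(df, x="x", y="y", covar=["z1", "z2"])
        assert ours_r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
        assert ours_p == pytest.approx(float(ref["p_val"].iloc[0]), rel=1e-6)

    def test_zero_variance_residuals_error(self):
        z = np.arange(30.0)
        with pytest.raises(ValueError, match="zero-variance"):
            partial_correlation(2 * z, np.random.default_rng(0).normal(size=30), z)


def _long_data(rng, n_subj=80, sigma_u=0.8, male_effect=0.5):
    subj = np.repeat(np.arange(n_subj), 3)
    male = rng.integers(0, 2, n_subj)
    age = rng.normal(23, 3, n_subj)
    room = rng.integers(0, 2, n_subj)
    u = rng.normal(0, sigma_u, n_subj)
    val = np.tile(["negative", "neutral", "positive"], n_subj)
    y = (
        8 + male_effect * male[subj] - 2.0 * (val == "neutral")
        + 0.05 * age[subj] + 0.5 * room[subj] + u[subj]
        + rng.normal(0, 0.7, len(subj))
    )
    return pd.DataFrame(
        {"id": subj, "male": male[subj], "age": age[subj], "room2": room[subj],
         "valence": val, "recall": y}
    )


class TestRandomInterceptLmm:
    BETWEEN = ["male", "age", "room2"]
    WITHIN = ["valence", "male:valence"]

    def test_no_subject_variance_matches_ols(self):
        rng = np.random.default_rng(10)
        df = _long_data(rng, n_subj=120, sigma_u=0.0)
        lmm = fit_random_intercept_lmm(df, "recall", "id", self.BETWEEN, self.WITHIN)
        ols = fit_ols(df, "recall", self.BETWEEN + self.WITHIN)
        assert np.allclose(lmm.coef.to_numpy(), ols.coef.to_numpy(), atol=0.02)
        assert lmm.variance_components["sigma2_subject"] < 0.05

    def test_reml_maximum_matches_grid_search(self):
        rng = np.random.default_rng(11)
        df = _long_data(rng, n_subj=6)
        lmm = fit_random_intercept_lmm(df, "recall", "id", ["male"], ["valence"])
        gamma_hat = (lmm.variance_components["sigma2_subject"]
                     / lmm.variance_components["sigma2_resid"])
        grid = np.linspace(max(gamma_hat - 1.0, 1e-6), gamma_hat + 1.0, 2001)
        crit = reml_log_likelihood_profile(df, "recall", "id", ["male"], ["valence"], grid)
        assert abs(grid[np.argmin(crit)] - gamma_hat) < 2e-3

    def test_matches_statsmodels_mixedlm(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(12)
        df = _long_data(rng)
        lmm = fit_random_intercept_lmm(df, "recall", "id", self.BETWEEN, self.WITHIN)
        md = sm.MixedLM.from_formula(
            "recall ~ male + age + room2 + valence + male:valence",
            groups="id", data=df,
        ).fit(reml=True)
        assert lmm.variance_components["sigma2_resid"] == pytest.approx(
            md.scale, rel=1e-4
        )
        assert lmm.variance_components["sigma2_subject"] == pytest.approx(
            float(md.cov_re.iloc[0, 0]), rel=1e-3, abs=1e-6
        )
        ours = lmm.coef.sort_index()
        theirs = pd.Series(
            {
                "Intercept": md.params["Intercept"],
                "male": md.params["male"],
                "age": md.params["age"],
                "room2": md.params["room2"],
                "valence[neutral]": md.params["valence[T.neutral]"],
                "valence[positive]": md.params["valence[T.positive]"],
                "male:valence[neutral]": md.params["male:valence[T.neutral]"],
                "male:valence[positive]": md.params["male:valence[T.positive]"],
            }
        ).sort_index()
        assert np.allclose(ours.to_numpy(), theirs.to_numpy(), atol=1e-6)

    def test_fixed_effect_recovery_over_replicates(self):
        rng = np.random.default_rng(13)
        coefs = []
        for _ in range(100):
            df = _long_data(rng, n_subj=60, male_effect=0.5)
            lmm = fit_random_intercept_lmm(df, "recall", "id",
                                           self.BETWEEN, self.WITHIN)
            coefs.append(lmm.coef["male"])
        se = np.std(coefs, ddof=1) / np.sqrt(len(coefs))
        assert np.mean(coefs) == pytest.approx(0.5, abs=2.5 * se + 0.02)

    def test_denominator_df_between_within_convention(self):
        rng = np.random.default_rng(14)
        df = _long_data(rng, n_subj=655)
        lmm = fit_random_intercept_lmm(df, "recall", "id", self.BETWEEN, self.WITHIN)
        assert lmm["male"].df2 == 651      # 655 subjects - 4 between columns
        assert lmm["valence"].df2 == 1306  # 1965 - 655 - 4 within columns
        assert lmm["male:valence"].df2 == 1306

    def test_unbalanced_groups_rejected(self):
        rng = np.random.default_rng(15)
        df = _long_data(rng).iloc[:-1]
        with pytest.raises(ValueError, match="balanced"):
            fit_random_intercept_lmm(df, "recall", "id", self.BETWEEN, self.WITHIN)


class TestTypeIErrorControl:
    def test_null_p_values_uniform(self):
        """Under the null the sex-term p-values are Uniform(0, 1)."""
        rng = np.random.default_rng(16)
        pvals = []
        for _ in range(400):
            df = _frame(rng, 60)
            df["y"] = rng.normal(size=60)  # unrelated to everything
            pvals.append(fit_ols(df, "y", ["male", "age", "icv"])["male"].p)
        stat, p = sps.kstest(pvals, "uniform")
        assert p > 0.001


class TestNodeScan:
    def _cohort(self, rng, n=300):
        df = pd.DataFrame(
            {
                "male": rng.integers(0, 2, n),
                "age": rng.normal(23, 3, n),
                "icv": rng.normal(16, 1.5, n),
            }
        )
        return df

    def test_single_node_reduces_to_fit_ols(self):
        rng = np.random.default_rng(17)
        cohort = self._cohort(rng)
        y = rng.normal(size=len(cohort))
        scan = node_level_scan(pd.DataFrame({"n0": y}), cohort)
        cohort2 = cohort.copy()
        cohort2["_y"] = y
        direct = fit_ols(cohort2, "_y", ["male", "age", "icv"])
        assert scan.loc[0, "F"] == pytest.approx(direct["male"].f)
        assert scan.attrs["alpha_node"] == 0.05

    def test_injected_effect_flagged(self):
        rng = np.random.default_rng(18)
        cohort = self._cohort(rng, n=655)
        nodes = pd.DataFrame(
            rng.normal(size=(655, 20)), columns=[f"n{i}" for i in range(20)]
        )
        nodes["n7"] = nodes["n7"] + 0.8 * cohort["male"]  # d = 0.8 at n = 655
        scan = node_level_scan(nodes, cohort)
        assert bool(scan.loc[scan.node == "n7", "significant"].iloc[0])

    def test_null_false_flag_rate(self):
        rng = np.random.default_rng(19)
        flags = 0
        total = 0
        for _ in range(40):
            cohort = self._cohort(rng, n=120)
            nodes = pd.DataFrame(
                rng.normal(size=(120, 25)), columns=[f"n{i}" for i in range(25)]
            )
            scan = node_level_scan(nodes, cohort)
            flags += int(scan["significant"].sum())
            total += len(scan)
        # expected false-flag rate alpha/R per node => alpha per scan
        expected = 0.05 * total / 25
        assert flags <= expected + 3 * np.sqrt(expected) + 1


class TestCovariateVariants:
    def _cohort(self, rng, n=400):
        male = rng.integers(0, 2, n)
        hc = np.where(
            male == 1, "na",
            rng.choice(["no", "yes", None], n, p=[0.4, 0.5, 0.1]),
        )
        df = pd.DataFrame(
            {
                "male": male,
                "age": rng.normal(23, 3, n),
                "icv": rng.normal(16, 1.5, n) + male,
                "hc_use": hc,
            }
        )
        metric = 0.3 * male + 0.02 * df.age + rng.normal(0, 1, n)
        return df, metric

    def test_orthogonal_noise_covariate_leaves_sex_f_stable(self):
        rng = np.random.default_rng(20)
        df, metric = self._cohort(rng)
        extra = pd.DataFrame({"noise": rng.normal(size=len(df))})
        out = covariate_variants(metric, df, extra_covariates=extra)
        f_base = out["base"]["male"].f
        f_plus = out["plus_noise"]["male"].f
        assert f_plus == pytest.approx(f_base, rel=0.15)

    def test_hc_factor_splits_females(self):
        rng = np.random.default_rng(21)
        df, metric = self._cohort(rng)
        out = covariate_variants(metric, df)
        assert "hc_use" in out
        res = out["hc_use"]
        assert res["hc_use"].df1 == 2  # three levels: na(male), no, yes

    def test_collinear_extra_covariate_raises(self):
        rng = np.random.default_rng(22)
        df, metric = self._cohort(rng)
        extra = pd.DataFrame({"gmv": df["icv"].to_numpy()})
        with pytest.raises(ValueError, match="collinear"):
            covariate_variants(metric, df, extra_covariates=extra)
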