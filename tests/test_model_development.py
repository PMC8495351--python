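"""REML random-coefficient fitting, subset selection and phase-two OLS."""

import numpy as np
import pandas as pd
import pytest

from dmintake.errors import ConfigurationError, DesignError
from dmintake.model_development import (
    DesignSpec,
    enumerate_and_select,
    fit_ols,
    fit_random_coefficient,
)
from dmintake.synthetic_data import LiteratureGenConfig, generate_literature


def _one_way(rng, s, n, mu=10.0, sd_b=1.5, sd_w=1.0):
    u = rng.normal(0, sd_b, s)
    y = mu + np.repeat(u, n) + rng.normal(0, sd_w, s * n)
    return y, np.ones((s * n, 1)), np.repeat(np.arange(s), n)


class TestRandomCoefficientFit:
    def test_balanced_one_way_matches_anova_closed_form(self, rng):
        """REML on a balanced one-way layout equals the ANOVA estimators."""
        s, n = 20, 5
        y, X, g = _one_way(rng, s, n)
        fit = fit_random_coefficient(y, X, g)
        ybar = y.reshape(s, n).mean(axis=1)
        msb = n * ((ybar - y.mean()) ** 2).sum() / (s - 1)
        msw = ((y.reshape(s, n) - ybar[:, None]) ** 2).sum() / (s * (n - 1))
        assert fit.g_var[0] == pytest.approx((msb - msw) / n, rel=1e-4)
        assert fit.sigma2 == pytest.approx(msw, rel=1e-4)
        assert fit.beta[0] == pytest.approx(y.mean(), abs=1e-6)

    def test_zero_between_study_variance_hits_boundary(self, rng):
        s, n = 25, 6
        y, X, g = _one_way(rng, s, n, sd_b=0.0)
        fit = fit_random_coefficient(y, X, g)
        assert fit.g_var[0] < 0.05
        pooled = y.var(ddof=1)
        assert fit.sigma2 == pytest.approx(pooled, rel=0.1)

    def test_variance_component_recovery(self):
        """Mean REML estimates over replicates recover g=2.25, sigma2=1."""
        reps, s, n = 120, 50, 6
        g_hat, s2_hat = [], []
        for seed in range(reps):
            rng = np.random.default_rng(1000 + seed)
            y, X, g = _one_way(rng, s, n, sd_b=1.5, sd_w=1.0)
            fit = fit_random_coefficient(y, X, g)
            g_hat.append(fit.g_var[0])
            s2_hat.append(fit.sigma2)
        for est, truth in ((g_hat, 2.25), (s2_hat, 1.0)):
            est = np.asarray(est)
            mc_se = est.std(ddof=1) / np.sqrt(reps)
            assert abs(est.mean() - truth) < 3 * mc_se

    def test_single_study_collapses_to_ols(self, rng):
        n = 30
        x = rng.normal(0, 1, n)
        y = 2 + 3 * x + rng.normal(0, 1, n)
        X = np.column_stack([np.ones(n), x])
        fit = fit_random_coefficient(y, X, np.zeros(n, dtype=int))
        ols = fit_ols(y, X)
        assert np.allclose(fit.beta, ols.params.to_numpy(), atol=1e-6)
        assert np.all(fit.g_var == 0)

    def test_blups_sum_near_zero(self, rng):
        s, n = 30, 5
        y, X, g = _one_way(rng, s, n)
        fit = fit_random_coefficient(y, X, g)
        intercept_blups = np.array([fit.u[k][0] for k in fit.u])
        assert abs(intercept_blups.mean()) < 0.05

    def test_rank_deficient_design(self, rng):
        y = rng.normal(size=20)
        X = np.column_stack([np.ones(20), np.ones(20)])
        with pytest.raises(DesignError):
            fit_random_coefficient(y, X, np.repeat(np.arange(4), 5))

    def test_aic_bic_bookkeeping(self, rng):
        s, n = 15, 4
        y, X, g = _one_way(rng, s, n)
        fit = fit_random_coefficient(y, X, g)
        q = X.shape[1] + 1
        assert fit.aic == pytest.approx(-2 * fit.loglik_reml + 2 * q)
        assert fit.bic == pytest.approx(-2 * fit.loglik_reml + q * np.log(s))
        assert fit.n_obs == s * n and fit.n_studies == s


class TestSelection:
    def test_single_candidate_trivially_selected(self, literature_df):
        spec = DesignSpec(candidates=("fcm",))
        table = enumerate_and_select(literature_df, spec)
        assert len(table) == 1 and table.iloc[0]["subset"] == ("fcm",)

    def test_exclusion_pair_never_coselected(self, literature_df):
        df = literature_df.copy()
        df["bw"] = df["bw_kg"]
        spec = DesignSpec(candidates=("bw", "mbw"))
        table = enumerate_and_select(df, spec)
        subsets = [set(s) for s in table["subset"]]
        assert {"bw", "mbw"} not in subsets
        assert len(table) == 2  # the two singletons

    def test_true_subset_wins_aic(self, literature_df):
        spec = DesignSpec(candidates=("mbw", "fcm", "ndf_pct_dm"), max_subset_size=3)
        table = enumerate_and_select(literature_df, spec)
        assert tuple(table.iloc[0]["subset"]) == ("mbw", "fcm", "ndf_pct_dm")

    def test_no_admissible_subset(self, literature_df):
        spec = DesignSpec(candidates=("mbw",), max_subset_size=0)
        with pytest.raises(ConfigurationError):
            enumerate_and_select(literature_df, spec)

    def test_common_complete_case_rows(self, literature_df):
        """Missing values in one candidate shrink the row set for all fits."""
        df = literature_df.copy()
        df.loc[df.index[:12], "ndf_pct_dm"] = np.nan
        spec = DesignSpec(candidates=("fcm", "ndf_pct_dm"), max_subset_size=2)
        table = enumerate_and_select(df, spec)
        # AICs must come from the same rows: refit fcm-only on complete cases
        cc = df.dropna(subset=["dmi_kg_d", "study_id", "fcm", "ndf_pct_dm"])
        X = np.column_stack([np.ones(len(cc)), cc["fcm"]])
        fit = fit_random_coefficient(cc["dmi_kg_d"].to_numpy(), X,
                                     cc["study_id"].to_numpy())
        row = table[table["subset"] == ("fcm",)].iloc[0]
        assert row["aic"] == pytest.approx(fit.aic, rel=1e-6)


class TestOls:
    def test_exact_fit(self):
        X = np.column_stack([np.ones(5), np.arange(5.0)])
        y = 2.0 + 0.5 * np.arange(5.0)
        fit = fit_ols(y, X)
        assert fit.resid_sd == pytest.approx(0.0, abs=1e-10)
        assert fit.params.to_numpy() == pytest.approx([2.0, 0.5])

    def test_three_point_hand_example(self):
        X = np.column_stack([np.ones(3), [0.0, 1.0, 2.0]])
        fit = fit_ols(np.array([1.0, 2.0, 4.0]), X)
        assert fit.params.iloc[1] == pytest.approx(1.5)
        assert fit.params.iloc[0] == pytest.approx(5 / 6)

    def test_matches_normal_equations(self, rng):
        n = 60
        X = np.column_stack([np.ones(n), rng.normal(size=(n, 2))])
        y = X @ [1.0, 2.0, -0.5] + rng.normal(0, 0.3, n)
        fit = fit_ols(y, X)
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert np.allclose(fit.params.to_numpy(), beta, atol=1e-8)
        resid = y - X @ beta
        s2 = resid @ resid / (n - 3)
        se = np.sqrt(np.diag(s2 * np.linalg.inv(X.T @ X)))
        assert np.allclose(fit.se.to_numpy(), se, atol=1e-8)

    def test_rank_deficiency_raises(self, rng):
        X = np.column_stack([np.ones(10), np.ones(10)])
        with pytest.raises(DesignError):
            fit_ols(rng.normal(size=10), X)

    def test_coefficient_recovery_from_generator(self):
        """OLS on KFSD-generative data recovers the generating coefficients."""
        reps = 25
        est = []
        for seed in range(reps):
            df = generate_literature(LiteratureGenConfig(
                n_studies=40, n_obs_total=170, seed=3000 + seed))
            X = np.column_stack([np.ones(len(df)), df["mbw"], df["fcm"],
                                 df["ndf_pct_dm"]])
            est.append(fit_ols(df["dmi_kg_d"].to_numpy(), X).params.to_numpy())
        est = np.asarray(est)
        truth = np.array([4.103, 0.112, 0.284, -0.119])
        mc_se = est.std(axis=0, ddof=1) / np.sqrt(reps)
        assert np.all(np.abs(est.mean(axis=0) - truth) < 3 * mc_se + 1e-9)
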