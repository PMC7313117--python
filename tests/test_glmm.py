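"""Binomial GLMM machinery: likelihood, repeatability, effect sizes,
conditional modes, pruning."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.special import expit

from cpforage import (
    adjusted_repeatability,
    backward_prune_interactions,
    build_design,
    conditional_modes,
    effect_size_r,
    fit_glm_binomial,
    fit_glmm_binomial,
    lrt_random_effect,
    r2_nakagawa,
    sigma_id_for_repeatability,
    standardize_columns,
)
from cpforage.simulate import simulate_binomial_dataset


@pytest.fixture(scope="module")
def fitted_study():
    df = simulate_binomial_dataset(30, 20, sigma_id=0.77, seed=11)
    X, names = build_design(df, ["solar", "cwc", "stage"])
    fit = fit_glmm_binomial(df["df_trip"], X, df["individual_id"], names=names)
    return df, fit


class TestLikelihood:
    def test_zero_sigma_data_matches_plain_logistic(self):
        df = simulate_binomial_dataset(25, 20, sigma_id=0.0, seed=2)
        X, names = build_design(df, ["solar", "stage"])
        fit = fit_glmm_binomial(df["df_trip"], X, df["individual_id"], names=names)
        glm = fit_glm_binomial(df["df_trip"], X)
        # variance estimate collapses, coefficients agree with the GLM oracle
        assert fit.sigma_id < 0.15
        if fit.sigma_id < 1e-6:
            assert np.allclose(fit.beta, glm["beta"], atol=1e-6)
        assert fit.loglik >= glm["loglik"] - 1e-6

    def test_no_predictor_balanced_data(self):
        rng = np.random.default_rng(5)
        y = rng.integers(0, 2, size=400).astype(float)
        X = np.ones((400, 1))
        groups = np.repeat(np.arange(20), 20)
        fit = fit_glmm_binomial(y, X, groups, names=["intercept"])
        assert abs(fit.beta[0]) < 0.25
        assert fit.sigma_id < 0.3

    def test_requires_two_individuals(self):
        with pytest.raises(ValueError):
            fit_glmm_binomial(np.array([1.0, 0.0]), np.ones((2, 1)), ["a", "a"])


class TestRepeatability:
    def test_zero_variance_gives_zero(self, fitted_study):
        _, fit = fitted_study
        import copy

        f0 = copy.copy(fit)
        f0.sigma_id = 0.0
        assert adjusted_repeatability(f0).r_adj == 0.0

    def test_direct_substitution(self):
        # sigma2 = pi^2/3 and pbar = 0.5 -> R = (pi^2/3) / (pi^2/3 + 4)
        sigma2 = np.pi**2 / 3
        expected = sigma2 / (sigma2 + 4.0)
        got = sigma2 / (sigma2 + 1.0 / (0.5 * 0.5))
        assert got == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.451, abs=5e-4)

    def test_sigma_for_target_round_trips(self):
        s = sigma_id_for_repeatability(0.13, 0.5)
        assert s**2 / (s**2 + 4.0) == pytest.approx(0.13, rel=1e-12)

    def test_recovers_target_in_simulation(self):
        s = sigma_id_for_repeatability(0.13, 0.5)
        vals = []
        for seed in range(8):
            df = simulate_binomial_dataset(40, 30, sigma_id=s, seed=300 + seed)
            X, names = build_design(df, ["solar", "rain", "twc", "cwc", "stage"])
            fit = fit_glmm_binomial(df["df_trip"], X, df["individual_id"], names=names)
            vals.append(adjusted_repeatability(fit).r_adj)
        assert abs(np.mean(vals) - 0.13) < 0.05


class TestR2AndEffectSize:
    def test_null_model_has_zero_marginal_r2(self):
        df = simulate_binomial_dataset(20, 15, beta={}, sigma_id=0.5, seed=3)
        X, names = build_design(df, [])
        fit = fit_glmm_binomial(df["df_trip"], X, df["individual_id"], names=names)
        r2m, r2c = r2_nakagawa(fit)
        assert r2m == pytest.approx(0.0, abs=1e-9)
        assert r2c >= r2m

    def test_variance_partition_substitution(self, fitted_study):
        _, fit = fitted_study
        r2m, r2c = r2_nakagawa(fit)
        var_f = np.var(fit.X @ fit.beta)
        s2d = adjusted_repeatability(fit).sigma2_dist
        assert r2m == pytest.approx(var_f / (var_f + fit.sigma2_id + s2d), rel=1e-12)
        assert r2c - r2m == pytest.approx(fit.sigma2_id / (var_f + fit.sigma2_id + s2d), rel=1e-12)

    def test_effect_size_zero_when_beta_zero(self, fitted_study):
        _, fit = fitted_study
        import copy

        f0 = copy.copy(fit)
        f0.beta = fit.beta.copy()
        f0.beta[fit.names.index("cwc")] = 0.0
        assert effect_size_r(f0, "cwc") == 0.0

    def test_single_covariate_effect_size_is_sqrt_marginal_r2(self):
        df = simulate_binomial_dataset(25, 20, beta={"solar": 0.8}, sigma_id=0.5, seed=9)
        X, names = build_design(df, ["solar"])
        fit = fit_glmm_binomial(df["df_trip"], X, df["individual_id"], names=names)
        r2m, _ = r2_nakagawa(fit)
        assert effect_size_r(fit, "solar") == pytest.approx(np.sqrt(r2m), rel=1e-9)


class TestConditionalModes:
    def test_zero_sigma_gives_all_zero_modes(self):
        df = simulate_binomial_dataset(20, 10, sigma_id=0.0, seed=21)
        X, names = build_design(df, ["solar"])
        fit = fit_glmm_binomial(df["df_trip"], X, df["individual_id"], names=names)
        if fit.sigma_id < 1e-6:
            assert np.allclose(fit.conditional_mode, 0.0)
            assert np.allclose(fit.mode_sd, 0.0)

    def test_mode_matches_grid_search_oracle(self, fitted_study):
        df, fit = fitted_study
        code = fit.group_code
        eta = fit.X @ fit.beta
        g = 0
        ix = code == g
        grid = np.linspace(-4, 4, 40001)
        y = fit.y[ix]
        dens = (
            (y[:, None] * (eta[ix][:, None] + grid[None, :])
             - np.logaddexp(0, eta[ix][:, None] + grid[None, :])).sum(axis=0)
            - 0.5 * grid**2 / fit.sigma2_id
        )
        assert fit.conditional_mode[g] == pytest.approx(grid[np.argmax(dens)], abs=1e-3)

    def test_shrinkage_direction(self, fitted_study):
        df, fit = fitted_study
        marg = expit(fit.X @ fit.beta)
        frame = pd.DataFrame(
            {"ind": df["individual_id"], "resid": fit.y - marg}
        ).groupby("ind").mean()
        modes = conditional_modes(fit).set_index("individual_id")["mode"]
        excess = frame["resid"].reindex(modes.index)
        # individuals with more DF trips than the fixed effects predict sit above 0
        agree = np.mean(np.sign(excess[np.abs(excess) > 0.05]) ==
                        np.sign(modes[np.abs(excess) > 0.05]))
        assert agree > 0.9

    def test_mean_of_modes_near_zero(self, fitted_study):
        _, fit = fitted_study
        assert abs(np.mean(fit.conditional_mode)) < 0.15


class TestLRT:
    def test_identical_models_give_zero(self):
        chi2, df, p = lrt_random_effect(-100.0, -100.0)
        assert chi2 == 0.0 and p == 1.0

    def test_lower_full_loglik_rejected(self):
        with pytest.raises(ValueError):
            lrt_random_effect(-101.0, -100.0)

    def test_detects_strong_heterogeneity(self):
        df = simulate_binomial_dataset(30, 20, sigma_id=1.2, seed=8)
        X, names = build_design(df, ["solar"])
        full = fit_glmm_binomial(df["df_trip"], X, df["individual_id"], names=names)
        red = fit_glm_binomial(df["df_trip"], X)
        chi2, dfree, p = lrt_random_effect(full.loglik, red["loglik"])
        assert p < 1e-4


class TestPruning:
    def _data(self, beta_int, seed=0, n_ind=40, n_per=25):
        df = simulate_binomial_dataset(n_ind, n_per, sigma_id=0.5, seed=seed)
        rng = np.random.default_rng(seed + 999)
        sex = np.repeat((rng.random(n_ind) < 0.4).astype(float), n_per)
        df["sex"] = (sex - sex.mean()) / sex.std()
        eta_extra = beta_int * df["sex"] * df["solar"]
        flip = expit(eta_extra)  # add interaction signal by re-drawing y
        eta0 = np.log(flip / (1 - flip))
        # regenerate response including the interaction term
        base_eta = (0.7 * df["solar"] - 0.12 * df["rain"] - 0.16 * df["twc"]
                    + 0.32 * df["cwc"] + 0.53 * df["stage"] + eta0)
        df["df_trip"] = (rng.random(len(df)) < expit(base_eta)).astype(float)
        return df

    BASE = ["solar", "rain", "twc", "cwc", "stage", "sex"]
    INTS = ["sex:solar", "sex:rain", "sex:twc", "sex:cwc"]

    def test_all_weak_interactions_removed(self):
        df = self._data(beta_int=0.0, seed=4)
        fit, kept = backward_prune_interactions(
            df, "df_trip", self.BASE, self.INTS, "individual_id"
        )
        assert kept == [] or all(
            not fit.ci_contains_zero(t) for t in kept
        )  # usually all pruned under the null
        assert "sex:solar" not in fit.names or kept

    def test_true_interaction_retained(self):
        df = self._data(beta_int=1.0, seed=6)
        fit, kept = backward_prune_interactions(
            df, "df_trip", self.BASE, self.INTS, "individual_id"
        )
        assert "sex:solar" in kept

    def test_no_ci_contains_zero_leaves_model_unchanged(self):
        df = self._data(beta_int=1.0, seed=7)
        X, names = build_design(df, self.BASE + ["sex:solar"])
        fit = fit_glmm_binomial(df["df_trip"], X, df["individual_id"], names=names)
        if not fit.ci_contains_zero("sex:solar"):
            refit, kept = backward_prune_interactions(
                df, "df_trip", self.BASE, ["sex:solar"], "individual_id"
            )
            assert kept == ["sex:solar"]
            assert np.allclose(refit.beta, fit.beta, atol=1e-8)


class TestDesignHelpers:
    def test_standardize_columns(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0], "b": [0, 0, 1, 1]})
        z = standardize_columns(df, ["a", "b"])
        assert z["a"].mean() == pytest.approx(0, abs=1e-12)
        assert z["a"].std(ddof=0) == pytest.approx(1, rel=1e-12)

    def test_constant_column_rejected(self):
        df = pd.DataFrame({"a": [1.0, 1.0, 1.0]})
        with pytest.raises(ValueError):
            standardize_columns(df, ["a"])

    def test_interaction_column_is_product(self):
        df = pd.DataFrame(
            {"a": [1.0, 2.0, 4.0, -1.0, 0.5], "b": [3.0, 5.0, 7.0, 2.0, -4.0]}
        )
        X, names = build_design(df, ["a", "b", "a:b"])
        assert np.allclose(X[:, 3], df["a"] * df["b"])
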