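"""Detection-model estimation: IRLS against an independent optimizer,
likelihood identities, dispersion, information criteria and mixed-model
machinery."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from camtel.glmm import agq_loglik, fit_glmm_arrays
from camtel.inference import (
    FitResult,
    ModelSpec,
    conditional_r2,
    fit_glm,
    fit_glmm,
    information_criteria,
    likelihood_ratio_test,
    offset_consistency_check,
    quasi_dispersion,
    selection_table,
)


def _binary_fixture(n=300, seed=0, beta_ud=1.0, sexdiff=0.7):
    """Small table with known cloglog structure.

    The intercept is centred so that the linear predictor stays in a
    realistic range (mean detection probability ~0.3) for any exponent.
    """
    rng = np.random.default_rng(seed)
    ud = np.exp(rng.uniform(-19, -15, n))
    sex = rng.choice(["F", "M"], n)
    T = np.full(n, 36.0)
    intercept = -1.0 - beta_ud * float(np.mean(np.log(ud))) - math.log(36.0)
    eta = intercept + sexdiff * (sex == "M") + beta_ud * np.log(ud) + np.log(T)
    p = -np.expm1(-np.exp(eta))
    y = (rng.uniform(size=n) < p).astype(int)
    return pd.DataFrame(
        dict(
            animal_id=[f"A{i % 20}" for i in range(n)],
            camera_id=[f"C{i % 30}" for i in range(n)],
            sex=sex,
            exposure_days=T,
            ud=ud,
            isopleth_pct=rng.integers(1, 91, n),
            core=rng.integers(0, 2, n).astype(bool),
            photo_count=y,
            detected=y,
        )
    )


def _count_fixture(n=400, seed=1, frailty_shape=None):
    rng = np.random.default_rng(seed)
    ud = np.exp(rng.uniform(-19, -15, n))
    sex = rng.choice(["F", "M"], n)
    T = np.full(n, 36.0)
    mu = np.exp(12.2 + 0.7 * (sex == "M") + np.log(ud) + np.log(T))
    if frailty_shape is not None:
        mu = mu * rng.gamma(frailty_shape, 1.0 / frailty_shape, n)
    y = rng.poisson(mu)
    return pd.DataFrame(
        dict(
            animal_id=[f"A{i % 20}" for i in range(n)],
            camera_id=[f"C{i % 40}" for i in range(n)],
            sex=sex,
            exposure_days=T,
            ud=ud,
            isopleth_pct=rng.integers(1, 91, n),
            core=rng.integers(0, 2, n).astype(bool),
            photo_count=y,
            detected=(y > 0).astype(int),
        )
    )


class TestFitGlm:
    def test_irls_matches_independent_optimizer_cloglog(self):
        """IRLS coefficients equal a Nelder-Mead/BFGS maximization of the
        same bernoulli-cloglog likelihood to 1e-5."""
        table = _binary_fixture(n=250, seed=3)
        fit = fit_glm(table, ModelSpec(terms="Sex + logUD"))
        y = table["detected"].to_numpy(float)
        X = np.column_stack(
            [
                np.ones(len(table)),
                (table["sex"] == "M").to_numpy(float),
                np.log(table["ud"].to_numpy()),
            ]
        )
        off = np.log(table["exposure_days"].to_numpy())

        def nll(b):
            eta = X @ b + off
            p = -np.expm1(-np.exp(np.clip(eta, -30, 30)))
            p = np.clip(p, 1e-12, 1 - 1e-12)
            return -np.sum(y * np.log(p) + (1 - y) * np.log1p(-p))

        ybar = y.mean()
        b0 = np.array([math.log(-math.log(1 - ybar)) - off.mean(), 0.0, 0.0])
        res = optimize.minimize(nll, b0, method="BFGS",
                                options={"gtol": 1e-10, "maxiter": 2000})
        assert np.allclose(fit.params.to_numpy(), res.x, atol=1e-5)

    def test_irls_matches_independent_optimizer_poisson(self):
        table = _count_fixture(n=300, seed=4)
        spec = ModelSpec(response="count", link="log", family="poisson",
                         terms="Sex + logUD")
        fit = fit_glm(table, spec)
        y = table["photo_count"].to_numpy(float)
        X = np.column_stack(
            [
                np.ones(len(table)),
                (table["sex"] == "M").to_numpy(float),
                np.log(table["ud"].to_numpy()),
            ]
        )
        off = np.log(table["exposure_days"].to_numpy())

        def nll(b):
            eta = np.clip(X @ b + off, -30, 30)
            return -np.sum(y * eta - np.exp(eta))

        res = optimize.minimize(nll, np.zeros(3), method="BFGS",
                                options={"gtol": 1e-10, "maxiter": 2000})
        assert np.allclose(fit.params.to_numpy(), res.x, atol=1e-5)

    def test_poisson_constant_intercept_closed_form(self):
        """Intercept-only Poisson log-link: intercept = log(mean count)."""
        table = _count_fixture(n=200, seed=5)
        spec = ModelSpec(response="count", link="log", family="poisson",
                         terms="1", exposure_offset=False)
        fit = fit_glm(table, spec)
        assert fit.params["Intercept"] == pytest.approx(
            math.log(table["photo_count"].mean()), abs=1e-8
        )

    def test_cloglog_identity_on_fitted_values(self):
        table = _binary_fixture()
        fit = fit_glm(table, ModelSpec(terms="Sex + logUD"))
        assert np.allclose(fit.fitted, -np.expm1(-np.exp(fit.eta)), atol=1e-10)

    def test_parameter_recovery_large_n(self):
        """beta_Sex and beta_UD recovered on a large simple-model table."""
        table = _binary_fixture(n=5000, seed=6, beta_ud=1.0, sexdiff=0.7)
        fit = fit_glm(table, ModelSpec(terms="Sex + logUD"))
        assert fit.params["logUD"] == pytest.approx(1.0, abs=0.1)
        assert fit.params["Sex[T.M]"] == pytest.approx(0.7, abs=0.2)

    def test_quasi_same_point_estimates_scaled_ses(self):
        table = _count_fixture(n=300, seed=7, frailty_shape=1.0)
        base = ModelSpec(response="count", link="log", family="poisson",
                         terms="Sex + logUD")
        quasi = ModelSpec(response="count", link="log", family="quasipoisson",
                          terms="Sex + logUD")
        f1, f2 = fit_glm(table, base), fit_glm(table, quasi, c_hat=4.0)
        assert np.allclose(f1.params, f2.params)
        assert np.allclose(f2.bse / f1.bse, 2.0)

    def test_nonpositive_ud_rejected(self):
        table = _binary_fixture(n=50)
        table.loc[0, "ud"] = 0.0
        with pytest.raises(ValueError, match="non-positive UD"):
            fit_glm(table, ModelSpec(terms="Sex + logUD"))

    def test_spec_invariants(self):
        with pytest.raises(ValueError):
            ModelSpec(terms="Sex + logUD", offset_log_ud=True)
        with pytest.raises(ValueError):
            ModelSpec(response="count", link="cloglog")
        with pytest.raises(ValueError):
            ModelSpec(family="quasibinomial", random=("Fisher",))


class TestOffsetIdentity:
    def test_identity_holds_everywhere(self):
        """Offset-model log-likelihood equals the free model's likelihood
        at exponent 1 (other coefficients at the offset fit's values)."""
        for seed in range(5):
            table = _binary_fixture(n=200, seed=seed)
            chk = offset_consistency_check(table)
            assert chk["identity_gap"] < 1e-8

    def test_ci_covers_one_under_truth(self):
        table = _binary_fixture(n=2000, seed=8, beta_ud=1.0)
        chk = offset_consistency_check(table)
        assert chk["covers_one"]

    def test_wrong_exponent_detected(self):
        """With true exponent 2 the offset model loses decisively."""
        table = _binary_fixture(n=2000, seed=9, beta_ud=2.0)
        chk = offset_consistency_check(table)
        assert chk["beta_ud"] == pytest.approx(2.0, abs=0.4)
        assert chk["aicc_offset"] > chk["aicc_free"] + 2


class TestDispersion:
    def test_pure_poisson_near_one(self):
        vals = []
        for seed in range(10):
            table = _count_fixture(n=400, seed=100 + seed)
            fit = fit_glm(table, ModelSpec(response="count", link="log",
                                           family="poisson",
                                           terms="Sex * Isopleth + logUD"))
            vals.append(quasi_dispersion(fit))
        # chat ~ 1 with MC standard error ~ sqrt(2/df)/sqrt(reps)
        se = math.sqrt(2.0 / 394) / math.sqrt(10)
        assert abs(np.mean(vals) - 1.0) < 4 * se

    def test_zero_residual_df_errors(self):
        table = _count_fixture(n=4, seed=1)
        fit = fit_glm(
            table.iloc[:3],
            ModelSpec(response="count", link="log", family="poisson",
                      terms="Sex + logUD"),
        )
        with pytest.raises(ValueError):
            quasi_dispersion(fit)


class TestInformationCriteria:
    def _fake_fit(self, llf, K, n):
        return FitResult(
            spec=ModelSpec(terms="1"), params=pd.Series(dtype=float),
            bse=pd.Series(dtype=float), llf=llf, deviance=np.nan,
            pearson_chi2=np.nan, df_resid=n - K, n=n, K=K,
            eta=np.zeros(n), fitted=np.zeros(n), converged=True,
        )

    def test_aicc_worked_example(self):
        # AIC = 100 with K = 3, n = 10 -> AICc = 100 + 2*3*4/6 = 104
        fit = self._fake_fit(llf=-47.0, K=3, n=10)
        aic, _ = information_criteria(fit, "AIC")
        assert aic == pytest.approx(100.0)
        aicc, _ = information_criteria(fit, "AICc")
        assert aicc == pytest.approx(104.0)

    def test_aicc_converges_to_aic(self):
        fit = self._fake_fit(llf=-500.0, K=3, n=10**6)
        aic, _ = information_criteria(fit, "AIC")
        aicc, _ = information_criteria(fit, "AICc")
        assert aicc - aic < 1e-4

    def test_qaicc_formula(self):
        """QAICc at c-hat 1 equals AICc computed with one extra parameter."""
        fit = self._fake_fit(llf=-47.0, K=3, n=50)
        q, kq = information_criteria(fit, "QAICc", c_hat=1.0)
        assert kq == 4
        manual = (94.0 + 2 * 4 + 2 * 4 * 5 / (50 - 4 - 1))
        assert q == pytest.approx(manual)

    def test_qaicc_scales_loglik(self):
        fit = self._fake_fit(llf=-47.0, K=3, n=50)
        q1, _ = information_criteria(fit, "QAICc", c_hat=1.0)
        q2, _ = information_criteria(fit, "QAICc", c_hat=2.0)
        assert q2 == pytest.approx(q1 - 94.0 / 2.0)

    def test_small_n_errors(self):
        fit = self._fake_fit(llf=-1.0, K=3, n=4)
        with pytest.raises(ValueError, match="too small"):
            information_criteria(fit, "AICc")

    def test_selection_weights_closed_form(self):
        f1 = self._fake_fit(llf=-50.0, K=2, n=100)
        f2 = self._fake_fit(llf=-51.0, K=2, n=100)  # delta AIC = 2
        f1.spec = ModelSpec(terms="1", label="best")
        f2.spec = ModelSpec(terms="1", label="second")
        sel = selection_table([f1, f2], criterion="AIC")
        assert sel["Delta"].tolist() == pytest.approx([0.0, 2.0])
        assert sel["Weight"].tolist() == pytest.approx([0.731, 0.269], abs=1e-3)
        assert sel["Weight"].sum() == pytest.approx(1.0)
        assert sel["CumWeight"].iloc[-1] == pytest.approx(1.0)

    def test_single_model_weight_one(self):
        f = self._fake_fit(llf=-10.0, K=1, n=30)
        sel = selection_table([f], criterion="AIC")
        assert sel["Weight"].iloc[0] == pytest.approx(1.0)

    def test_mixed_rows_rejected(self):
        f1 = self._fake_fit(llf=-10.0, K=1, n=30)
        f2 = self._fake_fit(llf=-10.0, K=1, n=40)
        with pytest.raises(ValueError):
            selection_table([f1, f2])


class TestLikelihoodRatio:
    def test_identical_models(self):
        table = _binary_fixture(n=150, seed=2)
        fit = fit_glm(table, ModelSpec(terms="Sex + logUD"))
        stat, df, p = likelihood_ratio_test(fit, fit)
        assert stat == pytest.approx(0.0, abs=1e-10) and p == 1.0

    def test_chi2_quantile(self):
        assert stats.chi2.sf(3.84, 1) == pytest.approx(0.05, abs=0.001)

    def test_non_nested_rejected(self):
        table = _binary_fixture(n=150, seed=2)
        f1 = fit_glm(table, ModelSpec(terms="Core"))
        f2 = fit_glm(table, ModelSpec(terms="Sex + logUD"))
        with pytest.raises(ValueError, match="nested"):
            likelihood_ratio_test(f1, f2)

    def test_null_distribution_matches_chi2(self):
        """Under the null (no Core effect), the LRT statistic follows a
        chi-square with 1 df (KS test at alpha = 0.01)."""
        stats_ = []
        for seed in range(150):
            table = _binary_fixture(n=120, seed=2000 + seed)
            nested = fit_glm(table, ModelSpec(terms="Sex + logUD"))
            full = fit_glm(table, ModelSpec(terms="Sex + logUD + Core"))
            stats_.append(likelihood_ratio_test(nested, full)[0])
        ks = stats.kstest(stats_, stats.chi2(1).cdf)
        assert ks.pvalue > 0.01


class TestGlmm:
    def test_degenerate_variance_matches_glm(self):
        """Data without group heterogeneity: variance near zero and fixed
        effects equal to the plain GLM's."""
        table = _binary_fixture(n=600, seed=10)
        glm = fit_glm(table, ModelSpec(terms="Sex + logUD"))
        glmm = fit_glmm(table, ModelSpec(terms="Sex + logUD",
                                         random=("Fisher",)))
        assert glmm.re_var["Fisher"] < 0.2
        assert np.allclose(glm.params, glmm.params, atol=0.1)
        assert glmm.llf <= glm.llf + 1e-6 or abs(glmm.llf - glm.llf) < 0.5

    def test_variance_recovery(self):
        """Known sigma^2 = 1 logit GLMM with 200 groups is recovered
        within the usual sampling band."""
        rng = np.random.default_rng(1)
        G, m = 200, 8
        u = rng.normal(0, 1.0, G)
        x = rng.normal(size=G * m)
        codes = np.repeat(np.arange(G), m)
        eta = -0.3 + 0.6 * x + u[codes]
        y = (rng.uniform(size=G * m) < 1 / (1 + np.exp(-eta))).astype(float)
        X = np.column_stack([np.ones(G * m), x])
        fit = fit_glmm_arrays(y, X, {"g": codes})
        assert 0.7 <= fit.re_sd["g"] ** 2 <= 1.4
        assert fit.converged

    def test_laplace_vs_adaptive_quadrature(self):
        """On a fixture with enough observations per group, the Laplace
        log-likelihood agrees with 15-node adaptive Gauss-Hermite within
        0.1."""
        rng = np.random.default_rng(2)
        G, m = 50, 150
        u = rng.normal(0, 0.8, G)
        x = rng.normal(size=G * m)
        codes = np.repeat(np.arange(G), m)
        eta = 0.2 + 0.5 * x + u[codes]
        y = (rng.uniform(size=G * m) < 1 / (1 + np.exp(-eta))).astype(float)
        X = np.column_stack([np.ones(G * m), x])
        fit = fit_glmm_arrays(y, X, {"g": codes})
        ll_agq = agq_loglik(y, X, codes, fit.beta, fit.re_sd["g"], nodes=15)
        assert abs(ll_agq - fit.loglik) < 0.1

    def test_single_level_factor_rejected(self):
        y = np.array([0.0, 1.0, 1.0])
        X = np.ones((3, 1))
        with pytest.raises(ValueError, match="fewer than 2"):
            fit_glmm_arrays(y, X, {"g": np.zeros(3, dtype=int)})

    def test_conditional_r2_closed_forms(self):
        table = _binary_fixture(n=400, seed=11)
        spec = ModelSpec(terms="Sex + logUD", link="logit",
                         random=("Fisher",))
        fit = fit_glmm(table, spec)
        r2 = conditional_r2(fit)
        var_f = float(np.var(fit.eta_fixed))
        var_r = sum(fit.re_var.values())
        expected = (var_f + var_r) / (var_f + var_r + math.pi**2 / 3)
        assert r2 == pytest.approx(expected)
        assert 0.0 <= r2 <= 1.0
        # a pure GLM has no conditional R^2
        with pytest.raises(ValueError):
            conditional_r2(fit_glm(table, ModelSpec(terms="Sex + logUD")))

    def test_conditional_r2_known_variances(self):
        """Simulated logit GLMM: plug-in truth formula within 0.05."""
        rng = np.random.default_rng(5)
        G, m = 150, 10
        sigma2 = 1.0
        u = rng.normal(0, math.sqrt(sigma2), G)
        x = rng.normal(size=G * m)
        codes = np.repeat(np.arange(G), m)
        beta = np.array([0.0, 1.0])
        eta = beta[0] + beta[1] * x + u[codes]
        y = (rng.uniform(size=G * m) < 1 / (1 + np.exp(-eta))).astype(float)
        X = np.column_stack([np.ones(G * m), x])
        fit = fit_glmm_arrays(y, X, {"g": codes})
        var_f_true = float(np.var(beta[0] + beta[1] * x))
        truth = (var_f_true + sigma2) / (var_f_true + sigma2 + math.pi**2 / 3)
        var_f = float(np.var(X @ fit.beta))
        got = (var_f + fit.re_sd["g"] ** 2) / (
            var_f + fit.re_sd["g"] ** 2 + math.pi**2 / 3
        )
        assert got == pytest.approx(truth, abs=0.05)
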