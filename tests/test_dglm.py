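"""Double GLM engine: identities, oracle equivalence, recovery, tests."""

import numpy as np
import pytest
from scipy import stats

from vqtlscan import DGLMSpec, dglm_fit, dglm_vqtl_test, leverages
from vqtlscan.errors import MonomorphicError, ValidationError
from vqtlscan.glmfit import gamma_glm_log, poisson_glm_log


def _random_regression(rng, n=60, het=True):
    g = rng.binomial(2, 0.4, n).astype(float)
    x = rng.normal(size=n)
    Xm = np.column_stack([np.ones(n), x, g])
    scale = np.exp(0.3 * g) if het else 1.0
    y = Xm @ np.array([0.5, 1.0, -0.3]) + rng.normal(size=n) * scale
    return y, Xm, g


class TestLeverages:
    def test_intercept_only_balanced(self):
        h = leverages(np.ones((10, 1)))
        np.testing.assert_allclose(h, 0.1)

    def test_simple_regression_matrix_oracle(self):
        X = np.array([[1.0, 0], [1, 1], [1, 2]])
        h = leverages(X)
        np.testing.assert_allclose(h, [5 / 6, 1 / 3, 5 / 6], atol=1e-12)
        assert h.sum() == pytest.approx(2.0, abs=1e-12)

    def test_trace_equals_column_count(self, rng):
        for _ in range(10):
            n, p = int(rng.integers(10, 40)), int(rng.integers(1, 5))
            X = np.column_stack([np.ones(n), rng.normal(size=(n, p - 1))]) \
                if p > 1 else np.ones((n, 1))
            w = rng.uniform(0.5, 2.0, n)
            h = leverages(X, w)
            assert h.sum() == pytest.approx(p, abs=1e-10)
            assert np.all((h >= 0) & (h <= 1))

    def test_explicit_hat_matrix_agreement(self, rng):
        n = 25
        X = np.column_stack([np.ones(n), rng.normal(size=(n, 2))])
        w = rng.uniform(0.5, 2.0, n)
        Wh = np.diag(np.sqrt(w))
        H = Wh @ X @ np.linalg.inv(X.T @ np.diag(w) @ X) @ X.T @ Wh
        np.testing.assert_allclose(leverages(X, w), np.diag(H), atol=1e-10)


class TestGLMBuildingBlocks:
    """The internal IRLS fitters against the statsmodels oracle."""

    def test_gamma_log_link_matches_statsmodels(self, rng):
        sm = pytest.importorskip("statsmodels.api")
        n = 200
        X = np.column_stack([np.ones(n), rng.binomial(2, 0.4, n)])
        d = rng.gamma(shape=0.5, scale=2 * np.exp(0.3 * X[:, 1]))
        d = np.maximum(d, 1e-12)
        pw = rng.uniform(0.3, 0.7, n)
        coef, cov, converged = gamma_glm_log(d, X, pw)
        fit = sm.GLM(d, X, family=sm.families.Gamma(sm.families.links.Log()),
                     var_weights=pw).fit()
        assert converged
        np.testing.assert_allclose(coef, fit.params, atol=1e-6)

    def test_poisson_log_link_matches_statsmodels(self, rng):
        sm = pytest.importorskip("statsmodels.api")
        n = 300
        X = np.column_stack([np.ones(n), rng.binomial(2, 0.4, n)])
        y = rng.poisson(np.exp(-0.5 + 0.3 * X[:, 1]))
        pw = rng.uniform(0.5, 1.5, n)
        coef, cov, mu, w, converged = poisson_glm_log(y.astype(float), X, pw)
        fit = sm.GLM(y, X, family=sm.families.Poisson(),
                     var_weights=pw).fit()
        assert converged
        np.testing.assert_allclose(coef, fit.params, atol=1e-6)


class TestGaussianDGLM:
    def test_intercept_only_dispersion_reduces_to_ols(self, rng):
        """With a constant dispersion model the DGLM must reproduce OLS:
        beta = (X'X)^{-1}X'y and sigma^2 = RSS/(n-p), on 50 random datasets."""
        for _ in range(50):
            y, Xm, _ = _random_regression(rng, het=False)
            fit = dglm_fit(y, DGLMSpec("gaussian", Xm, np.ones((len(y), 1))))
            beta_ols, *_ = np.linalg.lstsq(Xm, y, rcond=None)
            rss = np.sum((y - Xm @ beta_ols) ** 2)
            np.testing.assert_allclose(fit.beta, beta_ols, atol=1e-8)
            np.testing.assert_allclose(
                fit.sigma2, rss / (len(y) - Xm.shape[1]), atol=1e-8
            )
            assert fit.converged

    def test_leverage_sum_and_variance_positivity(self, rng):
        y, Xm, g = _random_regression(rng)
        Xd = np.column_stack([np.ones(len(y)), g])
        fit = dglm_fit(y, DGLMSpec("gaussian", Xm, Xd))
        assert fit.leverages.sum() == pytest.approx(Xm.shape[1], abs=1e-8)
        assert np.all(fit.sigma2 > 0)
        assert np.isfinite(fit.loglik)

    def test_dispersion_parameter_recovery_large_n(self):
        """lambda_g within +-0.03 of the generating 0.2 at n = 50,000."""
        rng = np.random.default_rng(1234)
        n = 50_000
        g = rng.binomial(2, 0.4, n).astype(float)
        y = rng.normal(scale=np.exp(0.5 * 0.2 * g))  # log sigma^2 = 0.2 g
        Xm = np.column_stack([np.ones(n), g])
        Xd = Xm.copy()
        fit = dglm_fit(y, DGLMSpec("gaussian", Xm, Xd))
        assert fit.lam[1] == pytest.approx(0.2, abs=0.03)

    def test_consistency_error_shrinks_with_n(self):
        """Median |lambda_hat - lambda| decreases from n=1,000 to n=10,000."""
        errors = {}
        for n in (1000, 10_000):
            errs = []
            for seed in range(40):
                rng = np.random.default_rng(500 + seed)
                g = rng.binomial(2, 0.4, n).astype(float)
                y = rng.normal(loc=0.1 * g, scale=np.exp(0.5 * 0.3 * g))
                Xm = np.column_stack([np.ones(n), g])
                fit = dglm_fit(y, DGLMSpec("gaussian", Xm, Xm))
                errs.append(abs(fit.lam[1] - 0.3))
            errors[n] = np.median(errs)
        assert errors[10_000] < errors[1000]

    def test_rank_deficient_design_rejected(self, rng):
        n = 30
        x = rng.normal(size=n)
        Xm = np.column_stack([np.ones(n), x, 2 * x])
        with pytest.raises(ValidationError, match="rank"):
            DGLMSpec("gaussian", Xm, np.ones((n, 1)))


class TestPoissonDGLM:
    def test_requires_integer_counts(self, rng):
        y, Xm, g = _random_regression(rng)
        with pytest.raises(ValidationError, match="integer"):
            dglm_fit(y, DGLMSpec("poisson", Xm, np.ones((len(y), 1))))

    def test_mean_submodel_matches_plain_poisson_glm_under_constant_phi(self, rng):
        sm = pytest.importorskip("statsmodels.api")
        n = 500
        g = rng.binomial(2, 0.4, n).astype(float)
        y = rng.poisson(np.exp(-1 + 0.05 * g)).astype(float)
        Xm = np.column_stack([np.ones(n), g])
        fit = dglm_fit(y, DGLMSpec("poisson", Xm, np.ones((n, 1))))
        oracle = sm.GLM(y, Xm, family=sm.families.Poisson()).fit()
        # constant dispersion cancels from the mean-submodel score equations
        np.testing.assert_allclose(fit.beta, oracle.params, atol=1e-6)

    def test_equidispersed_counts_give_small_dispersion_effect(self):
        rng = np.random.default_rng(99)
        n = 20_000
        g = rng.binomial(2, 0.4, n).astype(float)
        y = rng.poisson(np.exp(-1 + 0.05 * g)).astype(float)
        res = dglm_vqtl_test(y, None, g, family="poisson")
        assert abs(res.disp_beta) < 0.2
        assert res.disp_p > 1e-4  # no strong spurious vQTL signal


class TestVQTLTest:
    def test_monomorphic_genotype_rejected(self, rng):
        y = rng.normal(size=50)
        with pytest.raises(MonomorphicError):
            dglm_vqtl_test(y, None, np.ones(50))

    def test_lrt_nonnegative_and_p_in_unit_interval(self, toy_dataset):
        y, g = toy_dataset
        res = dglm_vqtl_test(y, None, g, family="gaussian", test="lrt")
        assert res.disp_stat >= 0
        assert 0 <= res.disp_p <= 1
        assert res.disp_df == 1

    def test_detects_true_variance_effect(self, toy_dataset):
        y, g = toy_dataset
        res = dglm_vqtl_test(y, None, g, family="gaussian")
        assert res.disp_p < 1e-4
        assert res.disp_beta > 0

    def test_wald_and_lrt_agree_at_large_n(self):
        rng = np.random.default_rng(11)
        n = 20_000
        g = rng.binomial(2, 0.4, n).astype(float)
        y = rng.normal(scale=np.exp(0.05 * g))
        lrt = dglm_vqtl_test(y, None, g, test="lrt")
        wald = dglm_vqtl_test(y, None, g, test="wald")
        assert np.log10(max(lrt.disp_p, 1e-300)) == pytest.approx(
            np.log10(max(wald.disp_p, 1e-300)), abs=0.15
        )

    def test_covariate_is_absorbed_by_mean_model(self, rng):
        n = 2000
        g = rng.binomial(2, 0.4, n).astype(float)
        x = rng.normal(size=n)
        y = 2.0 * x + rng.normal(size=n)
        res = dglm_vqtl_test(y, x, g, family="gaussian")
        assert res.mean_se < 0.1  # covariate removed most residual noise
        assert res.disp_p > 0.001  # no spurious variance signal

    def test_mean_effect_reported_from_full_model(self, rng):
        n = 3000
        g = rng.binomial(2, 0.4, n).astype(float)
        y = 0.5 * g + rng.normal(size=n)
        res = dglm_vqtl_test(y, None, g)
        assert res.mean_beta == pytest.approx(0.5, abs=0.1)
        assert res.mean_p < 1e-10
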