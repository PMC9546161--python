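"""GLM/OLS estimation: conventions, parameter recovery, bootstrap, oracle."""

import numpy as np
import pytest

from selgrad import (
    LandeArnoldRegression,
    LogQuadraticCoefficients,
    LogQuadraticGLM,
    TraitFitnessTable,
    bootstrap_se,
    build_design_matrix,
    fit_log_quadratic_glm,
    gradients_from_fit,
    numerical_average_estimator,
    ols_lande_arnold,
    standardize_traits,
)
from selgrad.estimators import (
    DegenerateTrait,
    SeparationOrRankDeficiency,
    ZeroMeanFitness,
)
from selgrad.uncertainty import convert_unhalved_covariance
from selgrad import var_beta_univariate


def make_poisson_table(n, b, g, seed=0, a=0.0):
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(n)
    lam = np.exp(a + b * z + 0.5 * g * z ** 2)
    return TraitFitnessTable(traits=z, fitness=rng.poisson(lam).astype(float))


class TestStandardize:
    def test_none_is_identity(self):
        t = TraitFitnessTable([1.0, 2.0, 3.0], [1.0, 1.0, 1.0])
        out, center, scale = standardize_traits(t, "none")
        np.testing.assert_array_equal(out.traits, t.traits)
        np.testing.assert_array_equal(center, [0.0])
        np.testing.assert_array_equal(scale, [1.0])

    def test_unit_variance_uses_sample_sd(self):
        # ddof=1 sample SD of (1,2,3) is 1, so output is (-1, 0, 1)
        t = TraitFitnessTable([1.0, 2.0, 3.0], [1.0, 1.0, 1.0])
        out, center, scale = standardize_traits(t, "unit_variance")
        np.testing.assert_allclose(out.traits.ravel(), [-1.0, 0.0, 1.0])
        assert center[0] == pytest.approx(2.0)
        assert scale[0] == pytest.approx(1.0)
        assert out.traits.std(ddof=1) == pytest.approx(1.0)

    def test_mean_standardize_divides_by_mean(self):
        t = TraitFitnessTable([2.0, 4.0], [1.0, 1.0])
        out, center, scale = standardize_traits(t, "mean_standardize")
        np.testing.assert_allclose(out.traits.ravel(), [2 / 3, 4 / 3])
        assert center[0] == 0.0
        assert scale[0] == pytest.approx(3.0)

    def test_degenerate_trait_rejected(self):
        t = TraitFitnessTable([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        with pytest.raises(DegenerateTrait):
            standardize_traits(t, "unit_variance")
        t2 = TraitFitnessTable([-1.0, 1.0], [1.0, 1.0])
        with pytest.raises(DegenerateTrait):
            standardize_traits(t2, "mean_standardize")


class TestDesignMatrix:
    def test_univariate_half_square_column(self):
        X, labels = build_design_matrix(np.array([1.0, 2.0]))
        np.testing.assert_allclose(X, [[1, 1, 0.5], [1, 2, 2.0]])
        assert labels == ["intercept", "z1", "z1^2/2"]

    def test_bivariate_row_ordering(self):
        X, labels = build_design_matrix(np.array([[2.0, 3.0]]))
        np.testing.assert_allclose(X, [[1, 2, 3, 2, 4.5, 6]])
        assert labels == ["intercept", "z1", "z2", "z1^2/2", "z2^2/2",
                          "z1*z2"]

    def test_linear_only(self):
        X, labels = build_design_matrix(np.array([[2.0, 3.0]]), False)
        np.testing.assert_allclose(X, [[1, 2, 3]])


class TestLogQuadraticGLM:
    def test_recovers_truth_large_n(self):
        table = make_poisson_table(20000, b=0.3, g=-0.2, seed=42)
        fit = fit_log_quadratic_glm(table)
        se = np.sqrt(np.diag(fit.sampling_cov.cov))
        assert abs(fit.coef.b[0] - 0.3) < 3 * se[0]
        assert abs(fit.coef.g[0, 0] + 0.2) < 3 * se[1]
        assert fit.converged

    def test_halving_convention_round_trip(self):
        # fitting with an unhalved z^2 column gives coefficient g/2; after
        # doubling both workflows agree
        import statsmodels.api as sm
        table = make_poisson_table(5000, b=0.2, g=-0.3, seed=7)
        fit = fit_log_quadratic_glm(table)
        z = table.traits.ravel()
        X_unhalved = np.column_stack([np.ones(table.n), z, z ** 2])
        res = sm.GLM(table.fitness, X_unhalved,
                     family=sm.families.Poisson()).fit()
        assert 2 * res.params[2] == pytest.approx(fit.coef.g[0, 0], abs=1e-8)
        assert res.params[1] == pytest.approx(fit.coef.b[0], abs=1e-8)
        from selgrad.uncertainty import CoefficientCovariance
        cc_unhalved = CoefficientCovariance(res.cov_params()[1:, 1:])
        cc = convert_unhalved_covariance(cc_unhalved, k=1)
        np.testing.assert_allclose(cc.cov, fit.sampling_cov.cov, rtol=1e-6)

    def test_negative_fitness_rejected_before_fit(self):
        with pytest.raises(ValueError):
            TraitFitnessTable([0.0, 1.0], [-1.0, 2.0])

    def test_non_integer_counts_rejected(self):
        with pytest.raises(ValueError, match="integer-valued"):
            LogQuadraticGLM().fit([0.0, 1.0, 2.0, -1.0], [0.5, 1.0, 2.0, 1.0])

    def test_too_few_rows_for_quadratic(self):
        with pytest.raises(ValueError, match="at least"):
            LogQuadraticGLM().fit([0.0, 1.0], [1.0, 2.0])

    def test_constant_trait_is_rank_deficient(self):
        with pytest.raises(SeparationOrRankDeficiency):
            LogQuadraticGLM().fit(np.ones(50), np.ones(50))

    def test_sklearn_api(self):
        from sklearn.base import clone
        est = LogQuadraticGLM(family="poisson", standardize="unit_variance")
        assert clone(est).get_params()["standardize"] == "unit_variance"
        table = make_poisson_table(500, b=0.2, g=0.0, seed=1)
        est.fit(table.traits, table.fitness)
        pred = est.predict(table.traits[:5])
        assert pred.shape == (5,)
        assert np.all(pred > 0)

    def test_standardization_recorded(self):
        rng = np.random.default_rng(3)
        z = rng.normal(10.0, 2.0, 2000)
        w = rng.poisson(np.exp(0.1 * (z - 10.0))).astype(float)
        est = LogQuadraticGLM(standardize="unit_variance").fit(z, w)
        assert est.center_[0] == pytest.approx(z.mean())
        assert est.scale_[0] == pytest.approx(z.std(ddof=1))
        # fitted-scale traits are centred, so pheno_ has mean ~0, var ~1
        assert est.pheno_.mu[0] == pytest.approx(0.0, abs=1e-12)
        assert est.pheno_.sigma[0, 0] == pytest.approx(1.0, abs=1e-12)


class TestGradientsFromFit:
    def test_linear_only_beta_equals_b(self):
        table = make_poisson_table(2000, b=0.25, g=0.0, seed=11)
        fit = fit_log_quadratic_glm(table, include_quadratic=False)
        sg, gu = gradients_from_fit(fit)
        assert sg.beta[0] == pytest.approx(fit.coef.b[0])
        assert np.sqrt(gu.var_beta[0, 0]) == pytest.approx(
            np.sqrt(fit.sampling_cov.cov[0, 0]))

    def test_univariate_standardized_closed_form(self):
        table = make_poisson_table(3000, b=0.3, g=-0.2, seed=5)
        est = LogQuadraticGLM(standardize="unit_variance").fit(
            table.traits, table.fitness)
        b, g = est.coef_.b[0], est.coef_.g[0, 0]
        mu, s2 = est.pheno_.mu[0], est.pheno_.sigma[0, 0]
        # on the standardized scale mu=0, sigma^2=1: beta = b/(1-g)
        assert est.beta_[0] == pytest.approx((b + g * mu) / (1 - g * s2),
                                             rel=1e-8)
        assert est.uncertainty_.var_beta[0, 0] == pytest.approx(
            var_beta_univariate(b, g, est.sampling_cov_), rel=1e-4)


class TestLandeArnoldOLS:
    def test_constant_fitness_gives_zero_gradients(self):
        rng = np.random.default_rng(0)
        z = rng.standard_normal(50)
        res = ols_lande_arnold(TraitFitnessTable(z, np.full(50, 3.0)))
        np.testing.assert_allclose(res.beta_hat, 0.0, atol=1e-12)
        np.testing.assert_allclose(res.gamma_hat, 0.0, atol=1e-12)

    def test_three_point_exact_fit(self):
        res = ols_lande_arnold(
            TraitFitnessTable([-1.0, 0.0, 1.0], [1.0, 2.0, 3.0]))
        assert res.intercept == pytest.approx(1.0)
        assert res.beta_hat[0] == pytest.approx(0.5)
        assert res.gamma_hat[0, 0] == pytest.approx(0.0, abs=1e-12)

    def test_zero_mean_fitness_rejected(self):
        with pytest.raises(ZeroMeanFitness):
            ols_lande_arnold(TraitFitnessTable([0.0, 1.0, 2.0, 3.0],
                                               np.zeros(4)))

    def test_ols_and_glm_agree_under_log_linear_truth(self):
        table = make_poisson_table(20000, b=0.2, g=0.0, seed=21)
        ols = ols_lande_arnold(table)
        fit = fit_log_quadratic_glm(table)
        sg, gu = gradients_from_fit(fit)
        combined = np.sqrt(ols.se_beta[0] ** 2 + gu.var_beta[0, 0])
        assert abs(ols.beta_hat[0] - sg.beta[0]) < 3 * combined
        assert abs(ols.beta_hat[0] - 0.2) < 3 * ols.se_beta[0]

    def test_two_step_beta_from_linear_model(self):
        table = make_poisson_table(500, b=0.3, g=-0.4, seed=2)
        one = ols_lande_arnold(table, two_step=False)
        two = ols_lande_arnold(table, two_step=True)
        # gamma identical, beta generally differs between protocols
        np.testing.assert_array_equal(one.gamma_hat, two.gamma_hat)
        assert one.beta_hat[0] != two.beta_hat[0]


class TestBootstrap:
    def test_same_seed_is_bit_identical(self):
        table = make_poisson_table(120, b=0.2, g=0.0, seed=9)
        r1 = bootstrap_se(table, "ols", b_reps=50, seed=123)
        r2 = bootstrap_se(table, "ols", b_reps=50, seed=123)
        np.testing.assert_array_equal(r1.se, r2.se)
        r3 = bootstrap_se(table, "ols", b_reps=50, seed=124)
        assert not np.array_equal(r1.se, r3.se)

    def test_constant_fitness_gives_zero_se(self):
        rng = np.random.default_rng(1)
        table = TraitFitnessTable(rng.standard_normal(60), np.full(60, 2.0))
        res = bootstrap_se(table, "ols", b_reps=30, seed=0)
        np.testing.assert_allclose(res.se, 0.0, atol=1e-12)

    def test_glm_bootstrap_tracks_delta_se(self):
        table = make_poisson_table(200, b=0.2, g=0.0, seed=17)
        res = bootstrap_se(table, "glm", b_reps=80, seed=5)
        fit = fit_log_quadratic_glm(table)
        _, gu = gradients_from_fit(fit)
        assert res.se[0] == pytest.approx(np.sqrt(gu.var_beta[0, 0]),
                                          rel=0.5)
        assert res.n_failed == 0

    def test_bad_reps_rejected(self):
        table = make_poisson_table(50, b=0.1, g=0.0)
        with pytest.raises(ValueError):
            bootstrap_se(table, "ols", b_reps=1)


class TestNumericalAverageEstimator:
    def test_zero_curvature_returns_b_for_any_sample(self):
        rng = np.random.default_rng(4)
        table = TraitFitnessTable(rng.normal(2.0, 3.0, 40), np.ones(40))
        coef = LogQuadraticCoefficients(a=1.0, b=[0.7], g=[[0.0]])
        sel = numerical_average_estimator(table, coef)
        assert sel.beta[0] == pytest.approx(0.7, rel=1e-12)

    def test_gamma_exactly_symmetric(self):
        rng = np.random.default_rng(5)
        table = TraitFitnessTable(rng.standard_normal((30, 3)), np.ones(30))
        coef = LogQuadraticCoefficients(
            a=0.0, b=[0.1, 0.2, -0.1],
            g=np.diag([-0.2, -0.1, -0.3]))
        sel = numerical_average_estimator(table, coef)
        np.testing.assert_array_equal(sel.gamma, sel.gamma.T)

    def test_converges_to_closed_form(self):
        from selgrad import PhenotypeDistribution, compute_gradients
        rng = np.random.default_rng(6)
        table = TraitFitnessTable(rng.standard_normal(10 ** 6), np.ones(10 ** 6))
        coef = LogQuadraticCoefficients(a=0.0, b=[0.3], g=[[0.4]])
        sel = numerical_average_estimator(table, coef)
        truth = compute_gradients(coef, PhenotypeDistribution.standardized(1))
        assert sel.beta[0] == pytest.approx(truth.beta[0], abs=0.01)
        assert sel.gamma[0, 0] == pytest.approx(truth.gamma[0, 0], abs=0.05)

    def test_glm_agrees_with_averaging_at_truth(self):
        # fitted closed-form gradients vs model-free averaging at the true
        # coefficients: asymptotically the same target
        table = make_poisson_table(10 ** 5, b=0.3, g=-0.2, seed=31)
        fit = fit_log_quadratic_glm(table)
        sg, gu = gradients_from_fit(fit)
        truth = LogQuadraticCoefficients(a=0.0, b=[0.3], g=[[-0.2]])
        avg = numerical_average_estimator(table, truth)
        assert abs(sg.beta[0] - avg.beta[0]) < 3 * np.sqrt(
            gu.var_beta[0, 0]) + 0.01
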