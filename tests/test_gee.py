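import numpy as np
import pytest
import statsmodels.api as sm

from wedgepower import (
    OutcomeSimulator,
    build_correlation,
    build_design_matrices,
    empirical_variances,
    fit_gee,
    model_based_variance,
    wald_test_hte,
)


@pytest.fixture
def simulated(base_spec):
    spec = base_spec.with_(cluster_size=40)
    sim = OutcomeSimulator(spec)
    mats = build_design_matrices(spec)
    Y = sim.sample(np.random.default_rng(17))
    return spec, mats, Y


class TestFitting:
    def test_independence_fit_equals_pooled_logistic_mle(self, simulated):
        """With the working correlation fixed at independence the GEE
        solution is the ordinary logistic-regression MLE."""
        spec, mats, Y = simulated
        fit = fit_gee(Y, mats, fix_correlation=(0.0, 0.0), tol=1e-10)
        assert fit.converged
        X = np.vstack([mats.M[g] for g in mats.pattern_of])
        y = Y.ravel()
        glm = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        np.testing.assert_allclose(fit.theta_hat, glm.params, atol=1e-6)

    def test_converged_fit_has_small_final_step(self, simulated):
        spec, mats, Y = simulated
        fit = fit_gee(Y, mats, working="simple")
        assert fit.converged and fit.max_step < 1e-6

    def test_single_outcome_level_flagged(self, base_spec):
        mats = build_design_matrices(base_spec)
        Y = np.zeros((base_spec.n_clusters, base_spec.n_periods * base_spec.cluster_size), dtype=np.int8)
        fit = fit_gee(Y, mats)
        assert not fit.converged

    def test_parameter_recovery(self, base_spec):
        """Average interaction estimate over replicates stays within
        Monte-Carlo error of the generating value."""
        spec = base_spec.with_(cluster_size=40)
        sim = OutcomeSimulator(spec)
        mats = build_design_matrices(spec)
        ss = np.random.SeedSequence(23)
        est = []
        for child in ss.spawn(120):
            fit = fit_gee(sim.sample(np.random.default_rng(child)), mats,
                          working="simple", compute_corrected=False)
            if fit.converged:
                est.append(fit.theta_hat[fit.hte_index])
        est = np.asarray(est)
        mc_se = est.std(ddof=1) / np.sqrt(len(est))
        assert abs(est.mean() - np.log(1.5)) < 3.5 * mc_se

    def test_correlation_recovery(self, base_spec):
        spec = base_spec.with_(n_clusters=40, cluster_size=20, cac=0.8)
        sim = OutcomeSimulator(spec)
        mats = build_design_matrices(spec)
        alphas, rhos = [], []
        for child in np.random.SeedSequence(31).spawn(30):
            fit = fit_gee(sim.sample(np.random.default_rng(child)), mats,
                          working="nested", compute_corrected=False)
            if fit.converged:
                alphas.append(fit.alpha_hat)
                rhos.append(fit.rho_hat)
        assert np.mean(alphas) == pytest.approx(0.1, abs=0.02)
        assert np.mean(rhos) == pytest.approx(0.8, abs=0.12)


class TestVariances:
    def test_naive_at_truth_matches_design_engine(self, base_spec):
        """Evaluating the model-based estimator at the true coefficients and
        correlation reproduces the design-stage covariance."""
        mats = build_design_matrices(base_spec)
        bundle = build_correlation(base_spec.n_periods, base_spec.cluster_size,
                                   base_spec.icc, base_spec.cac)
        want = model_based_variance(mats, bundle).full_cov
        sim = OutcomeSimulator(base_spec)
        Y = sim.sample(np.random.default_rng(3))
        fit = fit_gee(Y, mats, max_iter=0, theta_init=mats.theta(base_spec),
                      fix_correlation=(base_spec.icc, base_spec.cac))
        np.testing.assert_allclose(fit.naive_cov, want, rtol=1e-10)

    def test_sandwich_ordering(self, simulated):
        spec, mats, Y = simulated
        fit = fit_gee(Y, mats, working="simple")
        covs = empirical_variances(fit)
        k = fit.hte_index
        assert covs["robust"][k, k] <= covs["kc"][k, k] <= covs["md"][k, k]

    def test_empirical_variances_require_convergence(self, base_spec):
        mats = build_design_matrices(base_spec)
        Y = np.zeros((base_spec.n_clusters, base_spec.n_periods * base_spec.cluster_size), dtype=np.int8)
        with pytest.raises(ValueError):
            empirical_variances(fit_gee(Y, mats))

    def test_naive_underestimates_empirical_spread_under_null(self, base_spec):
        """The model-based SE is known to sit below the empirical SD of the
        interaction estimate with few clusters."""
        spec = base_spec.with_(cluster_size=40, theta3=0.0)
        sim = OutcomeSimulator(spec)
        mats = build_design_matrices(spec)
        est, ses = [], []
        for child in np.random.SeedSequence(41).spawn(600):
            fit = fit_gee(sim.sample(np.random.default_rng(child)), mats,
                          working="simple", compute_corrected=False)
            if fit.converged:
                est.append(fit.theta_hat[fit.hte_index])
                ses.append(fit.hte_se("naive"))
        assert np.mean(ses) < np.std(est, ddof=1)


class TestWaldTest:
    def test_zero_estimate_never_rejects(self, simulated):
        spec, mats, Y = simulated
        fit = fit_gee(Y, mats, working="simple")
        fit.theta_hat[fit.hte_index] = 0.0
        assert not wald_test_hte(fit, "naive")

    def test_large_statistic_rejects(self, simulated):
        spec, mats, Y = simulated
        fit = fit_gee(Y, mats, working="simple")
        fit.theta_hat[fit.hte_index] = 50.0
        assert wald_test_hte(fit, "naive")
        assert wald_test_hte(fit, "naive", test="wald_t", t_df=4)
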