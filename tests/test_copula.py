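import numpy as np
import pytest
from scipy.stats import multivariate_normal, norm

from wedgepower import (
    InfeasibleCorrelationError,
    OutcomeSimulator,
    bivariate_normal_cdf,
    build_correlation,
    build_design_matrices,
    build_layout,
    repair_non_psd,
    simulate_cluster,
    solve_pairwise_xi,
)
from wedgepower.copula import build_latent_matrix


class TestBivariateNormalCdf:
    @pytest.mark.parametrize("r", [-0.9, -0.3, 0.0, 0.2, 0.7, 0.95])
    @pytest.mark.parametrize("h,k", [(-1.0, 0.5), (0.0, 0.3), (0.0, 0.0), (1.2, 1.2), (-2.0, -1.5)])
    def test_against_scipy_integrator(self, h, k, r):
        want = multivariate_normal(cov=[[1.0, r], [r, 1.0]]).cdf([h, k])
        assert bivariate_normal_cdf(h, k, r) == pytest.approx(want, abs=2e-6)

    def test_comonotone_limits(self):
        assert bivariate_normal_cdf(0.3, 1.0, 1.0) == pytest.approx(norm.cdf(0.3))
        assert bivariate_normal_cdf(0.5, -0.5, -1.0) == pytest.approx(0.0, abs=1e-12)


class TestPairwiseXi:
    def test_independence(self):
        assert solve_pairwise_xi(0.2, 0.4, 0.0) == 0.0

    def test_symmetry(self):
        assert solve_pairwise_xi(0.15, 0.35, 0.1) == pytest.approx(
            solve_pairwise_xi(0.35, 0.15, 0.1), abs=1e-10
        )

    def test_monte_carlo_oracle(self):
        """Thresholding correlated normals at the solved latent correlation
        must recover the target outcome correlation."""
        mu, target = 0.15, 0.1
        xi = solve_pairwise_xi(mu, mu, target)
        rng = np.random.default_rng(42)
        n = 1_000_000
        z1 = rng.standard_normal(n)
        z2 = xi * z1 + np.sqrt(1 - xi**2) * rng.standard_normal(n)
        c = norm.ppf(mu)
        y1, y2 = z1 <= c, z2 <= c
        got = np.corrcoef(y1, y2)[0, 1]
        mc_se = 1.0 / np.sqrt(n)  # conservative for a correlation estimate
        assert abs(got - target) < 3 * mc_se * 2

    def test_infeasible_target_rejected(self):
        with pytest.raises(InfeasibleCorrelationError):
            solve_pairwise_xi(0.05, 0.95, 0.9)

    def test_solved_joint_probability_is_exact(self):
        mu1, mu2, target = 0.2, 0.35, 0.12
        xi = solve_pairwise_xi(mu1, mu2, target)
        joint = bivariate_normal_cdf(norm.ppf(mu1), norm.ppf(mu2), xi)
        want = target * np.sqrt(mu1 * (1 - mu1) * mu2 * (1 - mu2)) + mu1 * mu2
        assert joint == pytest.approx(want, abs=1e-7)


class TestLatentMatrix:
    def _pieces(self, spec):
        mats = build_design_matrices(spec)
        bundle = build_correlation(spec.n_periods, spec.cluster_size,
                                   spec.icc, spec.cac)
        groups = build_layout(spec).x
        return mats, bundle, groups

    def test_identity_at_zero_icc(self, tiny_spec):
        spec = tiny_spec.with_(icc=0.0)
        mats, bundle, groups = self._pieces(spec)
        lat = build_latent_matrix(mats.u[0], groups, bundle)
        np.testing.assert_allclose(lat.Xi, np.eye(bundle.n))
        assert not lat.repaired

    def test_cache_covers_distinct_combinations_only(self, base_spec):
        mats, bundle, groups = self._pieces(base_spec)
        cache = {}
        build_latent_matrix(mats.u[0], groups, bundle, cache)
        # (period-mean pair) x (within/between) combinations bound the cache
        mus = {round(float(v), 12) for v in mats.u[0]}
        n_mu_pairs = len(mus) * (len(mus) + 1) // 2
        assert 0 < len(cache) <= 2 * n_mu_pairs

    def test_equal_means_single_off_diagonal_value(self, tiny_spec):
        spec = tiny_spec.with_(theta1=0.0, theta2=0.0, theta3=0.0,
                               gammas=(0.0,) * 3, cac=1.0)
        mats, bundle, groups = self._pieces(spec)
        lat = build_latent_matrix(mats.u[0], groups, bundle)
        off = lat.Xi[~np.eye(bundle.n, dtype=bool)]
        assert len(np.unique(np.round(off, 12))) == 1


class TestRepair:
    def test_psd_input_untouched(self):
        Xi = np.array([[1.0, 0.3, 0.2], [0.3, 1.0, 0.1], [0.2, 0.1, 1.0]])
        lat = repair_non_psd(Xi)
        assert not lat.repaired
        np.testing.assert_allclose(lat.Xi, Xi)
        np.testing.assert_allclose(lat.factor @ lat.factor.T, Xi, atol=1e-12)

    def test_indefinite_input_repaired_to_unit_diagonal(self):
        # eigenvalues ~ (1.95, 1.05, -0.35): genuinely indefinite
        Xi = np.array([[1.0, 0.9, -0.3], [0.9, 1.0, 0.6], [-0.3, 0.6, 1.0]])
        assert np.linalg.eigvalsh(Xi)[0] < 0
        lat = repair_non_psd(Xi, floor=1e-6)
        assert lat.repaired
        assert np.linalg.eigvalsh(lat.Xi)[0] >= 0
        np.testing.assert_allclose(np.diag(lat.Xi), 1.0, atol=1e-12)
        assert lat.max_adjustment > 0


class TestSimulation:
    def test_reproducible_given_seed(self, base_spec):
        sim = OutcomeSimulator(base_spec)
        a = sim.sample(np.random.default_rng(5))
        b = sim.sample(np.random.default_rng(5))
        np.testing.assert_array_equal(a, b)

    def test_marginals_and_correlations_recovered(self, base_spec):
        """10,000 simulated clusters reproduce every cell mean and the
        within-/cross-period outcome correlations within Monte-Carlo error."""
        spec = base_spec.with_(cluster_size=6)  # same mean structure, small n
        sim = OutcomeSimulator(spec)
        u = sim.matrices.u[0]
        rng = np.random.default_rng(11)
        reps = 10_000
        Y = simulate_cluster(sim.latents[0], u, rng, size=reps).astype(float)
        se = np.sqrt(u * (1 - u) / reps)
        assert np.all(np.abs(Y.mean(axis=0) - u) < 4 * se)
        # averaged pair correlations per lag class
        m, J = spec.cluster_size, spec.n_periods
        resid = (Y - u[None, :]) / np.sqrt(u * (1 - u))[None, :]
        r3 = resid.reshape(reps, J, m)
        s_j = r3.sum(axis=2)
        within = ((s_j**2).sum(axis=1) - (r3**2).sum(axis=(1, 2))) / (J * m * (m - 1))
        between = ((s_j.sum(axis=1) ** 2) - (s_j**2).sum(axis=1)) / (J * (J - 1) * m * m)
        for est, target in [(within, spec.icc), (between, spec.icc * spec.cac)]:
            mc_se = est.std(ddof=1) / np.sqrt(reps)
            assert abs(est.mean() - target) < 3 * mc_se

    def test_shared_pattern_shares_factorization(self, base_spec):
        sim = OutcomeSimulator(base_spec)
        assert len(sim.latents) == base_spec.n_periods - 1
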