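import numpy as np
import pytest
from scipy.special import logit

from wedgepower import (
    ConfigurationError,
    DegenerateCovariateError,
    DesignSpec,
    build_design_matrices,
    build_layout,
    marginal_mean,
    model_based_variance,
    build_correlation,
)
from wedgepower.design import covariate_count, default_size_step


class TestLayout:
    def test_balanced_schedule_row_sums(self, base_spec):
        layout = build_layout(base_spec)
        assert list(layout.W.sum(axis=1)) == [4, 4, 3, 3, 2, 2, 1, 1]
        assert not layout.W[:, 0].any()
        assert layout.W[:, -1].all()
        # uni-directional: rows non-decreasing
        assert (np.diff(layout.W, axis=1) >= 0).all()

    def test_exact_covariate_counts(self, base_spec):
        layout = build_layout(base_spec)  # m=20, 50%
        assert layout.n_x1 == 10
        per_period = layout.x.reshape(base_spec.n_periods, -1).sum(axis=1)
        assert (per_period == 10).all()

    def test_nearest_integer_allocation(self, base_spec):
        spec = base_spec.with_(cluster_size=15, prevalence=0.33)
        assert build_layout(spec).n_x1 == 5  # round(4.95)

    def test_indivisible_cluster_count_rejected(self, base_spec):
        with pytest.raises(ConfigurationError, match="divisible"):
            base_spec.with_(n_clusters=9)

    def test_degenerate_covariate_rejected(self, base_spec):
        with pytest.raises(DegenerateCovariateError):
            base_spec.with_(cluster_size=4, prevalence=0.05)

    @pytest.mark.parametrize(
        "p_x,expected", [(0.3, 10), (0.5, 2), (1 / 3, 3), (0.25, 4), (0.37, 1)]
    )
    def test_default_search_step_keeps_counts_integral(self, p_x, expected):
        assert default_size_step(p_x) == expected


class TestMarginalMean:
    def test_intercept_only(self, base_spec):
        spec = base_spec.with_(theta1=0.0, theta2=0.0, theta3=0.0,
                               gammas=(0.0,) * 5)
        for j, w, x in [(1, 0, 0), (3, 1, 0), (5, 1, 1)]:
            assert marginal_mean(spec, j, w, x) == pytest.approx(0.15)

    def test_disparity_example_cells(self, worked_example_spec):
        # minority control rate ~15%, minority treated rate ~30%
        assert marginal_mean(worked_example_spec, 1, 0, 1) == pytest.approx(0.151, abs=5e-4)
        assert marginal_mean(worked_example_spec, 1, 1, 1) == pytest.approx(0.302, abs=5e-4)
        # reference-group control rate is exactly 35%
        assert marginal_mean(worked_example_spec, 1, 0, 0) == pytest.approx(0.35)

    def test_period_bounds_checked(self, base_spec):
        with pytest.raises(ValueError):
            marginal_mean(base_spec, 0, 0, 0)


class TestDesignMatrices:
    def test_shapes_and_reference_period(self, base_spec):
        mats = build_design_matrices(base_spec)
        J, m = base_spec.n_periods, base_spec.cluster_size
        for M in mats.M:
            assert M.shape == (J * m, J + 3)
            # first-period rows carry no period indicator (gamma_1 = 0)
            assert not M[:m, 1:J].any()

    def test_linear_predictor_identity(self, base_spec):
        mats = build_design_matrices(base_spec)
        theta = mats.theta(base_spec)
        for M, u in zip(mats.M, mats.u):
            np.testing.assert_allclose(logit(u), M @ theta, atol=1e-12)

    def test_untreated_rows_have_zero_interaction(self, base_spec):
        mats = build_design_matrices(base_spec)
        J = base_spec.n_periods
        for M in mats.M:
            w, wx = M[:, J], M[:, J + 2]
            assert not wx[w == 0].any()

    def test_one_pattern_per_step(self, base_spec):
        mats = build_design_matrices(base_spec)
        assert mats.n_patterns == base_spec.n_periods - 1
        assert mats.n_clusters == base_spec.n_clusters

    def test_within_period_permutation_leaves_variance_unchanged(self, tiny_spec):
        """Exchangeability: shuffling individuals inside a period must not
        move any predicted variance."""
        mats = build_design_matrices(tiny_spec)
        bundle = build_correlation(tiny_spec.n_periods, tiny_spec.cluster_size,
                                   tiny_spec.icc, tiny_spec.cac)
        ref = model_based_variance(mats, bundle).full_cov
        m = tiny_spec.cluster_size
        rng = np.random.default_rng(7)
        perm = np.concatenate(
            [j * m + rng.permutation(m) for j in range(tiny_spec.n_periods)]
        )
        from dataclasses import replace

        shuffled = replace(
            mats,
            M=tuple(M[perm] for M in mats.M),
            u=tuple(u[perm] for u in mats.u),
            A=tuple(A[perm] for A in mats.A),
        )
        got = model_based_variance(shuffled, bundle).full_cov
        np.testing.assert_allclose(got, ref, rtol=1e-10)

    def test_reduced_model_drops_covariate_columns(self, base_spec):
        mats = build_design_matrices(base_spec, include_covariate=False)
        J = base_spec.n_periods
        assert mats.M[0].shape[1] == J + 1
        assert mats.hte_index == J  # treatment column is the target
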