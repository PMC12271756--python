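"""Softmax prior scaling, prior densities and the collapsed marginal likelihood."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from scipy.linalg import block_diag

from brainvc import (
    MarginalLikelihood,
    ModelData,
    ParameterState,
    PriorSpec,
    compute_psi,
    enrichment_ratio,
    log_marginal_likelihood,
    log_prior,
)

from conftest import make_data


class TestComputePsi:
    def test_zero_alpha_gives_uniform_allocation(self):
        Z = np.random.default_rng(0).standard_normal((4, 3))
        np.testing.assert_allclose(compute_psi(Z, np.zeros(3)), 0.25)

    def test_single_binary_annotation_hand_case(self):
        # features 1,2 annotated of B=4, alpha=ln 2: weights (2,2,1,1)/6
        Z = np.array([[1.0], [1.0], [0.0], [0.0]])
        psi = compute_psi(Z, np.array([np.log(2.0)]))
        np.testing.assert_allclose(psi, [1 / 3, 1 / 3, 1 / 6, 1 / 6])

    def test_annotated_to_unannotated_ratio_is_exp_alpha(self):
        Z = np.zeros((10, 1))
        Z[:4] = 1.0
        psi = compute_psi(Z, np.array([0.19]))
        assert psi[0] / psi[-1] == pytest.approx(1.21, abs=5e-3)

    def test_overflow_safe_for_extreme_scores(self):
        Z = np.linspace(-1, 1, 100_000)[:, None]
        psi = compute_psi(Z, np.array([700.0]))
        assert np.all(np.isfinite(psi))
        assert psi.sum() == pytest.approx(1.0, abs=1e-10)

    def test_invariant_to_constant_score_shift(self):
        rng = np.random.default_rng(1)
        Z = rng.standard_normal((50, 2))
        alpha = np.array([0.7, -1.2])
        shifted = np.hstack([Z, np.ones((50, 1))])
        np.testing.assert_allclose(
            compute_psi(Z, alpha),
            compute_psi(shifted, np.append(alpha, 3.5)),
            atol=1e-12,
        )

    def test_dimension_mismatch_and_nonfinite_alpha_raise(self):
        Z = np.zeros((5, 2))
        with pytest.raises(ValueError):
            compute_psi(Z, np.zeros(3))
        with pytest.raises(ValueError):
            compute_psi(Z, np.array([np.nan, 0.0]))

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        b=st.integers(2, 40),
        m=st.integers(1, 4),
        seed=st.integers(0, 10_000),
        scale=st.floats(0.01, 50.0),
    )
    def test_simplex_property(self, b, m, seed, scale):
        rng = np.random.default_rng(seed)
        Z = rng.standard_normal((b, m))
        psi = compute_psi(Z, scale * rng.standard_normal(m))
        assert np.all(psi > 0)
        assert psi.sum() == pytest.approx(1.0, abs=1e-10)


class TestEnrichmentRatio:
    @pytest.mark.parametrize(
        "alpha, expected, tol",
        [(0.19, 1.21, 5e-3), (0.0, 1.0, 0.0), (-1.13, 0.323, 5e-4)],
    )
    def test_values(self, alpha, expected, tol):
        assert enrichment_ratio(alpha) == pytest.approx(expected, abs=tol or 1e-12)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            enrichment_ratio(np.inf)


class TestLogPrior:
    def test_flat_beta_and_standard_normal_alpha_at_zero(self):
        state = ParameterState(h2=0.3, alpha=np.zeros(1))
        prior = PriorSpec(a=1, d=1, sigma_alpha_sq=1.0)
        assert log_prior(state, prior) == pytest.approx(-0.5 * np.log(2 * np.pi))

    def test_boundary_h2_rejected(self):
        with pytest.raises(ValueError):
            ParameterState(h2=0.0, alpha=np.zeros(1))
        with pytest.raises(ValueError):
            ParameterState(h2=1.0, alpha=np.zeros(1))

    def test_beta_term_matches_independent_normal_sum(self):
        psi = np.array([0.5, 0.5])
        beta = np.array([0.1, -0.2])
        state = ParameterState(h2=0.5, alpha=np.zeros(1), beta=beta)
        prior = PriorSpec()
        expected = stats.norm.logpdf(beta, scale=np.sqrt(0.5 * psi)).sum()
        base = log_prior(ParameterState(h2=0.5, alpha=np.zeros(1)), prior)
        assert log_prior(state, prior, psi) - base == pytest.approx(expected)

    def test_nonuniform_h2_prior_enters(self):
        state = ParameterState(h2=0.3, alpha=np.zeros(0))
        lp = log_prior(state, PriorSpec(a=2, d=5, sigma_alpha_sq=1.0))
        assert lp == pytest.approx(stats.beta.logpdf(0.3, 2, 5))


class TestMarginalLikelihood:
    def test_unit_case(self):
        data = ModelData(np.array([[1.0]]), np.array([0.0]), validate=False)
        val = log_marginal_likelihood(data, 0.5, np.zeros(0))
        assert val == pytest.approx(-0.5 * np.log(2 * np.pi), abs=1e-12)

    @pytest.mark.parametrize("n,B,M,h2", [(3, 6, 1, 0.3), (5, 8, 2, 0.7)])
    def test_brute_force_joint_marginalization_oracle(self, n, B, M, h2):
        """Marginalizing the explicit (beta, eps) joint numerically agrees."""
        data = make_data(n=n, B=B, M=M, seed=3, annotated=2, validate=False)
        alpha = np.array([0.8, -0.4])[:M]
        psi = compute_psi(data.Z, alpha)
        A = np.hstack([data.X, np.eye(n)])  # Y = A @ (beta, eps)
        C = block_diag(np.diag(h2 * psi), (1 - h2) * np.eye(n))
        oracle = stats.multivariate_normal(mean=np.zeros(n), cov=A @ C @ A.T)
        ours = log_marginal_likelihood(data, h2, alpha)
        assert ours == pytest.approx(oracle.logpdf(data.Y), abs=1e-8)

    def test_grouped_evaluator_matches_dense_formula(self):
        data = make_data(n=50, B=150, M=3, seed=7)
        ev = MarginalLikelihood(data)
        for h2, alpha in [(0.2, np.array([1.0, -0.5, 0.0])), (0.9, np.zeros(3))]:
            assert ev(h2, alpha).value == pytest.approx(
                log_marginal_likelihood(data, h2, alpha), abs=1e-8
            )

    def test_eigendecomposition_path_no_annotations(self):
        data = make_data(n=30, B=90, M=0, seed=5)
        ev = MarginalLikelihood(data)
        assert ev.n_groups == 1
        for h2 in (0.1, 0.5, 0.9):
            assert ev(h2, np.zeros(0)).value == pytest.approx(
                log_marginal_likelihood(data, h2, np.zeros(0)), abs=1e-8
            )

    def test_feature_permutation_invariance(self):
        data = make_data(n=20, B=40, M=1, seed=9, annotated=10)
        perm = np.random.default_rng(0).permutation(40)
        data2 = ModelData(data.X[:, perm], data.Y, data.Z[perm], validate=False)
        a = np.array([0.6])
        assert log_marginal_likelihood(data, 0.4, a) == pytest.approx(
            log_marginal_likelihood(data2, 0.4, a), abs=1e-9
        )

    def test_continuous_near_h2_boundaries(self):
        data = make_data(n=15, B=30, M=1, seed=2, annotated=10)
        grid = np.concatenate(
            [[1e-6, 1e-4], np.linspace(0.01, 0.99, 21), [1 - 1e-4, 1 - 1e-6]]
        )
        vals = [log_marginal_likelihood(data, h2, np.array([0.3])) for h2 in grid]
        assert np.all(np.isfinite(vals))

    def test_alpha_zero_prior_covariance_is_h2_over_B(self):
        data = make_data(n=10, B=25, M=2, seed=1, annotated=5)
        psi = compute_psi(data.Z, np.zeros(2))
        np.testing.assert_allclose(0.4 * psi, np.full(25, 0.4 / 25), atol=1e-14)
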