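"""Conditional beta draws, Metropolis updates and chain management."""

import numpy as np
import pytest
from scipy import stats

from brainvc import (
    MarginalLikelihood,
    McmcConfig,
    ModelData,
    PriorSpec,
    compute_psi,
    pool_chains,
    run_mcmc,
    sample_beta_conditional,
    simulation_based_calibration,
)
from brainvc.sampler import _make_state, mh_update_alpha, mh_update_h2

from conftest import make_data


class TestSampleBetaConditional:
    def test_moments_match_dense_posterior_formula(self):
        """Empirical mean/cov over many draws matches the exact B x B formula."""
        rng = np.random.default_rng(4)
        n, B, h2 = 200, 5, 0.5
        X = rng.standard_normal((n, B))
        X = (X - X.mean(0)) / X.std(0, ddof=1)
        beta_true = rng.normal(0, 0.3, B)
        Y = X @ beta_true + rng.standard_normal(n) * 0.7
        Y -= Y.mean()
        data = ModelData(X, Y, validate=False)
        psi = np.full(B, 1.0 / B)
        Sigma = np.linalg.inv(X.T @ X / (1 - h2) + np.diag(1.0 / (h2 * psi)))
        mean = Sigma @ X.T @ Y / (1 - h2)
        draws = np.array(
            [sample_beta_conditional(data, h2, psi, rng) for _ in range(5000)]
        )
        se = np.sqrt(np.diag(Sigma) / 5000)
        np.testing.assert_array_less(np.abs(draws.mean(0) - mean), 5 * se)
        emp_cov = np.cov(draws.T)
        assert np.linalg.norm(emp_cov - Sigma) / np.linalg.norm(Sigma) < 0.1

    def test_zero_phenotype_gives_symmetric_draws(self):
        rng = np.random.default_rng(0)
        data = make_data(n=30, B=10, M=0, seed=1, validate=False)
        data.Y[:] = 0.0
        psi = np.full(10, 0.1)
        draws = np.array(
            [sample_beta_conditional(data, 0.4, psi, rng) for _ in range(2000)]
        )
        prior_sd = np.sqrt(0.4 * 0.1)
        np.testing.assert_array_less(
            np.abs(draws.mean(0)), 5 * prior_sd / np.sqrt(2000)
        )

    def test_vanishing_prior_weight_pins_beta_to_zero(self):
        rng = np.random.default_rng(2)
        data = make_data(n=30, B=6, M=0, seed=3)
        psi = np.full(6, 1 / 6)
        psi[2] = 1e-14
        draws = np.array(
            [sample_beta_conditional(data, 0.5, psi, rng) for _ in range(200)]
        )
        assert np.abs(draws[:, 2]).max() < 1e-5


class TestMetropolisUpdates:
    def test_near_zero_proposal_scale_always_accepts(self, small_data):
        ev = MarginalLikelihood(small_data)
        prior = PriorSpec()
        rng = np.random.default_rng(0)
        state = _make_state(ev, 0.4, np.zeros(2), prior)
        accepts_a = [
            mh_update_alpha(ev, state, prior, 1e-14, rng)[1] for _ in range(50)
        ]
        accepts_h = [
            mh_update_h2(ev, state, prior, 1e-14, rng)[1] for _ in range(50)
        ]
        assert all(accepts_a) and all(accepts_h)

    def test_null_simulation_concentrates_h2_near_zero(self):
        # pure noise: Y independent of X, posterior mass of h2 near 0
        rng = np.random.default_rng(8)
        n, B = 500, 1000
        X = rng.standard_normal((n, B))
        X = (X - X.mean(0)) / X.std(0, ddof=1)
        Y = rng.standard_normal(n)
        Y = (Y - Y.mean()) / Y.std(ddof=1)
        data = ModelData(X, Y)
        draws = run_mcmc(
            data,
            PriorSpec(),
            McmcConfig(
                n_iterations=1500, n_burnin=500, thin=5, n_chains=2, seed=1,
                store_beta=False,
            ),
        )
        assert np.median(draws.h2_draws) < 0.1

    def test_degenerate_alpha_prior_reduces_to_gcta_submodel(self):
        data = make_data(n=60, B=120, M=1, seed=6, annotated=40)
        tight = PriorSpec(sigma_alpha_sq=1e-8)
        cfg = McmcConfig(
            n_iterations=1200, n_burnin=400, thin=4, n_chains=2, seed=2,
            store_beta=False,
        )
        draws = run_mcmc(data, tight, cfg)
        assert np.abs(draws.alpha_draws).max() < 1e-3
        no_annot = ModelData(data.X, data.Y)
        ref = run_mcmc(no_annot, PriorSpec(), cfg)
        assert np.median(draws.h2_draws) == pytest.approx(
            np.median(ref.h2_draws), abs=0.1
        )


class TestRunMcmc:
    def test_quadrature_oracle_small_instance(self):
        """Pooled posterior means agree with deterministic 2-D quadrature."""
        data = make_data(n=60, B=60, M=1, seed=11, annotated=20)
        rng = np.random.default_rng(5)
        psi = compute_psi(data.Z, np.array([1.2]))
        beta = rng.standard_normal(60) * np.sqrt(0.6 * psi)
        data.Y[:] = data.X @ beta + rng.standard_normal(60) * np.sqrt(0.4)
        prior = PriorSpec(sigma_alpha_sq=1.0)
        ev = MarginalLikelihood(data)
        h2_grid = np.linspace(0.005, 0.995, 60)
        a_grid = np.linspace(-4, 4, 81)
        logp = np.array(
            [[ev(h2, np.array([a])).value
              - 0.5 * a**2 / prior.sigma_alpha_sq
              for a in a_grid] for h2 in h2_grid]
        )
        w = np.exp(logp - logp.max())
        w /= w.sum()
        h2_quad = float((w.sum(axis=1) * h2_grid).sum())
        a_quad = float((w.sum(axis=0) * a_grid).sum())
        draws = run_mcmc(
            data, prior,
            McmcConfig(n_iterations=4000, n_burnin=1000, thin=3, n_chains=3,
                       seed=9, store_beta=False),
            evaluator=ev,
        )
        pooled = pool_chains(draws)
        assert pooled["h2"].mean() == pytest.approx(h2_quad, abs=0.04)
        assert pooled["alpha"][:, 0].mean() == pytest.approx(a_quad, abs=0.15)

    def test_acceptance_rates_in_band_after_adaptation(self):
        data = make_data(n=80, B=200, M=2, seed=13, annotated=60)
        draws = run_mcmc(
            data, PriorSpec(sigma_alpha_sq=1.0),
            McmcConfig(n_iterations=1500, n_burnin=700, thin=4, n_chains=2,
                       seed=3, store_beta=False),
        )
        for key in ("alpha", "h2"):
            assert np.all(draws.acceptance_rates[key] >= 0.1)
            assert np.all(draws.acceptance_rates[key] <= 0.6)

    def test_reproducible_given_seed(self, small_data):
        cfg = McmcConfig(n_iterations=300, n_burnin=100, thin=2, n_chains=2, seed=7)
        d1 = run_mcmc(small_data, config=cfg)
        d2 = run_mcmc(small_data, config=cfg)
        np.testing.assert_array_equal(d1.h2_draws, d2.h2_draws)
        np.testing.assert_array_equal(d1.alpha_draws, d2.alpha_draws)

    def test_empty_kept_schedule_rejected(self, small_data):
        with pytest.raises(ValueError):
            run_mcmc(
                small_data,
                config=McmcConfig(n_iterations=102, n_burnin=100, thin=5),
            )

    def test_r2_tracks_h2_in_correct_specification(self):
        """Across settings the empirical R^2 lies on the diagonal against h2."""
        from brainvc import SimulationConfig, simulate_dataset

        h2_all, r2_all = [], []
        for h2_true, seed in ((0.2, 21), (0.7, 22)):
            sim = simulate_dataset(
                SimulationConfig(n=300, B=900, M=4, h2_true=h2_true,
                                 alpha_true=(0.5, -0.5, 0.0, 0.0),
                                 annotation_fractions=(0.2,) * 4,
                                 x_model="block", seed=seed)
            )
            draws = run_mcmc(
                sim.data, PriorSpec(sigma_alpha_sq=1.0),
                McmcConfig(n_iterations=2000, n_burnin=800, thin=5, n_chains=2,
                           seed=5, store_beta=False),
            )
            pooled = pool_chains(draws)
            h2_all.append(pooled["h2"])
            r2_all.append(pooled["r2"])
            # within a setting the medians agree
            assert np.median(pooled["r2"]) == pytest.approx(
                np.median(pooled["h2"]), abs=0.05
            )
        slope = np.polyfit(np.concatenate(h2_all), np.concatenate(r2_all), 1)[0]
        assert 0.8 <= slope <= 1.2


class TestSimulationBasedCalibration:
    def test_buggy_sampler_rejected(self, monkeypatch):
        """Doubling the likelihood must break rank uniformity (negative control)."""
        import brainvc.prior_model as pm

        orig = pm.MarginalLikelihood.__call__

        def doubled(self, h2, alpha):
            st = orig(self, h2, alpha)
            st.value *= 2.0
            return st

        monkeypatch.setattr(pm.MarginalLikelihood, "__call__", doubled)
        report = simulation_based_calibration(
            n=60, B=90, M=1, n_replicates=60, seed=4,
            mcmc=McmcConfig(n_iterations=700, n_burnin=250, thin=5,
                            n_chains=1, store_beta=False),
        )
        assert min(report.pvalues.values()) < 0.01

    def test_report_covers_h2_and_alpha(self):
        report = simulation_based_calibration(
            n=40, B=60, M=2, n_replicates=12, seed=1,
            mcmc=McmcConfig(n_iterations=400, n_burnin=150, thin=5,
                            n_chains=1, store_beta=False),
        )
        assert set(report.ranks) == {"h2", "alpha_0", "alpha_1"}
        assert all(r.size == 12 for r in report.ranks.values())
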