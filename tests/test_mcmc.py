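"""Sampler correctness: conditionals, determinism, diagnostics, oracle match."""

import numpy as np
import pytest
from scipy import stats

from ovizip.mcmc import (
    SamplerConfig,
    fit_model,
    gelman_rubin,
    mc_standard_error,
    sample_posterior,
    summarize_posterior,
    update_latent_suitability,
)

FAST = SamplerConfig(n_chains=2, n_iter=3000, n_burnin=1000, thin=2, seed=13)


class TestLatentSuitability:
    def test_positive_count_forces_suitable(self, rng):
        z = update_latent_suitability(np.array([3, 1, 7]), np.full(3, 0.5), 0.99, rng)
        assert z.all()

    def test_zero_count_conditional_probability(self, rng):
        # rho = 0.5, lambda = ln 3: P(z=1 | y=0) = (0.5/3) / (0.5 + 0.5/3) = 0.25
        n = 200_000
        z = update_latent_suitability(
            np.zeros(n, dtype=int), np.full(n, np.log(3.0)), 0.5, rng
        )
        assert z.mean() == pytest.approx(0.25, abs=3 * np.sqrt(0.25 * 0.75 / n))

    def test_no_inflation_always_suitable(self, rng):
        z = update_latent_suitability(np.zeros(50, dtype=int), np.full(50, 2.0), 0.0, rng)
        assert z.all()


class TestSamplerContracts:
    def test_same_seed_is_bitwise_identical(self, intercept_only_design):
        d1 = sample_posterior(intercept_only_design, config=FAST, hierarchical=False)
        d2 = sample_posterior(intercept_only_design, config=FAST, hierarchical=False)
        np.testing.assert_array_equal(d1.beta, d2.beta)
        np.testing.assert_array_equal(d1.gamma, d2.gamma)
        np.testing.assert_array_equal(d1.sigma2, d2.sigma2)

    def test_adding_a_chain_preserves_earlier_chains(self, intercept_only_design):
        two = sample_posterior(
            intercept_only_design,
            config=SamplerConfig(**{**FAST.__dict__, "n_chains": 2}),
            hierarchical=False,
        )
        three = sample_posterior(
            intercept_only_design,
            config=SamplerConfig(**{**FAST.__dict__, "n_chains": 3}),
            hierarchical=False,
        )
        np.testing.assert_array_equal(two.beta, three.beta[:2])

    def test_acceptance_rates_reasonable_after_adaptation(self, site_level_study):
        from ovizip.zip_model import build_design_matrix

        data = build_design_matrix(site_level_study.records_frame(), "AEG", "A")
        draws = sample_posterior(data, config=FAST)
        for block in ("beta", "gamma", "alpha"):
            assert 0.1 < draws.acceptance[block] < 0.6

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SamplerConfig(n_iter=100, n_burnin=100)
        with pytest.raises(ValueError):
            SamplerConfig(thin=0)


class TestGridOracle:
    def test_poisson_posterior_mean_matches_grid(self, intercept_only_design):
        """MCMC vs dense grid integration on the 1-parameter fixture."""
        data = intercept_only_design
        draws = sample_posterior(
            data,
            config=SamplerConfig(n_chains=3, n_iter=6000, n_burnin=2000, thin=2, seed=9),
            zero_inflated=False,
            hierarchical=False,
        )
        rate_draws = np.exp(draws.beta[:, :, 0])
        grid = np.linspace(-2.0, 4.0, 120_001)
        logpost = (
            stats.norm.logpdf(grid, 0.0, np.sqrt(1000.0))
            + data.y.sum() * grid
            - len(data.y) * np.exp(grid)
        )
        w = np.exp(logpost - logpost.max())
        w /= w.sum()
        grid_mean = float(np.sum(w * np.exp(grid)))
        se = mc_standard_error(rate_draws)
        assert abs(rate_draws.mean() - grid_mean) < 3 * se


class TestGelmanRubin:
    def test_null_chains_near_one(self, rng):
        chains = rng.standard_normal((4, 2000))
        assert gelman_rubin(chains) < 1.05

    def test_shifted_chains_flagged(self, rng):
        chains = rng.standard_normal((2, 500))
        chains[1] += 5.0
        assert gelman_rubin(chains) > 1.2

    def test_constant_chains_convention(self):
        assert gelman_rubin(np.ones((2, 100))) == 1.0

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError):
            gelman_rubin(np.zeros((1, 100)))

    def test_agrees_with_arviz(self, rng):
        arviz = pytest.importorskip("arviz")
        chains = rng.standard_normal((4, 1000)) + 0.3 * np.linspace(0, 1, 1000)
        ours = gelman_rubin(chains)
        theirs = float(arviz.rhat(chains, method="split"))
        assert ours == pytest.approx(theirs, abs=0.01)


class TestSummaries:
    def test_constant_draws_point_mass(self):
        from ovizip.mcmc import PosteriorDraws

        c = 2.5
        draws = PosteriorDraws(
            beta=np.full((2, 50, 1), c),
            gamma=np.zeros((2, 50, 2)),
            alpha=np.zeros((2, 50, 1)),
            sigma2=np.ones((2, 50)),
            loglik=np.zeros((2, 50)),
            presence=np.full((2, 50), 0.4),
            param_names=["intercept", "zi_intercept", "zi_month", "alpha_c", "sigma2"],
            acceptance={},
            zero_inflated=True,
            hierarchical=True,
        )
        s = summarize_posterior(draws).set_index("parameter")
        assert s.loc["intercept", "mean"] == c
        assert s.loc["intercept", "q2.5"] == c
        assert s.loc["intercept", "q97.5"] == c
        assert s.loc["intercept", "excludes_zero"]
        assert s.loc["Presence", "mean"] == pytest.approx(0.4)

    def test_mean_of_arithmetic_sequence(self):
        from ovizip.mcmc import PosteriorDraws

        vals = np.arange(1, 101, dtype=float).reshape(2, 50, 1)
        draws = PosteriorDraws(
            beta=vals,
            gamma=np.zeros((2, 50, 0)),
            alpha=np.zeros((2, 50, 0)),
            sigma2=np.ones((2, 50)),
            loglik=np.zeros((2, 50)),
            presence=np.zeros((2, 50)),
            param_names=["b0"],
            acceptance={},
            zero_inflated=False,
            hierarchical=False,
        )
        s = summarize_posterior(draws)
        assert s.loc[0, "mean"] == pytest.approx(50.5)

    def test_chain_order_exchangeable(self, intercept_only_design):
        draws = sample_posterior(intercept_only_design, config=FAST, hierarchical=False)
        flipped = sample_posterior(intercept_only_design, config=FAST, hierarchical=False)
        for arr in ("beta", "gamma", "sigma2", "loglik", "presence"):
            setattr(flipped, arr, getattr(flipped, arr)[::-1])
        s1 = summarize_posterior(draws)
        s2 = summarize_posterior(flipped)
        np.testing.assert_allclose(s1["mean"], s2["mean"])
        np.testing.assert_allclose(s1["rhat"], s2["rhat"], atol=1e-12)

    def test_true_parameters_recovered_on_synthetic_fit(self, site_level_study):
        """Known generative coefficients fall inside their 95% CIs (n=300)."""
        from ovizip.zip_model import build_design_matrix

        data = build_design_matrix(site_level_study.records_frame(), "AEG", "A")
        fit = fit_model(
            data, config=SamplerConfig(n_chains=2, n_iter=5000, n_burnin=2000, seed=3)
        )
        s = fit.summary.set_index("parameter")
        truth = site_level_study.config.beta["AEG"]
        assert s.loc["month", "q2.5"] <= truth["month"] <= s.loc["month", "q97.5"]
        assert s.loc["month", "excludes_zero"]
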