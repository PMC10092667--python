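import math

import numpy as np
import pytest
from scipy.integrate import simpson

from ddpop import (
    MCMCConfig,
    ModelSpec,
    SimSpec,
    SpeciesParams,
    beta0_prior_bounds,
    fit_deterministic_ricker,
    fit_state_space,
    gelman_rubin,
    log_obs_density,
    log_process_density,
    simulate_colony_counts,
)
from .conftest import make_series


class TestBeta0PriorBounds:
    def test_paper_default_values(self):
        lo, hi = beta0_prior_bounds(SpeciesParams(clutch_max=1.0, survival_floor=0.2))
        assert lo == pytest.approx(-1.6094, abs=1e-4)
        assert hi == pytest.approx(0.4055, abs=1e-4)

    def test_interval_collapses_in_limit(self):
        sp = SpeciesParams(clutch_max=1e-6, survival_floor=1 - 1e-9)
        lo, hi = beta0_prior_bounds(sp)
        assert abs(lo) < 1e-6 and abs(hi) < 1e-6

    def test_clutch_three(self):
        lo, hi = beta0_prior_bounds(SpeciesParams(clutch_max=3.0))
        assert lo == pytest.approx(math.log(0.2))
        assert hi == pytest.approx(math.log(2.5))

    def test_invalid_species_rejected(self):
        with pytest.raises(ValueError):
            SpeciesParams(clutch_max=0.0)
        with pytest.raises(ValueError):
            SpeciesParams(survival_floor=1.5)


class TestLogProcessDensity:
    def test_zero_residual_peak(self):
        params = dict(beta0=0.05, beta1=-0.0005, sigma_eps=0.1)
        # mean of next state equals 100: residual 0, density = log-normal peak
        val = log_process_density(100.0, 100.0, params, kind="M1")
        peak = -math.log(100.0) - math.log(0.1) - 0.5 * math.log(2 * math.pi)
        assert val == pytest.approx(peak)

    def test_m0_nests_in_m1(self):
        p0 = dict(beta0=0.1, sigma_eps=0.2)
        p1 = dict(beta0=0.1, beta1=0.0, sigma_eps=0.2)
        for nt in (50.0, 120.0, 300.0):
            assert log_process_density(nt, 100.0, p0, "M0") == pytest.approx(
                log_process_density(nt, 100.0, p1, "M1")
            )

    def test_density_integrates_to_one(self):
        params = dict(beta0=0.1, beta1=-0.001, sigma_eps=0.15)
        grid = np.linspace(1e-3, 400.0, 40001)
        dens = np.exp([log_process_density(x, 100.0, params, "M1") for x in grid])
        assert simpson(dens, x=grid) == pytest.approx(1.0, abs=1e-3)

    def test_nonpositive_abundance_rejected(self):
        params = dict(beta0=0.1, beta1=-0.001, sigma_eps=0.1)
        with pytest.raises(ValueError):
            log_process_density(-1.0, 100.0, params, "M1")
        with pytest.raises(ValueError):
            log_process_density(100.0, 0.0, params, "M1")

    def test_m2_requires_second_lag(self):
        params = dict(beta0=0.1, beta1=-0.001, beta2=-0.0001, sigma_eps=0.1)
        with pytest.raises(ValueError):
            log_process_density(100.0, 100.0, params, "M2")
        assert np.isfinite(log_process_density(100.0, 100.0, params, "M2", N_prev2=90.0))


class TestLogObsDensity:
    def test_zero_count_rate_one(self):
        assert log_obs_density(0, 1.0) == pytest.approx(-1.0)

    def test_matches_logfactorial_oracle(self):
        # independent pmf computation: y log(mu) - mu - sum(log k)
        y, mu = 100, 100.0
        oracle = y * math.log(mu) - mu - sum(math.log(k) for k in range(1, y + 1))
        assert log_obs_density(y, mu) == pytest.approx(oracle, abs=1e-9)

    def test_individuals_rate_equivalence(self):
        assert log_obs_density(80, 200.0, K_t=0.5, unit="individuals") == pytest.approx(
            log_obs_density(80, 100.0)
        )

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            log_obs_density(-1, 10.0)
        with pytest.raises(ValueError):
            log_obs_density(5, 0.0)
        with pytest.raises(ValueError):
            log_obs_density(5, 10.0, unit="individuals")  # K missing


class TestGelmanRubin:
    def test_identical_chains_at_most_one(self, rng):
        x = rng.normal(size=500)
        chains = np.vstack([x, x, x])
        assert gelman_rubin(chains) <= 1.0

    def test_same_distribution_near_one(self, rng):
        chains = rng.normal(size=(2, 10_000))
        assert gelman_rubin(chains) < 1.01

    def test_offset_chains_flagged(self, rng):
        chains = rng.normal(size=(2, 1000))
        chains[1] += 10.0
        assert gelman_rubin(chains) > 1.1

    def test_single_chain_rejected(self, rng):
        with pytest.raises(ValueError):
            gelman_rubin(rng.normal(size=(1, 100)))


class TestModelSpec:
    def test_m0_has_no_dd_params(self):
        assert ModelSpec(kind="M0").param_names == ("beta0", "sigma_eps")

    def test_unordered_bounds_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec(kind="M1", sigma_bounds=(2.0, 0.0))

    def test_mcmc_validation(self):
        with pytest.raises(ValueError):
            MCMCConfig(n_iter=100, n_burnin=100)
        with pytest.raises(ValueError):
            MCMCConfig(n_chains=1)


class TestFitStateSpace:
    def test_short_series_rejected(self, quick_mcmc):
        s = make_series("c", [2000, 2001], [10, 12])
        with pytest.raises(ValueError):
            fit_state_space(s, species=SpeciesParams(), mcmc=quick_mcmc)

    def test_individuals_without_conversion_rejected(self, quick_mcmc):
        s = make_series("c", np.arange(2000, 2010), np.full(10, 50.0), unit="individuals")
        with pytest.raises(ValueError):
            fit_state_space(s, species=SpeciesParams(), mcmc=quick_mcmc)

    def test_posterior_respects_prior_supports(self, m1_series, quick_mcmc, species_default):
        series, _ = m1_series
        fit = fit_state_space(series, species=species_default, mcmc=quick_mcmc)
        lo, hi = beta0_prior_bounds(species_default)
        assert fit.draws("beta0").min() >= lo and fit.draws("beta0").max() <= hi
        assert fit.draws("sigma_eps").min() > 0 and fit.draws("sigma_eps").max() < 2
        assert np.all(fit.N > 0)

    def test_reproducible_given_seed(self, m1_series, species_default):
        series, _ = m1_series
        mcmc = MCMCConfig(n_iter=1200, n_burnin=400, thin=2, seed=5)
        a = fit_state_space(series, species=species_default, mcmc=mcmc)
        b = fit_state_space(series, species=species_default, mcmc=mcmc)
        np.testing.assert_array_equal(a.draws("beta1"), b.draws("beta1"))
        np.testing.assert_array_equal(a.N, b.N)

    def test_m0_recovery_of_beta0(self, species_c3):
        # M0 data: posterior mean of beta0 within a few MC SEs of truth
        spec = SimSpec(model_kind="M0", beta0=0.02, sigma_eps=0.1, n_years=40, N0=500, seed=21)
        series, _ = simulate_colony_counts(spec)
        fit = fit_state_space(
            series,
            species=species_c3,
            model_spec=ModelSpec.for_species("M0", species_c3),
            mcmc=MCMCConfig(n_iter=5000, n_burnin=1500, thin=3, seed=2),
        )
        draws = fit.draws("beta0")
        assert abs(draws.mean() - 0.02) < 3 * draws.std()

    def test_m1_credible_interval_covers_truth(self, m1_series, species_default):
        series, truth = m1_series
        fit = fit_state_space(
            series,
            species=species_default,
            mcmc=MCMCConfig(n_iter=6000, n_burnin=2000, thin=4, seed=11),
        )
        lo, hi = np.percentile(fit.draws("beta1"), [1, 99])
        assert lo <= truth.spec.beta1 <= hi

    def test_missing_years_imputed(self, m1_series, species_default, quick_mcmc):
        series, _ = m1_series
        fit = fit_state_space(series, species=species_default, mcmc=quick_mcmc)
        n_missing = int(np.isnan(fit.series.counts).sum())
        assert fit.y_rep_missing is not None
        assert fit.y_rep_missing.shape[-1] == n_missing
        # imputations track neighbouring latent abundance
        miss_idx = np.where(np.isnan(fit.series.counts))[0]
        imput_mean = fit.y_rep_missing.mean(axis=(0, 1))
        latent_mean = fit.N.mean(axis=(0, 1))[miss_idx]
        assert np.all(np.abs(imput_mean - latent_mean) < 0.2 * latent_mean + 5)

    def test_m2_fit_runs_and_nests(self, species_default):
        spec = SimSpec(model_kind="M1", beta0=0.1, beta1=-0.0005, sigma_eps=0.1,
                       n_years=25, N0=200, seed=3)
        series, _ = simulate_colony_counts(spec)
        fit = fit_state_space(
            series,
            species=species_default,
            model_spec=ModelSpec.for_species("M2", species_default),
            mcmc=MCMCConfig(n_iter=2500, n_burnin=1000, thin=3, seed=4),
        )
        assert set(fit.params) == {"beta0", "beta1", "beta2", "sigma_eps"}
        assert np.all(fit.N > 0)

    def test_individuals_series_with_conversion(self, species_default):
        from ddpop import simulate_conversion_factors

        conv = simulate_conversion_factors(1986 + np.arange(30), level=0.67, se=0.02, seed=0)
        spec = SimSpec(count_unit="individuals", beta0=0.1, beta1=-0.0005, sigma_eps=0.1,
                       n_years=30, N0=200, seed=10)
        series, truth = simulate_colony_counts(spec, conversion=conv)
        fit = fit_state_space(
            series, conversion=conv, species=species_default,
            mcmc=MCMCConfig(n_iter=4000, n_burnin=1500, thin=3, seed=9),
        )
        assert fit.K is not None
        assert np.all(fit.K >= 0.05)
        # latent N should sit near truth's scale, not the raw individual counts
        assert abs(np.log(fit.N.mean() / truth.N.mean())) < 0.5


class TestCollapsedSampler:
    def test_matches_grid_posterior_mean(self):
        spec = SimSpec(model_kind="M1", beta0=0.05, beta1=-0.0005, sigma_eps=0.0,
                       n_years=5, N0=100, seed=7)
        series, _ = simulate_colony_counts(spec)
        ms = ModelSpec(kind="M1")
        draws = fit_deterministic_ricker(
            series, model_spec=ms,
            mcmc=MCMCConfig(n_iter=20000, n_burnin=4000, thin=4, seed=3),
        )
        assert np.isfinite(draws["beta1"]).all()
        assert draws["N0"].min() >= series.observed_counts[:4].min()
        assert draws["N0"].max() <= series.observed_counts[:4].max()
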