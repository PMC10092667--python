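import numpy as np
import pytest

from ddpop import CountTimeSeries, MCMCConfig, SimSpec, SpeciesParams, simulate_colony_counts


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def species_default():
    return SpeciesParams()


@pytest.fixture()
def species_c3():
    return SpeciesParams(name="big-clutch", clutch_max=3.0)


@pytest.fixture()
def m1_series():
    """A 30-year M1 series near equilibrium, with some missing years."""
    spec = SimSpec(
        model_kind="M1",
        beta0=0.1,
        beta1=-0.0005,
        sigma_eps=0.1,
        n_years=30,
        N0=200,
        missing_fraction=0.1,
        seed=42,
    )
    series, truth = simulate_colony_counts(spec)
    return series, truth


@pytest.fixture()
def quick_mcmc():
    """Small-but-converging sampler settings for unit tests."""
    return MCMCConfig(n_iter=4000, n_burnin=1500, thin=3, seed=7)


def make_series(colony_id, years, counts, species="sp", unit="pairs"):
    return CountTimeSeries(
        colony_id=colony_id,
        species=species,
        years=np.asarray(years),
        counts=np.asarray(counts, dtype=float),
        unit=unit,
    )
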