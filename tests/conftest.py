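import numpy as np
import pytest

import avitrend as av


@pytest.fixture(scope="session")
def small_bundle():
    """A 20-species assemblage with known truth, shared across tests."""
    cfg = av.SimulationConfig(n_species=20, year_start=1990, year_end=2019)
    return av.simulate_assemblage(cfg, seed=11)


@pytest.fixture(scope="session")
def small_posterior(small_bundle):
    """A fitted posterior on the small bundle (reduced MCMC)."""
    bundle, truth = small_bundle
    smoothed = [av.fit_gam(s) for s in bundle.index_series.values()]
    post = av.fit_hierarchical(
        smoothed,
        bundle.estimates,
        species=bundle.species,
        mcmc=av.MCMCSettings(chains=2, warmup=300, draws=300, seed=7),
    )
    return post, truth


@pytest.fixture(scope="session")
def yule_50():
    return av.yule_tree(50, np.random.default_rng(5))


@pytest.fixture(scope="session")
def yule_100():
    return av.yule_tree(100, np.random.default_rng(42))
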