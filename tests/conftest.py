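import numpy as np
import pytest

from gwnr import (
    ModelSpec,
    SimulationScenario,
    WeightScheme,
    fit_gwnr,
    fit_mnr,
    gen_dataset,
)

UNIFORM_BANDWIDTH = 1e8  # gaussian weights indistinguishable from 1 at unit-square distances


@pytest.fixture(scope="session")
def null_scenario():
    """Constant-coefficient (H0) scenario at the default study conditions."""
    return SimulationScenario(seed=11)


@pytest.fixture(scope="session")
def small_scenario():
    """A smaller dataset for per-test fits."""
    return SimulationScenario(n=40, seed=7)


@pytest.fixture(scope="session")
def small_data(small_scenario):
    data, truth = gen_dataset(small_scenario)
    return data, truth


@pytest.fixture(scope="session")
def small_fits(small_data, small_scenario):
    data, _ = small_data
    gwnr = fit_gwnr(data, small_scenario.spec)
    mnr = fit_mnr(data.y, gwnr.design)
    return data, mnr, gwnr


@pytest.fixture(scope="session")
def uniform_spec():
    return ModelSpec(weights=WeightScheme(kernel="gaussian", bandwidth=UNIFORM_BANDWIDTH))


@pytest.fixture()
def rng():
    return np.random.default_rng(20240915)
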