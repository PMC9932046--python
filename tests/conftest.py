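import numpy as np
import pytest

from ivmedsurv import SimulationConfig, generate_dataset, scenario_sparse


@pytest.fixture(scope="session")
def sparse500():
    """One fixed cohort from the 1,000-covariate scenario at n=500."""
    return generate_dataset(scenario_sparse(500, 0.2, seed=1))


def small_config(n=300, p_total=120, censor=0.2, seed=0, **kw):
    """Reduced covariate pool with the same signal structure; fast pipelines."""
    return SimulationConfig(n=n, p_total=p_total, censor_rate_target=censor,
                           seed=seed, **kw)


@pytest.fixture(scope="session")
def small_data():
    return generate_dataset(small_config(seed=4))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
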