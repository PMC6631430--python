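import numpy as np
import pytest

import brushflow as bf


@pytest.fixture(scope="session")
def coating14():
    """A moderate N=14 coating: 6 chains per wall, fixed seed."""
    return bf.generate_grafted_coating(14, 6, seed=3)


@pytest.fixture(scope="session")
def small_scenario():
    """Default N=14 scenario on a reduced grid, with its profiles and the
    noiseless forward-solved velocity."""
    scen = bf.SyntheticScenario(n_grid=801)
    profiles = bf.scenario_profiles(scen)
    velocity = bf.synthesize_velocity(scen, profiles)
    return scen, profiles, velocity


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
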