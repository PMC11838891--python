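import numpy as np
import pytest

import tvartlab as tl


@pytest.fixture(scope="session")
def two_attractor_set():
    return tl.find_fixed_points(tl.two_attractor_parameters(), n_seeds=40, seed=1)


@pytest.fixture(scope="session")
def four_attractor_set():
    return tl.find_fixed_points(tl.four_attractor_parameters(), n_seeds=40, seed=1)


@pytest.fixture(scope="session")
def two_attractor_traj():
    """One 120 s two-attractor trajectory at sigma=0.5, 2 ms sampling."""
    return tl.simulate_heun(
        tl.two_attractor_parameters(sigma=0.5), tl.SimulationSettings(seed=3)
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
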