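import numpy as np
import pytest

import corneafit as cf


@pytest.fixture(scope="session")
def noiseless_pair():
    """Default healthy ellipsoid (Rx=Ry=7.8 mm, Q=-0.3), no noise/dropout."""
    grid, truth = cf.make_ellipsoid_grid(cf.SyntheticSpec(seed=0))
    return grid, truth


@pytest.fixture(scope="session")
def noiseless_cloud(noiseless_pair):
    grid, _ = noiseless_pair
    return cf.polar_to_cartesian(grid)


@pytest.fixture(scope="session")
def noisy_pair():
    """Same ellipsoid with 5 um Gaussian elevation noise."""
    grid, truth = cf.make_ellipsoid_grid(
        cf.SyntheticSpec(noise_sigma=0.005, seed=7))
    return grid, truth


@pytest.fixture(scope="session")
def noisy_cloud(noisy_pair):
    grid, _ = noisy_pair
    return cf.polar_to_cartesian(grid)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_ga_config():
    """Cheap GA settings for determinism/behaviour tests (not accuracy)."""
    return cf.GAConfig(pop_per_variable=10, max_generations=60,
                       stall_generations=20, restarts=1,
                       refine_generations=15, refine_population=40)
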