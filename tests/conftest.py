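import numpy as np
import pytest

import habgame as hg


@pytest.fixture(scope="session")
def table_params():
    """Default parameters at the Fig. 4-style operating point K=3, c=0."""
    return hg.derive_parameters({"K": 3.0, "c": 0.0})


@pytest.fixture(scope="session")
def grid300():
    return hg.build_grid(100.0, 300)


@pytest.fixture(scope="session")
def grid21():
    return hg.build_grid(100.0, 21)


@pytest.fixture(scope="session")
def env300(table_params, grid300):
    return hg.environment_profiles(table_params, grid300)


@pytest.fixture(scope="session")
def equilibrium_K3(table_params, grid300, env300):
    """The coexistence equilibrium at K=3, c=0 on the default grid."""
    return hg.solve_coexistence_equilibrium(table_params, env300, grid300,
                                            tol=1e-10)


def random_density(rng, grid):
    sigma = rng.gamma(2.0, size=grid.n_nodes)
    return sigma / np.sum(grid.weights * sigma)


@pytest.fixture
def density_factory():
    return random_density
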