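import numpy as np
import pytest

from lactoburst import ModelParams, build_singular_orbit


@pytest.fixture(scope="session")
def p():
    """Default lactotroph parameter set."""
    return ModelParams()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture(scope="session")
def orbit_gk4():
    """Singular periodic orbit in the mixed-mode (funnel-entry) regime."""
    return build_singular_orbit(ModelParams(gK=4.0))


@pytest.fixture(scope="session")
def orbit_gk51():
    """Singular periodic orbit in the relaxation (spiking) regime."""
    return build_singular_orbit(ModelParams(gK=5.1))


def random_states(rng, n, V_range=(-70.0, 40.0), n_range=(0.0, 0.6),
                  c_range=(0.02, 1.2)):
    V = rng.uniform(*V_range, n)
    nn = rng.uniform(*n_range, n)
    c = rng.uniform(*c_range, n)
    return np.column_stack([V, nn, c])
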