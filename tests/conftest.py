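import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import mvphi as m

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def p53_net():
    return m.p53_model()


@pytest.fixture(scope="session")
def p53_fn():
    return m.p53_evolution_function()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_probabilistic_net(radices, rng, concentration=1.0):
    """A random conditionally-independent probabilistic network built from
    per-node Dirichlet conditionals (test helper)."""
    from mvphi.network import tpm_from_conditionals

    S = int(np.prod(radices))
    tables = [
        rng.dirichlet(np.full(r, concentration), size=S) for r in radices
    ]
    return m.Network(tpm_from_conditionals(tables, tuple(radices)), radices)


@pytest.fixture
def small_nets(rng):
    """A spread of small deterministic and probabilistic networks."""
    nets = [
        m.random_deterministic_net("22", rng),
        m.random_deterministic_net("32", rng),
        m.random_deterministic_net("33", rng),
        m.random_deterministic_net("222", rng),
        random_probabilistic_net((2, 2), rng),
        random_probabilistic_net((3, 2), rng),
        random_probabilistic_net((2, 2, 2), rng),
    ]
    return nets
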