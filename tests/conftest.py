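import numpy as np
import pytest

from metacoop import DEFAULT_PARAMS, Protocol, isolated, star, standard_initial_state


@pytest.fixture(scope="session")
def params():
    """Fitted study parameter set."""
    return DEFAULT_PARAMS


@pytest.fixture(scope="session")
def star9():
    return star(9)


@pytest.fixture(scope="session")
def iso1():
    return isolated(1)


@pytest.fixture(scope="session")
def benign_protocol(params):
    """Reference daily protocol: dilution 650, migration 0.6."""
    return Protocol(D=650.0, m=0.6, params=params, n_cycles=1000)


def dense_start(n, fraction=0.1):
    """Saturated-culture-scale start used throughout the tests."""
    return standard_initial_state(n, fraction=fraction)


@pytest.fixture(scope="session")
def iso_equilibrium(iso1, params):
    """Isolated-node equilibrium at the benign reference protocol."""
    from metacoop import steady_state

    ss = steady_state(iso1, Protocol(D=650.0, m=0.0, params=params, n_cycles=1000))
    assert ss.status == "converged"
    return ss


@pytest.fixture(scope="session")
def star_equilibrium(star9, params):
    """10-node star equilibrium at the benign reference protocol."""
    from metacoop import steady_state

    ss = steady_state(star9, Protocol(D=650.0, m=0.6, params=params, n_cycles=1000))
    assert ss.status == "converged"
    return ss
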