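import numpy as np
import pytest

from vepcal.dynamics import NetworkModel


@pytest.fixture
def single_node():
    """Isolated node in the seizure-free (HZ) regime."""
    return NetworkModel(connectome=np.zeros((1, 1)),
                        excitability=np.array([-3.5]), timescale=10.0)


@pytest.fixture
def ez_node():
    """Isolated node above the critical excitability (oscillatory)."""
    return NetworkModel(connectome=np.zeros((1, 1)),
                        excitability=np.array([-1.6]), timescale=10.0)


@pytest.fixture
def small_network():
    """Three coupled regions, one epileptogenic."""
    rng = np.random.default_rng(3)
    C = rng.uniform(0.1, 1.0, size=(3, 3))
    C = np.triu(C, 1)
    C = C + C.T
    C /= C.max()
    return NetworkModel(connectome=C,
                        excitability=np.array([-1.6, -2.2, -3.5]),
                        coupling=1.0, timescale=10.0)
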