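import numpy as np
import pytest

from memee.itl_losses import KernelSpec
from memee.network import NetworkConfig, init_network
from memee.neuron import NeuronParams


@pytest.fixture(scope="session")
def unit_kernel():
    return KernelSpec(1.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_net():
    """3 hidden neurons, surrogate-friendly (no refractoriness), delay 1."""
    params = NeuronParams(refractory_steps=0)
    cfg = NetworkConfig(n_in=2, n_hidden=3, n_out=2, sparsity=1.0, seed=7,
                        neuron=params, delay_steps=1)
    return init_network(cfg)


@pytest.fixture(scope="session")
def small_net():
    """A 20-neuron network with default neuron parameters."""
    cfg = NetworkConfig(n_in=10, n_hidden=20, n_out=2, sparsity=0.3, seed=11)
    return init_network(cfg)
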