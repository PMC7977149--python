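import numpy as np
import pytest

from stcnet.params import (CouplingParams, NeuronParams, PlasticityParams,
                           TopologyParams)


@pytest.fixture
def neuron_params():
    return NeuronParams()


@pytest.fixture
def plast_network():
    return PlasticityParams(calcium_mode="network")


@pytest.fixture
def plast_invitro():
    return PlasticityParams(calcium_mode="invitro")


@pytest.fixture
def tiny_net():
    """Small recurrent network for fast dynamical tests."""
    from stcnet.network import build_network
    return build_network(TopologyParams(N_e=40, N_i=10, p_c=0.15),
                         CouplingParams(), seed=12345)


@pytest.fixture
def rng():
    return np.random.default_rng(987)
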