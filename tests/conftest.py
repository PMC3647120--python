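import numpy as np
import pytest

from shuntnet.compartmental import DistanceModel, NeuronParams
from shuntnet.network import NetworkParams


@pytest.fixture
def params() -> NeuronParams:
    """Default single-neuron parameter table."""
    return NeuronParams()


@pytest.fixture
def distance_model() -> DistanceModel:
    return DistanceModel()


@pytest.fixture
def small_net() -> NetworkParams:
    """Scaled-down network for fast structural tests (same in-degree fractions)."""
    return NetworkParams(N_E=200, N_I=50, p=0.1, dt=0.1)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
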