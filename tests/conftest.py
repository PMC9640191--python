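import numpy as np
import pytest

from surroneuron import (
    EventTrain,
    active_point_model,
    excitatory_synapse,
    inhibitory_synapse,
    passive_point_model,
)
from surroneuron.biophys.point import simulate_point_neuron, steady_state_init
from surroneuron import stimgen
from surroneuron.data import make_windows, normalize


@pytest.fixture(scope="session")
def passive_model():
    return passive_point_model()


@pytest.fixture(scope="session")
def active_model():
    return active_point_model()


@pytest.fixture(scope="session")
def passive_init(passive_model):
    return steady_state_init(passive_model)


@pytest.fixture(scope="session")
def active_init(active_model):
    return steady_state_init(active_model)


@pytest.fixture(scope="session")
def point_synapses():
    return [excitatory_synapse(), inhibitory_synapse()]


@pytest.fixture(scope="session")
def small_passive_pairs(passive_model, passive_init, point_synapses):
    """Three 3-s passive traces under random 8:3 trains."""
    pairs = []
    for k in range(3):
        train = stimgen.random_train(3000.0, 150, seed=100 + k)
        tr = simulate_point_neuron(
            passive_model, point_synapses, train, 3000.0, init=passive_init
        )
        pairs.append((tr, train))
    return pairs


@pytest.fixture(scope="session")
def small_passive_ds(small_passive_pairs):
    return normalize(make_windows(small_passive_pairs))
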