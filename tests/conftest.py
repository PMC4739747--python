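import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from dendrisp.model import NeuronParams, SynapticWeights, simulate_trial
from dendrisp.tasks import gen_frozen_poisson


@pytest.fixture
def neuron():
    return NeuronParams()


@pytest.fixture
def small_neuron():
    """A 3-branch neuron for cheap trials."""
    return NeuronParams(n_branches=3)


@pytest.fixture
def pattern():
    return gen_frozen_poisson(20, 6.0, 200.0, seed=42)


@pytest.fixture
def trial(small_neuron, pattern):
    """One free-running trial with enough drive for plateaus and spikes."""
    rng = np.random.default_rng(3)
    weights = SynapticWeights.initialize(
        small_neuron.replace(w0=60.0), pattern.n_channels, rng
    )
    return simulate_trial(small_neuron, weights, pattern, mode="free", rng=rng), weights
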