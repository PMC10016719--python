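import numpy as np
import pytest

from neurochar.synth import (
    SyntheticNeuron,
    SyntheticNeuronSpec,
    default_clamp_protocols,
)


@pytest.fixture(scope="session")
def clamp_protocols():
    return default_clamp_protocols()


@pytest.fixture
def basic_spec():
    """A quiet regular-spiking neuron with exactly known parameters."""
    return SyntheticNeuronSpec(
        rheobase_na=0.5,
        delay_ms=50.0,
        isi_base_ms=20.0,
        accommodation_rate=1.0,
        noise_sd_mv=0.0,
        seed=7,
    )


@pytest.fixture
def basic_neuron(basic_spec):
    return SyntheticNeuron(basic_spec)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
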