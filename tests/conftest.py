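"""Shared fixtures: small simulated waveforms reused across test modules."""

import numpy as np
import pytest
from hypothesis import settings

from oscsense.oscillator import ONNConfig, OscillatorNode, randomized_init, simulate

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def single_osc_config():
    node = OscillatorNode("1", 8.2e3, 500e-12)
    return ONNConfig(nodes=[node], pulse_duration=100e-6, record_stride=2, seed=0)


@pytest.fixture(scope="session")
def single_osc_waveform(single_osc_config):
    return simulate(single_osc_config)


@pytest.fixture(scope="session")
def antiphase_pair_waveform():
    nodes = [OscillatorNode("1", 8.2e3, 500e-12), OscillatorNode("2", 8.2e3, 500e-12)]
    cfg = ONNConfig(nodes=nodes, coupling={("1", "2"): 100e-12},
                    pulse_duration=150e-6, record_stride=4, seed=1)
    cfg.init_voltages = randomized_init(cfg, 1)
    return simulate(cfg)


@pytest.fixture(scope="session")
def triple_waveform():
    """Three slightly detuned, all-to-all coupled oscillators (locked)."""
    nodes = [
        OscillatorNode("1", 8.2e3, 500e-12),
        OscillatorNode("2", 8.2e3, 503e-12),
        OscillatorNode("3", 8.2e3, 506e-12),
    ]
    coup = {("1", "2"): 100e-12, ("1", "3"): 100e-12, ("2", "3"): 100e-12}
    cfg = ONNConfig(nodes=nodes, coupling=coup, pulse_duration=200e-6,
                    record_stride=4, seed=2)
    return simulate(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
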