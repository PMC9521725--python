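import numpy as np
import pytest

from deepmap import ChannelSpec, SimulationConfig, generate_recording


@pytest.fixture(scope="session")
def clean_case():
    """Noise-free 8xS1 + S2 recording with a mix of planted behaviours."""
    cfg = SimulationConfig(
        noise_sd=0.0,
        channels=[
            ChannelSpec("B1", base_ep_latency=40.0, planted_decrement=0.0),
            ChannelSpec("B2", base_ep_latency=40.0, planted_decrement=20.0),
            ChannelSpec("B3", base_ep_latency=45.0, planted_decrement=35.0),
            ChannelSpec("B4", base_ep_latency=50.0, planted_decrement=0.0,
                        s2_blocked=True),
        ],
        rng_seed=11,
    )
    recording, truth = generate_recording(cfg)
    return cfg, recording, truth


@pytest.fixture(scope="session")
def noisy_case():
    """Low-noise recording (SNR ~ 25 per sample on the EP peak)."""
    cfg = SimulationConfig(
        noise_sd=0.02,
        channels=[
            ChannelSpec("B1", base_ep_latency=40.0, planted_decrement=0.0),
            ChannelSpec("B2", base_ep_latency=40.0, planted_decrement=30.0),
        ],
        n_surface_leads=4,
        rng_seed=5,
    )
    recording, truth = generate_recording(cfg)
    return cfg, recording, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(20260921)
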