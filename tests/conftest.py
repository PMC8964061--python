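import numpy as np
import pytest

from lsmkit import NeuronParams, SyntheticConfig, build_model


@pytest.fixture
def params():
    """Default LIF constants: u_th=0.3, tau_m=9.4912 ms, dt=1 ms (decay 0.9)."""
    return NeuronParams()


@pytest.fixture
def tiny_model(params):
    """A small seeded LSM: 6 inputs, 5 liquid neurons, 3 readout classes."""
    return build_model(n_input=6, n_hidden=5, n_classes=3, params=params, seed=3)


@pytest.fixture
def tiny_synth_config():
    """A fast synthetic study: 8x8 grid, 60 ms streams, 3 samples per class."""
    return SyntheticConfig(
        n_classes=4,
        grid=(8, 8),
        duration_ms=60,
        base_rate=2.0,
        noise_rate=0.002,
        jitter_ms=0.5,
        samples_per_class=3,
        seed=5,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
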