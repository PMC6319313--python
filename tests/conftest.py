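import numpy as np
import pytest

from tuda.simulate import LinearStateSimSpec, simulate_linear_states


@pytest.fixture(scope="session")
def small_sequential():
    """Small five-state sequential dataset with moderate trial jitter."""
    spec = LinearStateSimSpec(
        n_trials=60,
        n_timepoints=300,
        sampling_rate=150.0,
        dwell_means=(0.3, 0.4, 0.5, 0.4, 0.4),
        dwell_dispersions=(0.02, 0.03, 0.04, 0.05, 0.05),
        seed=11,
    )
    data, truth = simulate_linear_states(spec)
    return spec, data, truth


@pytest.fixture(scope="session")
def synchronous_two_state():
    """Two perfectly synchronous regimes: change-point exactly at T/2."""
    spec = LinearStateSimSpec(
        n_trials=40,
        n_timepoints=80,
        sampling_rate=100.0,
        n_channels=10,
        n_states=2,
        n_stim_features=2,
        active_channels_per_state=4,
        noise_sd=0.05,
        dwell_means=(0.4, 0.4),
        dwell_dispersions=(0.0, 0.0),
        seed=7,
    )
    data, truth = simulate_linear_states(spec)
    return spec, data, truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
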