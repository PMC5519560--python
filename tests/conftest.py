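import numpy as np
import pytest

from npil.dynamics import CalciumDynamicsParams
from npil.responses import StimulusProtocol
from npil.synth import SimConfig, simulate_calcium_trace, simulate_spike_train


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def ogb_params():
    """8 Hz imaging of an OGB-like indicator (tau = 1 s)."""
    return CalciumDynamicsParams.from_frame_rate(8.0, 1.0)


@pytest.fixture
def small_sim_config():
    """Reduced-size FOV for fast integration tests."""
    return SimConfig(seed=7, n_cells=8, protocol=StimulusProtocol(repeats=8))


def make_noisy_trace(rng, ogb_params, *, n_frames=800, rate_hz=2.0,
                     amplitude=0.1, noise_frac=0.25):
    """Single-pixel OGB-like trace with ground truth spikes."""
    counts = simulate_spike_train(rate_hz, 8.0, n_frames, rng)
    trace, n_true = simulate_calcium_trace(
        counts, ogb_params, noise_frac * amplitude, rng, amplitude=amplitude
    )
    return trace, n_true
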