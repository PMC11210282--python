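import numpy as np
import pytest

import catrack as ct


@pytest.fixture(scope="session")
def small_config():
    """A quick 4-day population: paper-style session timings, 12 neurons."""
    return ct.SimulationConfig(
        n_neurons=12,
        n_days=4,
        frac_responsive_by_day=(0.25, 0.5, 0.4, 0.4),
        seed=42,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return ct.simulate_population(small_config)


@pytest.fixture(scope="session")
def small_normalized(small_dataset):
    return ct.normalize_recording(
        small_dataset.recording, small_dataset.timelines[0].basal_window_s
    )


def make_norm(z, fs=10.0, day_starts=(0,), ids=None):
    """Wrap a Z matrix directly into a NormalizedRecording for unit tests."""
    z = np.asarray(z, dtype=float)
    n = z.shape[0]
    ids = ids or [f"n{i}" for i in range(n)]
    return ct.NormalizedRecording(
        dff=np.zeros_like(z),
        z=z,
        fmean_day1=np.ones(n),
        fstd_day1=np.ones(n),
        sampling_rate_hz=fs,
        day_starts=list(day_starts),
        neuron_ids=ids,
    )
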