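"""Generator contracts: determinism, ground-truth accounting, trace model."""

import numpy as np
import pytest

import catrack as ct
from catrack.simulate import calcium_kernel, kernel_peak_time_s


def test_zero_responsive_fraction_gives_no_responsive_flags():
    cfg = ct.SimulationConfig(n_neurons=8, frac_responsive_by_day=(0, 0, 0, 0), seed=3)
    ds = ct.simulate_population(cfg)
    assert not ds.truth.responsive_flags.any()
    assert not (ds.truth.events["kind"] == "evoked").any()


def test_paper_scale_shapes():
    """79 tracked neurons, 4 concatenated daily sessions at 10 Hz."""
    cfg = ct.SimulationConfig(n_neurons=79, n_days=4, seed=0)
    ds = ct.simulate_population(cfg)
    n_per_day = int(cfg.session_duration_s * cfg.sampling_rate_hz)
    assert ds.recording.F.shape == (79, 4 * n_per_day)
    assert list(ds.recording.day_starts) == [i * n_per_day for i in range(4)]
    assert len(ds.timelines) == 4
    assert all(tl.n_trials == 8 for tl in ds.timelines)


def test_same_seed_bit_identical(small_config):
    a = ct.simulate_population(small_config)
    b = ct.simulate_population(small_config)
    assert np.array_equal(a.recording.F, b.recording.F)
    assert a.truth.events.equals(b.truth.events)
    assert np.array_equal(a.truth.responsive_flags, b.truth.responsive_flags)


def test_adding_neurons_preserves_existing_substreams():
    base = ct.SimulationConfig(n_neurons=5, seed=11)
    bigger = ct.SimulationConfig(n_neurons=9, seed=11)
    a = ct.simulate_population(base)
    b = ct.simulate_population(bigger)
    assert np.array_equal(a.recording.F, b.recording.F[:5])


def test_noiseless_eventless_trace_is_f0_times_shift():
    cfg = ct.SimulationConfig(
        n_neurons=6, noise_sd=0.0, amplitude_unit=1.0, spont_rate_hz=0.0,
        frac_responsive_by_day=(0, 0, 0, 0), frac_shifted_day2=1.0,
        frac_persist_elevated=1.0, basal_shift_day2_z=2.0, seed=5,
    )
    ds = ct.simulate_population(cfg)
    f0 = ds.truth.f0
    day1 = ds.recording.day_slice(1)
    day2 = ds.recording.day_slice(2)
    # day 1: exactly F0; day 2 onward: F0 + shift_z * amplitude-unit... but with
    # noise_sd = 0 the shift (defined in noise-SD units) vanishes too
    assert np.array_equal(ds.recording.F[:, day1], np.tile(f0[:, None], (1, day1.stop)))
    assert np.array_equal(ds.recording.F[:, day2], ds.recording.F[:, day1])


def test_shift_steps_up_at_injection_and_persists_per_truth():
    cfg = ct.SimulationConfig(
        n_neurons=40, noise_sd=1.0, spont_rate_hz=0.0,
        frac_responsive_by_day=(0, 0, 0, 0), frac_shifted_day2=0.5,
        frac_persist_elevated=0.5, basal_shift_day2_z=2.0, seed=9,
    )
    ds = ct.simulate_population(cfg)
    truth = ds.truth
    assert not truth.basal_shift_flags[:, 0].any()
    # persisting flags are a subset of day-2 shifted flags
    assert not (truth.basal_shift_flags[:, 2] & ~truth.basal_shift_flags[:, 1]).any()
    assert np.array_equal(truth.basal_shift_flags[:, 2], truth.basal_shift_flags[:, 3])
    # the day-2 basal mean moves up by ~2 noise SDs exactly for flagged neurons
    d1 = ds.recording.F[:, ds.recording.day_slice(1)][:, :3000].mean(axis=1)
    d2 = ds.recording.F[:, ds.recording.day_slice(2)][:, :3000].mean(axis=1)
    delta = d2 - d1
    assert np.all(delta[truth.basal_shift_flags[:, 1]] > 1.5)
    assert np.all(np.abs(delta[~truth.basal_shift_flags[:, 1]]) < 0.5)


def test_evoked_events_lock_to_stimuli_with_latency():
    cfg = ct.SimulationConfig(n_neurons=20, frac_responsive_by_day=(1, 1, 1, 1),
                              response_prob_per_trial=1.0, seed=2)
    ds = ct.simulate_population(cfg)
    ev = ds.truth.events.query("kind == 'evoked'")
    stim = np.array(ds.timelines[0].stimulus_times_s)
    lat = ev["time_s"].to_numpy() - stim[ev["trial"].to_numpy()]
    assert np.all((lat >= 0.1) & (lat <= 0.5))
    # every responsive neuron-day has one event per trial at prob 1
    assert len(ev) == 20 * 4 * 8


def test_evoked_count_is_binomial_mean():
    """Mean evoked events/neuron/day ~ Binomial(8, p) mean within 3 SE."""
    p = 0.7
    cfg = ct.SimulationConfig(n_neurons=150, n_days=1, frac_responsive_by_day=(1.0,),
                              response_prob_per_trial=p, spont_rate_hz=0.0, seed=6)
    ds = ct.simulate_population(cfg)
    counts = ds.truth.events.query("kind == 'evoked'").groupby("neuron_id").size()
    counts = counts.reindex(ds.truth.neuron_ids, fill_value=0)
    se = np.sqrt(8 * p * (1 - p) / 150)
    assert abs(counts.mean() - 8 * p) < 3 * se


def test_invalid_config_names_field():
    with pytest.raises(ct.ConfigError, match="kernel_decay_s"):
        ct.SimulationConfig(kernel_rise_s=2.0, kernel_decay_s=1.0).validate()
    with pytest.raises(ct.ConfigError, match="response_prob_per_trial"):
        ct.SimulationConfig(response_prob_per_trial=1.5).validate()
    with pytest.raises(ct.ConfigError, match="frac_responsive_by_day"):
        ct.SimulationConfig(frac_responsive_by_day=(0.5,)).validate()


def test_kernel_unit_peak_and_support():
    t = np.linspace(-1, 10, 5000)
    k = calcium_kernel(t, 0.1, 1.5)
    assert np.all(k[t < 0] == 0)
    assert k.max() == pytest.approx(1.0, abs=1e-4)
    t_pk = kernel_peak_time_s(0.1, 1.5)
    assert calcium_kernel(np.array([t_pk]), 0.1, 1.5)[0] == pytest.approx(1.0)
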