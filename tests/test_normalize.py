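"""Normalization identities, exclusions, and peristimulus extraction."""

import numpy as np
import pytest

import catrack as ct
from conftest import make_norm


def _rec(F, fs=10.0, day_starts=(0,)):
    F = np.atleast_2d(np.asarray(F, dtype=float))
    return ct.FluorescenceRecording(
        F=F, sampling_rate_hz=fs, day_starts=list(day_starts),
        neuron_ids=[f"n{i}" for i in range(F.shape[0])],
    )


def test_dff_of_constant_trace_is_zero():
    """Constant F = 100: dF/F is exactly 0 everywhere; Z is undefined."""
    rec = _rec(np.full(100, 100.0))
    norm = ct.compute_dff(rec, (0.0, 5.0))
    assert norm.n_neurons == 1
    assert np.all(norm.dff == 0.0)
    assert np.isnan(norm.z).all()
    # the Z pipeline proper excludes the constant neuron with a logged reason
    strict = ct.normalize_recording(rec, (0.0, 5.0))
    assert strict.n_neurons == 0
    assert "SD" in strict.excluded["n0"]


def test_dff_arithmetic_from_definition():
    """Baseline mean 100, sample 150 -> dF/F = 0.5."""
    F = np.full(100, 100.0) + np.tile([-1.0, 1.0], 50)  # mean 100, nonzero SD
    F[60] = 150.0
    norm = ct.normalize_recording(_rec(F), (0.0, 5.0))
    fm = norm.fmean_day1[0]
    assert fm == pytest.approx(100.0)
    assert norm.dff[0, 60] == pytest.approx((150.0 - fm) / fm)


def test_z_against_independent_mean_sd():
    """Baseline {1,2,3} (sample SD 1): a value of 4 maps to z = 2."""
    F = np.array([1.0, 2.0, 3.0, 4.0, 4.0, 4.0])
    norm = ct.normalize_recording(_rec(F, fs=1.0), (0.0, 3.0))
    assert norm.fmean_day1[0] == pytest.approx(2.0)
    assert norm.fstd_day1[0] == pytest.approx(1.0)
    assert norm.z[0, 3] == pytest.approx(2.0)


def test_baseline_window_z_mean_is_zero(small_dataset):
    tl = small_dataset.timelines[0]
    norm = ct.normalize_recording(small_dataset.recording, tl.basal_window_s)
    fs = norm.sampling_rate_hz
    sl = slice(int(tl.basal_window_s[0] * fs), int(tl.basal_window_s[1] * fs))
    assert np.all(np.abs(norm.z[:, sl].mean(axis=1)) < 1e-9)


def test_nonpositive_mean_and_zero_sd_are_excluded_with_reasons():
    F = np.vstack([
        np.zeros(100),                      # zero mean
        np.full(100, 5.0),                  # constant -> zero SD
        100.0 + np.tile([-1.0, 1.0], 50),   # fine
    ])
    norm = ct.normalize_recording(_rec(F), (0.0, 10.0))
    assert norm.n_neurons == 1
    assert norm.neuron_ids == ["n2"]
    assert "mean" in norm.excluded["n0"]
    assert "SD" in norm.excluded["n1"]


def test_z_is_affine_invariant_to_raw_scale(small_dataset):
    """Scaling F by c > 0 and shifting by d leaves Z unchanged."""
    rec = small_dataset.recording
    tl = small_dataset.timelines[0]
    scaled = ct.FluorescenceRecording(
        F=3.0 * rec.F + 50.0, sampling_rate_hz=rec.sampling_rate_hz,
        day_starts=list(rec.day_starts), neuron_ids=list(rec.neuron_ids),
    )
    a = ct.normalize_recording(rec, tl.basal_window_s)
    b = ct.normalize_recording(scaled, tl.basal_window_s)
    assert np.allclose(a.z, b.z, atol=1e-8)


def test_dff_and_z_are_monotone_transforms(small_normalized):
    """Per neuron, dF/F and Z order the timepoints identically."""
    n = small_normalized
    for i in range(n.n_neurons):
        assert np.array_equal(np.argsort(n.dff[i]), np.argsort(n.z[i]))


def test_peristim_constant_trace_re_references_to_zero():
    norm = make_norm(np.full((2, 1000), 3.7))
    tl = ct.SessionTimeline(day=1, basal_window_s=(0.0, 10.0), stimulus_times_s=[40.0])
    tens = ct.extract_peristim(norm, tl, re_reference=True)
    assert np.all(np.abs(tens.values) < 1e-12)


def test_peristim_ramp_closed_form():
    """For z(t) = t the re-referenced segment is t - (t0 - 10.05): the last
    sample (t0 + 19.9 s) equals 29.95 on the 10-Hz half-open grid."""
    t = np.arange(1000) / 10.0
    norm = make_norm(t[None, :])
    tl = ct.SessionTimeline(day=1, basal_window_s=(0.0, 10.0), stimulus_times_s=[50.0])
    tens = ct.extract_peristim(norm, tl, re_reference=True)
    assert tens.values.shape == (1, 1, 400)
    assert tens.values[0, 0, -1] == pytest.approx(29.95)
    assert tens.values[0, 0, 200] == pytest.approx(10.05)  # stimulus sample


def test_peristim_window_geometry_and_pre_mean(small_normalized, small_dataset):
    """8 trials, 400 samples at 10 Hz, pre-window mean 0 after re-referencing."""
    tl = small_dataset.timelines[1]
    tens = ct.extract_peristim(small_normalized, tl, re_reference=True)
    assert tens.values.shape[1:] == (8, 400)
    assert tens.time_axis_s[0] == -20.0 and tens.time_axis_s[-1] == pytest.approx(19.9)
    pre = tens.values[:, :, :200].mean(axis=2)
    assert np.all(np.abs(pre) < 1e-10)


def test_peristim_is_plain_slicing_before_rereference(small_normalized, small_dataset):
    tl = small_dataset.timelines[0]
    tens = ct.extract_peristim(small_normalized, tl, re_reference=False)
    i0 = small_normalized.sample_index(tl.day, tl.stimulus_times_s[3])
    assert np.array_equal(tens.values[:, 3, :], small_normalized.z[:, i0 - 200: i0 + 200])


def test_window_beyond_session_bounds_names_trial():
    norm = make_norm(np.zeros((1, 300)))  # 30 s of data
    tl = ct.SessionTimeline(day=1, basal_window_s=(0.0, 5.0), stimulus_times_s=[25.0])
    with pytest.raises(ValueError, match="trial 1"):
        ct.extract_peristim(norm, tl)
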