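"""Multi-day tracking: fractions, transitions, basal elevation, averages."""

import numpy as np
import pandas as pd
import pytest

import catrack as ct
from conftest import make_norm


def _calls(labels_by_day):
    """Build a calls frame from {day: [labels...]}."""
    rows = []
    for day, labels in labels_by_day.items():
        for i, lab in enumerate(labels):
            rows.append({"neuron_id": f"n{i}", "day": day, "label": lab})
    return pd.DataFrame(rows)


def test_all_increased_is_100_percent():
    calls = _calls({d: ["increased"] * 5 for d in (1, 2, 3, 4)})
    pct = ct.responsive_fractions(calls)
    assert pct["day1"] == 100.0
    assert pct["days3_4_pooled"] == 100.0


def test_none_increased_is_0_percent():
    calls = _calls({d: ["unresponsive"] * 5 for d in (1, 2, 3, 4)})
    pct = ct.responsive_fractions(calls)
    assert all(v == 0.0 for v in pct.values())


def test_pooled_either_vs_both():
    calls = _calls({
        1: ["unresponsive"] * 4,
        2: ["unresponsive"] * 4,
        3: ["increased", "increased", "unresponsive", "unresponsive"],
        4: ["increased", "unresponsive", "increased", "unresponsive"],
    })
    either = ct.responsive_fractions(calls, pooled_mode="either")
    both = ct.responsive_fractions(calls, pooled_mode="both")
    assert either["days3_4_pooled"] == 75.0
    assert both["days3_4_pooled"] == 25.0


def test_missing_labels_error_lists_neurons():
    calls = _calls({1: ["increased"] * 3, 2: ["increased"] * 3})
    calls = calls.drop(calls[(calls.neuron_id == "n1") & (calls.day == 2)].index)
    with pytest.raises(ValueError, match="n1"):
        ct.responsive_fractions(calls)


def test_transition_all_unresponsive_to_all_increased():
    calls = _calls({1: ["unresponsive"] * 6, 2: ["increased"] * 6})
    res = ct.transition_analysis(calls)
    assert res["unresponsive_to_responsive_pct"] == 100.0
    assert np.isnan(res["responsive_lost_pct"])  # empty source class
    m = res["matrices"]["day1_to_day2"]
    assert m["counts"].loc["unresponsive", "increased"] == 6
    assert m["counts"].to_numpy().sum() == 6


def test_identity_transition_has_zero_off_diagonal():
    labels = ["increased", "unresponsive", "decreased"] * 2
    calls = _calls({1: labels, 2: labels})
    m = ct.transition_analysis(calls)["matrices"]["day1_to_day2"]
    counts = m["counts"].to_numpy()
    assert np.all(counts - np.diag(np.diag(counts)) == 0)
    # row-normalized fractions: diagonal 1 where the source class is occupied
    fr = m["fractions"]
    for lab in ("increased", "unresponsive", "decreased"):
        assert fr.loc[lab, lab] == 1.0


def test_transition_row_sums_match_source_counts(small_dataset, small_normalized):
    cfg = ct.PipelineConfig(simulation=small_dataset.config)
    res = ct.analyze_recording(small_dataset.recording, small_dataset.timelines, cfg)
    trans = res.summary.transitions
    pivot = res.calls.pivot(index="neuron_id", columns="day", values="label")
    for name, m in trans["matrices"].items():
        day_a = int(name.split("_to_day")[0].removeprefix("day"))
        row_sums = m["counts"].sum(axis=1)
        for lab in ("increased", "unresponsive", "decreased"):
            assert row_sums[lab] == (pivot[day_a] == lab).sum()
        assert m["counts"].to_numpy().sum() == small_normalized.n_neurons


def test_reordering_neurons_leaves_outputs_unchanged():
    labels1 = ["increased", "unresponsive", "decreased", "increased"]
    labels2 = ["unresponsive", "increased", "increased", "decreased"]
    calls = _calls({1: labels1, 2: labels2})
    shuffled = calls.sample(frac=1.0, random_state=0).reset_index(drop=True)
    a = ct.transition_analysis(calls)
    b = ct.transition_analysis(shuffled)
    assert a["unresponsive_to_responsive_pct"] == b["unresponsive_to_responsive_pct"]
    assert a["matrices"]["day1_to_day2"]["counts"].equals(
        b["matrices"]["day1_to_day2"]["counts"])


def _norm_with_day_means(day_means, n_per_day=600, fs=10.0):
    """Neurons x days constant Z levels, 60-s days with a 30-s basal window."""
    day_means = np.asarray(day_means, dtype=float)
    n, d = day_means.shape
    z = np.repeat(day_means, n_per_day, axis=1)
    starts = [i * n_per_day for i in range(d)]
    return make_norm(z, fs=fs, day_starts=starts), [
        ct.SessionTimeline(day=i + 1, basal_window_s=(0.0, 30.0),
                           stimulus_times_s=[50.0])
        for i in range(d)
    ]


def test_basal_elevation_null_case():
    norm, tls = _norm_with_day_means(np.zeros((5, 4)))
    res = ct.basal_elevation(norm, tls, theta_z=0.5)
    assert not res["elevated_flags"].any()
    assert np.isnan(res["elevated_persist_pct"])  # nobody elevated on day 2


def test_basal_elevation_saturating_case():
    """All neurons shifted +3 from day 2 onward: elevated everywhere, 100%."""
    means = np.zeros((6, 4))
    means[:, 1:] = 3.0
    norm, tls = _norm_with_day_means(means)
    res = ct.basal_elevation(norm, tls, theta_z=0.5)
    assert np.all(res["elevated_flags"][:, 1:])
    assert res["elevated_persist_pct"] == 100.0
    assert list(res["elevated_pct_by_day"]) == [0.0, 100.0, 100.0, 100.0]


def test_basal_elevation_monotone_in_threshold():
    rng = np.random.default_rng(4)
    means = np.zeros((30, 4))
    means[:, 1:] += rng.uniform(0, 2, (30, 1))
    norm, tls = _norm_with_day_means(means)
    prev = None
    for theta in (0.25, 0.5, 1.0, 1.5, 3.0):
        n_elev = ct.basal_elevation(norm, tls, theta_z=theta)["elevated_flags"].sum()
        if prev is not None:
            assert n_elev <= prev
        prev = n_elev
    assert ct.basal_elevation(norm, tls, theta_z=100.0)["elevated_flags"].sum() == 0


def test_basal_elevation_rejects_bad_threshold():
    norm, tls = _norm_with_day_means(np.zeros((2, 4)))
    with pytest.raises(ValueError):
        ct.basal_elevation(norm, tls, theta_z=0.0)


def test_population_average_constructed_shift():
    """Uniform +1 shift on days 2-4 gives day means {0, 1, 1, 1}."""
    means = np.zeros((8, 4))
    means[:, 1:] = 1.0
    norm, tls = _norm_with_day_means(means)
    pop = ct.population_average(norm, tls)
    assert np.allclose(pop["mean_basal_z"], [0.0, 1.0, 1.0, 1.0])
    assert np.allclose(pop["sem"], 0.0)


def test_population_day2_increase_is_significant_under_generator():
    """The simulated injection raises day-2 basal Z; the package's own
    Wilcoxon on per-neuron (day2, day1) pairs confirms it at p < 0.05."""
    cfg = ct.SimulationConfig(n_neurons=10, basal_shift_day2_z=2.0,
                              frac_shifted_day2=1.0, seed=13)
    ds = ct.simulate_population(cfg)
    norm = ct.normalize_recording(ds.recording, ds.timelines[0].basal_window_s)
    bm = ct.basal_mean_z(norm, ds.timelines)
    res = ct.wilcoxon_signed_rank_exact(bm[:, 1], bm[:, 0])
    assert res.direction == "increase"
    assert res.p_two_sided < 0.05
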