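"""Synthetic multi-day GCaMP fluorescence generator with known ground truth.

Each neuron's raw trace follows

    F(t) = F0 * (1 + shift(t)) + sum_events A * k(t - t_event) + eps(t)

with ``k`` a unit-peak double-exponential calcium kernel, ``eps`` i.i.d.
Gaussian noise, and ``shift`` a sustained step that switches on at the day-2
injection for a subset of neurons and persists on days 3-4 only for a
persisting fraction.  Event amplitudes ``A`` are expressed in noise-SD units
so that, after day-1-baseline Z-scoring, an amplitude of 3 peaks near z = 3.

Randomness uses one master seed with a per-neuron ``SeedSequence`` substream,
so enlarging the population leaves existing neurons' traces unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

from .config import SimulationConfig
from .session import FluorescenceRecording, SessionTimeline

NTG_DAY = 2  # injection day on which the sustained basal shift switches on


def calcium_kernel(t_s: np.ndarray, rise_s: float, decay_s: float) -> np.ndarray:
    """Unit-peak double-exponential kernel (1 - e^(-t/rise)) * e^(-t/decay).

    Zero for t < 0.  With ``rise_s == 0`` the kernel is a pure exponential
    decay peaking at 1 for t = 0.
    """
    t = np.asarray(t_s, dtype=float)
    out = np.zeros_like(t)
    pos = t >= 0
    if rise_s == 0.0:
        out[pos] = np.exp(-t[pos] / decay_s)
        return out
    raw = (1.0 - np.exp(-t[pos] / rise_s)) * np.exp(-t[pos] / decay_s)
    t_peak = rise_s * np.log1p(decay_s / rise_s)
    peak = (1.0 - np.exp(-t_peak / rise_s)) * np.exp(-t_peak / decay_s)
    out[pos] = raw / peak
    return out


def kernel_peak_time_s(rise_s: float, decay_s: float) -> float:
    """Time at which the continuous kernel attains its unit peak."""
    if rise_s == 0.0:
        return 0.0
    return rise_s * np.log1p(decay_s / rise_s)


@dataclass
class GroundTruth:
    """Generator-side record of what each synthetic neuron really did.

    ``events`` has one row per calcium event with columns ``neuron_id``,
    ``day``, ``kind`` (evoked/spont), ``time_s`` (day-relative onset),
    ``trial`` (evoked only, else -1) and ``amplitude_z``.
    """

    responsive_flags: np.ndarray  # (n_neurons, n_days) bool
    basal_shift_flags: np.ndarray  # (n_neurons, n_days) bool
    events: pd.DataFrame
    f0: np.ndarray  # (n_neurons,) baseline fluorescence
    neuron_ids: List[str]

    def to_dict(self) -> dict:
        return {
            "neuron_ids": self.neuron_ids,
            "responsive_flags": self.responsive_flags.astype(int).tolist(),
            "basal_shift_flags": self.basal_shift_flags.astype(int).tolist(),
            "f0": self.f0.tolist(),
            "events": self.events.to_dict(orient="list"),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(
            responsive_flags=np.asarray(d["responsive_flags"], dtype=bool),
            basal_shift_flags=np.asarray(d["basal_shift_flags"], dtype=bool),
            events=pd.DataFrame(d["events"]),
            f0=np.asarray(d["f0"], dtype=float),
            neuron_ids=list(d["neuron_ids"]),
        )


@dataclass
class SyntheticDataset:
    """Bundle of a synthetic recording, its timelines, and the ground truth."""

    recording: FluorescenceRecording
    timelines: List[SessionTimeline]
    truth: GroundTruth
    config: SimulationConfig


def make_timelines(config: SimulationConfig) -> List[SessionTimeline]:
    """Session timelines implied by the config: basal window then n_trials
    stimuli; the injection (vehicle day 1, NTG day 2) at session start."""
    timelines = []
    for day in range(1, config.n_days + 1):
        stim = [
            config.basal_duration_s + config.first_stim_offset_s + k * config.inter_trial_s
            for k in range(config.n_trials)
        ]
        timelines.append(
            SessionTimeline(
                day=day,
                basal_window_s=(0.0, config.basal_duration_s),
                stimulus_times_s=stim,
                injection_time_s=0.0 if day in (1, NTG_DAY) else None,
            )
        )
    return timelines


def simulate_population(config: SimulationConfig) -> SyntheticDataset:
    """Generate a deterministic multi-day population dataset.

    Per neuron and day, responsiveness is an independent Bernoulli draw with
    that day's ``frac_responsive_by_day`` entry; responsive neurons receive an
    evoked event per stimulus with probability ``response_prob_per_trial`` at
    a latency drawn uniformly from [0.1, 0.5] s.  Spontaneous events arrive as
    a Poisson process throughout every session.
    """
    config.validate()
    fs = config.sampling_rate_hz
    n_per_day = int(round(config.session_duration_s * fs))
    n_total = n_per_day * config.n_days
    day_starts = [d * n_per_day for d in range(config.n_days)]
    timelines = make_timelines(config)
    amp_unit = config.resolved_amplitude_unit
    t_day = np.arange(n_per_day) / fs

    master = np.random.SeedSequence(config.seed)
    children = master.spawn(max(config.n_neurons, 1))

    F = np.empty((config.n_neurons, n_total), dtype=float)
    responsive = np.zeros((config.n_neurons, config.n_days), dtype=bool)
    shifted = np.zeros((config.n_neurons, config.n_days), dtype=bool)
    f0_arr = np.empty(config.n_neurons, dtype=float)
    neuron_ids = [f"n{idx:04d}" for idx in range(config.n_neurons)]
    event_rows: List[Tuple] = []

    for idx in range(config.n_neurons):
        rng = np.random.default_rng(children[idx])
        f0 = max(rng.normal(config.f0_mean, config.f0_sd), 1e-6)
        f0_arr[idx] = f0

        resp = rng.random(config.n_days) < np.asarray(config.frac_responsive_by_day)
        responsive[idx] = resp
        is_shifted = rng.random() < config.frac_shifted_day2
        persists = rng.random() < config.frac_persist_elevated
        for d in range(NTG_DAY - 1, config.n_days):
            if d == NTG_DAY - 1:
                shifted[idx, d] = is_shifted
            else:
                shifted[idx, d] = is_shifted and persists

        trace = np.empty(n_total, dtype=float)
        for d in range(config.n_days):
            tl = timelines[d]
            # sustained multiplicative shift calibrated so the additive effect
            # equals basal_shift_day2_z noise-SDs of fluorescence
            shift_frac = (
                config.basal_shift_day2_z * config.noise_sd / f0 if shifted[idx, d] else 0.0
            )
            day_trace = np.full(n_per_day, f0)
            if shift_frac:
                onset = tl.injection_time_s if tl.injection_time_s is not None else 0.0
                day_trace[t_day >= onset] *= 1.0 + shift_frac

            # spontaneous Poisson events
            n_spont = rng.poisson(config.spont_rate_hz * config.session_duration_s)
            spont_times = np.sort(rng.uniform(0.0, config.session_duration_s, n_spont))
            for ts in spont_times:
                amp = config.spont_amplitude_z
                day_trace += amp * amp_unit * calcium_kernel(
                    t_day - ts, config.kernel_rise_s, config.kernel_decay_s
                )
                event_rows.append((neuron_ids[idx], d + 1, "spont", float(ts), -1, amp))

            # evoked events locked to stimuli
            trial_hit = rng.random(config.n_trials) < config.response_prob_per_trial
            latencies = rng.uniform(0.1, 0.5, config.n_trials)
            if resp[d]:
                for k, t_stim in enumerate(tl.stimulus_times_s):
                    if not trial_hit[k]:
                        continue
                    ts = t_stim + latencies[k]
                    amp = config.evoked_amplitude_z
                    day_trace += amp * amp_unit * calcium_kernel(
                        t_day - ts, config.kernel_rise_s, config.kernel_decay_s
                    )
                    event_rows.append((neuron_ids[idx], d + 1, "evoked", float(ts), k, amp))

            trace[day_starts[d]: day_starts[d] + n_per_day] = day_trace

        if config.noise_sd > 0:
            trace = trace + rng.normal(0.0, config.noise_sd, n_total)
        F[idx] = trace

    events = pd.DataFrame(
        event_rows,
        columns=["neuron_id", "day", "kind", "time_s", "trial", "amplitude_z"],
    )
    truth = GroundTruth(
        responsive_flags=responsive,
        basal_shift_flags=shifted,
        events=events,
        f0=f0_arr,
        neuron_ids=neuron_ids,
    )
    recording = FluorescenceRecording(
        F=F, sampling_rate_hz=fs, day_starts=day_starts, neuron_ids=neuron_ids
    )
    return SyntheticDataset(recording=recording, timelines=timelines, truth=truth,
                            config=config)
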