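"""Calcium-transient detection and per-session summaries.

Detection is a threshold-hysteresis rule on the Z-scored trace: an event
opens when the trace stays at or above ``threshold_z`` for at least
``min_duration_s`` of consecutive samples, extends in both directions while
the trace remains at or above ``release_fraction * threshold_z``, and events
separated by less than ``merge_gap_s`` are merged.  Amplitude is the maximum
Z inside the event; AUC is the left Riemann sum of Z over the event samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .config import DetectionParams


@dataclass
class TransientEvent:
    """One detected calcium transient on a Z-scored trace."""

    neuron_id: str
    onset_s: float
    offset_s: float
    peak_time_s: float
    amplitude_z: float
    auc_z_s: float
    day: int = 0


def _runs(mask: np.ndarray) -> List[tuple]:
    """(start, stop) index pairs of maximal True runs; stop is exclusive."""
    if not mask.any():
        return []
    padded = np.diff(np.concatenate(([0], mask.view(np.int8), [0])))
    starts = np.flatnonzero(padded == 1)
    stops = np.flatnonzero(padded == -1)
    return list(zip(starts, stops))


def detect_transients(
    z_trace: np.ndarray,
    sampling_rate_hz: float,
    params: Optional[DetectionParams] = None,
    neuron_id: str = "",
    day: int = 0,
    t_offset_s: float = 0.0,
) -> List[TransientEvent]:
    """Detect transients on one neuron's Z trace.

    ``t_offset_s`` shifts reported times (e.g. to day-relative seconds when
    passing a day's slice of a concatenated trace).  Non-finite samples raise
    a ValueError naming the first offending index.
    """
    params = (params or DetectionParams()).validate()
    z = np.asarray(z_trace, dtype=float)
    bad = ~np.isfinite(z)
    if bad.any():
        raise ValueError(f"non-finite sample at index {int(np.flatnonzero(bad)[0])}")

    fs = sampling_rate_hz
    dt = 1.0 / fs
    min_samples = max(int(round(params.min_duration_s * fs)), 1)
    merge_samples = int(round(params.merge_gap_s * fs))
    release = params.release_fraction * params.threshold_z

    above_rel = z >= release
    intervals = []
    for start, stop in _runs(z >= params.threshold_z):
        if stop - start < min_samples:
            continue
        # hysteresis: extend while the trace stays above the release level
        while start > 0 and above_rel[start - 1]:
            start -= 1
        while stop < z.size and above_rel[stop]:
            stop += 1
        intervals.append([start, stop])

    merged: List[list] = []
    for start, stop in intervals:
        if merged and start - merged[-1][1] < merge_samples:
            merged[-1][1] = max(merged[-1][1], stop)
        elif merged and start < merged[-1][1]:  # hysteresis overlap
            merged[-1][1] = max(merged[-1][1], stop)
        else:
            merged.append([start, stop])

    events = []
    for start, stop in merged:
        seg = z[start:stop]
        peak_rel = int(np.argmax(seg))
        events.append(
            TransientEvent(
                neuron_id=neuron_id,
                onset_s=t_offset_s + start * dt,
                offset_s=t_offset_s + (stop - 1) * dt,
                peak_time_s=t_offset_s + (start + peak_rel) * dt,
                amplitude_z=float(seg[peak_rel]),
                auc_z_s=float(seg.sum() * dt),
                day=day,
            )
        )
    return events


def events_to_frame(events: Sequence[TransientEvent]) -> pd.DataFrame:
    cols = ["neuron_id", "day", "onset_s", "offset_s", "peak_time_s",
            "amplitude_z", "auc_z_s"]
    if not events:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame([{c: getattr(e, c) for c in cols} for e in events])


def transient_summary(
    events: pd.DataFrame | Sequence[TransientEvent],
    neuron_ids: Sequence[str],
    days: Sequence[int],
) -> pd.DataFrame:
    """Count, mean amplitude, and total AUC per neuron per day.

    Every requested neuron x day cell appears in the output; cells with no
    events get count 0 and NaN amplitude (undefined, never coerced to a
    number).
    """
    if not isinstance(events, pd.DataFrame):
        events = events_to_frame(events)
    index = pd.MultiIndex.from_product([neuron_ids, days], names=["neuron_id", "day"])
    out = pd.DataFrame(index=index, columns=["count", "mean_amplitude_z", "total_auc_z_s"],
                       dtype=float)
    out["count"] = 0.0
    out["total_auc_z_s"] = 0.0
    if len(events):
        g = events.groupby(["neuron_id", "day"])
        agg = g.agg(count=("amplitude_z", "size"),
                    mean_amplitude_z=("amplitude_z", "mean"),
                    total_auc_z_s=("auc_z_s", "sum"))
        out.loc[agg.index, "count"] = agg["count"].astype(float)
        out.loc[agg.index, "mean_amplitude_z"] = agg["mean_amplitude_z"]
        out.loc[agg.index, "total_auc_z_s"] = agg["total_auc_z_s"]
    out["count"] = out["count"].astype(int)
    return out.reset_index()
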