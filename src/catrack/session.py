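"""Data containers for multi-day fluorescence recordings and session timelines.

All times inside a :class:`SessionTimeline` are seconds relative to the start
of that day's session; sample indices into the concatenated recording are
obtained through :meth:`FluorescenceRecording.day_slice` and
:meth:`FluorescenceRecording.sample_index`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd


@dataclass
class SessionTimeline:
    """Timeline of one daily session.

    Parameters
    ----------
    day:
        1-based day number.
    injection_time_s:
        Time of the i.p. injection relative to session start, or ``None``
        when the session had no injection (days 3-4).
    basal_window_s:
        Half-open ``[start, end)`` window of unstimulated basal activity.
    stimulus_times_s:
        Onset times of the von Frey filament applications.
    """

    day: int
    basal_window_s: Tuple[float, float]
    stimulus_times_s: Sequence[float]
    injection_time_s: Optional[float] = None

    def __post_init__(self) -> None:
        lo, hi = self.basal_window_s
        if not hi > lo:
            raise ValueError(f"day {self.day}: empty basal window [{lo}, {hi})")
        st = list(self.stimulus_times_s)
        if any(b <= a for a, b in zip(st, st[1:])):
            raise ValueError(f"day {self.day}: stimulus times must be strictly increasing")
        if st and st[0] < hi:
            raise ValueError(f"day {self.day}: basal window must precede first stimulus")

    @property
    def n_trials(self) -> int:
        return len(self.stimulus_times_s)

    def to_dict(self) -> dict:
        return {
            "day": self.day,
            "basal_window_s": list(self.basal_window_s),
            "stimulus_times_s": [float(t) for t in self.stimulus_times_s],
            "injection_time_s": self.injection_time_s,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SessionTimeline":
        return cls(
            day=int(d["day"]),
            basal_window_s=tuple(d["basal_window_s"]),
            stimulus_times_s=list(d["stimulus_times_s"]),
            injection_time_s=d.get("injection_time_s"),
        )


@dataclass
class FluorescenceRecording:
    """Raw fluorescence, neurons x timepoints, concatenated across days.

    ``day_starts`` holds the sample index at which each day's session begins;
    the last day runs to the end of the trace.
    """

    F: np.ndarray
    sampling_rate_hz: float
    day_starts: Sequence[int]
    neuron_ids: Sequence[str]

    def __post_init__(self) -> None:
        self.F = np.asarray(self.F, dtype=float)
        if self.F.ndim != 2:
            raise ValueError("F must be a 2-D neurons x timepoints array")
        ds = list(self.day_starts)
        if ds[0] != 0 or any(b <= a for a, b in zip(ds, ds[1:])):
            raise ValueError("day_starts must begin at 0 and increase strictly")
        if ds[-1] >= self.F.shape[1]:
            raise ValueError("day_starts exceed trace length")
        ids = list(self.neuron_ids)
        if len(ids) != self.F.shape[0]:
            raise ValueError("neuron_ids length must match number of rows")
        if len(set(ids)) != len(ids):
            raise ValueError("neuron_ids must be unique")

    @property
    def n_neurons(self) -> int:
        return self.F.shape[0]

    @property
    def n_days(self) -> int:
        return len(list(self.day_starts))

    def day_slice(self, day: int) -> slice:
        """Sample slice of the given 1-based day."""
        ds = list(self.day_starts)
        if not 1 <= day <= len(ds):
            raise ValueError(f"day {day} outside 1..{len(ds)}")
        start = ds[day - 1]
        end = ds[day] if day < len(ds) else self.F.shape[1]
        return slice(start, end)

    def sample_index(self, day: int, t_s: float) -> int:
        """Concatenated sample index of a day-relative time."""
        return list(self.day_starts)[day - 1] + int(round(t_s * self.sampling_rate_hz))

    # -- I/O ---------------------------------------------------------------

    def to_csv(self, path: str | Path) -> None:
        """Write one row per neuron; first column ``neuron_id``, then samples."""
        df = pd.DataFrame(self.F, index=pd.Index(list(self.neuron_ids), name="neuron_id"))
        df.columns = [f"t{i}" for i in range(self.F.shape[1])]
        df.to_csv(path)

    @classmethod
    def from_csv(
        cls,
        path: str | Path,
        sampling_rate_hz: float,
        day_starts: Sequence[int],
    ) -> "FluorescenceRecording":
        df = pd.read_csv(path, index_col="neuron_id")
        return cls(
            F=df.to_numpy(dtype=float),
            sampling_rate_hz=sampling_rate_hz,
            day_starts=day_starts,
            neuron_ids=[str(i) for i in df.index],
        )


def save_timelines(
    timelines: Sequence[SessionTimeline],
    path: str | Path,
    sampling_rate_hz: float,
    day_starts: Sequence[int],
) -> None:
    """Write session timelines plus recording geometry as a JSON sidecar."""
    payload = {
        "sampling_rate_hz": sampling_rate_hz,
        "day_starts": [int(i) for i in day_starts],
        "timelines": [tl.to_dict() for tl in timelines],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)


def load_timelines(path: str | Path) -> Tuple[List[SessionTimeline], float, List[int]]:
    """Inverse of :func:`save_timelines`; returns (timelines, fs, day_starts)."""
    with open(path) as fh:
        payload = json.load(fh)
    timelines = [SessionTimeline.from_dict(d) for d in payload["timelines"]]
    return timelines, float(payload["sampling_rate_hz"]), [int(i) for i in payload["day_starts"]]


@dataclass
class NormalizedRecording:
    """DeltaF/F and Z-scored traces anchored to the day-1 basal window.

    ``fmean_day1``/``fstd_day1`` are the per-neuron mean and SD of raw
    fluorescence over the day-1 basal window, applied to all days.  Neurons
    failing normalization preconditions (non-positive baseline mean, zero
    baseline SD) are dropped from every array and listed in ``excluded``.
    """

    dff: np.ndarray
    z: np.ndarray
    fmean_day1: np.ndarray
    fstd_day1: np.ndarray
    sampling_rate_hz: float
    day_starts: Sequence[int]
    neuron_ids: Sequence[str]
    excluded: Dict[str, str] = field(default_factory=dict)

    @property
    def n_neurons(self) -> int:
        return self.z.shape[0]

    @property
    def n_days(self) -> int:
        return len(list(self.day_starts))

    def day_slice(self, day: int) -> slice:
        ds = list(self.day_starts)
        if not 1 <= day <= len(ds):
            raise ValueError(f"day {day} outside 1..{len(ds)}")
        start = ds[day - 1]
        end = ds[day] if day < len(ds) else self.z.shape[1]
        return slice(start, end)

    def sample_index(self, day: int, t_s: float) -> int:
        return list(self.day_starts)[day - 1] + int(round(t_s * self.sampling_rate_hz))


@dataclass
class PeristimTensor:
    """Peristimulus segments, neurons x trials x window samples.

    ``time_axis_s`` holds seconds relative to the stimulus; the window is
    half-open, so at 10 Hz a [-20, 20) window has exactly 400 samples and the
    stimulus sample sits at t = 0.  When ``re_referenced`` is true each
    trial's mean over the pre-stimulus half [-20, 0) has been subtracted from
    the whole segment.
    """

    values: np.ndarray
    time_axis_s: np.ndarray
    sampling_rate_hz: float
    day: int
    neuron_ids: Sequence[str]
    re_referenced: bool

    @property
    def n_trials(self) -> int:
        return self.values.shape[1]
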