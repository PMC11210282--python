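"""Trace normalization anchored to the day-1 basal window.

Two dimensionless representations of the raw fluorescence F are computed,
both referenced to the day-1 basal period only and applied to all days of the
concatenated recording:

    dF/F = (F - Fmean) / Fmean
    Z    = (F - Fmean) / Fstd

where Fmean and Fstd are the mean and sample SD (ddof=1 by default) of F over
the day-1 basal window.  Neurons with a non-positive baseline mean or zero
baseline SD cannot be normalized; they are dropped from the output and
recorded, with a reason, in ``NormalizedRecording.excluded``.
"""

from __future__ import annotations

import logging
from typing import Sequence, Tuple

import numpy as np

from .session import (
    FluorescenceRecording,
    NormalizedRecording,
    PeristimTensor,
    SessionTimeline,
)

logger = logging.getLogger("catrack")


def _baseline_slice(rec: FluorescenceRecording, baseline_window_s: Tuple[float, float]) -> slice:
    lo, hi = baseline_window_s
    if not hi > lo:
        raise ValueError(f"empty baseline window [{lo}, {hi})")
    i0 = rec.sample_index(1, lo)
    i1 = rec.sample_index(1, hi)
    day1 = rec.day_slice(1)
    if i0 < day1.start or i1 > day1.stop:
        raise ValueError("baseline window must lie within day 1")
    if i1 - i0 < 2:
        raise ValueError("baseline window must contain at least 2 samples")
    return slice(i0, i1)


def normalize_recording(
    rec: FluorescenceRecording,
    baseline_window_s: Tuple[float, float],
    ddof: int = 1,
    require: str = "both",
) -> NormalizedRecording:
    """Compute dF/F and Z for every neuron from the day-1 basal window.

    Parameters
    ----------
    rec:
        Raw concatenated recording.
    baseline_window_s:
        Half-open [start, end) window in day-1 session seconds.
    ddof:
        Delta degrees of freedom for the baseline SD (1 = sample SD).
    require:
        ``"both"`` (default) excludes neurons that fail either normalization;
        ``"dff"`` keeps zero-SD neurons (their Z rows are NaN), excluding
        only non-positive baseline means.
    """
    if require not in ("both", "dff"):
        raise ValueError("require must be 'both' or 'dff'")
    sl = _baseline_slice(rec, baseline_window_s)
    base = rec.F[:, sl]
    fmean = base.mean(axis=1)
    fstd = base.std(axis=1, ddof=ddof)

    excluded = {}
    keep = np.ones(rec.n_neurons, dtype=bool)
    ids = list(rec.neuron_ids)
    for i in range(rec.n_neurons):
        if fmean[i] <= 0:
            excluded[ids[i]] = f"non-positive baseline mean ({fmean[i]:.6g})"
            keep[i] = False
        elif fstd[i] == 0 and require == "both":
            excluded[ids[i]] = "zero baseline SD (constant baseline)"
            keep[i] = False
    for nid, reason in excluded.items():
        logger.warning("excluding neuron %s: %s", nid, reason)

    Fk = rec.F[keep]
    fmean_k = fmean[keep]
    fstd_k = fstd[keep]
    dff = (Fk - fmean_k[:, None]) / fmean_k[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(
            fstd_k[:, None] > 0,
            (Fk - fmean_k[:, None]) / np.where(fstd_k[:, None] > 0, fstd_k[:, None], 1.0),
            np.nan,
        )
    return NormalizedRecording(
        dff=dff,
        z=z,
        fmean_day1=fmean_k,
        fstd_day1=fstd_k,
        sampling_rate_hz=rec.sampling_rate_hz,
        day_starts=list(rec.day_starts),
        neuron_ids=[i for i, k in zip(ids, keep) if k],
        excluded=excluded,
    )


def compute_dff(
    rec: FluorescenceRecording, baseline_window_s: Tuple[float, float]
) -> NormalizedRecording:
    """dF/F relative to the day-1 basal mean.

    Only a non-positive baseline mean excludes a neuron here; a constant
    trace yields dF/F identically 0 (and a NaN Z row).
    """
    return normalize_recording(rec, baseline_window_s, require="dff")


def compute_z(
    rec: FluorescenceRecording,
    baseline_window_s: Tuple[float, float],
    ddof: int = 1,
) -> NormalizedRecording:
    """Day-1-baseline Z-score applied to the whole concatenated trace."""
    return normalize_recording(rec, baseline_window_s, ddof=ddof)


def extract_peristim(
    norm: NormalizedRecording,
    timeline: SessionTimeline,
    window_s: Tuple[float, float] = (-20.0, 20.0),
    re_reference: bool = True,
) -> PeristimTensor:
    """Cut peristimulus Z segments for every neuron x trial of one day.

    The window is half-open [lo, hi): at 10 Hz a [-20, 20) window yields 400
    samples with the stimulus sample at relative index ``-lo * fs``.  With
    ``re_reference`` each trial's mean over the pre-stimulus half [lo, 0) is
    subtracted from the whole segment, so trials are comparable across days
    despite different basal activity levels.
    """
    lo, hi = window_s
    if not (lo < 0 < hi):
        raise ValueError(f"window [{lo}, {hi}) must straddle the stimulus at 0")
    fs = norm.sampling_rate_hz
    n_lo = int(round(-lo * fs))
    n_hi = int(round(hi * fs))
    day = norm.day_slice(timeline.day)

    segs = np.empty((norm.n_neurons, timeline.n_trials, n_lo + n_hi), dtype=float)
    for k, t_stim in enumerate(timeline.stimulus_times_s):
        i0 = norm.sample_index(timeline.day, t_stim)
        if i0 - n_lo < day.start or i0 + n_hi > day.stop:
            raise ValueError(
                f"trial {k + 1} at t={t_stim:g}s: window [{lo}, {hi})s exceeds "
                f"day {timeline.day} session bounds"
            )
        segs[:, k, :] = norm.z[:, i0 - n_lo: i0 + n_hi]

    if re_reference:
        pre_mean = segs[:, :, :n_lo].mean(axis=2, keepdims=True)
        segs = segs - pre_mean

    time_axis = (np.arange(-n_lo, n_hi)) / fs
    return PeristimTensor(
        values=segs,
        time_axis_s=time_axis,
        sampling_rate_hz=fs,
        day=timeline.day,
        neuron_ids=list(norm.neuron_ids),
        re_referenced=re_reference,
    )
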