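"""Multi-day tracking: responder fractions, label transitions, basal activity.

These summaries operate on a tracked population: the same neurons, with the
same ids, labelled on every day.  Fractions with empty denominators are
reported as NaN (undefined), never coerced to 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .responders import LABELS
from .session import NormalizedRecording, SessionTimeline


def _label_matrix(calls: pd.DataFrame) -> pd.DataFrame:
    """Pivot calls into a neurons x days label table, validating coverage."""
    pivot = calls.pivot(index="neuron_id", columns="day", values="label")
    if pivot.isna().any().any():
        missing = pivot[pivot.isna().any(axis=1)].index.tolist()
        raise ValueError(f"neurons missing labels on some days: {missing}")
    return pivot


def responsive_fractions(
    calls: pd.DataFrame,
    pooled_days: Tuple[int, int] = (3, 4),
    pooled_mode: str = "either",
) -> Dict[str, float]:
    """Percentage of neurons labelled increased per day, plus a pooled value.

    The pooled entry counts a neuron responsive on ``pooled_days`` if it is
    increased on either day (default) or on both (``pooled_mode='both'``).
    """
    pivot = _label_matrix(calls)
    out = {}
    for day in sorted(pivot.columns):
        out[f"day{day}"] = 100.0 * (pivot[day] == "increased").mean()
    present = [d for d in pooled_days if d in pivot.columns]
    if len(present) == len(pooled_days):
        flags = pivot[list(pooled_days)] == "increased"
        pooled = flags.any(axis=1) if pooled_mode == "either" else flags.all(axis=1)
        out[f"days{pooled_days[0]}_{pooled_days[1]}_pooled"] = 100.0 * pooled.mean()
    return out


def transition_analysis(calls: pd.DataFrame) -> Dict[str, object]:
    """Label transition matrices between consecutive days plus headlines.

    Returns counts and row-normalized fractions for each consecutive day
    pair, and two headline quantities for the day-1 -> day-2 transition: the
    fraction of initially unresponsive neurons that become increased, and the
    fraction of initially increased neurons that are no longer increased.
    """
    pivot = _label_matrix(calls)
    days = sorted(pivot.columns)
    if len(days) < 2:
        raise ValueError("transition analysis needs labels on at least 2 days")

    matrices = {}
    for a, b in zip(days, days[1:]):
        counts = pd.DataFrame(0, index=list(LABELS), columns=list(LABELS), dtype=int)
        for src, dst in zip(pivot[a], pivot[b]):
            counts.loc[src, dst] += 1
        row_sums = counts.sum(axis=1)
        fractions = counts.div(row_sums.replace(0, np.nan), axis=0)
        matrices[f"day{a}_to_day{b}"] = {"counts": counts, "fractions": fractions}

    d1, d2 = days[0], days[1]
    unresp = pivot[pivot[d1] == "unresponsive"]
    incr = pivot[pivot[d1] == "increased"]
    unresp_to_resp = (
        100.0 * (unresp[d2] == "increased").mean() if len(unresp) else float("nan")
    )
    resp_lost = (
        100.0 * (incr[d2] != "increased").mean() if len(incr) else float("nan")
    )
    return {
        "matrices": matrices,
        "unresponsive_to_responsive_pct": unresp_to_resp,
        "responsive_lost_pct": resp_lost,
    }


def basal_mean_z(
    norm: NormalizedRecording, timelines: Sequence[SessionTimeline]
) -> np.ndarray:
    """Mean Z over each day's basal window, neurons x days."""
    out = np.empty((norm.n_neurons, len(timelines)))
    for j, tl in enumerate(timelines):
        lo, hi = tl.basal_window_s
        i0 = norm.sample_index(tl.day, lo)
        i1 = norm.sample_index(tl.day, hi)
        out[:, j] = norm.z[:, i0:i1].mean(axis=1)
    return out


def basal_elevation(
    norm: NormalizedRecording,
    timelines: Sequence[SessionTimeline],
    theta_z: float = 0.5,
    base: str = "day2",
) -> Dict[str, object]:
    """Sustained basal-elevation flags and the persistence percentage.

    A neuron is elevated on day d when its basal-window mean Z exceeds its
    day-1 value by more than ``theta_z``.  The persistence percentage is the
    share of neurons elevated on both day 3 and day 4, among neurons elevated
    on day 2 (``base='day2'``) or among all neurons (``base='all'``).
    """
    if theta_z <= 0:
        raise ValueError("theta_z must be > 0")
    if base not in ("day2", "all"):
        raise ValueError("base must be 'day2' or 'all'")
    bm = basal_mean_z(norm, timelines)
    elevated = (bm - bm[:, [0]]) > theta_z
    n_days = bm.shape[1]
    persist_pct = float("nan")
    if n_days >= 4:
        both_late = elevated[:, 2] & elevated[:, 3]
        if base == "day2":
            denom = elevated[:, 1]
            if denom.any():
                persist_pct = 100.0 * (both_late & denom).sum() / denom.sum()
        else:
            persist_pct = 100.0 * both_late.mean()
    return {
        "basal_mean_z": bm,
        "elevated_flags": elevated,
        "elevated_pct_by_day": 100.0 * elevated.mean(axis=0),
        "elevated_persist_pct": persist_pct,
    }


def population_average(
    norm: NormalizedRecording, timelines: Sequence[SessionTimeline]
) -> pd.DataFrame:
    """Per-day mean and SEM of basal-window mean Z across neurons."""
    bm = basal_mean_z(norm, timelines)
    n = bm.shape[0]
    sem = bm.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.full(bm.shape[1], np.nan)
    return pd.DataFrame(
        {"day": [tl.day for tl in timelines], "mean_basal_z": bm.mean(axis=0), "sem": sem}
    )


@dataclass
class LongitudinalSummary:
    """All multi-day summaries bundled for reporting."""

    responsive_pct: Dict[str, float]
    transitions: Dict[str, object]
    basal: Dict[str, object]
    population: pd.DataFrame

    def headline(self) -> Dict[str, float]:
        out = dict(self.responsive_pct)
        out["unresponsive_to_responsive_pct"] = self.transitions[
            "unresponsive_to_responsive_pct"
        ]
        out["responsive_lost_pct"] = self.transitions["responsive_lost_pct"]
        out["elevated_persist_pct"] = self.basal["elevated_persist_pct"]
        return out


def summarize_longitudinal(
    calls: pd.DataFrame,
    norm: NormalizedRecording,
    timelines: Sequence[SessionTimeline],
    theta_z: float = 0.5,
    pooled_mode: str = "either",
    persistence_base: str = "day2",
) -> LongitudinalSummary:
    return LongitudinalSummary(
        responsive_pct=responsive_fractions(calls, pooled_mode=pooled_mode),
        transitions=transition_analysis(calls),
        basal=basal_elevation(norm, timelines, theta_z=theta_z, base=persistence_base),
        population=population_average(norm, timelines),
    )
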