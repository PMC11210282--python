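"""End-to-end pipeline: input -> normalization -> classification -> summaries.

``run_pipeline`` executes the whole analysis from a :class:`PipelineConfig`
and writes machine-readable outputs to a directory:

* ``traces.csv`` — raw fluorescence, one row per neuron
* ``timeline.json`` — session timelines + recording geometry
* ``truth.json`` — synthetic mode only, generator ground truth
* ``responder_calls.csv`` — per-neuron, per-day labels and p-values
* ``block_auc_day<d>.csv`` — per-trial block AUCs
* ``transients.csv`` / ``transient_summary.csv``
* ``summary.json`` — headline fractions, transitions, basal persistence
* ``manifest.json`` — config hash, seed, versions, excluded neurons

Outputs are deterministic: rerunning with the same config and seed produces
byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import scipy

from . import __version__
from .config import PipelineConfig
from .imaging import extract_traces, read_movie
from .longitudinal import LongitudinalSummary, summarize_longitudinal
from .normalize import extract_peristim, normalize_recording
from .responders import block_auc, calls_to_frame, classify_day
from .session import (
    FluorescenceRecording,
    NormalizedRecording,
    load_timelines,
    save_timelines,
)
from .simulate import GroundTruth, SyntheticDataset, simulate_population
from .transients import detect_transients, events_to_frame, transient_summary

logger = logging.getLogger("catrack")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


@dataclass
class PipelineResult:
    recording: FluorescenceRecording
    normalized: NormalizedRecording
    calls: pd.DataFrame
    transients: pd.DataFrame
    transient_table: pd.DataFrame
    summary: LongitudinalSummary
    truth: Optional[GroundTruth] = None


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - annotate and re-raise
                raise PipelineError(f"stage '{name}' failed: {exc}") from exc
        return wrapper
    return deco


@_stage("input")
def _load_input(config: PipelineConfig):
    if config.mode == "synthetic":
        sim = config.simulation
        if config.seed != sim.seed:
            sim = type(sim)(**{**sim.__dict__, "seed": config.seed})
        ds = simulate_population(sim)
        return ds.recording, ds.timelines, ds.truth
    timelines, fs, day_starts = load_timelines(config.timeline_json)
    if config.mode == "traces":
        rec = FluorescenceRecording.from_csv(config.traces_csv, fs, day_starts)
    else:
        movie, mask = read_movie(config.movie_tiff, config.mask_tiff)
        rec = extract_traces(movie, mask, fs, day_starts)
    return rec, timelines, None


def analyze_recording(
    rec: FluorescenceRecording,
    timelines,
    config: PipelineConfig,
) -> PipelineResult:
    """Run normalization, classification, transient detection and summaries
    on an in-memory recording (no file output)."""
    norm = _stage("normalize")(normalize_recording)(rec, timelines[0].basal_window_s)
    if norm.n_neurons == 0:
        raise PipelineError("stage 'normalize' failed: no neurons survived normalization")

    all_calls = []
    events = []
    for tl in timelines:
        tensor = _stage("peristim")(extract_peristim)(
            norm, tl, window_s=config.window_s, re_reference=True
        )
        all_calls.extend(
            _stage("classify")(classify_day)(
                tensor, config.blocks, alpha=config.alpha, mode=config.classify_mode
            )
        )
        # transients are counted relative to each day's own basal level, so a
        # sustained injection-induced shift does not masquerade as events
        day = norm.day_slice(tl.day)
        b0 = norm.sample_index(tl.day, tl.basal_window_s[0])
        b1 = norm.sample_index(tl.day, tl.basal_window_s[1])
        day_base = norm.z[:, b0:b1].mean(axis=1)
        for i, nid in enumerate(norm.neuron_ids):
            events.extend(
                _stage("transients")(detect_transients)(
                    norm.z[i, day] - day_base[i], norm.sampling_rate_hz,
                    config.detection, neuron_id=nid, day=tl.day,
                )
            )

    calls = calls_to_frame(all_calls)
    ev_frame = events_to_frame(events)
    table = transient_summary(ev_frame, norm.neuron_ids, [tl.day for tl in timelines])
    summary = _stage("summarize")(summarize_longitudinal)(
        calls, norm, timelines,
        theta_z=config.theta_z,
        pooled_mode=config.pooled_mode,
        persistence_base=config.persistence_base,
    )
    return PipelineResult(
        recording=rec, normalized=norm, calls=calls,
        transients=ev_frame, transient_table=table, summary=summary,
    )


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def _write_json(path: Path, payload: dict) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True, default=_json_default)


def summary_payload(result: PipelineResult) -> dict:
    s = result.summary
    transitions = {
        name: {
            "counts": m["counts"].to_dict(orient="index"),
            "fractions": m["fractions"].to_dict(orient="index"),
        }
        for name, m in s.transitions["matrices"].items()
    }
    return {
        "headline": s.headline(),
        "responsive_pct": s.responsive_pct,
        "transitions": transitions,
        "elevated_pct_by_day": list(s.basal["elevated_pct_by_day"]),
        "elevated_persist_pct": s.basal["elevated_persist_pct"],
        "population_basal_z": s.population.to_dict(orient="list"),
        "n_neurons_analyzed": result.normalized.n_neurons,
        "n_neurons_excluded": len(result.normalized.excluded),
    }


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> PipelineResult:
    """Execute the full pipeline and write the result bundle to ``out_dir``."""
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    rec, timelines, truth = _load_input(config)
    result = analyze_recording(rec, timelines, config)
    result.truth = truth
    norm = result.normalized

    rec.to_csv(out / "traces.csv")
    save_timelines(timelines, out / "timeline.json", rec.sampling_rate_hz,
                   list(rec.day_starts))
    if truth is not None:
        _write_json(out / "truth.json", truth.to_dict())

    result.calls.to_csv(out / "responder_calls.csv", index=False)
    result.transients.to_csv(out / "transients.csv", index=False)
    result.transient_table.to_csv(out / "transient_summary.csv", index=False)

    for tl in timelines:
        tensor = extract_peristim(norm, tl, window_s=config.window_s, re_reference=True)
        auc = block_auc(tensor, config.blocks)
        n_blocks = auc.shape[2]
        frame = pd.DataFrame(
            auc.reshape(-1, n_blocks),
            columns=[f"block{b}" for b in range(n_blocks)],
        )
        frame.insert(0, "trial", np.tile(np.arange(1, tensor.n_trials + 1), norm.n_neurons))
        frame.insert(0, "neuron_id", np.repeat(norm.neuron_ids, tensor.n_trials))
        frame.to_csv(out / f"block_auc_day{tl.day}.csv", index=False)

    _write_json(out / "summary.json", summary_payload(result))

    config_dict = config.to_dict()
    config_blob = json.dumps(config_dict, sort_keys=True).encode()
    manifest = {
        "config": config_dict,
        "config_sha256": hashlib.sha256(config_blob).hexdigest(),
        "seed": config.seed,
        "versions": {
            "catrack": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scipy": scipy.__version__,
        },
        "n_neurons_input": rec.n_neurons,
        "excluded_neurons": norm.excluded,
        "outputs": sorted(p.name for p in out.iterdir() if p.name != "manifest.json"),
    }
    _write_json(out / "manifest.json", manifest)
    logger.info(
        "pipeline complete: %d neurons analyzed, %d excluded, outputs in %s",
        norm.n_neurons, len(norm.excluded), out,
    )
    return result
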