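"""Configuration objects for simulation, detection, and the full pipeline.

All configs are plain dataclasses with explicit ``validate`` methods so that an
invalid field raises a :class:`ConfigError` naming the offending field, and all
can be round-tripped through YAML/JSON dictionaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence, Tuple

import yaml


class ConfigError(ValueError):
    """Raised when a configuration field violates its invariants."""


def _require(cond: bool, field_name: str, message: str) -> None:
    if not cond:
        raise ConfigError(f"{field_name}: {message}")


@dataclass
class SimulationConfig:
    """Parameters of the synthetic multi-day miniscope session generator.

    The defaults describe the study design this package targets: 4 consecutive
    daily sessions sampled at 10 Hz, each with a 5-min unstimulated basal
    period followed by 8 von Frey stimulus trials at 1-min intervals, with a
    sustained basal-fluorescence elevation switched on at the day-2 injection
    and persisting on days 3-4 in a subset of neurons.

    Amplitudes carrying a ``_z`` suffix are expressed in units of the additive
    noise SD, so they approximate the peak height of the event on the day-1
    baseline Z scale.
    """

    n_neurons: int = 79
    n_days: int = 4
    sampling_rate_hz: float = 10.0
    basal_duration_s: float = 300.0
    n_trials: int = 8
    inter_trial_s: float = 60.0
    #: delay between the end of the basal window and the first stimulus
    first_stim_offset_s: float = 30.0
    #: per-day probability that a neuron is stimulus-responsive that day
    frac_responsive_by_day: Tuple[float, ...] = (0.24, 0.494, 0.405, 0.405)
    evoked_amplitude_z: float = 3.0
    response_prob_per_trial: float = 0.9
    spont_rate_hz: float = 0.01
    spont_amplitude_z: float = 3.0
    kernel_rise_s: float = 0.1
    kernel_decay_s: float = 1.5
    #: sustained basal shift (noise-SD units) from the day-2 injection onward
    basal_shift_day2_z: float = 2.0
    #: fraction of neurons that receive the day-2 shift at all
    frac_shifted_day2: float = 0.9
    #: fraction of shifted neurons whose elevation persists on days 3-4
    frac_persist_elevated: float = 0.6
    noise_sd: float = 1.0
    #: fluorescence units per Z unit of event amplitude; None -> noise_sd
    amplitude_unit: Optional[float] = None
    f0_mean: float = 100.0
    f0_sd: float = 10.0
    seed: int = 0

    def validate(self) -> "SimulationConfig":
        _require(self.n_neurons >= 0, "n_neurons", "must be >= 0")
        _require(self.n_days >= 1, "n_days", "must be >= 1")
        _require(self.sampling_rate_hz > 0, "sampling_rate_hz", "must be > 0")
        _require(self.basal_duration_s > 0, "basal_duration_s", "must be > 0")
        _require(self.n_trials >= 1, "n_trials", "must be >= 1")
        _require(self.inter_trial_s > 0, "inter_trial_s", "must be > 0")
        _require(self.first_stim_offset_s >= 0, "first_stim_offset_s", "must be >= 0")
        _require(
            len(self.frac_responsive_by_day) == self.n_days,
            "frac_responsive_by_day",
            f"needs one entry per day ({self.n_days})",
        )
        for f in self.frac_responsive_by_day:
            _require(0.0 <= f <= 1.0, "frac_responsive_by_day", "entries must lie in [0, 1]")
        for name in ("response_prob_per_trial", "frac_shifted_day2", "frac_persist_elevated"):
            v = getattr(self, name)
            _require(0.0 <= v <= 1.0, name, "must lie in [0, 1]")
        _require(self.spont_rate_hz >= 0, "spont_rate_hz", "must be >= 0")
        _require(self.kernel_rise_s >= 0, "kernel_rise_s", "must be >= 0")
        _require(
            self.kernel_decay_s > self.kernel_rise_s,
            "kernel_decay_s",
            "must exceed kernel_rise_s",
        )
        _require(self.noise_sd >= 0, "noise_sd", "must be >= 0")
        if self.amplitude_unit is not None:
            _require(self.amplitude_unit > 0, "amplitude_unit", "must be > 0")
        _require(self.f0_mean > 0, "f0_mean", "must be > 0")
        _require(self.f0_sd >= 0, "f0_sd", "must be >= 0")
        _require(self.evoked_amplitude_z >= 0, "evoked_amplitude_z", "must be >= 0")
        _require(self.spont_amplitude_z >= 0, "spont_amplitude_z", "must be >= 0")
        return self

    @property
    def session_duration_s(self) -> float:
        """Length of one daily session (basal period + stimulation period)."""
        return self.basal_duration_s + self.n_trials * self.inter_trial_s

    @property
    def resolved_amplitude_unit(self) -> float:
        if self.amplitude_unit is not None:
            return self.amplitude_unit
        return self.noise_sd if self.noise_sd > 0 else 1.0


@dataclass
class DetectionParams:
    """Threshold-hysteresis calcium-transient detection parameters.

    An event opens when the Z trace stays at or above ``threshold_z`` for at
    least ``min_duration_s``, extends while the trace remains above
    ``release_fraction * threshold_z``, and events closer than ``merge_gap_s``
    are merged.
    """

    threshold_z: float = 2.5
    release_fraction: float = 0.5
    min_duration_s: float = 0.5
    merge_gap_s: float = 0.3

    def validate(self) -> "DetectionParams":
        _require(self.threshold_z > 0, "threshold_z", "must be > 0")
        _require(0 < self.release_fraction < 1, "release_fraction", "must lie in (0, 1)")
        _require(self.min_duration_s > 0, "min_duration_s", "must be > 0")
        _require(self.merge_gap_s >= 0, "merge_gap_s", "must be >= 0")
        return self


@dataclass
class BlockDefinition:
    """Peristimulus AUC blocks, seconds relative to the stimulus.

    One pre-stimulus block and two post-stimulus blocks; each block is the
    half-open interval [start, end).
    """

    pre: Tuple[float, float] = (-5.0, 0.0)
    post: Tuple[Tuple[float, float], ...] = ((0.0, 5.0), (5.0, 10.0))

    def validate(self, window: Tuple[float, float] = (-20.0, 20.0)) -> "BlockDefinition":
        blocks = [self.pre, *self.post]
        for lo, hi in blocks:
            _require(hi > lo, "blocks", f"block [{lo}, {hi}) is empty")
            _require(
                window[0] <= lo and hi <= window[1],
                "blocks",
                f"block [{lo}, {hi}) outside window {window}",
            )
        ordered = sorted(blocks)
        for (a_lo, a_hi), (b_lo, b_hi) in zip(ordered, ordered[1:]):
            _require(a_hi <= b_lo, "blocks", "blocks must not overlap")
        _require(len(self.post) >= 1, "post", "at least one post block required")
        return self

    @property
    def all_blocks(self) -> Sequence[Tuple[float, float]]:
        return [self.pre, *self.post]


@dataclass
class PipelineConfig:
    """End-to-end pipeline configuration.

    Exactly one input mode is active: ``synthetic`` (generate data),
    ``traces`` (load a traces CSV + timeline JSON), or ``movie`` (extract
    traces from a TIFF stack + ROI label mask, with a timeline JSON).
    """

    mode: str = "synthetic"
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    traces_csv: Optional[str] = None
    timeline_json: Optional[str] = None
    movie_tiff: Optional[str] = None
    mask_tiff: Optional[str] = None
    detection: DetectionParams = field(default_factory=DetectionParams)
    blocks: BlockDefinition = field(default_factory=BlockDefinition)
    window_s: Tuple[float, float] = (-20.0, 20.0)
    alpha: float = 0.05
    theta_z: float = 0.5
    #: "any" labels a neuron increased when >= 1 post block is significantly
    #: up; "both" requires both post blocks
    classify_mode: str = "any"
    #: pooling rule for days 3-4 responsiveness: "either" or "both"
    pooled_mode: str = "either"
    #: denominator of the basal-persistence percentage: "day2" or "all"
    persistence_base: str = "day2"
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> "PipelineConfig":
        _require(self.mode in ("synthetic", "traces", "movie"), "mode",
                 "must be one of synthetic|traces|movie")
        if self.mode == "synthetic":
            self.simulation.validate()
        elif self.mode == "traces":
            _require(self.traces_csv is not None, "traces_csv", "required in traces mode")
            _require(self.timeline_json is not None, "timeline_json", "required in traces mode")
        else:
            _require(self.movie_tiff is not None, "movie_tiff", "required in movie mode")
            _require(self.mask_tiff is not None, "mask_tiff", "required in movie mode")
            _require(self.timeline_json is not None, "timeline_json", "required in movie mode")
        for name in ("traces_csv", "timeline_json", "movie_tiff", "mask_tiff"):
            p = getattr(self, name)
            if p is not None:
                _require(Path(p).exists(), name, f"file not found: {p}")
        self.detection.validate()
        self.blocks.validate(self.window_s)
        _require(0 < self.alpha < 1, "alpha", "must lie in (0, 1)")
        _require(self.theta_z > 0, "theta_z", "must be > 0")
        _require(self.classify_mode in ("any", "both"), "classify_mode", "must be any|both")
        _require(self.pooled_mode in ("either", "both"), "pooled_mode", "must be either|both")
        _require(self.persistence_base in ("day2", "all"), "persistence_base",
                 "must be day2|all")
        return self

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["simulation"]["frac_responsive_by_day"] = list(
            d["simulation"]["frac_responsive_by_day"]
        )
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "simulation" in d and not isinstance(d["simulation"], SimulationConfig):
            sim = dict(d["simulation"])
            if "frac_responsive_by_day" in sim:
                sim["frac_responsive_by_day"] = tuple(sim["frac_responsive_by_day"])
            d["simulation"] = SimulationConfig(**sim)
        if "detection" in d and not isinstance(d["detection"], DetectionParams):
            d["detection"] = DetectionParams(**d["detection"])
        if "blocks" in d and not isinstance(d["blocks"], BlockDefinition):
            b = dict(d["blocks"])
            b["pre"] = tuple(b["pre"])
            b["post"] = tuple(tuple(p) for p in b["post"])
            d["blocks"] = BlockDefinition(**b)
        if "window_s" in d:
            d["window_s"] = tuple(d["window_s"])
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Load a pipeline config from a YAML (or JSON, a YAML subset) file."""
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls.from_dict(data or {})
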