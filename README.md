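# catrack

Longitudinal one-photon calcium-imaging analysis for tracked neuron
populations.

When the same neurons are imaged through a head-mounted miniscope across
several days — say, before and after a sensitizing nitroglycerin injection
in a migraine model — two questions dominate: *did the population's basal
activity rise and stay up?* and *which individual cells gained or lost a
response to a sensory stimulus?* `catrack` implements the full trace-level
analysis for that design:

- **Normalization**: ΔF/F = (F − Fmean)/Fmean and Z = (F − Fmean)/Fstd, with
  Fmean/Fstd taken from the day-1 basal window and applied to all
  concatenated days, so sustained shifts remain visible.
- **Responder classification**: peristimulus Z segments (−20 to +20 s,
  re-referenced to their own pre-stimulus mean) are integrated over three
  5-s blocks (pre [−5,0), post [0,5) and [5,10) s) across 8 trials; each
  post block is compared with the pre block by an **exact Wilcoxon
  signed-rank test** (full 2ⁿ sign-assignment enumeration, midranks for
  ties), labelling each neuron per day *increased*, *decreased* or
  *unresponsive* at α = 0.05.
- **Transient detection**: threshold–hysteresis event detection with counts,
  peak amplitudes and AUCs per neuron per session.
- **Longitudinal tracking**: per-day responsive percentages, label
  transition matrices, basal-elevation persistence, population averages.
- **Synthetic generator**: a spike-to-fluorescence simulator with known
  ground truth (double-exponential GCaMP-like kernel, Poisson spontaneous
  events, stimulus-locked evoked events, a sustained injection-induced
  basal shift, per-neuron random substreams), plus an optional rendered
  movie + ROI-mask path for testing manual-ROI extraction.

## Worked example

```python
import catrack as ct

sim = ct.SimulationConfig(seed=11)          # 79 neurons x 4 days at 10 Hz
ds = ct.simulate_population(sim)
res = ct.analyze_recording(ds.recording, ds.timelines,
                           ct.PipelineConfig(simulation=sim, seed=11))
print(res.summary.headline())
```

prints (reformatted):

```
day1 25.3%  day2 45.6%  day3 39.2%  day4 49.4%  days3_4_pooled 67.1%
unresponsive_to_responsive_pct 50.8
responsive_lost_pct 70.0
elevated_persist_pct 49.3
```

Read: after the simulated day-2 injection the fraction of stimulus-responsive
neurons roughly doubles (25% → 46%) and stays elevated; about half of the
initially silent cells are recruited; and ~half of the cells whose basal
fluorescence rose on day 2 are still elevated on both later days. Each number
is computed from the labels/flags the pipeline assigned, so on synthetic data
it can be checked against the generator's ground truth (see
`examples/03_track_across_days.py`, which also prints the transition matrix
and per-day population basal Z of this exact run).

The `examples/` directory holds one short script per capability:
simulation, single-day classification, multi-day tracking, and the
movie → ROI-extraction round trip.

## Command line

```sh
catrack simulate --seed 1 --out sim/           # traces.csv + timeline/truth JSON
catrack run --config cfg.yaml --seed 1 --out out/
catrack report --out out/
```

`run` writes traces, per-day block AUCs, responder calls, transient tables,
a summary JSON and a manifest (config hash, versions, excluded neurons);
outputs are byte-identical across reruns at a fixed seed.

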