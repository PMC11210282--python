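"""Render a synthetic movie, extract manual-ROI traces, and verify the
round trip.

The generator's traces are painted onto Gaussian cell footprints to form a
frame stack plus an integer ROI label mask; `extract_traces` then averages
pixels per ROI per frame, which should recover each input trace up to a
positive affine transform (correlation ~1 at low noise).
"""

import numpy as np

import catrack as ct

sim = ct.SimulationConfig(
    n_neurons=9, n_days=1, basal_duration_s=60.0, inter_trial_s=30.0,
    first_stim_offset_s=10.0, frac_responsive_by_day=(0.5,),
    noise_sd=0.05, amplitude_unit=1.0, seed=5,
)
ds = ct.simulate_population(sim)
movie, mask = ct.render_movie(ds, frame_shape=(48, 48), footprint_sd=1.5)
print(f"movie: {movie.shape} frames, mask labels: 1..{mask.max()}")

rec = ct.extract_traces(movie, mask, ds.recording.sampling_rate_hz,
                        list(ds.recording.day_starts))
r = [np.corrcoef(rec.F[i], ds.recording.F[i])[0, 1] for i in range(9)]
print(f"trace correlation input vs extracted: min {min(r):.4f}, "
      f"mean {np.mean(r):.4f} — ROI averaging preserves each neuron's "
      "dynamics, so downstream Z-scores are identical up to the affine "
      "normalization anchor")
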