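# Methods

`catrack` analyzes longitudinal one-photon miniscope recordings of a tracked
neuron population — the design in which a GRIN-lens field of view is held
fixed for four consecutive daily sessions so the same cells can be followed
before and after a sensitizing injection (vehicle on day 1, nitroglycerin on
day 2, no injection on days 3–4). Each session comprises 5 min of
unstimulated basal activity followed by 8 von Frey filament applications at
1-min intervals, imaged at 10 Hz. This note records the model, the
parameters that matter, and the design choices made where the procedure was
genuinely open.

## Normalization

Raw per-neuron fluorescence F is normalized against the **day-1 basal
window** only, and that anchor is applied to all four concatenated days:

    ΔF/F = (F − Fmean) / Fmean        Z = (F − Fmean) / Fstd

with Fmean and Fstd the mean and SD of F over the day-1 basal period.
Anchoring to day 1 is what makes a sustained injection-induced elevation
*visible* in Z on later days; re-anchoring per day would subtract the effect
being measured.

Numerical choices:

- Fstd uses the sample SD (ddof = 1); the convention is configurable.
- A neuron with non-positive Fmean or zero Fstd cannot be normalized; it is
  dropped pipeline-wide and listed, with a reason, in the output manifest —
  never silently. `compute_dff` alone tolerates a zero-SD (constant)
  baseline, since ΔF/F is still defined there.

## Peristimulus windows and block AUCs

Around each stimulus the Z trace from −20 s to +20 s is extracted on a
half-open grid (−20 ≤ t < 20; exactly 400 samples at 10 Hz, stimulus sample
at t = 0). Each trial is **re-referenced** by subtracting its own mean over
the pre-stimulus half [−20, 0), because basal levels differ across days;
after re-referencing, every trial's pre-window mean is 0 by construction.

Three block AUCs are computed per trial — pre [−5, 0), post [0, 5) and
[5, 10) s — as left Riemann sums (Σ z·Δt over samples with start ≤ t < end),
so a constant signal integrates to exactly block-length × value; a 5-s block
at 10 Hz uses exactly 50 samples. Trapezoidal quadrature would differ by
O(Δt) and was not needed; block edges land exactly on the sample grid.

## Responder classification

Per neuron and day, each post block's 8 trial AUCs are compared with the pre
block's by a **Wilcoxon signed-rank test computed exactly**: zero
differences are dropped, |differences| are midranked (ties handled inside
the enumeration, no approximation), and the null distribution of W⁺ is built
by enumerating all 2ⁿ sign assignments of the observed ranks. The two-sided
p doubles the smaller tail, capped at 1; with no nonzero differences the
test returns p = 1 (no information). At n = 8 the smallest attainable
two-sided p is 2/256 ≈ 0.0078, and the test is conservative at α = 0.05
(true rejection mass 10/256 ≈ 3.9%), which the calibration tests exploit.

Labels at α = 0.05 (no multiple-testing correction across neurons — the
procedure tests each tracked cell on its own):

- **increased** — significant AUC increase in ≥ 1 post block (default).
  A strict mode requiring both blocks is available (`classify_mode="both"`).
  The one-or-more reading was chosen because the complementary rule —
  "unresponsive when *neither* post block is significant" — already implies
  that a single significant increase excludes unresponsiveness; requiring
  both would leave one-block responders unlabelled.
- **decreased** — significant decrease in *both* post blocks.
- **unresponsive** — otherwise.
- If one block is significantly up and the other significantly down,
  increase takes precedence and the conflict is logged and flagged.

## Transient detection

Detection is a threshold–hysteresis rule (the quantification of transient
counts and amplitudes requires one, and none is canonical): an event opens
when Z stays ≥ `threshold_z` (default 2.5) for ≥ `min_duration_s` (0.5 s),
extends while Z ≥ `release_fraction × threshold_z` (release 0.5), and events
separated by < `merge_gap_s` (0.3 s) merge. Amplitude is the peak Z inside
the event; AUC is the left Riemann sum over its samples. Count is provably
monotone non-increasing in the threshold.

In the pipeline, detection runs on each day's trace after subtracting that
day's basal-window mean. With the day-1-anchored Z a sustained 2-SD basal
shift would put later-day noise permanently near threshold and inflate
counts ten-fold; day-referencing keeps the detector a counter of *discrete
events*, and under the generator's defaults per-neuron counts are then
stable across days while the basal-level analyses (which use the day-1
anchor) still see the elevation.

## Longitudinal summaries

- **Responsive fraction per day** = % of neurons labelled increased. Days
  3–4 are also pooled; the default counts a neuron responsive if increased
  on *either* day (configurable to *both*) since a single pooled value does
  not define its own membership rule.
- **Transitions** between consecutive days are 3×3 label count matrices with
  row-normalized fractions; headline fractions are day-1-unresponsive →
  day-2-increased, and day-1-increased → no longer increased. Empty source
  classes yield NaN, never 0.
- **Basal elevation**: a neuron is elevated on day d when its basal-window
  mean Z exceeds its day-1 value by more than `theta_z` (default 0.5; the
  criterion itself is this package's operationalization — the finding it
  quantifies is stated in the literature without a rule). The persistence
  percentage is the share of neurons elevated on *both* days 3 and 4 among
  those elevated on day 2 (denominator configurable to all neurons).
- **Population average**: per-day mean ± SEM of basal mean Z across neurons.

## The synthetic generator

Because no raw data accession exists for this experimental design, the
generator is the test bed. Each neuron's trace is

    F(t) = F0·(1 + shift(t)) + Σ_events A·k(t − t_e) + ε(t)

- **Kernel** k: unit-peak double exponential (1 − e^(−t/τ_rise))·e^(−t/τ_decay),
  τ_rise = 0.1 s, τ_decay = 1.5 s — GCaMP6m-like rise and decay; the
  indicator's name constrains the timescale but not the functional form, and
  the unit-peak form makes amplitudes interpretable.
- **Noise** ε: i.i.d. Gaussian, `noise_sd` (default 1.0 fluorescence unit).
  Shot noise, bleaching, motion and neuropil are deliberately out of scope.
- **Amplitudes** are given in noise-SD units (`evoked_amplitude_z` default
  3.0, `spont_amplitude_z` 3.0) and multiplied by `amplitude_unit`
  (default = `noise_sd`) to get fluorescence; at `noise_sd = 0` set
  `amplitude_unit` explicitly to keep events nonzero.
- **Evoked events**: a neuron responsive that day fires on each trial with
  probability `response_prob_per_trial` (default 0.9 — trial-to-trial
  reliability is imperfect in awake recordings) at a latency uniform in
  [0.1, 0.5] s, which keeps the evoked mass inside the [0, 5) s block.
- **Responsiveness** is drawn independently per neuron × day with the
  per-day fractions (defaults 0.24 / 0.494 / 0.405 / 0.405, the reported
  study fractions). Independence across days is a simplification: it
  reproduces per-day marginals but not day-to-day label correlation, so
  pooled either-day fractions exceed the single-day ones.
- **Basal shift**: at the day-2 injection, a fraction `frac_shifted_day2`
  (0.9 — "most" neurons) of neurons step up by `basal_shift_day2_z` (2.0)
  noise-SDs, implemented multiplicatively on F0 but calibrated so the
  additive effect in day-1 Z units equals the stated value; the step
  persists on days 3–4 for `frac_persist_elevated` (0.6) of them.
- **Spontaneous events**: Poisson at `spont_rate_hz` (0.01 Hz ≈ one every
  100 s, sparse PBN-like activity).
- **Determinism**: one master seed spawns a `SeedSequence` substream per
  neuron, so a fixed seed is bit-reproducible and enlarging the population
  leaves existing neurons' traces unchanged.

The optional movie path paints traces onto unit-peak Gaussian footprints on
a deterministic grid (plus constant background) and writes a multi-page
TIFF + integer label mask; `extract_traces` averages pixels per ROI, an
affine transform of the true trace, which Z-scoring then cancels.

What passing tests show — and don't: the pipeline recovers known ground
truth under Gaussian noise with well-isolated cells and a stable field of
view. Real miniscope data add motion, crosstalk, bleaching and segmentation
error upstream of this pipeline; results here say nothing about those
stages.

## Problem sizes

Statistical checks run at sizes chosen to make their error bars decisive
while staying desk-cheap: 2,000 null neurons for calibration (MC SE ≈ 0.5
points on a 5% rate), 200–400 neurons for sensitivity/fraction recovery,
300 for basal persistence, and the full 79-neuron × 4-day scale for
end-to-end determinism. The headline acceptance run uses the default
79-neuron study scale, so its fractions carry ~5-point binomial noise —
matching the granularity of the experiment it emulates.

## Known limitations

- The exact test enumerates up to n_effective = 24; beyond that it raises
  rather than silently approximating (the assay uses n = 8).
- Day-to-day responsiveness correlation is not modeled (see above).
- The elevation criterion and detection parameters are operational choices;
  both are exposed in configuration and their defaults documented here.
- With 8 trials the label set {increased, decreased, unresponsive} is
  coarse: power against moderate effects (~2 SD) is limited, so estimated
  responsive fractions are mildly attenuated relative to generator truth at
  default reliability.
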