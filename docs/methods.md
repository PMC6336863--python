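# Methods

This note documents the models, estimators, parameter choices, and known
limitations behind `neurodish`. Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Spike detection and the activity criterion

Extracellular spikes are detected on the absolute value of the wideband
signal at `threshold_sigma` (default 6) times a robust noise estimate,
σ = MAD/0.6745. The MAD is used instead of the sample SD because spikes
themselves inflate the SD: with 1% contamination by 10σ events the MAD
estimate stays within a few percent of truth while the plain SD does not
(checked in the unit tests). Threshold crossings within one refractory window
(default 1 ms) are collapsed to the sample of largest absolute amplitude.
On a perfectly flat electrode σ = 0 and no spikes are reported, which makes a
TTX-silenced recording come out as zero activity rather than as a
divide-by-zero.

An electrode is **active** at ≥ 5 spikes·min⁻¹ evaluated over the whole
recording (the criterion is inclusive: 150 spikes in 30 min passes). Whether
the criterion should instead use sliding windows is not specified by common
practice; whole-recording evaluation is the simpler, documented choice.

**Weighted mean firing rate** averages only over active electrodes, so adding
silent electrodes to a well does not dilute the rate.

## Network bursts

The detector bins all active-electrode spikes at 25 ms and marks bins where at
least `min_active_electrodes` (default 5) distinct electrodes fire; adjacent
marked regions separated by less than 100 ms are merged. Breadth is the number
of distinct electrodes with at least one spike inside the merged interval.
Commercial MEA software implements proprietary variants of this rule; the
binned version used here is deterministic, reproduces the "≥ 5 electrodes"
set criterion exactly, and recovers generator ground truth (count within
±10%, breadth within ±1 electrode at full participation). Burst frequency is
reported as bursts/min per well; normalization by active-electrode count is
available (`normalize_burst_freq=True`) and flagged in the output metadata,
since "normalized burst frequency" has no single published definition.

## Synchrony index

For each pair of active electrodes (i, j), C_ij is the symmetrized count of
spikes with at least one partner on the other electrode within ±20 ms, and
E_ij its expectation for independent Poisson trains of the observed rates,
E = ½[n_i(1 − e^{−2wλ_j}) + n_j(1 − e^{−2wλ_i})]. The pair score is
(C − E)/(√(n_i n_j) − E), and the index is the mean over pairs clipped to
[0, 1]. The denominator is chosen so that duplicated trains score exactly 1;
independent trains score ≈ 0 after the chance correction; jittering a common
train degrades the score monotonically. This is a documented substitute for
the unpublished vendor metric of the same name: comparisons should use it
consistently within a study, not against vendor-reported absolute values.

## LFP band-power timecourse

The LFP is extracted by a zero-phase (forward–backward) 4th-order Butterworth
low-pass at 500 Hz; downsampling uses polyphase anti-aliased resampling. PSDs
are Welch estimates (2 s Hann segments, 50% overlap, density scaling), so the
integral over frequency approximates the signal variance; band power is the
trapezoidal integral over [f_lo, f_hi]. The two bands of interest default to
1–10 Hz and 100–150 Hz. The developmental timecourse is
log₁₀(P_day/P_first-day) with the first recorded day pinned to exactly 0; a
zero baseline power raises an explicit error instead of producing −∞. Band
power is computed per electrode and averaged per well before the ratio (one
curve per animal); electrode-level output is retained. Filter family/order
and PSD segmentation are configurable and echoed in output metadata, because
no single convention is canonical.

## Calcium analysis

ΔF/F uses a running 10th-percentile baseline over 30 s windows, clamped away
from zero. Transients are excursions above 3× the per-cell MAD-based noise
lasting ≥ 0.5 s (the duration requirement suppresses isolated noise
crossings); on a strictly noiseless trace the threshold degenerates to "any
sustained positive excursion". A cell is active if it has ≥ 1 transient.

The **correlated-firing-response ratio** is the fraction of active cells
whose ΔF/F correlates with the mean ΔF/F of the other active cells above the
(1 − α) quantile of circular time-shift surrogates of that cell (200
surrogates, shifts ≥ 10 s, α = 0.05). Circular shifts preserve each cell's
autocorrelation while destroying its alignment with the network, so on fully
independent cells the flag rate calibrates to ≈ α, and on fully coupled cells
the ratio is 1. The ratio is undefined (flagged `None`) with fewer than two
active cells. The statistic operates on continuous traces rather than
binarized events because it remains stable at low event counts; this is a
documented operationalization of a quantity with no published formula, and it
is validated by its calibration properties, not by matching any particular
published value.

## Morphometry

Sholl analysis counts, for each radius r = 10, 20, … µm, the neurite segments
whose endpoint distances from the soma straddle r (min < r ≤ max, so a node
exactly on a circle is counted once). Distances use the x–y projection by
default because tracings are 2-D; `use_3d=True` switches to spherical shells.
Total outgrowth sums segment lengths excluding soma-internal segments;
primary neurites are the root's children; soma area is πr² of the root
radius. Puncta detection is scale-matched Laplacian-of-Gaussian blob
detection with centroid-refined subpixel centers; colocalization is greedy
one-to-one nearest-neighbor matching under a 0.5 µm radius (a typical
synapse-scale value, configurable), with ties broken by point index, and
density is pairs × 50/length.

## Statistics layer

The default two-sample test is the pooled-variance t with df = n₁+n₂−2; in
summary mode group SDs are recovered as SEM·√n, which reproduces published
caption statistics from published mean ± SEM/n to ≲ 0.1% (the residue is SEM
rounding). Welch's correction is available by flag. Two-way ANOVA uses Type I
sums of squares on balanced designs (where all orders agree) and falls back
to Type II with a warning otherwise; designs without replication drop the
interaction. Degenerate designs are handled in the zero-variance limit: a
term with (numerically) zero sum of squares gets F = 0, and a real effect
over zero residual variance gets F = ∞, p = 0. Mann–Whitney U uses exact
enumeration for tie-free samples with n₁+n₂ ≤ 20 and the tie-corrected normal
approximation otherwise; U is oriented so complete separation with group 1
low gives U = 0. BH-FDR is the standard step-up rule with monotone adjusted
values.

## Synthetic generators

The generators define the conditions under which every stage is validated:

- **Spike trains**: per-electrode homogeneous Poisson background (default
  1 Hz) plus network bursts with Poisson onsets (default 6/min, 0.5 s,
  30 min recordings, 8 electrodes). Each burst draws a recruited electrode
  subset (participation fraction) and a shared "mother" Poisson train
  (50 Hz); each recruited electrode keeps each mother spike with probability
  `synchrony_coupling`, so one knob controls breadth and synchrony jointly.
  Ground truth records intended and realized recruited sets.
- **Raw voltage**: each spike is a fixed 2 ms biphasic template with peak
  `spike_amp_sigma`·noise SD; oscillations are added sinusoids; noise has
  PSD ∝ 1/fᵡ (χ = 1 by default, frequency-domain synthesis with random
  phases, exact-SD normalization; χ = 0 gives white noise).
- **Calcium**: difference-of-exponentials kernel (τ_rise 0.2 s, τ_decay
  1.5 s) normalized to unit peak; shared drive events accepted per cell with
  its coupling probability, private events at 1/min by default; Gaussian
  noise. The private-event channel exists so uncoupled cells are still
  active.
- **Morphology**: trees grown segment-by-segment (gamma-distributed segment
  lengths, small heading noise, branching probability per segment) until the
  target total length is reached; the total is guaranteed within 10% of
  target. Default target 848 µm with 3 primary neurites — the scale of a
  healthy cultured projection neuron.
- **Puncta**: pre puncta placed Poisson-uniformly along a straight neurite; a
  set fraction receives a post partner within the jitter radius; remaining
  post puncta are independent. Rendering uses Gaussian spots of the PSF
  width.

What the generators deliberately do **not** emulate: biophysical membrane
dynamics, electrode crosstalk, photobleaching and movement artifacts in
imaging, non-stationary firing within a session, and realistic arbor
geometry beyond total length/branching statistics. Passing tests therefore
demonstrate correctness of the estimators under controlled conditions, not
biological fidelity of any particular culture.

## Pipeline choices

The cohort pipeline treats one well/animal as the replicate for
cross-genotype tests (per-neuron analysis is available by using the
per-neuron outputs directly). Firing and bursting ramp linearly over
recording days to emulate maturation. Per-animal biological variability is
injected into morphology parameters (~10% CV on target length, ~5% on soma
radius). Child seeds are derived by hashing the root seed with the
animal/day/stage indices, so runs are reproducible and stages are
independent. The run manifest records every parameter value and a hash that
is stamped on each output row; the manifest hash excludes the output
directory so identical analyses in different locations produce identical
tables.

## Problem sizes

Validation workloads are desk-scale by design: 600 s, 8-electrode recordings
for detection/burst/synchrony checks; 10 kHz rendering for spike-detection
scoring; 20 seeds × 50 cells × 500 s for correlated-firing calibration;
10⁴ null simulations for t-test calibration; 2000 for ANOVA p-uniformity.

## Known limitations

- The synchrony index and correlated-firing ratio are documented substitutes
  for unpublished metrics; absolute values are not comparable to vendor
  software.
- Spike detection does not sort units; overlapping spikes within a
  refractory window on one electrode merge.
- The Sholl counter counts segment straddles; a segment that crosses a
  circle twice between its endpoints (re-entrant geometry) counts once.
- Exact Mann–Whitney enumeration is limited to n₁+n₂ ≤ 20.
- `delta_f_over_f` assumes positive raw fluorescence and flags anything
  else rather than guessing an offset.
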