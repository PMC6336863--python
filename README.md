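# neurodish

Quantification of **in vitro neuronal network development and neuron
morphology**: multielectrode-array (MEA) spike/burst/synchrony metrics, local
field potential (LFP) band-power timecourses, calcium-imaging correlated-firing
analysis, Sholl/synapse morphometry, and the two-group / factorial statistics
used to compare genotypes — plus a synthetic-data generator that produces every
input with known ground truth.

The package is aimed at cellular-neurophysiology studies that culture primary
cortical neurons (e.g. from a mutant mouse line and wild-type littermates) and
ask whether network development in the dish differs between groups.

## What it computes

**MEA activity** (`neurodish.mea`). Spikes are detected per electrode where the
field potential exceeds 6·σ of the noise (σ estimated robustly as MAD/0.6745);
an electrode is *active* at ≥ 5 spikes·min⁻¹; a *network burst* is an epoch in
which ≥ 5 active electrodes fire within 25 ms bins (gaps < 100 ms merged).
Summary metrics per well: weighted mean firing rate
wMFR = (Σ spikes on active electrodes)/(n_active · T), burst frequency, burst
breadth, and a chance-corrected synchrony index

SI = ⟨(C_ij − E_ij)/(√(n_i n_j) − E_ij)⟩_pairs ∈ [0, 1],

where C_ij counts spikes with a partner on the other electrode within ±20 ms
and E_ij is the Poisson chance expectation.

**LFP spectra** (`neurodish.lfp`). The LFP is the raw signal low-passed at
500 Hz (zero-phase 4th-order filter). Welch PSDs give band powers for
1–10 Hz (network depolarizations) and 100–150 Hz (broadband/high-gamma, an
index of aggregate firing); maturation is expressed per recording day as
log₁₀(P_day / P_first-day), so the first day in vitro recorded is exactly 0.

**Calcium imaging** (`neurodish.calcium`). ΔF/F with a running-percentile
baseline, transient detection (≥ 3σ for ≥ 0.5 s), and the
*correlated-firing-response ratio*: the fraction of active cells whose trace
correlates with the mean of the other active cells beyond the 95th percentile
of circular time-shift surrogates.

**Morphometry** (`neurodish.morphometry`). SWC I/O, Sholl intersections with
10 µm concentric circles around the soma, total neuritic outgrowth, soma area,
Laplacian-of-Gaussian puncta detection, and one-to-one pre/post puncta
colocalization reported as synapses per 50 µm of neurite.

**Statistics** (`neurodish.stats`). Pooled-variance two-sample *t* (from raw
samples *or* published mean ± SEM with n), fixed-effects two-way ANOVA
(genotype × DIV), Mann–Whitney U with exact small-sample p, and
Benjamini–Hochberg FDR control.

**Synthetic data** (`neurodish.synthetic`). Poisson background firing plus
network bursts drawn from a thinned shared mother train; raw voltage = biphasic
spike waveforms + sinusoids + 1/fᵡ noise; calcium traces driven by a shared
network process; random branching neurite trees grown to a target length;
pre/post puncta fields with a set colocalization fraction. All generators are
seed-deterministic and return ground truth.

## Worked example

Recompute published two-group comparisons from their mean ± SEM summaries:

```text
$ neurodish reproduce-paper-stats
                  label  printed_t  recomputed_t       df  p_two_sided  rel_deviation
              soma_area     2.0310        2.0334  70.0000       0.0458         0.0012
      neurite_outgrowth     4.9400        4.9410  70.0000       0.0000         0.0002
synaptic_puncta_density     6.6430        6.6353 104.0000       0.0000         0.0012
        social_approach     0.6379        0.6378  38.0000       0.5274         0.0001
         social_novelty     3.6430        3.6410  38.0000       0.0008         0.0005
      social_preference     2.2400        2.2388  38.0000       0.0311         0.0005
...
```

Each row recovers the group SDs as SEM·√n, forms the pooled-variance *t* with
df = n₁+n₂−2, and reports the relative deviation from the published statistic
(≤ ~0.1%, the residue of SEM rounding).

Simulate a culture well and quantify its network activity:

```text
$ neurodish simulate --seed 7 --out demo --duration-s 120
wrote demo/spikes.csv (1733 spikes, 5 bursts)
$ neurodish mea --spikes-csv demo/spikes.csv --out demo/summary.json
wmfr=1.805 Hz, active=8, bursts/min=3.00, SI=0.433
```

All 8 electrodes pass the 5 spikes·min⁻¹ criterion; the well fires at 1.8 Hz
per active electrode with 3 network bursts per minute at moderate synchrony.
`neurodish run-all --seed 7 --out results/run` pushes a whole two-genotype
cohort through every stage and writes activity tables, LFP timecourses,
per-animal endpoints, genotype tests, and a manifest that reproduces the run.

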