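"""Multielectrode-array (MEA) spike detection and network-activity metrics.

Cultured cortical neurons on an MEA produce extracellular field potentials.
This module implements the recording-criteria chain used to quantify
spontaneous network development in vitro:

* spike detection at a multiple of the per-electrode noise sigma
  (default 6 sigma, both polarities),
* the active-electrode criterion (default 5 spikes/min over the whole
  recording),
* weighted mean firing rate (rate averaged over active electrodes only),
* network-burst detection (epochs where at least 5 active electrodes fire
  near-simultaneously),
* a chance-corrected pairwise synchrony index in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RawRecording",
    "SpikeTrainSet",
    "NetworkBurst",
    "ActivitySummary",
    "estimate_noise_sigma",
    "detect_spikes",
    "active_electrodes",
    "weighted_mean_firing_rate",
    "detect_network_bursts",
    "synchrony_index",
    "activity_summary",
]

#: MAD -> SD conversion for a Gaussian (1/Phi^-1(0.75)).
_MAD_SCALE = 0.6744897501960817


@dataclass
class RawRecording:
    """Raw extracellular voltage, electrodes x samples.

    Parameters
    ----------
    voltage_uV : ndarray, shape (n_electrodes, n_samples)
        Wideband voltage in microvolts.
    fs_hz : float
        Sampling rate in Hz.
    div_day : int
        Day in vitro the recording was taken.
    well_id : str
        Culture-well label.
    """

    voltage_uV: np.ndarray
    fs_hz: float
    div_day: int = 0
    well_id: str = "well0"

    def __post_init__(self) -> None:
        self.voltage_uV = np.atleast_2d(np.asarray(self.voltage_uV, dtype=float))
        if self.fs_hz <= 0:
            raise ValueError(f"fs_hz must be positive, got {self.fs_hz}")
        if self.voltage_uV.shape[0] < 1:
            raise ValueError("recording needs at least one electrode")
        if not np.all(np.isfinite(self.voltage_uV)):
            raise ValueError("voltage contains non-finite samples")

    @property
    def n_electrodes(self) -> int:
        return self.voltage_uV.shape[0]

    @property
    def duration_s(self) -> float:
        return self.voltage_uV.shape[1] / self.fs_hz


@dataclass
class SpikeTrainSet:
    """Per-electrode sorted spike times (seconds) over a known duration."""

    spikes: list
    duration_s: float

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        clean = []
        for el, times in enumerate(self.spikes):
            t = np.asarray(times, dtype=float)
            if t.size and (t.min() < 0 or t.max() >= self.duration_s):
                raise ValueError(
                    f"electrode {el}: spike times outside [0, duration_s)"
                )
            if t.size and np.any(np.diff(t) <= 0):
                raise ValueError(f"electrode {el}: times not strictly increasing")
            clean.append(t)
        self.spikes = clean

    @property
    def n_electrodes(self) -> int:
        return len(self.spikes)

    def counts(self) -> np.ndarray:
        return np.array([t.size for t in self.spikes], dtype=int)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table with columns electrode_id, time_s."""
        rows = [
            (el, t) for el, times in enumerate(self.spikes) for t in times
        ]
        return pd.DataFrame(rows, columns=["electrode_id", "time_s"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame, duration_s: float,
                   n_electrodes: int | None = None) -> "SpikeTrainSet":
        n = int(n_electrodes if n_electrodes is not None
                else (df["electrode_id"].max() + 1 if len(df) else 0))
        spikes = [np.sort(df.loc[df["electrode_id"] == el, "time_s"].to_numpy())
                  for el in range(n)]
        return cls(spikes=spikes, duration_s=duration_s)


@dataclass
class NetworkBurst:
    """One network burst: interval, participating electrodes, spike count."""

    start_s: float
    end_s: float
    electrode_ids: frozenset
    n_spikes: int

    def __post_init__(self) -> None:
        if self.end_s <= self.start_s:
            raise ValueError("burst end must follow start")

    @property
    def breadth(self) -> int:
        return len(self.electrode_ids)


@dataclass
class ActivitySummary:
    """Per-well network activity metrics for one recording day."""

    wmfr_hz: float
    n_active: int
    burst_freq_per_min: float
    mean_burst_breadth: float
    synchrony_index: float
    well_id: str = "well0"
    div_day: int = 0
    meta: dict = field(default_factory=dict)


def estimate_noise_sigma(trace: np.ndarray) -> float:
    """Robust noise SD of a single-electrode voltage trace (uV).

    Uses the median absolute deviation scaled to be consistent with the
    Gaussian SD (MAD / 0.6745), which is insensitive to sparse large spikes.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.size < 100:
        raise ValueError("trace too short for noise estimation (need >= 100 samples)")
    if not np.all(np.isfinite(trace)):
        raise ValueError("trace contains non-finite samples")
    return float(np.median(np.abs(trace - np.median(trace))) / _MAD_SCALE)


def _merge_crossings(idx: np.ndarray, absv: np.ndarray, refractory: int) -> np.ndarray:
    """Collapse threshold crossings closer than `refractory` samples to the extremum."""
    if idx.size == 0:
        return idx
    out = []
    group_start = 0
    gaps = np.diff(idx)
    breakpoints = np.nonzero(gaps > refractory)[0]
    start = 0
    for bp in np.append(breakpoints, idx.size - 1):
        group = idx[start:bp + 1]
        out.append(group[np.argmax(absv[group])])
        start = bp + 1
    return np.array(out, dtype=int)


def detect_spikes(raw: RawRecording, threshold_sigma: float = 6.0,
                  refractory_ms: float = 1.0) -> SpikeTrainSet:
    """Detect spikes as |voltage| excursions >= threshold_sigma x noise sigma.

    Detection runs on the absolute value (extracellular spikes are biphasic);
    crossings within the refractory window are collapsed to the sample of
    largest absolute amplitude.

    Parameters
    ----------
    raw : RawRecording
        Wideband recording; sampling rate should be >= 1 kHz to retain
        spike content.
    threshold_sigma : float
        Detection threshold in multiples of the robust noise SD (default 6).
    refractory_ms : float
        Minimum separation between detected spikes, in milliseconds.
    """
    if not np.all(np.isfinite(raw.voltage_uV)):
        raise ValueError("voltage contains non-finite samples")
    refractory = max(int(round(refractory_ms * 1e-3 * raw.fs_hz)), 1)
    spikes = []
    for trace in raw.voltage_uV:
        sigma = estimate_noise_sigma(trace)
        absv = np.abs(trace)
        if sigma == 0.0:
            # flat trace: any nonzero sample is "suprathreshold"; a fully
            # flat trace yields no spikes
            idx = np.nonzero(absv > 0)[0]
        else:
            idx = np.nonzero(absv >= threshold_sigma * sigma)[0]
        idx = _merge_crossings(idx, absv, refractory)
        spikes.append(idx / raw.fs_hz)
    return SpikeTrainSet(spikes=spikes, duration_s=raw.duration_s)


def active_electrodes(spikes: SpikeTrainSet,
                      min_rate_per_min: float = 5.0) -> set:
    """Electrodes meeting the activity criterion (>= min_rate_per_min, inclusive)."""
    minutes = spikes.duration_s / 60.0
    return {el for el, t in enumerate(spikes.spikes)
            if t.size / minutes >= min_rate_per_min}


def weighted_mean_firing_rate(spikes: SpikeTrainSet,
                              min_rate_per_min: float = 5.0) -> float:
    """Mean firing rate (Hz) over electrodes meeting the activity criterion.

    Total spikes on active electrodes divided by (n_active x duration);
    0 if no electrode is active.  Silent electrodes therefore do not dilute
    the rate.
    """
    active = active_electrodes(spikes, min_rate_per_min)
    if not active:
        return 0.0
    total = sum(spikes.spikes[el].size for el in active)
    return total / (len(active) * spikes.duration_s)


def detect_network_bursts(spikes: SpikeTrainSet, bin_ms: float = 25.0,
                          min_active_electrodes: int = 5,
                          min_gap_ms: float = 100.0,
                          min_rate_per_min: float = 5.0):
    """Detect network bursts: bins where >= min_active_electrodes active electrodes fire.

    The recording is binned at `bin_ms`; bins in which at least
    `min_active_electrodes` electrodes (restricted to those meeting the
    activity criterion) each fire at least one spike are burst bins.
    Contiguous burst bins, and burst regions separated by less than
    `min_gap_ms`, are merged into a single burst.  Burst breadth is the
    number of distinct participating electrodes over the merged interval.

    Returns
    -------
    bursts : list of NetworkBurst
    burst_freq_per_min : float
    """
    bin_s = bin_ms * 1e-3
    if bin_s > spikes.duration_s:
        raise ValueError("bin larger than recording duration")
    active = sorted(active_electrodes(spikes, min_rate_per_min))
    n_bins = int(np.ceil(spikes.duration_s / bin_s))
    edges = np.arange(n_bins + 1) * bin_s
    occupancy = np.zeros(n_bins, dtype=int)
    per_el_bins = {}
    for el in active:
        t = spikes.spikes[el]
        if t.size == 0:
            continue
        b = np.unique(np.minimum((t / bin_s).astype(int), n_bins - 1))
        per_el_bins[el] = b
        occupancy[b] += 1
    burst_bins = occupancy >= min_active_electrodes

    # contiguous runs of burst bins
    runs = []
    in_run = False
    for i, flag in enumerate(burst_bins):
        if flag and not in_run:
            start = i
            in_run = True
        elif not flag and in_run:
            runs.append((start, i - 1))
            in_run = False
    if in_run:
        runs.append((start, n_bins - 1))

    # merge runs separated by < min_gap_ms
    gap_bins = min_gap_ms * 1e-3 / bin_s
    merged = []
    for run in runs:
        if merged and (run[0] - merged[-1][1] - 1) < gap_bins:
            merged[-1] = (merged[-1][0], run[1])
        else:
            merged.append(run)

    bursts = []
    for b0, b1 in merged:
        t0, t1 = edges[b0], edges[b1 + 1]
        members = set()
        n_spk = 0
        for el in active:
            t = spikes.spikes[el]
            k = int(np.searchsorted(t, t1, "left") - np.searchsorted(t, t0, "left"))
            if k > 0:
                members.add(el)
                n_spk += k
        bursts.append(NetworkBurst(start_s=float(t0), end_s=float(t1),
                                   electrode_ids=frozenset(members),
                                   n_spikes=n_spk))
    freq = len(bursts) / (spikes.duration_s / 60.0)
    return bursts, freq


def _pair_coincidence(t1: np.ndarray, t2: np.ndarray, window_s: float) -> float:
    """Symmetrized count of spikes having >= 1 partner in the other train."""
    def one_way(a, b):
        lo = np.searchsorted(b, a - window_s, "left")
        hi = np.searchsorted(b, a + window_s, "right")
        return int(np.count_nonzero(hi > lo))
    return 0.5 * (one_way(t1, t2) + one_way(t2, t1))


def synchrony_index(spikes: SpikeTrainSet, window_ms: float = 20.0,
                    min_rate_per_min: float = 5.0) -> float:
    """Chance-corrected pairwise spike-coincidence index in [0, 1].

    For each pair (i, j) of active electrodes, let C be the symmetrized count
    of spikes with at least one partner on the other electrode within
    +/- window, and E its expectation for independent Poisson trains of the
    observed rates.  The pair index is (C - E)/(sqrt(n_i n_j) - E), so
    duplicated trains score exactly 1 and independent trains score ~0 after
    chance correction; the result is the mean over pairs, clipped to [0, 1].
    Returns 0 with fewer than two active electrodes.
    """
    active = sorted(active_electrodes(spikes, min_rate_per_min))
    if len(active) < 2:
        return 0.0
    w = window_ms * 1e-3
    T = spikes.duration_s
    vals = []
    for a in range(len(active)):
        for b in range(a + 1, len(active)):
            t1, t2 = spikes.spikes[active[a]], spikes.spikes[active[b]]
            n1, n2 = t1.size, t2.size
            c = _pair_coincidence(t1, t2, w)
            # P(no partner within +/-w) for a Poisson train of rate n/T
            e = 0.5 * (n1 * (1.0 - np.exp(-2.0 * w * n2 / T))
                       + n2 * (1.0 - np.exp(-2.0 * w * n1 / T)))
            denom = np.sqrt(n1 * n2) - e
            vals.append((c - e) / denom if denom > 0 else 0.0)
    return float(np.clip(np.mean(vals), 0.0, 1.0))


def activity_summary(spikes: SpikeTrainSet, well_id: str = "well0",
                     div_day: int = 0, min_rate_per_min: float = 5.0,
                     normalize_burst_freq: bool = False,
                     **burst_kwargs) -> ActivitySummary:
    """All network metrics for one spike-train set.

    ``normalize_burst_freq=True`` divides the burst rate by the number of
    active electrodes (an alternative normalization; flagged in ``meta``).
    """
    active = active_electrodes(spikes, min_rate_per_min)
    bursts, freq = detect_network_bursts(
        spikes, min_rate_per_min=min_rate_per_min, **burst_kwargs)
    if normalize_burst_freq and active:
        freq = freq / len(active)
    breadth = float(np.mean([b.breadth for b in bursts])) if bursts else 0.0
    return ActivitySummary(
        wmfr_hz=weighted_mean_firing_rate(spikes, min_rate_per_min),
        n_active=len(active),
        burst_freq_per_min=freq,
        mean_burst_breadth=breadth,
        synchrony_index=synchrony_index(spikes, min_rate_per_min=min_rate_per_min),
        well_id=well_id,
        div_day=div_day,
        meta={"burst_freq_normalized_by_active": bool(normalize_burst_freq)},
    )
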