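"""Calcium-imaging trace analysis: dF/F, transient detection, and the
correlated-firing-response ratio.

The correlated-firing-response ratio is the fraction of active cells whose
fluorescence is significantly correlated with the rest of the network.
Significance is assessed per cell against circular time-shift surrogates:
the cell's trace is rotated by random offsets, destroying alignment with
the network while preserving its autocorrelation, and the observed
zero-lag correlation with the mean trace of the other active cells must
exceed the (1 - alpha) surrogate quantile.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import percentile_filter

__all__ = [
    "CalciumTraceSet",
    "CorrelationResult",
    "delta_f_over_f",
    "detect_transients",
    "correlated_firing_ratio",
]

_MAD_SCALE = 0.6744897501960817


@dataclass
class CalciumTraceSet:
    """Fluorescence traces, cells x samples, at a known sampling rate."""

    F: np.ndarray
    fs_hz: float

    def __post_init__(self) -> None:
        self.F = np.atleast_2d(np.asarray(self.F, dtype=float))
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")
        if not np.all(np.isfinite(self.F)):
            raise ValueError("traces contain non-finite samples")

    @property
    def n_cells(self) -> int:
        return self.F.shape[0]

    @property
    def n_samples(self) -> int:
        return self.F.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz


@dataclass
class CorrelationResult:
    """Outcome of the correlated-firing analysis.

    ``ratio`` is n_correlated / n_active, or ``None`` (undefined) when
    fewer than two cells are active.
    """

    active_cell_ids: list
    statistic: dict
    threshold: dict
    correlated: dict
    ratio: float | None
    meta: dict = field(default_factory=dict)

    @property
    def n_active(self) -> int:
        return len(self.active_cell_ids)

    @property
    def n_correlated(self) -> int:
        return sum(bool(v) for v in self.correlated.values())


def delta_f_over_f(traces: CalciumTraceSet, baseline_percentile: float = 10.0,
                   window_s: float = 30.0) -> CalciumTraceSet:
    """Baseline-normalized fluorescence (F - F0)/F0.

    F0 is a running percentile (default 10th over 30 s), clamped away from
    zero so quiet dim cells cannot blow up the normalization.
    """
    n = traces.n_samples
    win = int(round(window_s * traces.fs_hz))
    if win >= n:
        raise ValueError("baseline window must be shorter than the recording")
    win = max(win, 3)
    if np.any(traces.F <= 0):
        raise ValueError("raw fluorescence must be positive for dF/F")
    out = np.empty_like(traces.F)
    for i, f in enumerate(traces.F):
        f0 = percentile_filter(f, baseline_percentile, size=win,
                               mode="nearest")
        f0 = np.maximum(f0, 1e-6 * max(np.abs(f).max(), 1.0))
        out[i] = (f - f0) / f0
    return CalciumTraceSet(F=out, fs_hz=traces.fs_hz)


def detect_transients(dff: CalciumTraceSet, k_sigma: float = 3.0,
                      min_duration_s: float = 0.5):
    """Detect calcium transients as suprathreshold excursions of dF/F.

    An event is a contiguous run where dF/F exceeds ``k_sigma`` x the
    per-cell robust noise SD for at least ``min_duration_s``; the event
    time is the run's peak.  Cells with >= 1 event are "active".

    Returns
    -------
    events : list of ndarray (per-cell event times, seconds)
    active : list of int (indices of active cells)
    """
    min_len = max(int(round(min_duration_s * dff.fs_hz)), 1)
    events, active = [], []
    for cell, x in enumerate(dff.F):
        sigma = np.median(np.abs(x - np.median(x))) / _MAD_SCALE
        if sigma == 0:
            # noiseless trace: any sustained positive excursion is an event;
            # a perfectly flat trace yields none
            if np.ptp(x) == 0:
                events.append(np.array([]))
                continue
            above = x > 0
        else:
            above = x > k_sigma * sigma
        # run-length encode
        d = np.diff(above.astype(int))
        starts = list(np.nonzero(d == 1)[0] + 1)
        ends = list(np.nonzero(d == -1)[0] + 1)
        if above[0]:
            starts.insert(0, 0)
        if above[-1]:
            ends.append(x.size)
        times = [(s + int(np.argmax(x[s:e]))) / dff.fs_hz
                 for s, e in zip(starts, ends) if e - s >= min_len]
        t = np.array(times)
        events.append(t)
        if t.size:
            active.append(cell)
    return events, active


def correlated_firing_ratio(dff: CalciumTraceSet, n_surrogates: int = 200,
                            alpha: float = 0.05, seed: int = 0,
                            k_sigma: float = 3.0,
                            min_duration_s: float = 0.5,
                            min_shift_s: float = 10.0) -> CorrelationResult:
    """Fraction of active cells significantly correlated with the network.

    Per active cell the statistic is the Pearson correlation between its
    dF/F trace and the mean dF/F of all *other* active cells; the null
    threshold is the (1 - alpha) quantile of the same statistic under
    ``n_surrogates`` circular time shifts of that cell's trace (shifts of at
    least ``min_shift_s`` so surrogates decorrelate).  Constant traces are
    excluded from the active set.
    """
    rng = np.random.default_rng(seed)
    _, active = detect_transients(dff, k_sigma=k_sigma,
                                  min_duration_s=min_duration_s)
    active = [c for c in active if np.std(dff.F[c]) > 0]
    stat, thr, corr = {}, {}, {}
    if len(active) < 2:
        return CorrelationResult(active_cell_ids=active, statistic=stat,
                                 threshold=thr, correlated=corr, ratio=None,
                                 meta={"reason": "fewer than 2 active cells"})
    X = dff.F[active]
    n = X.shape[1]
    min_shift = min(int(round(min_shift_s * dff.fs_hz)), n // 4)
    total = X.sum(axis=0)
    for i, cell in enumerate(active):
        x = X[i]
        others = (total - x) / (len(active) - 1)
        if np.std(others) == 0:
            continue
        r_obs = float(np.corrcoef(x, others)[0, 1])
        shifts = rng.integers(min_shift, n - min_shift, size=n_surrogates)
        null = np.empty(n_surrogates)
        for k, s in enumerate(shifts):
            null[k] = np.corrcoef(np.roll(x, s), others)[0, 1]
        t = float(np.quantile(null, 1.0 - alpha))
        stat[cell] = r_obs
        thr[cell] = t
        corr[cell] = r_obs > t
    ratio = (sum(corr.values()) / len(active)) if active else None
    return CorrelationResult(active_cell_ids=active, statistic=stat,
                             threshold=thr, correlated=corr, ratio=ratio,
                             meta={"n_surrogates": n_surrogates,
                                   "alpha": alpha, "seed": seed})
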