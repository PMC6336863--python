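"""Local field potential (LFP) extraction and band-power timecourses.

The LFP is obtained by zero-phase low-pass filtering the raw MEA signal at
500 Hz.  Network maturation is tracked by the power in two bands — 1-10 Hz
(network synchronized depolarizations) and 100-150 Hz (broadband / high
gamma, an index of aggregate local firing) — expressed per recording day as
log10(P_day / P_first_day), so the first day is exactly 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "LFPSeries",
    "SpectralSummary",
    "BandPowerTimecourse",
    "LOW_BAND",
    "HIGH_BAND",
    "extract_lfp",
    "compute_psd",
    "band_power",
    "log_power_ratio_timecourse",
]

#: network synchronized depolarization band (Hz)
LOW_BAND = (1.0, 10.0)
#: broadband / high-gamma band (Hz)
HIGH_BAND = (100.0, 150.0)


@dataclass
class LFPSeries:
    """Single low-passed voltage series with sampling rate and DIV day."""

    samples_uV: np.ndarray
    fs_hz: float
    div_day: int = 0

    def __post_init__(self) -> None:
        self.samples_uV = np.asarray(self.samples_uV, dtype=float).ravel()
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")
        if not np.all(np.isfinite(self.samples_uV)):
            raise ValueError("non-finite samples")


@dataclass
class SpectralSummary:
    """One-sided PSD on a frequency grid, with estimation metadata."""

    freqs_hz: np.ndarray
    psd_uV2_per_hz: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.any(self.psd_uV2_per_hz < 0):
            raise ValueError("PSD must be nonnegative")
        if np.any(np.diff(self.freqs_hz) <= 0):
            raise ValueError("frequency grid must be strictly increasing")


@dataclass
class BandPowerTimecourse:
    """Per-day band power and log10 ratio to the first recording day."""

    band: tuple
    div_days: list
    power_uV2: np.ndarray
    log10_ratio: np.ndarray

    def to_frame(self, well_id: str = "well0") -> pd.DataFrame:
        return pd.DataFrame({
            "well_id": well_id,
            "div_day": self.div_days,
            "f_lo_hz": self.band[0],
            "f_hi_hz": self.band[1],
            "power_uV2": self.power_uV2,
            "log10_ratio": self.log10_ratio,
        })


def extract_lfp(raw, cutoff_hz: float = 500.0,
                downsample_to_hz: float | None = None,
                electrode: int = 0) -> LFPSeries:
    """Zero-phase 4th-order low-pass of one electrode of a raw recording.

    Optionally resamples (anti-aliased polyphase) to ``downsample_to_hz``.
    """
    if cutoff_hz >= raw.fs_hz / 2:
        raise ValueError(
            f"cutoff {cutoff_hz} Hz >= Nyquist {raw.fs_hz / 2} Hz")
    x = np.asarray(raw.voltage_uV)[electrode]
    sos = signal.butter(4, cutoff_hz, btype="low", fs=raw.fs_hz, output="sos")
    y = signal.sosfiltfilt(sos, x)
    fs = raw.fs_hz
    if downsample_to_hz is not None and downsample_to_hz < raw.fs_hz:
        frac = Fraction(downsample_to_hz / raw.fs_hz).limit_denominator(1000)
        y = signal.resample_poly(y, frac.numerator, frac.denominator)
        fs = raw.fs_hz * frac.numerator / frac.denominator
    return LFPSeries(samples_uV=y, fs_hz=fs, div_day=raw.div_day)


def compute_psd(lfp: LFPSeries, segment_s: float = 2.0,
                overlap: float = 0.5) -> SpectralSummary:
    """Welch PSD: averaged Hann-tapered overlapping modified periodograms.

    Density normalization — the integral over frequency approximates the
    signal variance (Parseval).
    """
    nper = int(round(segment_s * lfp.fs_hz))
    if nper > lfp.samples_uV.size:
        raise ValueError("segment longer than the series")
    freqs, psd = signal.welch(lfp.samples_uV, fs=lfp.fs_hz, nperseg=nper,
                              noverlap=int(round(overlap * nper)),
                              window="hann", detrend="constant",
                              scaling="density")
    return SpectralSummary(freqs_hz=freqs, psd_uV2_per_hz=psd,
                           meta={"segment_s": segment_s, "overlap": overlap,
                                 "taper": "hann", "fs_hz": lfp.fs_hz})


def band_power(psd: SpectralSummary, f_lo_hz: float, f_hi_hz: float) -> float:
    """Trapezoidal integral of the PSD over [f_lo, f_hi] (uV^2)."""
    nyq = psd.freqs_hz[-1]
    if not (f_lo_hz < f_hi_hz <= nyq):
        raise ValueError(
            f"need f_lo < f_hi <= Nyquist ({nyq} Hz), got [{f_lo_hz}, {f_hi_hz}]")
    mask = (psd.freqs_hz >= f_lo_hz) & (psd.freqs_hz <= f_hi_hz)
    if mask.sum() < 2:
        raise ValueError("band contains fewer than two frequency bins")
    return float(np.trapezoid(psd.psd_uV2_per_hz[mask], psd.freqs_hz[mask]))


def log_power_ratio_timecourse(recordings: list, band: tuple,
                               segment_s: float = 2.0,
                               overlap: float = 0.5) -> BandPowerTimecourse:
    """log10 band-power ratio of each day to the first recording day.

    ``recordings`` is a list of LFPSeries (sorted by ``div_day``); the first
    day's ratio is exactly 0 by construction.
    """
    if not recordings:
        raise ValueError("need at least one recording day")
    recs = sorted(recordings, key=lambda r: r.div_day)
    powers = np.array([
        band_power(compute_psd(r, segment_s=segment_s, overlap=overlap),
                   band[0], band[1]) for r in recs])
    if powers[0] <= 0:
        raise ValueError("baseline (first-day) band power is zero; "
                         "log ratio undefined")
    ratios = np.log10(powers / powers[0])
    ratios[0] = 0.0
    return BandPowerTimecourse(band=tuple(band),
                               div_days=[r.div_day for r in recs],
                               power_uV2=powers, log10_ratio=ratios)
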