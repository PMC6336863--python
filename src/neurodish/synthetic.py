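"""Synthetic generators for every input the analysis stages consume.

Ground truth is returned alongside each artifact so detection and
quantification stages can be scored without external data:

* multi-electrode spike trains = per-electrode background Poisson firing
  plus network bursts (Poisson onsets; recruited electrodes share a
  "mother" spike train thinned per electrode, so one knob controls both
  burst breadth and within-burst synchrony),
* raw voltage = rendered biphasic spike waveforms + sinusoidal
  oscillations + 1/f^chi noise,
* calcium fluorescence = baseline + difference-of-exponentials transients
  driven by a shared network process (accepted per cell with a coupling
  probability) plus private events and Gaussian noise,
* branching neurite trees grown to a target total length (SWC-writable),
* pre/post synaptic puncta fields with a set colocalization fraction,
  optionally rendered to a two-channel image.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mea import RawRecording, SpikeTrainSet
from .calcium import CalciumTraceSet
from .morphometry import NeuronMorphology, PunctaField

__all__ = [
    "SimulationProfile",
    "CalciumSimProfile",
    "MorphologyParams",
    "PunctaParams",
    "GroundTruthBurst",
    "simulate_spike_trains",
    "synthesize_raw",
    "simulate_calcium",
    "generate_morphology",
    "generate_puncta",
    "render_puncta_image",
]


def _check(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


@dataclass
class SimulationProfile:
    """Parameters of the spike-train generator (one culture well).

    Defaults emulate a healthy mature culture recorded for 30 min on an
    8-electrode well: ~1 Hz background firing and ~6 network bursts/min
    recruiting every electrode.
    """

    n_electrodes: int = 8
    duration_s: float = 1800.0
    base_rate_hz: float = 1.0
    burst_rate_per_min: float = 6.0
    burst_duration_s: float = 0.5
    burst_participation: float = 1.0
    within_burst_rate_hz: float = 50.0
    synchrony_coupling: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("base_rate_hz", "burst_rate_per_min",
                     "within_burst_rate_hz", "burst_duration_s"):
            v = getattr(self, name)
            _check(np.isfinite(v) and v >= 0, f"{name} must be finite and >= 0")
        _check(np.isfinite(self.duration_s) and self.duration_s > 0,
               "duration_s must be positive")
        _check(0 <= self.burst_participation <= 1,
               "burst_participation must be in [0, 1]")
        _check(0 <= self.synchrony_coupling <= 1,
               "synchrony_coupling must be in [0, 1]")
        _check(self.n_electrodes >= 1, "need at least one electrode")


@dataclass
class GroundTruthBurst:
    onset_s: float
    duration_s: float
    recruited: frozenset      #: electrodes drawn for this burst
    realized: frozenset       #: recruited electrodes that actually fired


def simulate_spike_trains(profile: SimulationProfile):
    """Simulate per-electrode spike trains with network bursts.

    Returns
    -------
    spikes : SpikeTrainSet
    bursts : list of GroundTruthBurst
    """
    rng = np.random.default_rng(profile.seed)
    T = profile.duration_s
    n_el = profile.n_electrodes
    per_el = [[] for _ in range(n_el)]

    for el in range(n_el):
        n_bg = rng.poisson(profile.base_rate_hz * T)
        per_el[el].append(rng.uniform(0.0, T, size=n_bg))

    n_bursts = rng.poisson(profile.burst_rate_per_min / 60.0 * T)
    onsets = np.sort(rng.uniform(0.0, max(T - profile.burst_duration_s, 0.0),
                                 size=n_bursts))
    n_recruit = int(round(profile.burst_participation * n_el))
    bursts = []
    for onset in onsets:
        recruited = rng.choice(n_el, size=n_recruit, replace=False)
        n_mother = rng.poisson(profile.within_burst_rate_hz
                               * profile.burst_duration_s)
        mother = onset + np.sort(
            rng.uniform(0.0, profile.burst_duration_s, size=n_mother))
        realized = set()
        for el in recruited:
            keep = rng.random(n_mother) < profile.synchrony_coupling
            if keep.any():
                per_el[el].append(mother[keep])
                realized.add(int(el))
        bursts.append(GroundTruthBurst(
            onset_s=float(onset), duration_s=profile.burst_duration_s,
            recruited=frozenset(int(e) for e in recruited),
            realized=frozenset(realized)))

    trains = [np.unique(np.concatenate(parts)) if parts else np.array([])
              for parts in per_el]
    trains = [t[(t >= 0) & (t < T)] for t in trains]
    return SpikeTrainSet(spikes=trains, duration_s=T), bursts


def _one_over_f_noise(rng: np.random.Generator, n: int, fs: float,
                      exponent: float, sd: float) -> np.ndarray:
    """Gaussian noise with PSD ~ 1/f^exponent, normalized to the given SD."""
    if sd == 0:
        return np.zeros(n)
    white = rng.standard_normal(n)
    if exponent == 0:
        return sd * white
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shaping = np.ones_like(freqs)
    nz = freqs > 0
    shaping[nz] = freqs[nz] ** (-exponent / 2.0)
    shaping[0] = 0.0  # no DC power
    shaped = np.fft.irfft(spec * shaping, n=n)
    s = shaped.std()
    return sd * shaped / s if s > 0 else shaped


def _biphasic_template(fs_hz: float, width_ms: float = 2.0) -> np.ndarray:
    """Biphasic extracellular spike shape, 2 ms, peak normalized to -1."""
    n = max(int(round(width_ms * 1e-3 * fs_hz)), 3)
    t = np.linspace(0.0, 1.0, n)
    w = -np.sin(2 * np.pi * t) * np.exp(-3.0 * t)
    return w / np.max(np.abs(w))


def synthesize_raw(spikes: SpikeTrainSet, fs_hz: float,
                   spike_amp_sigma: float = 10.0,
                   oscillations: list | None = None,
                   noise_sd_uV: float = 3.0,
                   one_over_f_exponent: float = 1.0,
                   seed: int = 0,
                   div_day: int = 0, well_id: str = "well0") -> RawRecording:
    """Render spike trains into a raw voltage recording.

    Each spike becomes a 2 ms biphasic waveform of peak amplitude
    ``spike_amp_sigma * noise_sd_uV``; sinusoidal oscillations
    (``[(freq_hz, amplitude_uV), ...]``) and 1/f^chi noise of SD
    ``noise_sd_uV`` are added.
    """
    oscillations = oscillations or []
    for f, _a in oscillations:
        if f >= fs_hz / 2:
            raise ValueError(
                f"oscillation at {f} Hz aliases (Nyquist {fs_hz / 2} Hz)")
    rng = np.random.default_rng(seed)
    n = int(round(spikes.duration_s * fs_hz))
    tgrid = np.arange(n) / fs_hz
    template = _biphasic_template(fs_hz)
    out = np.empty((spikes.n_electrodes, n))
    osc = np.zeros(n)
    for f, a in oscillations:
        osc += a * np.sin(2 * np.pi * f * tgrid)
    for el, times in enumerate(spikes.spikes):
        v = _one_over_f_noise(rng, n, fs_hz, one_over_f_exponent, noise_sd_uV)
        v += osc
        amp = spike_amp_sigma * noise_sd_uV
        for t in times:
            i0 = int(round(t * fs_hz))
            i1 = min(i0 + template.size, n)
            v[i0:i1] += amp * template[: i1 - i0]
        out[el] = v
    return RawRecording(voltage_uV=out, fs_hz=fs_hz, div_day=div_day,
                        well_id=well_id)


@dataclass
class CalciumSimProfile:
    """Parameters of the calcium-trace generator.

    ``coupling_per_cell`` is the probability each cell accepts a shared
    network event; private events occur independently per cell at
    ``private_event_rate_per_min``.  Transients are difference-of-exponential
    kernels normalized to unit peak, scaled by ``event_amplitude`` (dF/F-like
    units on a baseline of 1).
    """

    n_cells: int = 50
    fs_hz: float = 10.0
    duration_s: float = 600.0
    coupling_per_cell: float | np.ndarray = 0.8
    tau_rise_s: float = 0.2
    tau_decay_s: float = 1.5
    noise_sd: float = 0.02
    event_amplitude: float = 1.0
    private_event_rate_per_min: float = 1.0
    baseline: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        _check(self.tau_decay_s > self.tau_rise_s > 0,
               "need tau_decay_s > tau_rise_s > 0")
        _check(self.noise_sd >= 0, "noise_sd must be >= 0")
        _check(self.fs_hz > 0 and self.duration_s > 0,
               "fs_hz and duration_s must be positive")
        c = np.asarray(self.coupling_per_cell, dtype=float)
        _check(np.all((c >= 0) & (c <= 1)), "coupling must be in [0, 1]")
        if self.fs_hz < 2.0 / self.tau_rise_s:
            raise ValueError(
                "sampling rate too low to resolve tau_rise "
                f"(need fs >= {2.0 / self.tau_rise_s:.1f} Hz)")

    def coupling_array(self) -> np.ndarray:
        c = np.asarray(self.coupling_per_cell, dtype=float)
        if c.ndim == 0:
            c = np.full(self.n_cells, float(c))
        return c


def _calcium_kernel(fs: float, tau_r: float, tau_d: float) -> np.ndarray:
    t = np.arange(0.0, 5.0 * tau_d, 1.0 / fs)
    k = np.exp(-t / tau_d) - np.exp(-t / tau_r)
    return k / k.max()


def simulate_calcium(profile: CalciumSimProfile,
                     drive_event_rate_per_min: float = 6.0):
    """Simulate fluorescence traces driven by a shared network process.

    Returns
    -------
    traces : CalciumTraceSet
    truth : dict with keys ``event_times`` (per-cell list), ``coupled``
        (bool array; coupling probability > 0), ``drive_times``.
    """
    rng = np.random.default_rng(profile.seed)
    n = int(round(profile.duration_s * profile.fs_hz))
    coupling = profile.coupling_array()
    n_drive = rng.poisson(drive_event_rate_per_min / 60.0 * profile.duration_s)
    drive = np.sort(rng.uniform(0.0, profile.duration_s, size=n_drive))
    kernel = _calcium_kernel(profile.fs_hz, profile.tau_rise_s,
                             profile.tau_decay_s)
    F = np.empty((profile.n_cells, n))
    event_times = []
    for cell in range(profile.n_cells):
        accepted = drive[rng.random(n_drive) < coupling[cell]]
        n_priv = rng.poisson(
            profile.private_event_rate_per_min / 60.0 * profile.duration_s)
        private = rng.uniform(0.0, profile.duration_s, size=n_priv)
        events = np.sort(np.concatenate([accepted, private]))
        impulse = np.zeros(n)
        idx = np.minimum((events * profile.fs_hz).astype(int), n - 1)
        np.add.at(impulse, idx, profile.event_amplitude)
        trace = profile.baseline + np.convolve(impulse, kernel)[:n]
        if profile.noise_sd > 0:
            trace = trace + rng.normal(0.0, profile.noise_sd, size=n)
        F[cell] = trace
        event_times.append(events)
    truth = {"event_times": event_times, "coupled": coupling > 0,
             "drive_times": drive}
    return CalciumTraceSet(F=F, fs_hz=profile.fs_hz), truth


@dataclass
class MorphologyParams:
    """Parameters of the random-neuron generator.

    Trees are grown segment by segment from ``n_primary_neurites`` radial
    trunks, branching with probability ``branch_prob`` per segment, until
    the total neurite length reaches ``target_total_length_um`` (within
    10%). Defaults target a healthy cultured projection neuron:
    ~3 primary neurites and ~850 um total outgrowth.
    """

    n_primary_neurites: int = 3
    mean_segment_um: float = 10.0
    branch_prob: float = 0.3
    target_total_length_um: float = 848.0
    soma_radius_um: float = 9.0
    seed: int = 0

    def __post_init__(self) -> None:
        _check(self.mean_segment_um > 0 and self.target_total_length_um > 0
               and self.soma_radius_um > 0, "lengths must be positive")
        _check(0 <= self.branch_prob <= 1, "branch_prob must be in [0, 1]")
        _check(self.n_primary_neurites >= 1, "need >= 1 primary neurite")
        if self.target_total_length_um < self.mean_segment_um:
            raise ValueError("target length smaller than one segment")


def generate_morphology(params: MorphologyParams) -> NeuronMorphology:
    """Grow a random branching neurite tree to a target total length."""
    rng = np.random.default_rng(params.seed)
    nodes = [(1, 1, 0.0, 0.0, 0.0, params.soma_radius_um, -1)]  # soma root
    next_id = 2
    total = 0.0
    # each tip: (node id, position, direction)
    tips = []
    for k in range(params.n_primary_neurites):
        theta = 2 * np.pi * k / params.n_primary_neurites \
            + rng.uniform(-0.2, 0.2)
        tips.append((1, np.zeros(3),
                     np.array([np.cos(theta), np.sin(theta), 0.0])))
    target = params.target_total_length_um
    while total < 0.98 * target and tips:
        i = int(rng.integers(len(tips)))
        parent_id, pos, direction = tips.pop(i)
        seg = min(rng.gamma(4.0, params.mean_segment_um / 4.0),
                  max(target - total, 1e-6))
        phi = rng.normal(0.0, 0.3)
        c, s = np.cos(phi), np.sin(phi)
        d = np.array([c * direction[0] - s * direction[1],
                      s * direction[0] + c * direction[1], 0.0])
        new_pos = pos + seg * d
        nodes.append((next_id, 3, float(new_pos[0]), float(new_pos[1]),
                      float(new_pos[2]), 0.5, parent_id))
        total += seg
        tips.append((next_id, new_pos, d))
        if rng.random() < params.branch_prob:
            ang = rng.uniform(0.4, 1.0) * rng.choice([-1.0, 1.0])
            c2, s2 = np.cos(ang), np.sin(ang)
            d2 = np.array([c2 * d[0] - s2 * d[1],
                           s2 * d[0] + c2 * d[1], 0.0])
            tips.append((next_id, new_pos, d2))
        next_id += 1
    return NeuronMorphology.from_rows(nodes)


@dataclass
class PunctaParams:
    """Parameters of the synaptic-puncta field generator.

    Pre (e.g. VGLUT1) and post (e.g. HOMER1) puncta are placed along a
    straight neurite path; a ``colocalization_fraction`` of pre puncta get a
    post partner within ``jitter_um``.  Densities default to the scale seen
    on healthy cultured neurites (~0.22 colocalized pairs/um = 11 per 50 um).
    """

    neurite_length_um: float = 50.0
    pre_density_per_um: float = 0.3
    post_density_per_um: float = 0.3
    colocalization_fraction: float = 0.7
    jitter_um: float = 0.2
    pixel_size_um: float = 0.1
    image_shape: tuple = (128, 640)
    psf_sigma_um: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        _check(self.pre_density_per_um >= 0 and self.post_density_per_um >= 0,
               "densities must be >= 0")
        _check(0 <= self.colocalization_fraction <= 1,
               "colocalization_fraction must be in [0, 1]")
        _check(self.neurite_length_um > 0, "neurite length must be positive")
        if self.image_shape[1] * self.pixel_size_um < self.neurite_length_um:
            raise ValueError("image too small for the neurite length")


def generate_puncta(params: PunctaParams):
    """Place pre/post puncta on a straight neurite with known colocalization.

    Returns
    -------
    field : PunctaField
    truth : dict with ``n_colocalized`` (number of planted pairs) and the
        planted point sets.
    """
    rng = np.random.default_rng(params.seed)
    L = params.neurite_length_um
    width = 2.0  # um of lateral scatter about the neurite midline
    y0 = params.image_shape[0] * params.pixel_size_um / 2.0

    n_pre = rng.poisson(params.pre_density_per_um * L)
    pre = np.column_stack([rng.uniform(0.0, L, n_pre),
                           y0 + rng.uniform(-width / 2, width / 2, n_pre)])
    n_coloc = int(round(params.colocalization_fraction * n_pre))
    partner_idx = rng.choice(n_pre, size=n_coloc, replace=False) \
        if n_pre else np.array([], dtype=int)
    partners = pre[partner_idx] + rng.normal(
        0.0, params.jitter_um / np.sqrt(2.0), size=(n_coloc, 2)) \
        if params.jitter_um > 0 else pre[partner_idx].copy()
    n_post_extra = rng.poisson(
        max(params.post_density_per_um * L - n_coloc, 0.0))
    extra = np.column_stack([
        rng.uniform(0.0, L, n_post_extra),
        y0 + rng.uniform(-width / 2, width / 2, n_post_extra)])
    post = np.vstack([partners, extra]) if (n_coloc or n_post_extra) \
        else np.empty((0, 2))
    path = np.array([[0.0, y0], [L, y0]])
    field = PunctaField(pre_points_um=pre, post_points_um=post,
                        neurite_path_um=path)
    truth = {"n_colocalized": n_coloc, "pre": pre, "post": post}
    return field, truth


def render_puncta_image(field: PunctaField, params: PunctaParams,
                        peak: float = 1000.0,
                        background: float = 100.0,
                        noise_sd: float = 0.0,
                        seed: int = 0) -> np.ndarray:
    """Render a puncta field to a (2, H, W) image: channel 0 pre, 1 post.

    Each punctum is a Gaussian spot of SD ``psf_sigma_um``.
    """
    rng = np.random.default_rng(seed)
    h, w = params.image_shape
    img = np.full((2, h, w), background, dtype=float)
    yy, xx = np.mgrid[0:h, 0:w]
    sig_px = params.psf_sigma_um / params.pixel_size_um
    for ch, pts in enumerate([field.pre_points_um, field.post_points_um]):
        for x_um, y_um in pts:
            cx = x_um / params.pixel_size_um
            cy = y_um / params.pixel_size_um
            r2 = (xx - cx) ** 2 + (yy - cy) ** 2
            img[ch] += peak * np.exp(-r2 / (2 * sig_px ** 2))
    if noise_sd > 0:
        img += rng.normal(0.0, noise_sd, size=img.shape)
    return img
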