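"""Synthetic EEG generator with ground-truth blinks and BRO signatures.

Emulates the acquisition conditions of a 19-channel 10/20 recording with
bipolar VEOG/HEOG at 256 Hz during a multi-level workload task:

* background: 1/f ("pink") broadband noise per channel, a posterior-dominant
  alpha rhythm (8-12 Hz) and theta rhythm (4-7 Hz), 60 Hz line noise, and
  independent white sensor noise;
* blinks: a renewal process whose rate depends on the workload level
  (defaults 19.4 / 16.0 / 11.9 blinks/min for low/medium/high), each blink
  injecting a frontally-mixed raised-cosine-squared VEOG artifact (>250 uV);
* BRO: a posterior-dominant delta-band dual-peak waveform (positive C1 near
  +300 ms, negative C2 near +550 ms) whose amplitude depends on workload,
  an additive beta-band (20 Hz) burst shortly after the blink (event-related
  synchronization), and multiplicative attenuation of the theta and alpha
  rhythms post-blink plus a pre-blink theta dip near -500 ms (event-related
  desynchronization). The pre-blink theta ERD weakens with workload.

Everything is deterministic under the config seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .core_io import (ALL_CHANNELS, EEG_CHANNELS, BlinkEvent, Recording,
                      TRANSITION, WORKLOAD_LEVELS)

# Spatial gain maps on the 10/20 montage. The artifact map decays from the
# periocular frontal sites toward occipital; the BRO map is the converse,
# peaking over the parieto-occipital cortex (precuneus-adjacent electrodes).
FRONTAL_ARTIFACT_GAIN: dict[str, float] = {
    "Fp1": 1.0, "Fp2": 1.0, "F7": 0.75, "F3": 0.8, "Fz": 0.85, "F4": 0.8,
    "F8": 0.75, "T3": 0.3, "C3": 0.45, "Cz": 0.5, "C4": 0.45, "T4": 0.3,
    "T5": 0.15, "P3": 0.12, "Pz": 0.12, "P4": 0.12, "T6": 0.15,
    "O1": 0.05, "O2": 0.05, "VEOG": 1.0, "HEOG": 0.1,
}
POSTERIOR_BRO_GAIN: dict[str, float] = {
    "Fp1": 0.02, "Fp2": 0.02, "F7": 0.02, "F3": 0.03, "Fz": 0.05, "F4": 0.03,
    "F8": 0.02, "T3": 0.15, "C3": 0.3, "Cz": 0.35, "C4": 0.3, "T4": 0.15,
    "T5": 0.5, "P3": 0.8, "Pz": 1.0, "P4": 0.8, "T6": 0.5,
    "O1": 0.9, "O2": 0.9, "VEOG": 0.0, "HEOG": 0.0,
}
# Spatial weights of the ongoing alpha/theta rhythms (posterior dominant).
RHYTHM_GAIN: dict[str, float] = {
    "Fp1": 0.25, "Fp2": 0.25, "F7": 0.3, "F3": 0.35, "Fz": 0.4, "F4": 0.35,
    "F8": 0.3, "T3": 0.5, "C3": 0.6, "Cz": 0.65, "C4": 0.6, "T4": 0.5,
    "T5": 0.85, "P3": 0.9, "Pz": 1.0, "P4": 0.9, "T6": 0.85,
    "O1": 1.0, "O2": 1.0, "VEOG": 0.0, "HEOG": 0.0,
}


@dataclass
class SynthConfig:
    """Study-condition parameters of the generator (all rates/amps > 0)."""

    duration_s: float = 300.0
    fs: float = 256.0
    blink_rate_per_min: dict[str, float] = field(default_factory=lambda: {
        "low": 19.4, "medium": 16.0, "high": 11.9})
    refractory_s: float = 0.5
    isolation_fraction: float = 0.7
    artifact_peak_uv: float = 300.0
    artifact_width_s: float = 0.35
    bro_amplitude_uv: dict[str, float] = field(default_factory=lambda: {
        "low": 3.0, "medium": 2.5, "high": 2.0})
    beta_ers_uv: dict[str, float] = field(default_factory=lambda: {
        "low": 3.0, "medium": 2.5, "high": 1.5})
    theta_pre_erd_depth: dict[str, float] = field(default_factory=lambda: {
        "low": 0.6, "medium": 0.45, "high": 0.2})
    theta_post_erd_depth: float = 0.5
    alpha_post_erd_depth: float = 0.45
    pink_exponent: float = 1.0
    pink_scale_uv: float = 6.0
    alpha_amp_uv: float = 6.0
    theta_amp_uv: float = 4.0
    line_amp_uv: float = 2.0
    sensor_noise_uv: float = 2.0
    eog_noise_uv: float = 5.0
    scalp_artifact: bool = True
    segment_plan: list[tuple[str, float]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0 or self.fs <= 0:
            raise ValueError("duration_s and fs must be positive")
        if self.artifact_peak_uv <= 0 or self.artifact_width_s <= 0:
            raise ValueError("artifact peak and width must be positive")
        if any(v < 0 for v in self.blink_rate_per_min.values()):
            raise ValueError("blink rates must be non-negative")
        if not self.segment_plan:
            self.segment_plan = [("low", self.duration_s)]
        total = sum(d for _, d in self.segment_plan)
        if abs(total - self.duration_s) > 1e-6:
            raise ValueError("segment durations must sum to duration_s")
        for w, d in self.segment_plan:
            if d <= 0:
                raise ValueError("segment durations must be positive")
            if w not in WORKLOAD_LEVELS and w != TRANSITION:
                raise ValueError(f"unknown workload {w!r}")

    @classmethod
    def preset(cls, name: str, duration_s: float = 300.0, seed: int = 0,
               **overrides) -> "SynthConfig":
        """Named presets: single-workload low/medium/high, mixed, no_bro.

        ``mixed`` cycles low/medium/high segments separated by 2 s unlabeled
        transitions; ``no_bro`` keeps the blink artifact but injects no BRO
        (kernel gain zero) - the negative control for presence testing;
        ``null_tf`` additionally removes the scalp projection of the blink
        artifact (it stays on the EOG channels so detection still works) -
        the exchangeability control for trial-level time-frequency
        statistics, where even sub-microvolt residual ocular delta after ICA
        is detectable.
        """
        zero = {w: 0.0 for w in WORKLOAD_LEVELS}
        if name in WORKLOAD_LEVELS:
            plan = [(name, duration_s)]
        elif name == "mixed":
            gap = 2.0
            seg = (duration_s - 2 * gap) / 3.0
            if seg <= 0:
                raise ValueError("mixed preset needs duration > 4 s")
            plan = [("low", seg), (TRANSITION, gap), ("medium", seg),
                    (TRANSITION, gap), ("high", seg)]
        elif name in ("no_bro", "null_tf"):
            plan = [("low", duration_s)]
            overrides.setdefault("bro_amplitude_uv", dict(zero))
            overrides.setdefault("beta_ers_uv", dict(zero))
            overrides.setdefault("theta_pre_erd_depth", dict(zero))
            overrides.setdefault("theta_post_erd_depth", 0.0)
            overrides.setdefault("alpha_post_erd_depth", 0.0)
            if name == "null_tf":
                overrides.setdefault("scalp_artifact", False)
        else:
            raise ValueError(f"unknown preset {name!r}")
        return cls(duration_s=duration_s, segment_plan=plan, seed=seed,
                   **overrides)


@dataclass
class GroundTruth:
    """What was injected: true blink events and per-segment labels."""

    events: list[BlinkEvent]
    segment_plan: list[tuple[str, float]]
    config: SynthConfig

    def to_dict(self) -> dict:
        return {
            "events": [e.as_row() for e in self.events],
            "segment_plan": [[w, d] for w, d in self.segment_plan],
            "config": {k: v for k, v in dataclasses.asdict(self.config).items()
                       if k != "segment_plan"},
        }


# ---------------------------------------------------------------------------
# kernels
# ---------------------------------------------------------------------------

def blink_artifact_kernel(t: np.ndarray, peak_uv: float = 300.0,
                          width_s: float = 0.35) -> np.ndarray:
    """Raised-cosine-squared ocular artifact pulse.

    Smooth, unimodal, positive; exact maximum ``peak_uv`` at t=0; support
    [-width_s, +width_s] with zero value and slope at the edges.
    """
    if peak_uv <= 0 or width_s <= 0:
        raise ValueError("peak and width must be positive")
    if not (0.1 < width_s < 0.6):
        raise ValueError("width_s must lie in (0.1, 0.6) s")
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    inside = np.abs(t) < width_s
    out[inside] = peak_uv * np.cos(np.pi * t[inside] / (2 * width_s)) ** 2
    return out


def bro_delta_kernel(t: np.ndarray, amplitude_uv: float) -> np.ndarray:
    """Delta-band dual-peak BRO waveform at unit posterior gain.

    Positive C1 peak at +300 ms and a negative C2 trough at +550 ms (the
    polarity observed under a left-mastoid reference), built from two
    Gaussian lobes (sigma 120 ms) so the spectral energy is concentrated in
    the 0.5-4 Hz band and does not leak into theta.
    """
    t = np.asarray(t, dtype=float)
    sigma = 0.12
    c1 = np.exp(-0.5 * ((t - 0.30) / sigma) ** 2)
    c2 = np.exp(-0.5 * ((t - 0.55) / sigma) ** 2)
    return amplitude_uv * (c1 - 0.85 * c2)


def beta_burst_kernel(t: np.ndarray, amplitude_uv: float,
                      freq_hz: float = 20.0, center_s: float = 0.15,
                      sigma_s: float = 0.08) -> np.ndarray:
    """Gaussian-windowed beta burst (post-blink ERS) at unit gain."""
    t = np.asarray(t, dtype=float)
    env = np.exp(-0.5 * ((t - center_s) / sigma_s) ** 2)
    return amplitude_uv * env * np.sin(2 * np.pi * freq_hz * (t - center_s))


def bro_kernel(t: np.ndarray, channel_label: str, workload: str,
               cfg: SynthConfig) -> np.ndarray:
    """Additive part of the injected BRO at one channel (delta + beta ERS).

    The multiplicative ERD on the ongoing theta/alpha rhythms is applied
    during synthesis (see :func:`generate_recording`) because a power
    decrease of an ongoing rhythm cannot be represented additively.
    """
    if channel_label not in POSTERIOR_BRO_GAIN:
        raise KeyError(f"unknown channel {channel_label!r}")
    gain = POSTERIOR_BRO_GAIN[channel_label]
    return gain * (bro_delta_kernel(t, cfg.bro_amplitude_uv[workload])
                   + beta_burst_kernel(t, cfg.beta_ers_uv[workload]))


# ---------------------------------------------------------------------------
# blink times
# ---------------------------------------------------------------------------

ISOLATION_MARGIN_S = 3.4  # hard floor for "long" gaps; > the 3.2 s target


def sample_blink_times(segment_plan: list[tuple[str, float]],
                       rates: dict[str, float], refractory_s: float = 0.5,
                       isolation_fraction: float = 0.7,
                       seed: int | np.random.Generator = 0) -> np.ndarray:
    """Blink times (s) from a per-segment renewal process.

    Inter-blink gaps are a two-state mixture: with probability
    ``q = 1 - sqrt(isolation_fraction)`` a short "cluster" gap (uniform
    between the refractory period and 1 s), otherwise a long gap of
    3.4 s + gamma(shape 2). The long-gap mean is solved so the overall mean
    gap equals 60/rate, which pins the realized rate to the configured one
    while guaranteeing that at least ``isolation_fraction`` of blinks have
    >= 3.2 s to both neighbors in expectation.
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    times: list[float] = []
    t0 = 0.0
    for workload, dur in segment_plan:
        rate = rates.get(workload, 0.0)
        if workload == TRANSITION or rate <= 0:
            t0 += dur
            continue
        mean_gap = 60.0 / rate
        q = 1.0 - np.sqrt(np.clip(isolation_fraction, 0.0, 1.0))
        short_mean = (refractory_s + 1.0) / 2.0
        long_mean = (mean_gap - q * short_mean) / (1.0 - q)
        if long_mean <= ISOLATION_MARGIN_S:
            raise ValueError(
                f"rate {rate}/min incompatible with isolation_fraction "
                f"{isolation_fraction} and refractory {refractory_s} s")
        t = t0 + rng.uniform(0.5, mean_gap)
        end = t0 + dur
        while t < end - 0.5:
            times.append(t)
            if rng.random() < q:
                gap = rng.uniform(refractory_s, 1.0)
            else:
                gap = ISOLATION_MARGIN_S + rng.gamma(
                    2.0, (long_mean - ISOLATION_MARGIN_S) / 2.0)
            t += gap
        t0 = end
    return np.asarray(times)


# ---------------------------------------------------------------------------
# noise components
# ---------------------------------------------------------------------------

def _pink_noise(rng: np.random.Generator, n: int, fs: float,
                exponent: float) -> np.ndarray:
    """Unit-variance 1/f^exponent noise via spectral shaping."""
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    shape = np.zeros_like(freqs)
    nz = freqs > 0
    shape[nz] = freqs[nz] ** (-exponent / 2.0)
    phases = rng.standard_normal(len(freqs)) + 1j * rng.standard_normal(len(freqs))
    x = np.fft.irfft(shape * phases, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _narrowband(rng: np.random.Generator, n: int, fs: float, low: float,
                high: float) -> np.ndarray:
    """Unit-variance band-limited Gaussian noise (an ongoing rhythm)."""
    from scipy import signal

    sos = signal.butter(4, [low, high], btype="bandpass", fs=fs, output="sos")
    x = signal.sosfilt(sos, rng.standard_normal(n + int(4 * fs)))[int(4 * fs):]
    sd = x.std()
    return x / sd if sd > 0 else x


def _erd_envelope(n: int, fs: float, blink_samples: np.ndarray,
                  depths: np.ndarray, center_s: float,
                  sigma_s: float) -> np.ndarray:
    """Multiplicative gain (<=1) dipping around each blink."""
    env = np.ones(n)
    half = int(round(4 * sigma_s * fs))
    kernel_t = np.arange(-half, half + 1) / fs
    kernel = np.exp(-0.5 * ((kernel_t - center_s) / sigma_s) ** 2)
    for s, d in zip(blink_samples, depths):
        lo = s - half
        hi = s + half + 1
        klo = max(0, -lo)
        khi = len(kernel) - max(0, hi - n)
        lo = max(lo, 0)
        hi = min(hi, n)
        if lo < hi:
            env[lo:hi] -= d * kernel[klo:khi]
    return np.clip(env, 0.05, None)


# ---------------------------------------------------------------------------
# full recording
# ---------------------------------------------------------------------------

def generate_recording(cfg: SynthConfig) -> tuple[Recording, GroundTruth]:
    """Synthesize a Recording plus its GroundTruth, deterministic under seed."""
    rng = np.random.default_rng(cfg.seed)
    fs = cfg.fs
    n = int(round(cfg.duration_s * fs))
    channels = list(ALL_CHANNELS)
    n_ch = len(channels)

    # per-sample workload labels
    workload = np.full(n, TRANSITION, dtype="<U10")
    pos = 0
    for w, d in cfg.segment_plan:
        stop = min(n, pos + int(round(d * fs)))
        workload[pos:stop] = w
        pos = stop

    # blink times and their labels
    times = sample_blink_times(cfg.segment_plan, cfg.blink_rate_per_min,
                               cfg.refractory_s, cfg.isolation_fraction, rng)
    samples = np.round(times * fs).astype(int)
    samples = samples[(samples >= 0) & (samples < n)]
    blink_workloads = workload[samples]

    data = np.zeros((n_ch, n))

    # broadband 1/f background, independent per channel
    for i in range(n_ch):
        scale = cfg.pink_scale_uv if channels[i] in EEG_CHANNELS \
            else cfg.eog_noise_uv
        data[i] += scale * rng.uniform(0.85, 1.15) * _pink_noise(
            rng, n, fs, cfg.pink_exponent)

    # ongoing rhythms: one coherent source each, ERD-modulated, spatially mixed
    theta_src = cfg.theta_amp_uv * _narrowband(rng, n, fs, 4.0, 7.0)
    alpha_src = cfg.alpha_amp_uv * _narrowband(rng, n, fs, 8.0, 12.0)
    pre_depths = np.array([cfg.theta_pre_erd_depth.get(w, 0.0)
                           for w in blink_workloads])
    theta_env = (_erd_envelope(n, fs, samples, pre_depths, -0.5, 0.12)
                 * _erd_envelope(n, fs, samples,
                                 np.full(len(samples), cfg.theta_post_erd_depth),
                                 0.5, 0.15))
    alpha_env = _erd_envelope(n, fs, samples,
                              np.full(len(samples), cfg.alpha_post_erd_depth),
                              0.4, 0.15)
    theta_mod = theta_src * theta_env
    alpha_mod = alpha_src * alpha_env
    for i, ch in enumerate(channels):
        g = RHYTHM_GAIN[ch]
        if g:
            data[i] += g * (theta_mod + alpha_mod)

    # 60 Hz line noise, common phase
    tax = np.arange(n) / fs
    if cfg.line_amp_uv > 0:
        line = cfg.line_amp_uv * np.sin(2 * np.pi * 60.0 * tax)
        for i, ch in enumerate(channels):
            data[i] += line * rng.uniform(0.8, 1.2)

    # independent white sensor noise
    data += cfg.sensor_noise_uv * rng.standard_normal((n_ch, n))

    # blink artifact + additive BRO kernels, time-locked to each blink
    half_art = int(round(cfg.artifact_width_s * fs))
    t_art = np.arange(-half_art, half_art + 1) / fs
    art = blink_artifact_kernel(t_art, cfg.artifact_peak_uv,
                                cfg.artifact_width_s)
    half_bro = int(round(1.2 * fs))
    t_bro = np.arange(-half_bro, half_bro + 1) / fs
    art_gains = np.array([FRONTAL_ARTIFACT_GAIN[c] for c in channels])
    if not cfg.scalp_artifact:
        art_gains = np.where([c in EEG_CHANNELS for c in channels], 0.0,
                             art_gains)
    bro_gains = np.array([POSTERIOR_BRO_GAIN[c] for c in channels])
    for s, w in zip(samples, blink_workloads):
        _add_window(data, art_gains[:, None] * art[None, :], s - half_art)
        if w in WORKLOAD_LEVELS:
            wave = (bro_delta_kernel(t_bro, cfg.bro_amplitude_uv[w])
                    + beta_burst_kernel(t_bro, cfg.beta_ers_uv[w]))
            _add_window(data, bro_gains[:, None] * wave[None, :], s - half_bro)

    events = _as_events(samples, times[:len(samples)], data, channels, fs,
                        blink_workloads)
    rec = Recording(data=data, fs=fs, channel_labels=channels,
                    reference="left mastoid", workload=workload,
                    meta={"synthetic": True, "seed": cfg.seed})
    truth = GroundTruth(events=events, segment_plan=list(cfg.segment_plan),
                        config=cfg)
    return rec, truth


def _add_window(data: np.ndarray, block: np.ndarray, start: int) -> None:
    """Add a channels-x-width block into data with edge clipping."""
    n = data.shape[1]
    width = block.shape[1]
    lo = max(start, 0)
    hi = min(start + width, n)
    if lo < hi:
        data[:, lo:hi] += block[:, lo - start:hi - start]


def _as_events(samples: np.ndarray, times: np.ndarray, data: np.ndarray,
               channels: list[str], fs: float,
               workloads: np.ndarray) -> list[BlinkEvent]:
    veog = data[channels.index("VEOG")]
    events = []
    for i, s in enumerate(samples):
        prev_gap = (samples[i] - samples[i - 1]) / fs if i > 0 else np.inf
        next_gap = (samples[i + 1] - samples[i]) / fs \
            if i < len(samples) - 1 else np.inf
        events.append(BlinkEvent(
            sample=int(s), time_s=float(s / fs),
            amplitude=float(veog[s]),
            isolated=bool(prev_gap > 3.0 and next_gap > 3.0),
            workload=str(workloads[i])))
    return events
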