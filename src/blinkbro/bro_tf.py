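"""Time-frequency BRO analysis: Morlet CWT log power and permutation maps.

Each blink-locked epoch at one channel is decomposed with a 6-cycle complex
Morlet wavelet on a 40-point log-spaced grid from 0.5 to 30 Hz (covering the
delta/theta/alpha/beta bands with >=6 points per band). Coefficients are
normalized so a unit-amplitude sinusoid at a grid frequency produces a ridge
of squared magnitude ~1, making log power directly interpretable as log
amplitude-squared in uV^2. Epochs are reflect-padded before convolution by
the half-support of the slowest wavelet, which is what makes the baseline
window usable up to the epoch edge at -1500 ms.

Log power is ln(|coef|^2 + eps) with eps = 1e-12 uV^2; baseline correction
subtracts each trial's mean log power over -1500..-500 ms per frequency.
Significance maps come from cell-wise paired t-statistics with permutation
nulls (sign flips of within-trial or within-subject pairings), using the
add-one p-value rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import signal

from .core_io import EpochSet
from .stats import paired_t_map, signflip_t_pvalues

EPS_FLOOR = 1e-12

#: Canonical frequency bands (Hz).
BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 7.0),
    "alpha": (8.0, 12.0),
    "beta": (15.0, 30.0),
}


def default_freqs(n: int = 40, low: float = 0.5,
                  high: float = 30.0) -> np.ndarray:
    """Log-spaced CWT frequency grid."""
    return np.geomspace(low, high, n)


def morlet_cwt(epochs: np.ndarray, fs: float,
               freqs: np.ndarray | None = None,
               n_cycles: float = 6.0) -> np.ndarray:
    """Complex Morlet CWT of one or more single-channel epochs.

    Parameters
    ----------
    epochs : ndarray, shape (..., n_times)
        One or a batch of single-channel series.
    fs : float
        Sampling rate in Hz.
    freqs : ndarray
        Strictly increasing analysis frequencies within (0, fs/2).
    n_cycles : float
        Wavelet width in cycles; 6 trades ~1 cycle of temporal smearing for
        clean band separation.

    Returns
    -------
    coefs : complex ndarray, shape (..., n_freqs, n_times)
    """
    x = np.atleast_2d(np.asarray(epochs, dtype=float))
    if freqs is None:
        freqs = default_freqs()
    freqs = np.asarray(freqs, dtype=float)
    if np.any(np.diff(freqs) <= 0):
        raise ValueError("freqs must be strictly increasing")
    if freqs[0] <= 0 or freqs[-1] >= fs / 2:
        raise ValueError("freqs must lie within (0, fs/2)")

    n_times = x.shape[-1]
    pad = int(np.ceil(n_cycles / (2.0 * freqs[0]) * fs))
    xp = np.pad(x, [(0, 0)] * (x.ndim - 1) + [(pad, pad)], mode="reflect")

    out = np.empty(x.shape[:-1] + (len(freqs), n_times), dtype=complex)
    for i, f in enumerate(freqs):
        sigma = n_cycles / (2.0 * np.pi * f)
        half = int(np.ceil(5.0 * sigma * fs))
        t = np.arange(-half, half + 1) / fs
        wavelet = np.exp(2j * np.pi * f * t) * np.exp(-t * t / (2 * sigma ** 2))
        # unit sinusoid at f -> |coef| ~= 1
        norm = 0.5 * np.sqrt(2.0 * np.pi) * sigma * fs
        conv = signal.fftconvolve(xp, np.conj(wavelet[::-1])[None, :],
                                  mode="same", axes=-1)
        out[..., i, :] = conv[..., pad:pad + n_times] / norm
    if np.asarray(epochs).ndim == 1:
        return out[0]
    return out


@dataclass
class TFMap:
    """Per-epoch log-power maps [epochs x frequencies x samples] at a channel."""

    power: np.ndarray
    freqs: np.ndarray
    times_ms: np.ndarray
    channel: str
    baseline_corrected: bool = False
    baseline_window_ms: tuple[float, float] | None = None
    workloads: list[str] = field(default_factory=list)
    eps_floor: float = EPS_FLOOR

    def __post_init__(self) -> None:
        self.power = np.asarray(self.power, dtype=float)
        if self.power.ndim != 3:
            raise ValueError("power must be [epochs x freqs x samples]")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("frequency grid must be strictly increasing")

    @property
    def n_epochs(self) -> int:
        return self.power.shape[0]

    def mean_map(self) -> np.ndarray:
        return self.power.mean(axis=0)


def log_power(coefs: np.ndarray, freqs: np.ndarray, times_ms: np.ndarray,
              channel: str = "Pz",
              workloads: list[str] | None = None) -> TFMap:
    """Natural-log squared magnitude with a tiny positive floor."""
    if not np.all(np.isfinite(coefs)):
        raise ValueError("non-finite CWT coefficients")
    p = np.log(np.abs(coefs) ** 2 + EPS_FLOOR)
    if p.ndim == 2:
        p = p[None]
    return TFMap(power=p, freqs=np.asarray(freqs), times_ms=np.asarray(times_ms),
                 channel=channel, workloads=list(workloads or []))


def epochs_to_tfmap(epochs: EpochSet, channel: str = "Pz",
                    freqs: np.ndarray | None = None,
                    n_cycles: float = 6.0) -> TFMap:
    """CWT log power of every epoch at one channel."""
    if freqs is None:
        freqs = default_freqs()
    coefs = morlet_cwt(epochs.channel(channel), epochs.fs, freqs, n_cycles)
    return log_power(coefs, freqs, epochs.times * 1000.0, channel=channel,
                     workloads=list(epochs.workloads))


def baseline_correct(tf: TFMap,
                     window_ms: tuple[float, float] = (-1500.0, -500.0)
                     ) -> TFMap:
    """Subtract each trial's mean baseline log power per frequency."""
    if tf.baseline_corrected:
        raise ValueError("TFMap already baseline-corrected")
    sel = (tf.times_ms >= window_ms[0]) & (tf.times_ms <= window_ms[1])
    if not sel.any():
        raise ValueError(f"baseline window {window_ms} outside epoch")
    base = tf.power[:, :, sel].mean(axis=2, keepdims=True)
    return TFMap(power=tf.power - base, freqs=tf.freqs, times_ms=tf.times_ms,
                 channel=tf.channel, baseline_corrected=True,
                 baseline_window_ms=window_ms, workloads=list(tf.workloads),
                 eps_floor=tf.eps_floor)


# ---------------------------------------------------------------------------
# permutation statistics
# ---------------------------------------------------------------------------

@dataclass
class TFSignificance:
    """Cell-wise t map with permutation p-values over a time-offset grid."""

    t: np.ndarray                 # freqs x offsets
    p: np.ndarray
    significant: np.ndarray
    freqs: np.ndarray
    offsets_ms: np.ndarray        # offset within the compared windows
    alpha: float
    contrast: str


def _window_slab(tf: TFMap, window_ms: tuple[float, float]) -> np.ndarray:
    sel = (tf.times_ms >= window_ms[0]) & (tf.times_ms <= window_ms[1])
    if not sel.any():
        raise ValueError(f"window {window_ms} ms outside epoch")
    return tf.power[:, :, sel]


def permutation_prepost(tf: TFMap,
                        pre_window_ms: tuple[float, float] = (-1350.0, -150.0),
                        post_window_ms: tuple[float, float] = (150.0, 1350.0),
                        n_perm: int = 1000, alpha: float = 0.05,
                        seed: int | None = None) -> TFSignificance:
    """Pre- vs post-blink presence test on a baseline-corrected TF map.

    The windows are mirror images around the blink (equal duration,
    disjoint), and cells are paired by mirrored latency: post-blink +t
    against pre-blink -t. Mirrored pairing puts both members of every pair
    at the same distance from their epoch edge, so the slight low-frequency
    power bias that reflect-padding induces near the edges cancels exactly
    in the difference; with index-aligned (non-mirrored) windows that bias
    masquerades as delta-band effects on pure noise.

    For each (frequency, post-window time) cell, a paired t across trials
    tests post minus mirrored pre; the null swaps pre/post labels within
    trial (sign flips), 1000 times by default. Positive t = post-blink
    synchronization, negative = desynchronization. ``offsets_ms`` on the
    result are post-blink latencies.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if pre_window_ms[1] > post_window_ms[0]:
        raise ValueError("pre and post windows must be disjoint")
    pre = _window_slab(tf, pre_window_ms)
    post = _window_slab(tf, post_window_ms)
    L = min(pre.shape[2], post.shape[2])
    if abs(pre.shape[2] - post.shape[2]) > 1:
        raise ValueError("pre and post windows must have equal duration")
    diff = post[:, :, :L] - pre[:, :, ::-1][:, :, :L]
    n_e, n_f = diff.shape[:2]
    t_obs, p = signflip_t_pvalues(diff.reshape(n_e, -1), n_perm=n_perm,
                                  seed=seed)
    t_obs = t_obs.reshape(n_f, L)
    p = p.reshape(n_f, L)
    sel = (tf.times_ms >= post_window_ms[0]) & (tf.times_ms <= post_window_ms[1])
    offsets = tf.times_ms[sel][:L]
    return TFSignificance(t=t_obs, p=p, significant=p < alpha,
                          freqs=tf.freqs, offsets_ms=offsets,
                          alpha=alpha, contrast="post vs mirrored pre")


def permutation_workload(subject_maps: dict[str, np.ndarray],
                         n_perm: int = 1000, alpha: float = 0.05,
                         n_comparisons: int | None = None,
                         seed: int | None = None
                         ) -> dict[tuple[str, str], TFSignificance]:
    """Workload contrasts on subject-level mean TF maps.

    ``subject_maps[w]`` is a subjects x freqs x samples array of per-subject
    mean baseline-corrected log power for workload ``w`` (same subjects in
    the same order across workloads). For each workload pair a cell-wise
    paired t across subjects is compared against a within-subject label
    permutation (sign-flip) null; the significance threshold is Bonferroni
    alpha / n_comparisons.
    """
    labels = list(subject_maps)
    if len(labels) < 2:
        raise ValueError("need at least two workload levels")
    shapes = {subject_maps[w].shape for w in labels}
    if len(shapes) != 1:
        raise ValueError("subject map arrays must share one shape")
    n_subj = next(iter(shapes))[0]
    if n_subj < 2:
        raise ValueError("need >=2 subjects per workload")
    pairs = list(combinations(labels, 2))
    if n_comparisons is None:
        n_comparisons = len(pairs)
    thresh = alpha / n_comparisons
    rng = np.random.default_rng(seed)
    out = {}
    for a, b in pairs:
        diff = subject_maps[a] - subject_maps[b]
        n_s, n_f, n_t = diff.shape
        t_obs, p = signflip_t_pvalues(
            diff.reshape(n_s, -1), n_perm=n_perm,
            seed=rng.integers(0, 2 ** 31 - 1))
        out[(a, b)] = TFSignificance(
            t=t_obs.reshape(n_f, n_t), p=p.reshape(n_f, n_t),
            significant=p.reshape(n_f, n_t) < thresh,
            freqs=np.arange(n_f, dtype=float), offsets_ms=np.arange(n_t,
                                                                    dtype=float),
            alpha=thresh, contrast=f"{a} vs {b}")
    return out


def band_cells(freqs: np.ndarray, band: str) -> np.ndarray:
    lo, hi = BANDS[band]
    return (freqs >= lo) & (freqs <= hi)


def write_significance_csv(res: TFSignificance, path) -> None:
    f_grid, t_grid = np.meshgrid(res.freqs, res.offsets_ms, indexing="ij")
    pd.DataFrame({
        "freq_hz": f_grid.ravel(),
        "time_ms": t_grid.ravel(),
        "t": res.t.ravel(),
        "p": res.p.ravel(),
        "significant": res.significant.ravel(),
    }).to_csv(path, index=False)
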