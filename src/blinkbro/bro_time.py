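"""Blink-locked epoching and time-domain BRO quantification.

Epochs are 3 s windows centered on each blink maximum (769 samples at
256 Hz: center sample +/-384, so 0 ms is an exact sample), restricted to
blinks with >3 s separation from both neighbors, fully in bounds, outside
masked spans, and not in workload transitions. The delta-band (0.5-4 Hz)
filtered epochs carry the BRO waveform, quantified as mean amplitudes over
fixed windows:

====================  =================
baseline              -1300 .. -1100 ms
C1 (first peak)        +200 .. +400 ms
C2 (second peak)       +450 .. +650 ms
pre500                 -550 .. -450 ms
p150                   +100 .. +200 ms
p300                   +250 .. +350 ms
p500                   +450 .. +550 ms
====================  =================

Window endpoints are inclusive; sample index = round(t*fs), ties to even.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import signal

from .core_io import (POSTERIOR_CHANNELS, TRANSITION, BlinkEvent, EpochSet,
                      Recording, StatResult)
from . import stats as bstats

#: Named analysis windows in ms relative to blink maximum.
PEAK_WINDOWS_MS: dict[str, tuple[float, float]] = {
    "baseline": (-1300.0, -1100.0),
    "C1": (200.0, 400.0),
    "C2": (450.0, 650.0),
    "pre500": (-550.0, -450.0),
    "p150": (100.0, 200.0),
    "p300": (250.0, 350.0),
    "p500": (450.0, 550.0),
}


def extract_epochs(rec: Recording, events: list[BlinkEvent],
                   epoch_s: float = 3.0, isolation_s: float = 3.0,
                   mask: np.ndarray | None = None) -> EpochSet:
    """Blink-locked epochs around each sufficiently isolated blink."""
    half = int(round(epoch_s * rec.fs / 2.0))
    n = rec.n_samples
    times = np.arange(-half, half + 1) / rec.fs
    samples = [e.sample for e in events]

    keep: list[int] = []
    for i, e in enumerate(events):
        prev_gap = (samples[i] - samples[i - 1]) / rec.fs if i > 0 else np.inf
        next_gap = (samples[i + 1] - samples[i]) / rec.fs \
            if i < len(samples) - 1 else np.inf
        if prev_gap <= isolation_s or next_gap <= isolation_s:
            continue
        lo, hi = e.sample - half, e.sample + half + 1
        if lo < 0 or hi > n:
            continue
        if mask is not None and mask[lo:hi].any():
            continue
        if rec.workload[e.sample] == TRANSITION:
            continue
        keep.append(i)

    tensor = np.empty((len(keep), rec.n_channels, 2 * half + 1))
    workloads = []
    kept_events = []
    for j, i in enumerate(keep):
        e = events[i]
        tensor[j] = rec.data[:, e.sample - half:e.sample + half + 1]
        workloads.append(str(rec.workload[e.sample]))
        kept_events.append(e)
    return EpochSet(tensor=tensor, times=times,
                    channel_labels=list(rec.channel_labels), fs=rec.fs,
                    workloads=workloads, events=kept_events)


def delta_filter(epochs: EpochSet, low: float = 0.5, high: float = 4.0,
                 order: int = 4) -> EpochSet:
    """Zero-phase 0.5-4 Hz band-pass of every epoch/channel (reflect-padded)."""
    sos = signal.butter(order, [low, high], btype="bandpass", fs=epochs.fs,
                        output="sos")
    n = epochs.tensor.shape[-1]
    pad = n - 1
    padded = np.pad(epochs.tensor, ((0, 0), (0, 0), (pad, pad)),
                    mode="reflect")
    filtered = signal.sosfiltfilt(sos, padded, axis=-1,
                                  padlen=0)[..., pad:pad + n]
    return EpochSet(tensor=filtered, times=epochs.times,
                    channel_labels=list(epochs.channel_labels), fs=epochs.fs,
                    workloads=list(epochs.workloads),
                    events=list(epochs.events))


def window_samples(times_s: np.ndarray, fs: float,
                   window_ms: tuple[float, float]) -> np.ndarray:
    """Boolean selector for an inclusive-endpoint window.

    Implemented by index arithmetic: the first/last sample indices are
    round(t*fs) (banker's rounding) relative to the epoch center.
    """
    center = len(times_s) // 2
    lo = center + int(np.round(window_ms[0] / 1000.0 * fs))
    hi = center + int(np.round(window_ms[1] / 1000.0 * fs))
    if lo < 0 or hi >= len(times_s) or lo > hi:
        raise ValueError(f"window {window_ms} ms outside epoch")
    sel = np.zeros(len(times_s), dtype=bool)
    sel[lo:hi + 1] = True
    return sel


def window_mean(epochs: EpochSet, window: str | tuple[float, float],
                channels: list[str] | tuple[str, ...] = POSTERIOR_CHANNELS
                ) -> pd.DataFrame:
    """Mean amplitude per epoch and channel over one analysis window."""
    win = PEAK_WINDOWS_MS[window] if isinstance(window, str) else window
    sel = window_samples(epochs.times, epochs.fs, win)
    ch_idx = [epochs.index(c) for c in channels]
    vals = epochs.tensor[:, ch_idx, :][:, :, sel].mean(axis=-1)
    return pd.DataFrame(vals, columns=[epochs.channel_labels[i]
                                       for i in ch_idx])


def amplitude_table(delta_epochs: EpochSet,
                    channels: tuple[str, ...] = POSTERIOR_CHANNELS,
                    windows: tuple[str, ...] = tuple(PEAK_WINDOWS_MS)
                    ) -> pd.DataFrame:
    """Long-format table: epoch, workload, channel, window, mean_uv."""
    frames = []
    for w in windows:
        wm = window_mean(delta_epochs, w, channels)
        wm.insert(0, "epoch", np.arange(len(wm)))
        wm.insert(1, "workload", delta_epochs.workloads)
        long = wm.melt(id_vars=["epoch", "workload"], var_name="channel",
                       value_name="mean_uv")
        long.insert(2, "window", w)
        frames.append(long)
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

def presence_test(amplitudes: np.ndarray | pd.DataFrame) -> list[StatResult]:
    """BRO presence at one channel/workload: baseline vs C1 vs C2.

    ``amplitudes`` is a subjects x 3 array (columns baseline, C1, C2 of
    per-subject mean delta amplitude). Returns the one-way rm-ANOVA plus
    Bonferroni-corrected post hoc paired t-tests C1-vs-baseline and
    C2-vs-baseline (signed, so C1 positivity / C2 negativity is assertable).
    """
    if isinstance(amplitudes, pd.DataFrame):
        amplitudes = amplitudes[["baseline", "C1", "C2"]].to_numpy()
    x = np.asarray(amplitudes, dtype=float)
    if x.ndim != 2 or x.shape[1] != 3:
        raise ValueError("expected subjects x {baseline, C1, C2}")
    if x.shape[0] < 2:
        raise ValueError("need >=2 subjects")
    anova = bstats.rm_anova(x)
    anova.test_name = "bro_presence_rm_anova"
    out = [anova]
    posthocs = [
        bstats.paired_t(x[:, 1], x[:, 0], contrast="C1 vs baseline"),
        bstats.paired_t(x[:, 2], x[:, 0], contrast="C2 vs baseline"),
    ]
    corrected = bstats.bonferroni([p.p_raw for p in posthocs], m=2)
    for r, pc in zip(posthocs, corrected):
        r.p_corrected = float(pc)
        r.correction = "bonferroni(2)"
        out.append(r)
    return out


def covariate_adjust(values: np.ndarray, covariate: np.ndarray,
                     cells: np.ndarray) -> np.ndarray:
    """Regression-adjust values on a centered covariate within cells.

    A single pooled slope is estimated from within-cell deviations; the
    adjustment subtracts slope * (covariate - grand mean). With a constant
    covariate this is exactly a no-op, so the ANCOVA reduces to the plain
    rm-ANOVA.
    """
    values = np.asarray(values, dtype=float)
    cov = np.asarray(covariate, dtype=float)
    c = cov - cov.mean()
    cells = np.asarray(cells)
    v_dev = values.copy()
    c_dev = c.copy()
    for cell in np.unique(cells):
        sel = cells == cell
        v_dev[sel] -= v_dev[sel].mean()
        c_dev[sel] -= c_dev[sel].mean()
    denom = np.sum(c_dev ** 2)
    slope = np.sum(c_dev * v_dev) / denom if denom > 0 else 0.0
    return values - slope * c


def workload_contrast(table: pd.DataFrame,
                      channels: tuple[str, ...] = POSTERIOR_CHANNELS,
                      workloads: tuple[str, ...] = ("low", "medium", "high"),
                      ) -> list[StatResult]:
    """Channel x workload rm-ANOVA (with blink-count covariate) + post hocs.

    ``table`` columns: subject, channel, workload, mean_uv and optionally
    blink_count (the per-subject-condition epoch count, entered as a
    centered covariate by regression adjustment before the ANOVA).
    Post hoc Bonferroni-corrected paired t-tests compare workload pairs
    within each channel; the family size is the number of comparisons run.
    """
    required = {"subject", "channel", "workload", "mean_uv"}
    if not required.issubset(table.columns):
        raise ValueError(f"table needs columns {sorted(required)}")
    df = table[table["channel"].isin(channels)
               & table["workload"].isin(workloads)].copy()
    if "blink_count" in df.columns:
        cells = (df["channel"].astype(str) + "|" + df["workload"].astype(str))
        df["mean_uv"] = covariate_adjust(df["mean_uv"].to_numpy(),
                                         df["blink_count"].to_numpy(),
                                         cells.to_numpy())
    wide = df.pivot_table(index="subject", columns=["channel", "workload"],
                          values="mean_uv")
    subjects = wide.index.to_numpy()
    cube = np.empty((len(subjects), len(channels), len(workloads)))
    for i, ch in enumerate(channels):
        for j, w in enumerate(workloads):
            if (ch, w) not in wide.columns:
                raise ValueError(f"missing cell ({ch}, {w})")
            cube[:, i, j] = wide[(ch, w)].to_numpy()
    if not np.all(np.isfinite(cube)):
        raise ValueError("missing cells in the design")

    results = bstats.rm_anova_two_way(cube, factor_names=("channel",
                                                          "workload"))
    posthocs = []
    for i, ch in enumerate(channels):
        for a in range(len(workloads)):
            for b in range(a + 1, len(workloads)):
                posthocs.append(bstats.paired_t(
                    cube[:, i, a], cube[:, i, b],
                    contrast=f"{ch}: {workloads[a]} vs {workloads[b]}"))
    m = len(posthocs)
    corrected = bstats.bonferroni([p.p_raw for p in posthocs], m=m)
    for r, pc in zip(posthocs, corrected):
        r.p_corrected = float(pc)
        r.correction = f"bonferroni({m})"
    return results + posthocs
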