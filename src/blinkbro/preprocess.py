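"""Continuous-data conditioning: band-pass, notch, artifact-segment masking.

All filters are zero-phase (forward-backward) Butterworth designs. The
band-pass uses a 4th-order prototype, so the two-pass magnitude response is
the squared single-pass response: -6 dB at the band edges. Recordings are
reflect-padded (up to 10 s) before filtering to suppress edge transients,
which matters for the 0.1 Hz high-pass edge whose period is 10 s.

Artifactual stretches are handled by masking rather than deletion: sample
indexing is preserved so blink events and epochs can be bookkept against the
original time axis, and masked spans are simply excluded from event
eligibility and epoching downstream.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage, signal

from .core_io import EOG_CHANNELS, Recording

EDGE_PAD_S = 10.0


def _zero_phase(sos: np.ndarray, data: np.ndarray, fs: float) -> np.ndarray:
    """Forward-backward filter along the last axis with reflect padding."""
    n = data.shape[-1]
    pad = int(min(EDGE_PAD_S * fs, n - 1))
    padded = np.pad(data, [(0, 0)] * (data.ndim - 1) + [(pad, pad)],
                    mode="reflect") if pad else data
    out = signal.sosfiltfilt(sos, padded, axis=-1, padlen=0)
    return out[..., pad:n + pad] if pad else out


def bandpass_sos(low: float, high: float, fs: float, order: int = 4) -> np.ndarray:
    if not 0 < low < high:
        raise ValueError("need 0 < low < high")
    if high >= fs / 2:
        raise ValueError(f"high edge {high} Hz >= Nyquist {fs / 2} Hz")
    return signal.butter(order, [low, high], btype="bandpass", fs=fs,
                         output="sos")


def bandpass(rec: Recording, low: float = 0.1, high: float = 80.0,
             order: int = 4) -> Recording:
    """Zero-phase Butterworth band-pass (default 0.1-80 Hz, order 4)."""
    sos = bandpass_sos(low, high, rec.fs, order)
    out = rec.copy()
    out.data = _zero_phase(sos, out.data, rec.fs)
    out.meta.setdefault("filters", []).append(
        {"kind": "bandpass", "low_hz": low, "high_hz": high, "order": order,
         "zero_phase": True})
    return out


def lowpass_series(x: np.ndarray, fs: float, cutoff: float,
                   order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth low-pass on a single series."""
    if not 0 < cutoff < fs / 2:
        raise ValueError(f"cutoff {cutoff} Hz outside (0, {fs / 2}) Hz")
    sos = signal.butter(order, cutoff, btype="lowpass", fs=fs, output="sos")
    return _zero_phase(sos, np.asarray(x, dtype=float), fs)


def notch(rec: Recording, freq: float = 60.0, q: float = 30.0) -> Recording:
    """Zero-phase IIR notch (default 60 Hz line noise, Q=30)."""
    if freq >= rec.fs / 2:
        raise ValueError(f"notch frequency {freq} Hz >= Nyquist {rec.fs / 2} Hz")
    b, a = signal.iirnotch(freq, q, fs=rec.fs)
    sos = signal.tf2sos(b, a)
    out = rec.copy()
    out.data = _zero_phase(sos, out.data, rec.fs)
    out.meta.setdefault("filters", []).append(
        {"kind": "notch", "freq_hz": freq, "q": q, "zero_phase": True})
    return out


def reject_segments(rec: Recording, abs_threshold_uv: float = 500.0,
                    pad_s: float = 0.5) -> tuple[Recording, np.ndarray]:
    """Mask samples where any scalp EEG channel exceeds the threshold.

    EOG channels are excluded from thresholding (blink deflections routinely
    exceed any sane scalp threshold). The mask is padded by ``pad_s`` on each
    side of every violation; data values are left intact.
    """
    scalp = [i for i, c in enumerate(rec.channel_labels)
             if c not in EOG_CHANNELS]
    bad = np.zeros(rec.n_samples, dtype=bool)
    if scalp:
        bad = np.any(np.abs(rec.data[scalp]) > abs_threshold_uv, axis=0)
    if bad.any():
        pad = int(round(pad_s * rec.fs))
        if pad:
            bad = ndimage.binary_dilation(bad, np.ones(2 * pad + 1, dtype=bool))
    return rec, bad


def mask_to_intervals(mask: np.ndarray, fs: float) -> pd.DataFrame:
    """Bad-segment mask as (start_s, end_s) interval rows."""
    rows = []
    idx = np.flatnonzero(np.diff(np.r_[0, mask.astype(int), 0]))
    for start, stop in zip(idx[::2], idx[1::2]):
        rows.append({"start_s": start / fs, "end_s": stop / fs})
    return pd.DataFrame(rows, columns=["start_s", "end_s"])


def write_mask_csv(mask: np.ndarray, fs: float, path) -> None:
    mask_to_intervals(mask, fs).to_csv(path, index=False)
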