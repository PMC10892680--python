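"""ICA-based ocular artifact removal and the ocular contamination index.

The decomposition uses the InfoMax algorithm (via mne) on the scalp EEG
channels only. Following common practice, the unmixing matrix is estimated
on a 1 Hz high-passed, masked and decimated copy of the data (stationarity
and speed), then applied to the full 0.1 Hz-filtered recording. Components
are flagged automatically: high correlation with VEOG/HEOG, or a frontally
concentrated mixing column combined with blink-locked source amplitude well
above its own baseline. Removal back-projects the retained components; EOG
channels pass through untouched.

The ocular contamination index (OCI) quantifies residual artifact as the
ratio of trial-averaged RMS amplitude in a +/-50 ms window around the blink
maximum to a 100 ms baseline window centered at -1000 ms, over the frontal
channels. It is dimensionless, scale-invariant and >= 0; effective denoising
drives it toward 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import (EOG_CHANNELS, FRONTAL_CHANNELS, POSTERIOR_CHANNELS,
                      BlinkEvent, EpochSet, Recording, StatResult)
from .preprocess import bandpass_sos, _zero_phase
from .stats import paired_t

MAX_FIT_SAMPLES = 10240


@dataclass
class ICADecomposition:
    """Linear decomposition of the scalp EEG: data = mixing @ sources."""

    unmixing: np.ndarray          # components x channels
    mixing: np.ndarray            # channels x components
    sources: np.ndarray           # components x samples
    channel_labels: list[str]
    algorithm: str = "InfoMax"
    seed: int | None = None

    @property
    def n_components(self) -> int:
        return self.unmixing.shape[0]


def run_ica(rec: Recording, n_components: int | None = None,
            seed: int = 0, mask: np.ndarray | None = None,
            max_iter: int = 500) -> ICADecomposition:
    """InfoMax ICA on the EEG channels of a recording.

    Masked spans are excluded from fitting; fitting also uses a 1 Hz
    high-passed copy decimated to at most ~10k samples. The returned sources
    are the full-length unmixed 0.1 Hz data, so ``mixing @ sources``
    reconstructs the input exactly (full-rank decomposition).
    """
    from mne.preprocessing import infomax

    eeg_idx = rec.eeg_indices
    labels = rec.eeg_labels
    x = rec.data[eeg_idx]
    n_ch = x.shape[0]
    if n_components is None:
        n_components = n_ch
    if n_components > n_ch:
        raise ValueError("n_components exceeds EEG channel count")

    # fitting copy: 1 Hz high-pass, drop masked samples, decimate
    sos = bandpass_sos(1.0, min(80.0, rec.fs / 2 - 1), rec.fs, order=4)
    fit = _zero_phase(sos, x, rec.fs)
    if mask is not None and mask.any():
        fit = fit[:, ~mask]
    decim = max(1, fit.shape[1] // MAX_FIT_SAMPLES)
    fit = fit[:, ::decim]
    fit = fit - fit.mean(axis=1, keepdims=True)

    # PCA whitening
    u, s, _ = np.linalg.svd(fit, full_matrices=False)
    if np.any(s[:n_components] <= 0):
        raise ValueError("rank-deficient data; reduce n_components")
    whitener = (u[:, :n_components] / s[:n_components]).T \
        * np.sqrt(fit.shape[1])
    white = whitener @ fit

    w = infomax(white.T, extended=False, max_iter=max_iter,
                rng=np.random.default_rng(seed), verbose="error")
    unmixing = w @ whitener
    if n_components == n_ch:
        mixing = np.linalg.inv(unmixing)
    else:
        mixing = np.linalg.pinv(unmixing)
    sources = unmixing @ x

    # canonical order/sign: by explained variance, largest mixing weight > 0
    power = (mixing ** 2).sum(axis=0) * sources.var(axis=1)
    order = np.argsort(power)[::-1]
    unmixing, mixing, sources = unmixing[order], mixing[:, order], sources[order]
    signs = np.sign(mixing[np.argmax(np.abs(mixing), axis=0),
                           np.arange(mixing.shape[1])])
    signs[signs == 0] = 1.0
    mixing = mixing * signs[None, :]
    unmixing = unmixing * signs[:, None]
    sources = sources * signs[:, None]

    return ICADecomposition(unmixing=unmixing, mixing=mixing, sources=sources,
                            channel_labels=labels, seed=seed)


def identify_artifact_components(decomp: ICADecomposition,
                                 veog: np.ndarray | None = None,
                                 heog: np.ndarray | None = None,
                                 corr_threshold: float = 0.6,
                                 frontal_ratio: float = 2.0,
                                 events: list[BlinkEvent] | None = None,
                                 fs: float | None = None) -> dict[int, list[str]]:
    """Flag artifact components, with a reason per flag.

    Criteria (any suffices):
    - |corr(source, VEOG)| or |corr(source, HEOG)| >= ``corr_threshold``;
    - frontal/posterior absolute mixing-weight ratio >= ``frontal_ratio``
      together with blink-locked source amplitude >= 3x its baseline
      (requires ``events`` and ``fs``).
    """
    flagged: dict[int, list[str]] = {}

    def _corr(a: np.ndarray, b: np.ndarray) -> float:
        sa, sb = a.std(), b.std()
        if sa == 0 or sb == 0:
            return 0.0
        return float(np.corrcoef(a, b)[0, 1])

    for k in range(decomp.n_components):
        reasons = []
        src = decomp.sources[k]
        if veog is not None and abs(_corr(src, veog)) >= corr_threshold:
            reasons.append("VEOG correlation")
        if heog is not None and abs(_corr(src, heog)) >= corr_threshold:
            reasons.append("HEOG correlation")
        if events and fs and _frontal_ratio(decomp, k) >= frontal_ratio \
                and _blink_locked_ratio(src, events, fs) >= 3.0:
            reasons.append("frontal topography + blink-locked amplitude")
        if reasons:
            flagged[k] = reasons
    return flagged


def _frontal_ratio(decomp: ICADecomposition, k: int) -> float:
    col = np.abs(decomp.mixing[:, k])
    front = [i for i, c in enumerate(decomp.channel_labels)
             if c in FRONTAL_CHANNELS]
    post = [i for i, c in enumerate(decomp.channel_labels)
            if c in POSTERIOR_CHANNELS]
    if not front or not post or col[post].mean() == 0:
        return 0.0
    return float(col[front].mean() / col[post].mean())


def _blink_locked_ratio(src: np.ndarray, events: list[BlinkEvent],
                        fs: float) -> float:
    """|mean blink-locked source| at 0 ms over its -1000 ms baseline RMS."""
    half = int(round(1.2 * fs))
    snippets = [src[e.sample - half:e.sample + half + 1] for e in events
                if e.sample - half >= 0 and e.sample + half + 1 <= len(src)]
    if not snippets:
        return 0.0
    avg = np.mean(snippets, axis=0)
    center = half
    blink = np.abs(avg[center - int(0.05 * fs):center + int(0.05 * fs) + 1]).max()
    b0 = center - int(round(1.05 * fs))
    b1 = center - int(round(0.95 * fs))
    base = np.sqrt(np.mean(avg[b0:b1 + 1] ** 2))
    return float(blink / base) if base > 0 else np.inf


def remove_components(rec: Recording, decomp: ICADecomposition,
                      indices: list[int]) -> Recording:
    """Back-project the EEG without the given components; EOG untouched."""
    for k in indices:
        if not 0 <= k < decomp.n_components:
            raise IndexError(f"component index {k} out of range")
    keep = [k for k in range(decomp.n_components) if k not in set(indices)]
    out = rec.copy()
    cleaned = decomp.mixing[:, keep] @ decomp.sources[keep]
    out.data[rec.eeg_indices] = cleaned
    out.meta.setdefault("ica_removed", []).extend(sorted(set(indices)))
    return out


def write_component_report(decomp: ICADecomposition,
                           flagged: dict[int, list[str]], path) -> None:
    rows = []
    for k in range(decomp.n_components):
        rows.append({
            "component": k,
            "frontal_ratio": _frontal_ratio(decomp, k),
            "removed": k in flagged,
            "reasons": "; ".join(flagged.get(k, [])),
        })
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# ocular contamination index
# ---------------------------------------------------------------------------

@dataclass
class OCIResult:
    oci: float
    window_blink_ms: tuple[float, float]
    window_baseline_ms: tuple[float, float]
    channels: list[str]
    n_epochs: int

    def to_dict(self) -> dict:
        return {
            "oci": self.oci,
            "window_blink_ms": list(self.window_blink_ms),
            "window_baseline_ms": list(self.window_baseline_ms),
            "channels": self.channels,
            "n_epochs": self.n_epochs,
        }


def compute_oci(epochs: EpochSet,
                window_blink_ms: tuple[float, float] = (-50.0, 50.0),
                window_baseline_ms: tuple[float, float] = (-1050.0, -950.0),
                channels: tuple[str, ...] = FRONTAL_CHANNELS) -> OCIResult:
    """OCI: trial-averaged frontal RMS at blink time over baseline RMS."""
    if epochs.n_epochs == 0:
        raise ValueError("empty epoch set")
    ch_idx = [epochs.index(c) for c in channels if c in epochs.channel_labels]
    if not ch_idx:
        raise ValueError("none of the requested channels present")
    avg = epochs.tensor[:, ch_idx, :].mean(axis=0)   # channels x samples
    t_ms = epochs.times * 1000.0

    def _rms(win: tuple[float, float]) -> float:
        sel = (t_ms >= win[0]) & (t_ms <= win[1])
        if not sel.any():
            raise ValueError(f"window {win} ms outside epoch span")
        return float(np.sqrt(np.mean(avg[:, sel] ** 2)))

    denom = _rms(window_baseline_ms)
    oci = _rms(window_blink_ms) / denom if denom > 0 else np.inf
    return OCIResult(oci=float(oci), window_blink_ms=window_blink_ms,
                     window_baseline_ms=window_baseline_ms,
                     channels=[epochs.channel_labels[i] for i in ch_idx],
                     n_epochs=epochs.n_epochs)


def compare_oci(pre: list[OCIResult] | list[float],
                post: list[OCIResult] | list[float]) -> StatResult:
    """Paired two-tailed t-test of pre- vs post-denoising OCI values."""
    def _vals(xs):
        return np.array([x.oci if isinstance(x, OCIResult) else float(x)
                         for x in xs])

    a, b = _vals(pre), _vals(post)
    if len(a) != len(b):
        raise ValueError("pre and post lists must be paired (equal length)")
    res = paired_t(a, b, contrast="OCI pre vs post")
    res.test_name = "oci_paired_t"
    return res
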