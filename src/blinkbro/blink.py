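"""Blink detection on the VEOG channel and blink-rate computation.

Detection is convolution-based template matching: a sliding Pearson
correlation between the low-passed VEOG and a blink template. Candidates
require both high template correlation and a VEOG amplitude well above the
series' robust baseline; nearby candidates collapse to the strongest one and
each detection is refined to the local VEOG maximum (the blink maximum,
0 ms). A two-pass scheme replaces manual review: detect with a canonical
template, rebuild the template from the detections, and detect again.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

from .core_io import BlinkEvent, TRANSITION
from .preprocess import lowpass_series

TEMPLATE_HALF_WIDTH_S = 0.35
ISOLATION_S = 3.0


class BlinkTemplate:
    """Unit-L2-norm blink waveform with its provenance."""

    def __init__(self, waveform: np.ndarray, fs: float, source: str,
                 n_contributing: int = 0):
        waveform = np.asarray(waveform, dtype=float)
        norm = np.linalg.norm(waveform)
        if norm == 0:
            raise ValueError("template is identically zero")
        self.waveform = waveform / norm
        self.fs = fs
        self.source = source
        self.n_contributing = n_contributing

    @property
    def width_s(self) -> float:
        return len(self.waveform) / self.fs


def canonical_template(fs: float,
                       half_width_s: float = TEMPLATE_HALF_WIDTH_S
                       ) -> BlinkTemplate:
    """Raised-cosine-squared pulse, the default first-pass template."""
    half = int(round(half_width_s * fs))
    t = np.arange(-half, half + 1) / fs
    w = np.cos(np.pi * t / (2 * half_width_s)) ** 2
    w[np.abs(t) >= half_width_s] = 0.0
    return BlinkTemplate(w, fs, source="canonical")


def build_template(veog: np.ndarray, fs: float,
                   seed_peaks: list[int] | np.ndarray | None = None
                   ) -> BlinkTemplate:
    """Template from the mean of +/-0.35 s VEOG snippets around seed peaks.

    Falls back to the canonical raised-cosine-squared pulse when no seeds are
    given; requires at least 5 seed peaks otherwise.
    """
    if seed_peaks is None:
        return canonical_template(fs)
    seed_peaks = np.asarray(seed_peaks, dtype=int)
    if len(seed_peaks) < 5:
        raise ValueError("need >=5 seed peaks to build a data-derived template")
    half = int(round(TEMPLATE_HALF_WIDTH_S * fs))
    n = len(veog)
    snippets = [veog[p - half:p + half + 1] for p in seed_peaks
                if p - half >= 0 and p + half + 1 <= n]
    if len(snippets) < 5:
        raise ValueError("need >=5 in-bounds seed peaks")
    mean = np.mean(snippets, axis=0)
    mean = mean - mean.mean()
    return BlinkTemplate(mean, fs, source="data-derived",
                         n_contributing=len(snippets))


def lowpass_veog(veog: np.ndarray, fs: float,
                 cutoff: float = 30.0) -> np.ndarray:
    """Zero-phase 30 Hz low-pass of the VEOG series."""
    return lowpass_series(veog, fs, cutoff)


def _sliding_correlation(x: np.ndarray, template: np.ndarray) -> np.ndarray:
    """Pearson correlation of each centered window of x with the template."""
    t = template - template.mean()
    t_norm = np.linalg.norm(t)
    L = len(template)
    ones = np.ones(L)
    s1 = signal.fftconvolve(x, ones[::-1], mode="same")
    s2 = signal.fftconvolve(x * x, ones[::-1], mode="same")
    xt = signal.fftconvolve(x, t[::-1], mode="same")
    win_var = np.maximum(s2 - s1 * s1 / L, 0.0)
    denom = np.sqrt(win_var) * t_norm
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 1e-12, xt / denom, 0.0)
    return np.clip(r, -1.0, 1.0)


def detect_blinks(veog: np.ndarray, fs: float,
                  template: BlinkTemplate | None = None,
                  corr_threshold: float = 0.7,
                  amp_threshold_sd: float = 2.0,
                  amp_floor_uv: float = 100.0,
                  refractory_s: float = 0.25,
                  mask: np.ndarray | None = None,
                  workload: np.ndarray | None = None,
                  invert: bool = False) -> list[BlinkEvent]:
    """Template-matching blink detection on a low-passed VEOG series.

    A sample is a candidate when the sliding correlation with the template is
    >= ``corr_threshold`` and the VEOG amplitude is >= ``amp_threshold_sd``
    robust standard deviations (1.4826*MAD) above the series median and
    >= ``amp_floor_uv`` in absolute terms. The absolute floor encodes the
    physiology of this recording setup: blink artifacts exceed 250 uV on a
    bipolar VEOG, while slow background excursions of a few tens of uV can
    correlate well with the template — a purely relative gate admits them as
    spurious blinks. Set ``amp_floor_uv=0`` to disable (e.g., for heavily
    attenuated or pre-scaled data).

    Candidates within ``refractory_s`` collapse to the highest-amplitude one;
    each event is refined to the local VEOG maximum within +/-0.1 s. Events
    in masked spans are dropped; the isolated flag uses the >3 s rule.
    """
    x = np.asarray(veog, dtype=float)
    if invert:
        x = -x
    if template is None:
        template = canonical_template(fs)
    if len(template.waveform) > len(x):
        raise ValueError("template longer than series")

    r = _sliding_correlation(x, template.waveform)
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    amp_floor = max(med + amp_threshold_sd * 1.4826 * mad, amp_floor_uv)
    candidate = (r >= corr_threshold) & (x >= amp_floor)
    if not candidate.any():
        return []

    # one representative per contiguous run: the max-amplitude sample
    idx = np.flatnonzero(np.diff(np.r_[0, candidate.astype(int), 0]))
    peaks = []
    for start, stop in zip(idx[::2], idx[1::2]):
        peaks.append(start + int(np.argmax(x[start:stop])))

    # refractory collapse: keep highest amplitude within refractory_s
    peaks.sort()
    refr = int(round(refractory_s * fs))
    kept: list[int] = []
    for p in peaks:
        if kept and p - kept[-1] <= refr:
            if x[p] > x[kept[-1]]:
                kept[-1] = p
        else:
            kept.append(p)

    # refine to local VEOG maximum within +/-0.1 s
    n = len(x)
    win = int(round(0.1 * fs))
    refined = []
    for p in kept:
        lo = max(0, p - win)
        hi = min(n, p + win + 1)
        refined.append(lo + int(np.argmax(x[lo:hi])))
    refined = sorted(set(refined))

    if mask is not None:
        refined = [p for p in refined if not mask[p]]

    events = []
    for i, p in enumerate(refined):
        prev_gap = (refined[i] - refined[i - 1]) / fs if i > 0 else np.inf
        next_gap = (refined[i + 1] - refined[i]) / fs \
            if i < len(refined) - 1 else np.inf
        w = str(workload[p]) if workload is not None else TRANSITION
        events.append(BlinkEvent(
            sample=int(p), time_s=float(p / fs), amplitude=float(x[p]),
            isolated=bool(prev_gap > ISOLATION_S and next_gap > ISOLATION_S),
            workload=w))
    return events


def detect_blinks_two_pass(veog: np.ndarray, fs: float,
                           corr_threshold: float = 0.7,
                           amp_threshold_sd: float = 2.0,
                           amp_floor_uv: float = 100.0,
                           refractory_s: float = 0.25,
                           mask: np.ndarray | None = None,
                           workload: np.ndarray | None = None,
                           invert: bool = False) -> list[BlinkEvent]:
    """Canonical-template detection, template rebuild, re-detection."""
    kwargs = dict(corr_threshold=corr_threshold,
                  amp_threshold_sd=amp_threshold_sd,
                  amp_floor_uv=amp_floor_uv,
                  refractory_s=refractory_s, mask=mask, workload=workload,
                  invert=invert)
    first = detect_blinks(veog, fs, canonical_template(fs), **kwargs)
    if len(first) < 5:
        return first
    x = -np.asarray(veog, float) if invert else np.asarray(veog, float)
    try:
        refined = build_template(x, fs, [e.sample for e in first])
    except ValueError:
        return first
    return detect_blinks(veog, fs, refined, **kwargs)


def blink_rate(events: list[BlinkEvent], workload: np.ndarray, fs: float,
               mask: np.ndarray | None = None) -> dict[str, float]:
    """Blinks per unmasked minute for each workload present in the labels."""
    workload = np.asarray(workload)
    if mask is None:
        mask = np.zeros(len(workload), dtype=bool)
    rates: dict[str, float] = {}
    for w in np.unique(workload):
        if w == TRANSITION:
            continue
        minutes = np.sum((workload == w) & ~mask) / fs / 60.0
        if minutes <= 0:
            raise ValueError(f"zero unmasked duration for workload {w!r}")
        count = sum(1 for e in events if e.workload == w)
        rates[str(w)] = float(count / minutes)
    return rates
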