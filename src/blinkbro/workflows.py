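"""In-memory convenience workflows combining the pipeline stages.

These helpers mirror :func:`blinkbro.core_io.run_pipeline` but keep all
intermediates in memory — handy for simulation studies where many short
recordings are processed (parameter-recovery experiments, power analyses).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import blink, bro_time, denoise, preprocess, synth
from .core_io import BlinkEvent, EpochSet, Recording


@dataclass
class ProcessedRecording:
    """Everything the standard pipeline produces for one recording."""

    raw: Recording                # band-passed / notched, pre-ICA
    cleaned: Recording
    mask: np.ndarray
    events: list[BlinkEvent]
    epochs: EpochSet              # from the cleaned data
    epochs_raw: EpochSet          # same epochs cut from the pre-ICA data
    removed_components: list[int]


def process_recording(rec: Recording, seed: int = 0) -> ProcessedRecording:
    """Filter, detect blinks, denoise, and epoch one recording."""
    rec = preprocess.bandpass(rec)
    rec = preprocess.notch(rec)
    rec, mask = preprocess.reject_segments(rec)
    veog_lp = blink.lowpass_veog(rec.get("VEOG"), rec.fs)
    events = blink.detect_blinks_two_pass(veog_lp, rec.fs,
                                          workload=rec.workload, mask=mask)
    decomp = denoise.run_ica(rec, seed=seed, mask=mask)
    flagged = denoise.identify_artifact_components(
        decomp, veog=rec.get("VEOG"), heog=rec.get("HEOG"),
        events=events, fs=rec.fs)
    cleaned = denoise.remove_components(rec, decomp, sorted(flagged))
    epochs = bro_time.extract_epochs(cleaned, events, mask=mask)
    epochs_raw = bro_time.extract_epochs(rec, events, mask=mask)
    return ProcessedRecording(raw=rec, cleaned=cleaned, mask=mask,
                              events=events, epochs=epochs,
                              epochs_raw=epochs_raw,
                              removed_components=sorted(flagged))


def simulate_and_process(cfg: synth.SynthConfig) -> ProcessedRecording:
    rec, _ = synth.generate_recording(cfg)
    return process_recording(rec, seed=cfg.seed)


def pz_window_means(epochs: EpochSet,
                    windows: tuple[str, ...] = ("baseline", "C1", "C2"),
                    channel: str = "Pz") -> dict[str, dict[str, float]]:
    """Per-workload mean delta-band window amplitudes at one channel."""
    delta = bro_time.delta_filter(epochs)
    out: dict[str, dict[str, float]] = {}
    for w in sorted(set(delta.workloads)):
        sel = [i for i, x in enumerate(delta.workloads) if x == w]
        out[w] = {
            win: float(bro_time.window_mean(delta, win, [channel])
                       .iloc[sel, 0].mean())
            for win in windows
        }
    return out
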