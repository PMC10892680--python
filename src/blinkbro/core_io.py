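"""Data model, EDF/CSV input-output, and pipeline orchestration.

The central container is :class:`Recording`: a channels-by-samples matrix in
microvolts with a 10/20 channel set plus bipolar VEOG/HEOG, a single sampling
rate, and a per-sample cognitive-workload label (``low``/``medium``/``high``
or ``transition`` for the unlabeled padding between task segments).

Continuous data are exchanged as EDF. Reading goes through
``mne.io.read_raw_edf``; writing uses a minimal EDF writer implemented here
(plain EDF, 16-bit samples, one-second data records). Workload labels travel
in a CSV sidecar of ``(start_s, end_s, workload)`` intervals.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("blinkbro")

#: International 10/20 scalp montage used throughout (19 channels), in the
#: order they are synthesized and written.
EEG_CHANNELS: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T3", "C3", "Cz", "C4", "T4",
    "T5", "P3", "Pz", "P4", "T6",
    "O1", "O2",
)
EOG_CHANNELS: tuple[str, ...] = ("VEOG", "HEOG")
ALL_CHANNELS: tuple[str, ...] = EEG_CHANNELS + EOG_CHANNELS

#: Frontal set used for the ocular contamination index.
FRONTAL_CHANNELS: tuple[str, ...] = ("Fp1", "Fp2", "F3", "F4", "Fz")
#: Posterior set carrying the BRO response (precuneus-adjacent electrodes).
POSTERIOR_CHANNELS: tuple[str, ...] = ("P3", "Pz", "P4", "O1", "O2")

WORKLOAD_LEVELS: tuple[str, ...] = ("low", "medium", "high")
TRANSITION = "transition"

DEFAULT_FS = 256.0


class PipelineError(RuntimeError):
    """Raised when a pipeline stage cannot proceed."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class Recording:
    """Continuous multichannel recording in microvolts.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal in microvolts.
    fs : float
        Sampling rate in Hz (the study's acquisition rate is 256 Hz).
    channel_labels : list of str
        Unique channel names; scalp channels use 10/20 names, ocular
        channels are ``VEOG``/``HEOG``.
    reference : str
        Reference label, e.g. ``"left mastoid"``.
    workload : ndarray of str, shape (n_samples,)
        Per-sample workload label (``low``/``medium``/``high``/``transition``).
    meta : dict
        Free-form provenance.
    """

    data: np.ndarray
    fs: float = DEFAULT_FS
    channel_labels: list[str] = field(default_factory=lambda: list(ALL_CHANNELS))
    reference: str = "left mastoid"
    workload: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D [channels x samples]")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} labels for {self.data.shape[0]} channels"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        if self.workload is None:
            self.workload = np.full(self.n_samples, TRANSITION, dtype="<U10")
        else:
            self.workload = np.asarray(self.workload, dtype="<U10")
            if self.workload.shape != (self.n_samples,):
                raise ValueError("workload vector length must equal sample count")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in recording") from None

    def get(self, label: str) -> np.ndarray:
        return self.data[self.index(label)]

    @property
    def eeg_labels(self) -> list[str]:
        return [c for c in self.channel_labels if c not in EOG_CHANNELS]

    @property
    def eeg_indices(self) -> np.ndarray:
        return np.array([self.index(c) for c in self.eeg_labels])

    def copy(self) -> "Recording":
        return Recording(
            data=self.data.copy(),
            fs=self.fs,
            channel_labels=list(self.channel_labels),
            reference=self.reference,
            workload=self.workload.copy(),
            meta=dict(self.meta),
        )


@dataclass(frozen=True)
class BlinkEvent:
    """One blink, anchored at the VEOG maximum."""

    sample: int
    time_s: float
    amplitude: float
    isolated: bool
    workload: str

    def as_row(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class EpochSet:
    """Blink-locked epochs: tensor [epochs x channels x samples].

    ``times`` spans -1.5 .. +1.5 s with 0 at the center sample (769 samples at
    256 Hz: the center sample plus 384 on each side, so 0 ms is exact).
    """

    tensor: np.ndarray
    times: np.ndarray
    channel_labels: list[str]
    fs: float
    workloads: list[str]
    events: list[BlinkEvent]

    def __post_init__(self) -> None:
        self.tensor = np.asarray(self.tensor, dtype=float)
        if self.tensor.ndim != 3:
            raise ValueError("tensor must be [epochs x channels x samples]")
        n_e, n_c, n_s = self.tensor.shape
        if len(self.times) != n_s:
            raise ValueError("time axis length mismatch")
        if len(self.channel_labels) != n_c:
            raise ValueError("channel label count mismatch")
        if len(self.workloads) != n_e or len(self.events) != n_e:
            raise ValueError("per-epoch metadata length mismatch")
        center = n_s // 2
        if abs(self.times[center]) > 1e-9:
            raise ValueError("time axis must contain 0 at the center sample")

    @property
    def n_epochs(self) -> int:
        return self.tensor.shape[0]

    def index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in epochs") from None

    def channel(self, label: str) -> np.ndarray:
        """Epochs-by-samples slab for one channel."""
        return self.tensor[:, self.index(label), :]

    def select(self, workload: str) -> "EpochSet":
        keep = [i for i, w in enumerate(self.workloads) if w == workload]
        return EpochSet(
            tensor=self.tensor[keep],
            times=self.times,
            channel_labels=list(self.channel_labels),
            fs=self.fs,
            workloads=[self.workloads[i] for i in keep],
            events=[self.events[i] for i in keep],
        )

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez_compressed(
            path,
            tensor=self.tensor,
            times=self.times,
            channel_labels=np.array(self.channel_labels),
            fs=self.fs,
            workloads=np.array(self.workloads),
            events=np.array([
                (e.sample, e.time_s, e.amplitude, int(e.isolated), e.workload)
                for e in self.events
            ], dtype=object),
        )

    @classmethod
    def load(cls, path: str | Path) -> "EpochSet":
        with np.load(path, allow_pickle=True) as z:
            events = [
                BlinkEvent(int(s), float(t), float(a), bool(i), str(w))
                for s, t, a, i, w in z["events"]
            ]
            return cls(
                tensor=z["tensor"],
                times=z["times"],
                channel_labels=[str(c) for c in z["channel_labels"]],
                fs=float(z["fs"]),
                workloads=[str(w) for w in z["workloads"]],
                events=events,
            )


@dataclass
class StatResult:
    """A named statistical outcome (F or t)."""

    test_name: str
    statistic: float
    df: tuple[float, float]
    p_raw: float
    p_corrected: float | None = None
    epsilon: float | None = None
    correction: str | None = None
    contrast: str | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_raw <= 1.0):
            raise ValueError("p_raw outside [0, 1]")
        if self.p_corrected is not None:
            if not (0.0 <= self.p_corrected <= 1.0):
                raise ValueError("p_corrected outside [0, 1]")
            if self.p_corrected < self.p_raw - 1e-12:
                raise ValueError("p_corrected must be >= p_raw")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def save_stat_results(results: list[StatResult], path: str | Path) -> None:
    Path(path).write_text(
        json.dumps([r.to_dict() for r in results], indent=2, sort_keys=True)
    )


# ---------------------------------------------------------------------------
# events CSV
# ---------------------------------------------------------------------------

def write_events_csv(events: list[BlinkEvent], path: str | Path) -> None:
    pd.DataFrame([e.as_row() for e in events], columns=[
        "sample", "time_s", "amplitude", "isolated", "workload",
    ]).to_csv(path, index=False)


def read_events_csv(path: str | Path) -> list[BlinkEvent]:
    df = pd.read_csv(path)
    return [
        BlinkEvent(int(r.sample), float(r.time_s), float(r.amplitude),
                   bool(r.isolated), str(r.workload))
        for r in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# workload label sidecar
# ---------------------------------------------------------------------------

def workload_to_intervals(workload: np.ndarray, fs: float) -> pd.DataFrame:
    """Compress a per-sample label vector into (start_s, end_s, workload) rows."""
    rows = []
    n = len(workload)
    start = 0
    for i in range(1, n + 1):
        if i == n or workload[i] != workload[start]:
            rows.append({
                "start_s": start / fs,
                "end_s": i / fs,
                "workload": str(workload[start]),
            })
            start = i
    return pd.DataFrame(rows, columns=["start_s", "end_s", "workload"])


def intervals_to_workload(df: pd.DataFrame, n_samples: int, fs: float) -> np.ndarray:
    """Expand interval rows to a per-sample vector; gaps become transition."""
    required = {"start_s", "end_s", "workload"}
    if not required.issubset(df.columns):
        raise ValueError(f"sidecar must have columns {sorted(required)}")
    out = np.full(n_samples, TRANSITION, dtype="<U10")
    rows = df.sort_values("start_s").reset_index(drop=True)
    prev_end = -np.inf
    for r in rows.itertuples():
        if r.start_s < prev_end - 1e-9:
            raise ValueError(
                f"overlapping sidecar intervals: one ends at {prev_end} s, "
                f"next starts at {r.start_s} s"
            )
        prev_end = r.end_s
        i0 = max(0, int(round(r.start_s * fs)))
        i1 = min(n_samples, int(round(r.end_s * fs)))
        out[i0:i1] = str(r.workload)
    return out


# ---------------------------------------------------------------------------
# EDF input/output
# ---------------------------------------------------------------------------

_EDF_DIGITAL_MAX = 32767


def write_recording(rec: Recording, path: str | Path,
                    physical_range_uv: float = 1000.0) -> Path:
    """Write a Recording to plain EDF (16-bit) plus a workload sidecar CSV.

    One-second data records are used, so the recording must contain a whole
    number of seconds. The physical range defaults to +/-1000 uV and is
    widened automatically if the data exceed it (avoiding clipping at the
    cost of coarser quantization).
    """
    path = Path(path)
    if rec.n_samples == 0:
        raise ValueError("cannot write zero-length recording")
    spr = rec.fs
    if abs(spr - round(spr)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    spr = int(round(spr))
    if rec.n_samples % spr != 0:
        raise ValueError(
            "EDF writer requires a whole number of seconds "
            f"(got {rec.n_samples} samples at {spr} Hz)"
        )
    n_records = rec.n_samples // spr
    n_sig = rec.n_channels

    peak = float(np.max(np.abs(rec.data))) if rec.data.size else 0.0
    phys = max(physical_range_uv, np.ceil(peak * 1.05))

    def pad(s: str, width: int) -> bytes:
        b = s.encode("ascii")[:width]
        return b + b" " * (width - len(b))

    header = b"".join([
        pad("0", 8),
        pad("X X X X", 80),
        pad(f"Startdate X X X X ref:{rec.reference}", 80),
        pad("01.01.00", 8),
        pad("00.00.00", 8),
        pad(str(256 * (1 + n_sig)), 8),
        pad("", 44),
        pad(str(n_records), 8),
        pad("1", 8),
        pad(str(n_sig), 4),
    ])
    sig_fields = []
    sig_fields.append(b"".join(pad(lbl, 16) for lbl in rec.channel_labels))
    sig_fields.append(b"".join(pad("AgAgCl electrode", 80) for _ in range(n_sig)))
    sig_fields.append(b"".join(pad("uV", 8) for _ in range(n_sig)))
    sig_fields.append(b"".join(pad(f"{-phys:.0f}", 8) for _ in range(n_sig)))
    sig_fields.append(b"".join(pad(f"{phys:.0f}", 8) for _ in range(n_sig)))
    sig_fields.append(b"".join(pad(str(-_EDF_DIGITAL_MAX), 8) for _ in range(n_sig)))
    sig_fields.append(b"".join(pad(str(_EDF_DIGITAL_MAX), 8) for _ in range(n_sig)))
    sig_fields.append(b"".join(pad("", 80) for _ in range(n_sig)))
    sig_fields.append(b"".join(pad(str(spr), 8) for _ in range(n_sig)))
    sig_fields.append(b"".join(pad("", 32) for _ in range(n_sig)))

    scale = _EDF_DIGITAL_MAX / phys
    digital = np.clip(np.round(rec.data * scale), -_EDF_DIGITAL_MAX,
                      _EDF_DIGITAL_MAX).astype("<i2")

    with open(path, "wb") as f:
        f.write(header)
        for block in sig_fields:
            f.write(block)
        # records: for each second, each signal's samples contiguously
        view = digital.reshape(n_sig, n_records, spr)
        for r in range(n_records):
            f.write(view[:, r, :].tobytes())

    sidecar = path.with_suffix(path.suffix + ".labels.csv")
    workload_to_intervals(rec.workload, rec.fs).to_csv(sidecar, index=False)
    return path


def read_recording(path: str | Path,
                   label_sidecar: str | Path | None = None) -> Recording:
    """Read an EDF file (via mne) into a Recording in microvolts.

    If ``label_sidecar`` is not given but ``<path>.labels.csv`` exists, it is
    used automatically; samples outside any interval are ``transition``.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data_uv = raw.get_data() * 1e6
    fs = float(raw.info["sfreq"])
    labels = list(raw.ch_names)

    reference = "unknown"
    # recording-id field carries the reference label (see write_recording)
    with open(path, "rb") as f:
        rec_id = f.read(256)[88:168].decode("ascii", "replace")
    if "ref:" in rec_id:
        reference = rec_id.split("ref:", 1)[1].strip()

    if label_sidecar is None:
        default = path.with_suffix(path.suffix + ".labels.csv")
        if default.exists():
            label_sidecar = default
    workload = None
    if label_sidecar is not None:
        df = pd.read_csv(label_sidecar)
        workload = intervals_to_workload(df, data_uv.shape[1], fs)

    return Recording(data=data_uv, fs=fs, channel_labels=labels,
                     reference=reference, workload=workload,
                     meta={"source": str(path)})


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """End-to-end pipeline configuration (YAML/JSON-loadable).

    Either ``input_edf`` names an existing recording or ``synth_preset``
    requests on-the-fly synthesis.
    """

    out_dir: str = "blinkbro_out"
    seed: int = 0
    input_edf: str | None = None
    label_sidecar: str | None = None
    synth_preset: str | None = None
    synth_duration_s: float = 300.0
    veog_channel: str = "VEOG"
    heog_channel: str = "HEOG"
    bandpass_low_hz: float = 0.1
    bandpass_high_hz: float = 80.0
    notch_hz: float = 60.0
    reject_threshold_uv: float = 500.0
    reject_pad_s: float = 0.5
    veog_lowpass_hz: float = 30.0
    corr_threshold: float = 0.7
    amp_threshold_sd: float = 2.0
    amp_floor_uv: float = 100.0
    detect_refractory_s: float = 0.25
    invert_veog: bool = False
    ica_corr_threshold: float = 0.6
    ica_frontal_ratio: float = 2.0
    epoch_s: float = 3.0
    isolation_s: float = 3.0
    n_permutations: int = 1000
    alpha: float = 0.05

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_file(self, path: str | Path) -> None:
        import yaml

        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage in order and write all intermediate artifacts.

    Returns a result bundle (dict) with stage outputs and counts. Any stage
    failure aborts with the stage name; partial outputs stay on disk together
    with a MANIFEST.json recording completion state.
    """
    from . import blink, bro_time, denoise, preprocess, synth

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stages": {}, "seed": config.seed}
    counts: dict = {}
    bundle: dict = {"out_dir": str(out), "counts": counts}

    def done(stage: str, **info) -> None:
        manifest["stages"][stage] = {"status": "ok", **info}
        (out / "MANIFEST.json").write_text(json.dumps(manifest, indent=2))
        logger.info("stage %s ok: %s", stage, info)

    stage = "load"
    try:
        if config.input_edf is not None:
            rec = read_recording(config.input_edf, config.label_sidecar)
        elif config.synth_preset is not None:
            cfg = synth.SynthConfig.preset(
                config.synth_preset, duration_s=config.synth_duration_s,
                seed=config.seed)
            rec, truth = synth.generate_recording(cfg)
            write_recording(rec, out / "synthetic.edf")
            (out / "ground_truth.json").write_text(json.dumps(
                truth.to_dict(), indent=2))
        else:
            raise PipelineError("config needs input_edf or synth_preset")
        if config.veog_channel not in rec.channel_labels:
            raise PipelineError(
                f"VEOG channel {config.veog_channel!r} missing from recording")
        done(stage, n_channels=rec.n_channels, duration_s=rec.duration_s)

        stage = "preprocess"
        rec = preprocess.bandpass(rec, config.bandpass_low_hz,
                                  config.bandpass_high_hz)
        rec = preprocess.notch(rec, config.notch_hz)
        rec, mask = preprocess.reject_segments(
            rec, abs_threshold_uv=config.reject_threshold_uv,
            pad_s=config.reject_pad_s)
        preprocess.write_mask_csv(mask, rec.fs, out / "bad_segments.csv")
        counts["masked_fraction"] = float(mask.mean())
        done(stage, masked_fraction=counts["masked_fraction"])

        stage = "detect-blinks"
        veog = rec.get(config.veog_channel)
        veog_lp = blink.lowpass_veog(veog, rec.fs, config.veog_lowpass_hz)
        events = blink.detect_blinks_two_pass(
            veog_lp, rec.fs, workload=rec.workload, mask=mask,
            corr_threshold=config.corr_threshold,
            amp_threshold_sd=config.amp_threshold_sd,
            amp_floor_uv=config.amp_floor_uv,
            refractory_s=config.detect_refractory_s,
            invert=config.invert_veog)
        write_events_csv(events, out / "blink_events.csv")
        counts["blinks_detected"] = len(events)
        counts["blinks_isolated"] = sum(e.isolated for e in events)
        rates = blink.blink_rate(events, rec.workload, rec.fs, mask=mask)
        (out / "blink_rates.json").write_text(json.dumps(rates, indent=2))
        done(stage, **{k: counts[k] for k in
                       ("blinks_detected", "blinks_isolated")})

        stage = "denoise"
        decomp = denoise.run_ica(rec, seed=config.seed, mask=mask)
        flagged = denoise.identify_artifact_components(
            decomp, veog=rec.get(config.veog_channel),
            heog=rec.get(config.heog_channel),
            corr_threshold=config.ica_corr_threshold,
            frontal_ratio=config.ica_frontal_ratio,
            events=events, fs=rec.fs)
        denoise.write_component_report(decomp, flagged,
                                       out / "ica_components.csv")
        cleaned = denoise.remove_components(rec, decomp, sorted(flagged))
        write_recording(cleaned, out / "cleaned.edf")
        counts["components_removed"] = len(flagged)
        done(stage, components_removed=len(flagged))

        stage = "epochs"
        pre_epochs = bro_time.extract_epochs(
            rec, events, epoch_s=config.epoch_s,
            isolation_s=config.isolation_s, mask=mask)
        epochs = bro_time.extract_epochs(
            cleaned, events, epoch_s=config.epoch_s,
            isolation_s=config.isolation_s, mask=mask)
        epochs.save(out / "epochs.npz")
        counts["epochs"] = epochs.n_epochs
        counts["epochs_per_workload"] = {
            w: epochs.workloads.count(w) for w in WORKLOAD_LEVELS}
        done(stage, n_epochs=epochs.n_epochs)

        stage = "time-domain"
        oci_results = []
        if epochs.n_epochs:
            oci_pre = denoise.compute_oci(pre_epochs)
            oci_post = denoise.compute_oci(epochs)
            oci_results = [("pre", oci_pre.oci), ("post", oci_post.oci)]
            (out / "oci.json").write_text(json.dumps({
                "pre": oci_pre.to_dict(), "post": oci_post.to_dict()},
                indent=2))
            delta = bro_time.delta_filter(epochs)
            table = bro_time.amplitude_table(delta)
            table.to_csv(out / "amplitudes.csv", index=False)
        done(stage, oci=dict(oci_results))

        stage = "tfr"
        from . import bro_tf

        tf_out = {}
        if epochs.n_epochs >= 4:
            tf = bro_tf.epochs_to_tfmap(epochs, channel="Pz")
            tf = bro_tf.baseline_correct(tf)
            res = bro_tf.permutation_prepost(
                tf, n_perm=config.n_permutations, alpha=config.alpha,
                seed=config.seed)
            bro_tf.write_significance_csv(res, out / "tf_prepost.csv")
            tf_out["significant_fraction"] = float(res.significant.mean())
        done(stage, **tf_out)

        bundle["events"] = events
        bundle["epochs"] = epochs
        bundle["rates"] = rates
        manifest["complete"] = True
        (out / "MANIFEST.json").write_text(json.dumps(manifest, indent=2))
        return bundle
    except Exception as exc:
        manifest["stages"][stage] = {"status": "failed", "error": str(exc)}
        manifest["complete"] = False
        (out / "MANIFEST.json").write_text(json.dumps(manifest, indent=2))
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
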