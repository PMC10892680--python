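# blinkbro

Blink-related oscillation (BRO) analysis of multichannel EEG.

Spontaneous blinks are followed by a stereotyped neural response — distinct
from the ocular artifact itself — that indexes how the brain re-evaluates the
visual scene after the eyes reopen. At posterior electrodes the response
appears as a delta-band dual-peak complex (a first peak *C1* around
200–400 ms and a second peak *C2* around 450–650 ms after the blink maximum)
and, in the time–frequency plane, as early delta/beta event-related
synchronization (ERS) followed by theta/alpha desynchronization (ERD), with
an additional theta ERD about 500 ms *before* the blink. Because both blink
rate and BRO amplitude are modulated by cognitive workload, blink-locked EEG
offers a passive, task-free window on operator state — e.g. for pilots
performing multi-attribute task batteries.

`blinkbro` implements the full analysis chain for 10/20-montage EEG with
bipolar VEOG/HEOG at 256 Hz:

1. **Preprocessing** — zero-phase 4th-order Butterworth band-pass
   (0.1–80 Hz), 60 Hz notch, automated artifact-segment masking.
2. **Blink detection** — convolution-based template matching on the 30 Hz
   low-passed VEOG (two-pass: canonical template → rebuild from detections →
   re-detect); blink rate per workload in blinks/min.
3. **Denoising** — InfoMax ICA; ocular components flagged by EOG correlation
   and frontal topography, removed by back-projection; verified with the
   ocular contamination index, OCI = RMS(±50 ms around blink) /
   RMS(100 ms at −1000 ms) on trial-averaged frontal channels.
4. **Time domain** — 3 s blink-locked epochs (blinks with >3 s isolation),
   delta-band (0.5–4 Hz) filtering, mean amplitudes in fixed windows
   (baseline −1300..−1100 ms, C1 200..400 ms, C2 450..650 ms, plus peak
   windows at −500/150/300/500 ms), repeated-measures ANOVA with
   Huynh–Feldt correction, Bonferroni post hocs, blink-count covariate.
5. **Time–frequency** — 6-cycle Morlet CWT log power at Pz (40 log-spaced
   frequencies 0.5–30 Hz), per-trial baseline correction (−1500..−500 ms),
   cell-wise permutation statistics (1000 label swaps) for pre/post-blink
   presence and workload contrasts.
6. **Synthesis** — a generator producing EDF recordings with ground truth:
   1/f background, posterior alpha/theta rhythms, 60 Hz line noise,
   frontally-mixed >250 μV blink artifacts at workload-dependent rates
   (19.4 / 16.0 / 11.9 blinks·min⁻¹ for low/medium/high), and injected BRO
   signatures — so every downstream stage is testable without restricted
   clinical data.

## Worked example

```python
from blinkbro import synth, workflows
from blinkbro.denoise import compute_oci

cfg = synth.SynthConfig.preset("low", duration_s=240.0, seed=7)
proc = workflows.simulate_and_process(cfg)

print(len(proc.events), "blinks,", proc.epochs.n_epochs, "isolated epochs")
print("components removed:", proc.removed_components)
print("OCI pre  %.2f" % compute_oci(proc.epochs_raw).oci)
print("OCI post %.2f" % compute_oci(proc.epochs).oci)

means = workflows.pz_window_means(proc.epochs)["low"]
print("Pz delta window means (uV):",
      {k: round(v, 2) for k, v in means.items()})
```

```
79 blinks, 52 isolated epochs
components removed: [0]
OCI pre  8.82
OCI post 1.60
Pz delta window means (uV): {'baseline': 0.14, 'C1': 1.61, 'C2': -2.57}
```

The single removed component is the ocular artifact; the OCI collapsing
toward 1 indicates the blink-time frontal amplitude is back at baseline
level; the positive C1 / negative C2 window means at Pz are the recovered
dual-peak BRO, matching the injected amplitudes.

The same stages are scriptable from the shell:

```bash
blinkbro simulate --preset low --duration 600 --seed 1 --out run/
blinkbro run --seed 1 --out run/          # full pipeline on a mixed preset
```

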