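# Methods

This note documents the models, numerical choices, and synthetic-data
assumptions behind `blinkbro`, in the spirit of a package methods appendix.
It states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Data model

A `Recording` is a channels × samples matrix in microvolts at one sampling
rate (default 256 Hz), with the 19-channel international 10/20 montage plus
bipolar VEOG/HEOG, a reference label (default left mastoid), and a
per-sample workload label in {low, medium, high, transition}. "Transition"
marks unlabeled padding between task segments; blinks occurring there are
excluded from every analysis. Artifactual stretches are *masked*, never
deleted, so sample indexing stays valid for event bookkeeping.

Continuous data are exchanged as EDF. Reading uses `mne.io.read_raw_edf`;
writing uses a minimal plain-EDF writer (16-bit samples, one-second data
records, per-channel physical range defaulting to ±1000 μV and widening
automatically if the data demand it — quantization is then ~0.03 μV).
Workload labels travel in a `(start_s, end_s, workload)` CSV sidecar;
overlapping intervals are an error.

## Preprocessing

Band-pass 0.1–80 Hz with a zero-phase 4th-order Butterworth (two passes →
−6 dB at the edges), 60 Hz IIR notch (Q = 30), both applied after 10 s
reflect-padding so the 0.1 Hz edge (10 s period) is free of boundary
transients. The manual artifact screening of typical EEG workflows is
replaced by a reproducible surrogate: any scalp-channel excursion beyond
±500 μV masks the surrounding ±0.5 s. EOG channels are exempt — blink
deflections are supposed to be huge there.

## Blink detection

The VEOG is low-passed at 30 Hz, then scanned with a sliding Pearson
correlation against a blink template (a raised-cosine-squared pulse of
half-width 0.35 s on the first pass; the unit-norm mean of ±0.35 s snippets
around first-pass detections on the second). Candidates must satisfy
correlation ≥ 0.7 *and* an amplitude gate; runs of candidates reduce to
their amplitude maximum, detections within 0.25 s collapse to the largest,
and each event is refined to the local VEOG maximum within ±0.1 s (the
blink maximum defines 0 ms throughout).

The amplitude gate combines a relative floor (2 robust SDs above the series
median, robust SD = 1.4826·MAD) with an absolute floor of 100 μV. The
absolute floor encodes the recording physiology: blink artifacts on a
bipolar VEOG exceed 250 μV, whereas slow background excursions of a few
tens of μV can correlate > 0.7 with any smooth unimodal template. With only
the relative gate such excursions enter at a rate of a few per ten minutes
and bias blink-rate estimates upward, most strongly when true blinks are
sparse (the MAD floor falls with blink density). Both floors are
configuration parameters; the absolute floor can be disabled for attenuated
or rescaled data.

Blink rate per workload is the event count over unmasked minutes carrying
that label. The isolated flag marks >3 s separation from both neighbors.

## Denoising

InfoMax ICA (via `mne.preprocessing.infomax`, classic non-extended variant)
on the 19 scalp channels. Fitting uses a 1 Hz high-passed copy with masked
samples dropped, decimated to at most ~10k samples — a standard
stationarity and tractability aid — after PCA whitening; the resulting
unmixing is applied to the full 0.1 Hz data, so `mixing @ sources`
reconstructs the input to numerical precision (full-rank case). Components
are ordered by explained variance with signs fixed so the largest mixing
weight is positive, making the decomposition reproducible under a seed.

Artifact components are flagged automatically, each with a logged reason:
|r| ≥ 0.6 against VEOG or HEOG, or a frontal/posterior mean |mixing-weight|
ratio ≥ 2 combined with blink-locked source amplitude ≥ 3× its −1000 ms
baseline. Removal back-projects the retained components; EOG channels pass
through untouched.

Denoising quality is quantified by the ocular contamination index: the RMS
of the trial-averaged signal over frontal channels (Fp1, Fp2, F3, F4, Fz)
in ±50 ms around the blink maximum, divided by the RMS in a 100 ms window
centered at −1000 ms. The ratio form is unit-free and scale-invariant; 1.0
means blink-time amplitude is indistinguishable from baseline. Pre/post
comparisons use a paired two-tailed t-test.

## Time-domain BRO

Epochs are 3 s windows centered on blink maxima: 769 samples at 256 Hz
(center ± 384), so 0 ms is an exact sample. Eligible blinks need >3 s to
both neighbors (epochs therefore never overlap), full in-bounds support, no
mask overlap, and a non-transition label. Epochs are filtered to the delta
band (0.5–4 Hz, zero-phase 4th-order Butterworth, reflect-padded by one
epoch length) and summarized as window means with inclusive endpoints and
`round(t·fs)` indexing (ties to even): baseline −1300..−1100 ms, C1
200..400 ms, C2 450..650 ms, and 100 ms peak windows at −500, 150, 300,
500 ms.

Presence testing compares per-subject mean amplitudes of {baseline, C1, C2}
at Pz with a one-way repeated-measures ANOVA plus Bonferroni-corrected
paired t-tests (signed, so C1-positive / C2-negative polarity under a
mastoid reference is assertable). Workload contrasts use a two-way
(channel × workload) within-subject ANOVA over {P3, Pz, P4, O1, O2} with
the per-subject-condition blink count as a covariate: amplitudes are
regression-adjusted on the centered count (one pooled within-cell slope)
before the ANOVA, which reduces exactly to the unadjusted analysis when
counts are constant. Post hoc paired t-tests between workload pairs within
each channel are Bonferroni-corrected by the number of comparisons run.

## Statistical engine

Huynh–Feldt epsilon is computed per effect: Greenhouse–Geisser epsilon from
the covariance of orthonormal-contrast scores, then the HF adjustment
`(n·df·ε_GG − 2) / (df·(n − 1 − df·ε_GG))`, clamped to [1/df, 1]. Corrected
degrees of freedom are (df₁ε, df₂ε). With two levels ε = 1 and F = t² of
the paired t-test. The one-way implementation agrees with `pingouin` to
numerical precision (cross-checked in the tests); the degenerate case of
identical values in all cells returns F = 0, p = 1 by contract. Bonferroni
is `min(1, m·p)`. Permutation p-values use the add-one rule
`p = (1 + #{|t_null| ≥ |t_obs|}) / (1 + n_perm)`, so p is never zero and
the test is valid at any n_perm.

## Time–frequency BRO

Each epoch at Pz is decomposed with a 6-cycle complex Morlet wavelet on 40
log-spaced frequencies from 0.5 to 30 Hz (≥6 grid points in each of the
delta/theta/alpha/beta bands). Wavelet support is ±5σ; epochs are
reflect-padded by the half-support of the slowest wavelet (6 s at 0.5 Hz)
before convolution, which is what makes the baseline window usable up to
the epoch edge. Coefficients are normalized so a unit-amplitude sinusoid at
a grid frequency yields |coef|² ≈ 1 along its ridge; log power is
ln(|coef|² + 10⁻¹²) (the floor keeps silent data finite and is recorded in
the output metadata). Baseline correction subtracts each trial's mean log
power over −1500..−500 ms per frequency, making corrected maps invariant to
per-trial amplitude scaling.

The pre/post presence test compares mirror-image windows, −1350..−150 ms
against +150..+1350 ms, pairing each post-blink latency +t with its
pre-blink mirror −t and testing the per-cell paired t across trials against
a 1000-draw sign-flip null. Mirrored pairing is deliberate: reflect-padding
slightly biases low-frequency log power near the epoch edges, and pairing
cells at *equal* edge distance cancels that bias exactly (index-aligned
windows turn it into spurious delta-band "effects" on pure noise, which the
calibration tests would catch); it likewise cancels any residual of the
time-symmetric blink artifact. Workload contrasts run the same cell-wise
machinery on subject-level mean maps (within-subject label permutation =
sign flips across subjects), thresholded at α/number-of-pairs (Bonferroni).
Inference is cell-wise with no cluster correction.

## Synthetic data

The generator is the package's stand-in for the restricted flight-task
dataset and defines the study conditions; its defaults are fixed once:

* **Background**: per-channel 1/f noise (exponent 1, 6 μV RMS), a shared
  posterior-dominant alpha rhythm (8–12 Hz, 6 μV) and theta rhythm (4–7 Hz,
  4 μV) mixed through a smooth occipital→frontal gain map, 60 Hz line noise
  (2 μV, common phase), and 2 μV white sensor noise. EOG channels carry
  5 μV 1/f noise.
* **Blinks**: a renewal process per workload segment at 19.4 / 16.0 / 11.9
  blinks·min⁻¹ (low/medium/high). Inter-blink gaps are a two-state mixture
  — short "cluster" gaps (refractory 0.5 s to 1 s) with probability
  1 − √0.7, otherwise 3.4 s + gamma(shape 2) — with the long-gap mean
  solved so the overall mean gap is exactly 60/rate. This pins the realized
  rate to the configured one while guaranteeing ≥70% of blinks have >3.2 s
  isolation (a plain renewal process cannot satisfy both at ~19 blinks/min,
  where the mean gap is already below the isolation threshold). Rates
  incompatible with the refractory/isolation constraints raise an error.
* **Artifact**: a raised-cosine-squared pulse (300 μV peak at VEOG, 0.35 s
  half-width) mixed frontally (gain 1.0 at Fp1/Fp2 decaying to 0.05
  occipitally).
* **BRO**: a posterior-dominant (max at Pz, ≈0 frontally) delta dual-peak —
  Gaussian lobes of σ = 120 ms at +300 ms (positive) and +550 ms (negative,
  ×0.85) — scaled 3.0 / 2.5 / 2.0 μV by workload; these absolute amplitudes
  are an implementer's choice (no published value exists). σ = 120 ms keeps
  the lobe spectra inside the delta band; narrower lobes leak C2 energy
  into 4–5 Hz and masquerade as theta ERS. A 20 Hz Gaussian burst at
  +150 ms (3.0 / 2.5 / 1.5 μV) implements beta ERS. ERD is multiplicative —
  a power *decrease* of an ongoing rhythm cannot be additive — as Gaussian
  dips in the rhythm envelopes: theta at −500 ms (depth 0.6 / 0.45 / 0.2,
  weakening with workload) and +500 ms (0.5), alpha at +400 ms (0.45).
* **Presets**: `low` / `medium` / `high` single-workload, `mixed` (three
  segments with 2 s transitions), `no_bro` (artifact kept, BRO gain zero —
  the negative control for presence testing) and `null_tf` (additionally no
  scalp artifact projection — a strict exchangeability control for
  trial-level time–frequency calibration).

What the generator does *not* emulate: saccades, muscle or cardiac
artifacts, electrode drift or pops, inter-subject anatomical variability,
volume-conduction realism, or non-stationary blink statistics. Passing
tests therefore demonstrate that the pipeline recovers known ground truth
under idealized but structured conditions — not that it handles every
failure mode of clinical recordings.

## Problem sizes in the test suite

Monte-Carlo tests scale the per-subject data rather than the design: blink
rate recovery uses 120 simulated minutes per preset over 10 seeds; the
presence/workload studies use 20 replicates of 8 subjects with 240 s of low
and high and 90 s of medium workload per subject (the source paradigm
pooled ~15 sessions per subject, so minutes-scale per-subject data is the
faithful desk-scale analogue; 90 s suffices for presence power, while the
subject-level time–frequency contrast needs the longer low/high segments).
The negative-control runs use 60 s segments — type-I behavior does not
depend on power. A single ICA per subject serves all workload levels.

## Known limitations

* The OCI formula (RMS ratio over frontal channels) is a documented
  surrogate for an index whose exact published form is not restated here;
  comparisons should stay relative (pre vs post), not absolute.
* ICA separation of the artifact from a time-locked BRO is imperfect by
  construction (the sources are temporally dependent); a sub-μV residual of
  a 300 μV artifact survives at posterior channels. The mirror-paired
  presence test is insensitive to it, but trial-level statistics with many
  hundreds of trials could resolve it.
* Two-way rm-ANOVA epsilons are computed per effect from contrast
  covariances; with small n and many levels, HF epsilon estimates are noisy
  (the same caveat standard packages carry).
* The EDF writer emits plain EDF (no annotations, whole-second recordings,
  integer sampling rates).
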