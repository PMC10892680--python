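"""Morlet CWT, log power, baseline correction, permutation maps."""

import numpy as np
import pytest

from blinkbro import bro_tf
from blinkbro.bro_tf import (TFMap, baseline_correct, default_freqs,
                             log_power, morlet_cwt, permutation_prepost,
                             permutation_workload)

FS = 256.0


def _tone(freq, seconds=3.0, amp=1.0):
    t = np.arange(int(seconds * FS)) / FS
    return amp * np.sin(2 * np.pi * freq * t)


class TestMorletCWT:
    def test_ridge_localization(self):
        freqs = default_freqs()
        coefs = morlet_cwt(_tone(10.0), FS, freqs)
        ridge = np.abs(coefs[:, 300:-300] ** 2).mean(axis=1)
        assert freqs[np.argmax(ridge)] == pytest.approx(10.0, rel=0.05)

    def test_ridge_matches_mne_oracle(self):
        from mne.time_frequency import tfr_array_morlet

        freqs = np.linspace(4.0, 30.0, 27)
        x = _tone(12.0, seconds=4.0)
        ours = morlet_cwt(x, FS, freqs)
        theirs = tfr_array_morlet(x[None, None, :], FS, freqs, n_cycles=6.0,
                                  output="complex", verbose="error")[0, 0]
        mid = slice(300, -300)
        ridge_ours = np.abs(ours[:, mid]).mean(axis=1)
        ridge_mne = np.abs(theirs[:, mid]).mean(axis=1)
        assert np.argmax(ridge_ours) == np.argmax(ridge_mne)

    def test_unit_sinusoid_flat_unit_ridge(self):
        freqs = np.array([2.0, 8.0, 20.0])
        for f in freqs:
            coefs = morlet_cwt(_tone(f, seconds=6.0), FS, np.array([f]))
            mag2 = np.abs(coefs[0, 500:-500]) ** 2
            assert np.allclose(mag2, 1.0, atol=0.05)

    def test_two_ridges(self):
        freqs = default_freqs()
        coefs = morlet_cwt(_tone(5.0) + _tone(20.0), FS, freqs)
        prof = (np.abs(coefs[:, 250:-250]) ** 2).mean(axis=1)
        peaks = [i for i in range(1, len(prof) - 1)
                 if prof[i] > prof[i - 1] and prof[i] > prof[i + 1]
                 and prof[i] > 0.1 * prof.max()]
        located = sorted(freqs[i] for i in peaks)
        assert len(located) == 2
        assert located[0] == pytest.approx(5.0, rel=0.08)
        assert located[1] == pytest.approx(20.0, rel=0.08)

    def test_temporal_smearing_heisenberg_ordering(self):
        x = np.zeros(int(3 * FS))
        x[len(x) // 2] = 1.0

        def half_max_duration(f):
            mag = np.abs(morlet_cwt(x, FS, np.array([f]))[0])
            return (mag >= mag.max() / 2).sum() / FS

        assert half_max_duration(4.0) > half_max_duration(20.0)

    def test_out_of_range_frequency(self):
        with pytest.raises(ValueError):
            morlet_cwt(_tone(10.0), FS, np.array([0.0, 5.0]))
        with pytest.raises(ValueError):
            morlet_cwt(_tone(10.0), FS, np.array([5.0, 200.0]))


class TestLogPower:
    def _map(self, coefs):
        n = coefs.shape[-1]
        times = (np.arange(n) - n // 2) / FS * 1000
        return log_power(coefs, np.array([10.0]), times)

    def test_unit_coefficients_give_zero(self):
        tf = self._map(np.ones((1, 100), dtype=complex))
        assert np.allclose(tf.power, 0.0, atol=1e-9)

    def test_amplitude_doubling_adds_ln4(self):
        rng = np.random.default_rng(0)
        c = rng.normal(size=(1, 100)) + 1j * rng.normal(size=(1, 100))
        a = self._map(c)
        b = self._map(2 * c)
        np.testing.assert_allclose(b.power - a.power, np.log(4.0), atol=1e-9)

    def test_zero_signal_finite_floor(self):
        tf = self._map(np.zeros((1, 100), dtype=complex))
        assert np.all(np.isfinite(tf.power))
        assert np.allclose(tf.power, np.log(bro_tf.EPS_FLOOR))


def _toy_map(power, corrected=False):
    n_e, n_f, n_t = power.shape
    times = (np.arange(n_t) - n_t // 2) / FS * 1000
    return TFMap(power=power, freqs=np.arange(1, n_f + 1, dtype=float),
                 times_ms=times, channel="Pz", baseline_corrected=corrected)


class TestBaselineCorrect:
    def test_constant_in_time_becomes_zero(self):
        power = np.tile(np.array([[[1.0], [5.0]]]), (3, 1, 769))
        out = baseline_correct(_toy_map(power))
        assert np.allclose(out.power, 0.0)

    def test_hand_built_subtraction(self):
        n_t = 769
        times = (np.arange(n_t) - n_t // 2) / FS * 1000
        sel = (times >= -1500) & (times <= -500)
        power = np.zeros((2, 2, n_t))
        power[0, 0, sel] = 2.0     # trial 0, freq 0: baseline mean 2
        power[1, 1, :] = 7.0       # trial 1, freq 1: constant 7
        out = baseline_correct(_toy_map(power))
        assert out.power[0, 0, ~sel] == pytest.approx(-2.0)
        assert np.allclose(out.power[1, 1], 0.0)

    def test_postcondition_zero_baseline_mean(self):
        rng = np.random.default_rng(1)
        out = baseline_correct(_toy_map(rng.normal(size=(4, 5, 769))))
        sel = (out.times_ms >= -1500) & (out.times_ms <= -500)
        means = out.power[:, :, sel].mean(axis=2)
        assert np.abs(means).max() < 1e-9

    def test_double_correction_errors(self):
        out = baseline_correct(_toy_map(np.zeros((1, 1, 769))))
        with pytest.raises(ValueError, match="already"):
            baseline_correct(out)

    def test_per_trial_scaling_invariance(self):
        rng = np.random.default_rng(2)
        amp = np.exp(rng.normal(size=(6, 1, 1)))
        coefs = rng.normal(size=(6, 4, 769)) + 1j * rng.normal(size=(6, 4, 769))
        times = (np.arange(769) - 384) / FS * 1000
        a = baseline_correct(log_power(coefs, np.arange(1, 5.0), times))
        b = baseline_correct(log_power(coefs * amp, np.arange(1, 5.0), times))
        np.testing.assert_allclose(a.power, b.power, atol=1e-7)


class TestPermutationPrepost:
    def test_seed_reproducibility(self):
        rng = np.random.default_rng(3)
        tf = _toy_map(rng.normal(size=(12, 4, 769)), corrected=True)
        a = permutation_prepost(tf, n_perm=200, seed=9)
        b = permutation_prepost(tf, n_perm=200, seed=9)
        np.testing.assert_array_equal(a.p, b.p)

    def test_rejects_overlapping_windows(self):
        tf = _toy_map(np.zeros((4, 2, 769)), corrected=True)
        with pytest.raises(ValueError, match="disjoint"):
            permutation_prepost(tf, pre_window_ms=(-500, 100),
                                post_window_ms=(0, 600))

    def test_rejects_too_few_permutations(self):
        tf = _toy_map(np.zeros((4, 2, 769)), corrected=True)
        with pytest.raises(ValueError, match="n_perm"):
            permutation_prepost(tf, n_perm=10)

    def test_symmetric_trials_calibrate_at_alpha(self):
        # trials whose pre and post segments are exchangeable by construction
        rng = np.random.default_rng(4)
        fractions = []
        for _ in range(5):
            tf = _toy_map(rng.normal(size=(30, 10, 769)), corrected=True)
            res = permutation_prepost(tf, n_perm=200, alpha=0.05,
                                      seed=int(rng.integers(2 ** 31)))
            fractions.append(res.significant.mean())
        assert 0.5 * 0.05 <= np.mean(fractions) <= 2 * 0.05


class TestPermutationWorkload:
    def test_single_workload_errors(self):
        with pytest.raises(ValueError, match="two workload"):
            permutation_workload({"low": np.zeros((4, 2, 10))})

    def test_shape_mismatch_errors(self):
        with pytest.raises(ValueError, match="shape"):
            permutation_workload({"low": np.zeros((4, 2, 10)),
                                  "high": np.zeros((4, 2, 11))})

    def test_identical_presets_calibrate_at_corrected_alpha(self):
        rng = np.random.default_rng(5)
        fracs = []
        for _ in range(5):
            maps = {w: rng.normal(size=(8, 6, 40)) for w in ("low", "high")}
            res = permutation_workload(maps, n_perm=300, alpha=0.05,
                                       n_comparisons=3,
                                       seed=int(rng.integers(2 ** 31)))
            fracs.append(res[("low", "high")].significant.mean())
        target = 0.05 / 3
        assert 0.2 * target <= np.mean(fracs) <= 3 * target

    def test_detects_injected_difference(self):
        rng = np.random.default_rng(6)
        base = {w: rng.normal(size=(8, 6, 40)) for w in ("low", "high")}
        base["high"][:, 2, 10:20] += 3.0
        res = permutation_workload(base, n_perm=300, seed=0)
        sig = res[("low", "high")].significant
        assert sig[2, 10:20].mean() > 0.5
        assert sig[0].mean() < 0.1
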