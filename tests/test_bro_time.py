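"""Blink-locked epoching, delta filtering, window means, BRO statistics."""

import numpy as np
import pandas as pd
import pytest

from blinkbro import bro_time
from blinkbro.core_io import ALL_CHANNELS, BlinkEvent, Recording
from blinkbro.bro_time import (covariate_adjust, delta_filter, extract_epochs,
                               presence_test, window_mean, window_samples,
                               workload_contrast)

FS = 256.0


def _rec(seconds=10.0, workload="low"):
    n = int(seconds * FS)
    rec = Recording(data=np.zeros((21, n)), fs=FS,
                    workload=np.full(n, workload, dtype="<U10"))
    return rec


def _event(t):
    return BlinkEvent(int(t * FS), t, 300.0, True, "low")


class TestExtractEpochs:
    def test_isolation_rule_rejects_close_pair(self):
        eps = extract_epochs(_rec(), [_event(1.0), _event(3.5)])
        assert eps.n_epochs == 0

    def test_bounds_rule(self):
        eps = extract_epochs(_rec(), [_event(1.4)])
        assert eps.n_epochs == 0

    def test_single_event_shape_and_center(self):
        eps = extract_epochs(_rec(), [_event(5.0)])
        assert eps.tensor.shape == (1, 21, 769)
        assert eps.times[384] == 0.0
        assert eps.times[0] == pytest.approx(-1.5)

    def test_transition_events_dropped(self):
        rec = _rec(workload="transition")
        eps = extract_epochs(rec, [_event(5.0)])
        assert eps.n_epochs == 0

    def test_masked_epochs_dropped(self):
        rec = _rec()
        mask = np.zeros(rec.n_samples, dtype=bool)
        mask[int(6.0 * FS):int(6.1 * FS)] = True
        assert extract_epochs(rec, [_event(5.0)], mask=mask).n_epochs == 0

    def test_no_overlapping_epochs(self, processed_low):
        starts = np.array([e.sample for e in processed_low.epochs.events])
        assert np.all(np.diff(starts) > 3.0 * FS)


class TestDeltaFilter:
    def _epochs_with_tone(self, freq, amp=1.0):
        rec = _rec()
        t = np.arange(rec.n_samples) / FS
        rec.data[:] = amp * np.sin(2 * np.pi * freq * t)
        return extract_epochs(rec, [_event(5.0)])

    def test_passband_2hz(self):
        out = delta_filter(self._epochs_with_tone(2.0))
        amp = np.sqrt(2) * out.tensor[0, 0].std()
        assert abs(amp - 1.0) <= 0.05

    def test_stopband_10hz(self):
        out = delta_filter(self._epochs_with_tone(10.0))
        assert np.sqrt(2) * out.tensor[0, 0].std() <= 0.10

    def test_zero_stays_zero(self):
        out = delta_filter(extract_epochs(_rec(), [_event(5.0)]))
        assert np.abs(out.tensor).max() < 1e-12


class TestWindowMean:
    def test_constant_epoch(self):
        eps = extract_epochs(_rec(), [_event(5.0)])
        eps.tensor[:] = 3.0
        for w in bro_time.PEAK_WINDOWS_MS:
            assert window_mean(eps, w, ["Pz"]).iloc[0, 0] == pytest.approx(3.0)

    def test_baseline_window_sample_count(self):
        # -1300..-1100 ms inclusive at 256 Hz: indices round(-1.3*256) =
        # -333 .. round(-1.1*256) = -282, i.e. 52 samples
        times = (np.arange(769) - 384) / FS
        sel = window_samples(times, FS, (-1300.0, -1100.0))
        assert sel.sum() == 52
        first, last = np.flatnonzero(sel)[[0, -1]]
        assert first - 384 == round(-1.3 * FS)
        assert last - 384 == round(-1.1 * FS)

    def test_linearity(self):
        eps = extract_epochs(_rec(), [_event(5.0)])
        rng = np.random.default_rng(0)
        a = rng.normal(size=eps.tensor.shape)
        b = rng.normal(size=eps.tensor.shape)
        eps.tensor = 2 * a + 3 * b
        combined = window_mean(eps, "C1").to_numpy()
        eps.tensor = a
        wa = window_mean(eps, "C1").to_numpy()
        eps.tensor = b
        wb = window_mean(eps, "C1").to_numpy()
        np.testing.assert_allclose(combined, 2 * wa + 3 * wb, atol=1e-12)

    def test_window_outside_epoch(self):
        eps = extract_epochs(_rec(), [_event(5.0)])
        with pytest.raises(ValueError, match="outside"):
            window_mean(eps, (-2000.0, -1800.0), ["Pz"])

    def test_c1_exceeds_baseline_on_synthetic(self, processed_low):
        delta = delta_filter(processed_low.epochs)
        c1 = window_mean(delta, "C1", ["Pz"]).mean().iloc[0]
        base = window_mean(delta, "baseline", ["Pz"]).mean().iloc[0]
        assert c1 > base


class TestPresenceTest:
    def test_identical_conditions(self):
        x = np.tile(np.array([[1.0], [2.0], [3.0], [4.0]]), (1, 3))
        res = presence_test(x)
        assert res[0].statistic == 0.0
        assert res[0].p_raw == 1.0

    def test_matches_bruteforce_oracle(self):
        from conftest import rm_anova_bruteforce
        x = np.array([[0.1, 2.0, -1.5],
                      [-0.3, 1.2, -0.8],
                      [0.2, 2.5, -2.1],
                      [0.0, 1.8, -1.0]])
        res = presence_test(x)
        oracle = rm_anova_bruteforce(x)
        assert res[0].statistic == pytest.approx(oracle["F"], abs=1e-10)
        assert res[0].epsilon == pytest.approx(oracle["hf"], abs=1e-10)

    def test_posthoc_signs_and_correction(self):
        rng = np.random.default_rng(0)
        base = rng.normal(0, 0.1, 8)
        x = np.column_stack([base, base + 2.0, base - 2.0])
        res = presence_test(x)
        c1 = next(r for r in res if r.contrast == "C1 vs baseline")
        c2 = next(r for r in res if r.contrast == "C2 vs baseline")
        assert c1.statistic > 0 and c2.statistic < 0
        assert c1.p_corrected >= c1.p_raw

    def test_too_few_subjects(self):
        with pytest.raises(ValueError, match="subjects"):
            presence_test(np.zeros((1, 3)))


def _contrast_table(seed=0, effect=None):
    rng = np.random.default_rng(seed)
    channels = ("P3", "Pz", "P4", "O1", "O2")
    workloads = ("low", "medium", "high")
    rows = []
    for s in range(6):
        off = rng.normal(0, 0.5)
        for ci, ch in enumerate(channels):
            for wi, w in enumerate(workloads):
                val = off + rng.normal(0, 0.3)
                if effect:
                    val += effect * wi * (ci + 1) / 5.0
                rows.append({"subject": s, "channel": ch, "workload": w,
                             "mean_uv": val, "blink_count": 30 - 5 * wi})
    return pd.DataFrame(rows)


class TestWorkloadContrast:
    def test_identical_values_give_zero_f(self):
        df = _contrast_table()
        df["mean_uv"] = 1.0
        df["blink_count"] = 10
        res = workload_contrast(df)
        for r in res:
            if r.test_name in ("channel", "workload", "channel*workload"):
                assert r.statistic == 0.0

    def test_constant_covariate_is_noop(self):
        df = _contrast_table(seed=1)
        df_const = df.copy()
        df_const["blink_count"] = 25
        df_no = df.drop(columns=["blink_count"])
        res_const = workload_contrast(df_const)
        res_no = workload_contrast(df_no)
        for a, b in zip(res_const, res_no):
            assert a.statistic == pytest.approx(b.statistic, abs=1e-10)

    def test_missing_cell_errors(self):
        df = _contrast_table()
        df = df[~((df.subject == 0) & (df.channel == "Pz")
                  & (df.workload == "high"))]
        with pytest.raises(ValueError, match="missing cell"):
            workload_contrast(df)

    def test_detects_injected_workload_effect(self):
        res = workload_contrast(_contrast_table(seed=2, effect=2.0))
        workload_f = next(r for r in res if r.test_name == "workload")
        assert workload_f.p_corrected < 0.01


class TestCovariateAdjust:
    def test_centered_constant_covariate_noop(self):
        v = np.array([1.0, 2.0, 3.0, 4.0])
        out = covariate_adjust(v, np.full(4, 9.0), np.array(list("aabb")))
        np.testing.assert_allclose(out, v)

    def test_removes_known_slope(self):
        rng = np.random.default_rng(3)
        c = rng.normal(size=200)
        v = 2.5 * c + rng.normal(scale=0.01, size=200)
        out = covariate_adjust(v, c, np.zeros(200))
        slope = np.polyfit(c, out, 1)[0]
        assert abs(slope) < 0.01
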