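"""Statistical engine: rm-ANOVA, Huynh-Feldt, paired t, Bonferroni, permutation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from blinkbro import stats as bs
from conftest import paired_t_bruteforce, rm_anova_bruteforce


class TestRmAnova:
    def test_two_levels_equals_paired_t_squared(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(8, 2))
        res = bs.rm_anova(x)
        t = bs.paired_t(x[:, 0], x[:, 1])
        assert res.epsilon == pytest.approx(1.0)
        assert res.statistic == pytest.approx(t.statistic ** 2, rel=1e-10)
        assert res.p_raw == pytest.approx(t.p_raw, rel=1e-10)

    def test_matches_bruteforce_oracle(self):
        x = np.array([
            [3.1, 4.5, 2.2],
            [2.8, 5.1, 1.9],
            [3.5, 4.0, 2.8],
            [2.9, 4.8, 2.5],
        ])
        res = bs.rm_anova(x)
        oracle = rm_anova_bruteforce(x)
        assert res.statistic == pytest.approx(oracle["F"], abs=1e-10)
        assert res.epsilon == pytest.approx(oracle["hf"], abs=1e-10)
        assert res.p_raw == pytest.approx(oracle["p_raw"], abs=1e-10)
        assert res.p_corrected == pytest.approx(oracle["p_hf"], abs=1e-10)

    def test_matches_pingouin(self):
        import pandas as pd
        import pingouin as pg

        rng = np.random.default_rng(1)
        x = rng.normal(size=(7, 4)) + np.cumsum(
            rng.normal(size=(7, 4)), axis=1) * 0.4
        res = bs.rm_anova(x)
        df = pd.DataFrame({
            "y": x.ravel(),
            "s": np.repeat(np.arange(7), 4),
            "c": np.tile(np.arange(4), 7),
        })
        pr = pg.rm_anova(data=df, dv="y", within="c", subject="s",
                         correction=True, detailed=True)
        assert res.statistic == pytest.approx(float(pr.loc[0, "F"]), rel=1e-9)
        assert res.p_raw == pytest.approx(float(pr.loc[0, "p_unc"]), rel=1e-9)
        wide = df.pivot(index="s", columns="c", values="y")
        assert res.epsilon == pytest.approx(
            float(pg.epsilon(wide, correction="hf")), rel=1e-9)

    def test_epsilon_near_one_under_sphericity(self):
        rng = np.random.default_rng(2)
        eps = []
        for _ in range(500):
            x = rng.normal(size=(12, 4)) + rng.normal(size=(12, 1))
            eps.append(bs.rm_anova(x).epsilon)
        assert np.mean(eps) >= 0.9

    def test_epsilon_bounds(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            x = np.cumsum(rng.normal(size=(5, 4)), axis=1)
            e = bs.rm_anova(x).epsilon
            assert 1.0 / 3 <= e <= 1.0

    def test_incomplete_design_errors(self):
        x = np.ones((4, 3))
        x[0, 0] = np.nan
        with pytest.raises(ValueError, match="incomplete"):
            bs.rm_anova(x)


class TestTwoWay:
    def test_matches_pingouin_f_values(self):
        import pandas as pd
        import pingouin as pg

        rng = np.random.default_rng(4)
        z = rng.normal(size=(8, 3, 4)) + rng.normal(size=(8, 1, 1))
        res = {r.test_name: r for r in bs.rm_anova_two_way(z, ("A", "B"))}
        rows = [{"y": z[s, a, b], "s": s, "A": a, "B": b}
                for s in range(8) for a in range(3) for b in range(4)]
        pr = pg.rm_anova(data=pd.DataFrame(rows), dv="y", within=["A", "B"],
                         subject="s", detailed=False).set_index("Source")
        for ours, theirs in [("A", "A"), ("B", "B"), ("A*B", "A * B")]:
            assert res[ours].statistic == pytest.approx(
                float(pr.loc[theirs, "F"]), rel=1e-9)
            assert res[ours].p_raw == pytest.approx(
                float(pr.loc[theirs, "p_unc"]), rel=1e-9)

    def test_each_effect_has_own_epsilon(self):
        rng = np.random.default_rng(5)
        z = np.cumsum(rng.normal(size=(10, 3, 3)), axis=1)
        res = bs.rm_anova_two_way(z)
        eps = [r.epsilon for r in res]
        assert all(0.0 < e <= 1.0 for e in eps)
        assert len(set(np.round(eps, 6))) >= 2


class TestPairedT:
    def test_identical_inputs(self):
        x = np.array([1.0, 2.0, 3.0])
        res = bs.paired_t(x, x)
        assert res.statistic == 0.0 and res.p_raw == 1.0

    def test_antisymmetry(self):
        rng = np.random.default_rng(6)
        x, y = rng.normal(size=10), rng.normal(size=10)
        assert bs.paired_t(x, y).statistic == \
            pytest.approx(-bs.paired_t(y, x).statistic, rel=1e-12)

    def test_matches_closed_form(self):
        x = [2.1, 3.4, 1.9, 4.2, 3.3]
        y = [1.5, 2.9, 2.2, 3.1, 2.8]
        res = bs.paired_t(np.array(x), np.array(y))
        oracle = paired_t_bruteforce(x, y)
        assert res.statistic == pytest.approx(oracle["t"], abs=1e-10)
        assert res.p_raw == pytest.approx(oracle["p"], abs=1e-10)
        assert res.df[1] == oracle["df"]

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError, match="zero variance"):
            bs.paired_t(np.array([5.0, 6.0, 7.0]), np.array([3.0, 4.0, 5.0]))


class TestBonferroni:
    def test_examples(self):
        np.testing.assert_allclose(bs.bonferroni([0.01], 3), [0.03])
        np.testing.assert_allclose(bs.bonferroni([0.5], 3), [1.0])
        np.testing.assert_allclose(bs.bonferroni([0.2, 0.4], 2), [0.4, 0.8])

    def test_m_one_is_identity(self):
        np.testing.assert_allclose(bs.bonferroni([0.17], 1), [0.17])

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=6))
    def test_order_preserving_and_dominating(self, ps):
        out = bs.bonferroni(ps, m=len(ps))
        assert np.all(out >= np.asarray(ps))
        order_in = np.argsort(ps, kind="stable")
        assert np.all(np.diff(np.asarray(out)[order_in]) >= -1e-12)

    def test_invalid_p(self):
        with pytest.raises(ValueError):
            bs.bonferroni([1.2], 2)
        with pytest.raises(ValueError, match="family size"):
            bs.bonferroni([0.1, 0.2], 1)


def _t_stat(d):
    return d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))


def _signflip(rng, d):
    return d * (rng.integers(0, 2, size=len(d)) * 2 - 1)


class TestPermutationNull:
    def test_addone_lower_bound(self):
        d = np.full(10, 5.0) + np.random.default_rng(0).normal(0, 0.01, 10)
        null, p = bs.permutation_null(_t_stat, d, _signflip, n_perm=200,
                                      seed=1)
        # only the (rare) all-positive sign draw can tie the observed t, so
        # p sits at the add-one floor plus at most a couple of ties
        assert 1.0 / 201.0 <= p <= 3.0 / 201.0

    def test_seed_reproducibility(self):
        d = np.random.default_rng(1).normal(size=12)
        _, p1 = bs.permutation_null(_t_stat, d, _signflip, n_perm=150, seed=3)
        _, p2 = bs.permutation_null(_t_stat, d, _signflip, n_perm=150, seed=3)
        assert p1 == p2

    def test_calibration_under_null(self):
        rng = np.random.default_rng(2)
        rejections = 0
        n_rep = 500
        for _ in range(n_rep):
            d = rng.normal(size=10)
            _, p = bs.permutation_null(_t_stat, d, _signflip, n_perm=199,
                                       seed=int(rng.integers(2 ** 31)))
            rejections += p <= 0.05
        assert 0.03 <= rejections / n_rep <= 0.07

    def test_too_few_permutations(self):
        with pytest.raises(ValueError):
            bs.permutation_null(_t_stat, np.ones(5), _signflip, n_perm=50)


class TestSignflipMap:
    def test_matches_scalar_paired_t(self):
        rng = np.random.default_rng(7)
        d = rng.normal(size=(12, 5))
        t = bs.paired_t_map(d)
        for j in range(5):
            expected = _t_stat(d[:, j])
            assert t[j] == pytest.approx(expected, rel=1e-12)

    def test_pvalues_never_zero(self):
        rng = np.random.default_rng(8)
        d = rng.normal(size=(10, 20)) + 3.0
        _, p = bs.signflip_t_pvalues(d, n_perm=200, seed=0)
        assert p.min() >= 1.0 / 201.0
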