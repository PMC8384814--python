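"""Repeated-measures ANOVA, post-hoc tests, FDR, one-sample t."""

import numpy as np
import pandas as pd
import pytest

from neoms.groupstats import (fdr_adjust, one_sample_t, paired_posthoc,
                              rm_anova_2way)

# 5-subject 2x3 within-subject fixture (hand-checkable sums of squares)
FIXTURE = np.array([
    [[10.0, 12.0, 14.0], [11.0, 14.0, 17.0]],
    [[9.0, 11.0, 12.0], [10.0, 13.0, 15.0]],
    [[12.0, 13.0, 16.0], [12.0, 16.0, 18.0]],
    [[8.0, 10.0, 11.0], [9.0, 12.0, 14.0]],
    [[11.0, 13.0, 15.0], [12.0, 15.0, 18.0]],
])


def _ss_oracle(cube):
    """Direct sums-of-squares decomposition, written independently."""
    n, a, b = cube.shape
    g = cube.mean()
    out = {}
    ss_a = sum(b * n * (cube[:, i, :].mean() - g) ** 2 for i in range(a))
    ss_b = sum(a * n * (cube[:, :, j].mean() - g) ** 2 for j in range(b))
    ss_ab = 0.0
    for i in range(a):
        for j in range(b):
            ss_ab += n * (cube[:, i, j].mean() - cube[:, i, :].mean()
                          - cube[:, :, j].mean() + g) ** 2
    ss_sa = 0.0
    for s in range(n):
        for i in range(a):
            ss_sa += b * (cube[s, i, :].mean() - cube[s].mean()
                          - cube[:, i, :].mean() + g) ** 2
    ss_sb = 0.0
    for s in range(n):
        for j in range(b):
            ss_sb += a * (cube[s, :, j].mean() - cube[s].mean()
                          - cube[:, :, j].mean() + g) ** 2
    ss_total = ((cube - g) ** 2).sum()
    ss_subj = a * b * ((cube.mean(axis=(1, 2)) - g) ** 2).sum()
    ss_sab = ss_total - ss_subj - ss_a - ss_b - ss_ab - ss_sa - ss_sb
    out["A"] = (ss_a, a - 1, ss_sa, (a - 1) * (n - 1))
    out["B"] = (ss_b, b - 1, ss_sb, (b - 1) * (n - 1))
    out["A * B"] = (ss_ab, (a - 1) * (b - 1), ss_sab,
                    (a - 1) * (b - 1) * (n - 1))
    return out


class TestRmAnova:
    def test_matches_direct_ss_oracle(self):
        results = {r.effect: r for r in rm_anova_2way(FIXTURE)}
        oracle = _ss_oracle(FIXTURE)
        for effect, (ss_eff, df1, ss_err, df2) in oracle.items():
            r = results[effect]
            f_expect = (ss_eff / df1) / (ss_err / df2)
            assert r.F == pytest.approx(f_expect, rel=1e-10)
            pes = ss_eff / (ss_eff + ss_err)
            assert r.partial_eta_squared == pytest.approx(pes, rel=1e-10)

    def test_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        n, a, b = FIXTURE.shape
        rows = []
        for s in range(n):
            for i in range(a):
                for j in range(b):
                    rows.append(dict(subject=s, A=f"a{i}", B=f"b{j}",
                                     value=FIXTURE[s, i, j]))
        df = pd.DataFrame(rows)
        tab = pingouin.rm_anova(data=df, dv="value", within=["A", "B"],
                                subject="subject", correction=True,
                                effsize="np2", detailed=True)
        ours = {r.effect: r for r in rm_anova_2way(FIXTURE)}
        for src, key in (("A", "A"), ("B", "B"), ("A * B", "A * B")):
            row = tab[tab.Source == src].iloc[0]
            assert ours[key].F == pytest.approx(row.F, rel=1e-6)
            assert ours[key].partial_eta_squared == pytest.approx(
                row.np2, rel=1e-6)
            if "eps" in tab.columns and np.isfinite(row.eps) and \
                    ours[key].epsilon < 1.0:
                assert ours[key].epsilon == pytest.approx(row.eps, rel=1e-4)

    def test_zero_between_condition_variance_gives_f_zero(self):
        cube = np.tile(np.array([1.0, 2.0, 3.0, 4.0, 5.0])[:, None, None],
                       (1, 2, 3))
        for r in rm_anova_2way(cube):
            assert r.F == 0.0

    def test_df1_one_effect_skips_correction(self):
        for r in rm_anova_2way(FIXTURE):
            if r.effect == "A":                  # two levels
                assert r.epsilon == 1.0
                assert r.df1 == 1.0

    def test_gg_epsilon_one_equals_uncorrected(self):
        results = rm_anova_2way(FIXTURE)
        from scipy import stats as sstats
        for r in results:
            if r.epsilon == 1.0:
                raw_df1 = round(r.df1 / r.epsilon)
                raw_df2 = round(r.df2 / r.epsilon)
                assert r.p == pytest.approx(
                    float(sstats.f.sf(r.F, raw_df1, raw_df2)), rel=1e-10)

    def test_missing_cells_rejected(self):
        cube = FIXTURE.copy()
        cube[0, 0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            rm_anova_2way(cube)

    def test_long_dataframe_input(self):
        rows = []
        for s in range(5):
            for i in range(2):
                for j in range(3):
                    rows.append(dict(subject=f"s{s}", A=i, B=j,
                                     value=FIXTURE[s, i, j]))
        df = pd.DataFrame(rows)
        a = rm_anova_2way(df)
        b = rm_anova_2way(FIXTURE)
        for ra, rb in zip(a, b):
            assert ra.F == pytest.approx(rb.F, rel=1e-10)


class TestPairedPosthoc:
    def test_identical_vectors_give_p_one(self):
        x = np.arange(8.0)
        res = paired_posthoc({"same": (x, x.copy())})
        assert res[0].degenerate
        assert res[0].p_adjusted == 1.0

    def test_bonferroni_multiplication(self):
        rng = np.random.default_rng(1)
        pairs = {f"c{i}": (rng.normal(0, 1, 30), rng.normal(0, 1, 30))
                 for i in range(7)}
        res = paired_posthoc(pairs)
        for r in res:
            assert r.p_adjusted == pytest.approx(min(1.0, r.p_raw * 7))

    def test_detects_planted_shift(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, 40)
        res = paired_posthoc({"shift": (x, x + 1.0)})
        assert res[0].p_adjusted < 1e-6


class TestFdrAdjust:
    def test_bh_hand_computation(self):
        adj = fdr_adjust(np.array([0.01, 0.02, 0.03, 0.04]))
        np.testing.assert_allclose(adj, [0.04, 0.04, 0.04, 0.04], atol=1e-12)

    def test_single_p_unchanged(self):
        assert fdr_adjust(np.array([0.3]))[0] == pytest.approx(0.3)

    def test_monotone_in_rank_order(self, rng):
        p = rng.random(25)
        adj = fdr_adjust(p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_adjust(np.array([0.5, 1.5]))


class TestOneSampleT:
    def test_symmetric_values_give_t_zero(self):
        t, p, degen = one_sample_t(np.array([-2.0, -1.0, 1.0, 2.0]))
        assert t == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)
        assert not degen

    def test_matches_closed_form(self):
        vals = np.array([0.1, 0.12, 0.08, 0.11, 0.09, 0.1, 0.13, 0.07,
                         0.1, 0.1])
        t, p, _ = one_sample_t(vals)
        n = len(vals)
        t_expect = vals.mean() / (vals.std(ddof=1) / np.sqrt(n))
        assert t == pytest.approx(t_expect, rel=1e-12)
        from scipy import stats as sstats
        assert p == pytest.approx(2 * sstats.t.sf(abs(t_expect), n - 1),
                                  rel=1e-12)

    def test_zero_variance_degenerate(self):
        t, p, degen = one_sample_t(np.full(5, 0.2))
        assert degen and np.isnan(t) and p == 0.0

    def test_type_one_calibration(self):
        rng = np.random.default_rng(3)
        rej = sum(one_sample_t(rng.normal(0, 1, 15))[1] < 0.05
                  for _ in range(400))
        assert 0.02 <= rej / 400 <= 0.08        # 95% binomial band at n=400
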