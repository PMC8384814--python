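"""Backfitting, GEV and the duration/occurrence/coverage metrics."""

import numpy as np
import pytest

from neoms import synthetic as syn
from neoms.backfit import (LabelSequence, backfit, cohort_metrics, gev,
                           metrics, order_by_coverage)
from neoms.clustering import TemplateSet, match_templates
from neoms.io import EEGEpoch

from conftest import make_truth


def _seq(labels, fs=100.0, n_templates=None, peaks=None):
    labels = np.asarray(labels, dtype=int)
    k = n_templates or labels.max() + 1
    return LabelSequence(labels=labels, fs=fs, n_templates=k,
                         peak_indices=np.asarray(
                             peaks if peaks is not None else [], dtype=int))


class TestBackfit:
    def test_single_template_epoch_fully_labeled(self, planted_templates,
                                                 planted_template_set):
        env = np.sin(np.pi * (np.arange(1000) % 50) / 50)
        data = np.outer(planted_templates[3], env * 10)
        ep = EEGEpoch(data=data + 0.0, channels=planted_template_set.channels,
                      fs=100.0)
        seq = backfit(ep, planted_template_set)
        assert np.all(seq.labels == 3)

    def test_polarity_invariance(self, planted_templates,
                                 planted_template_set):
        env = np.sin(np.pi * (np.arange(500) % 40) / 40)
        data = np.outer(planted_templates[1], env * 8)
        ep = EEGEpoch(data=data, channels=planted_template_set.channels,
                      fs=100.0)
        a = backfit(ep, planted_template_set)
        b = backfit(ep.copy_with(data=-ep.data), planted_template_set)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_amplitude_scale_invariance(self, small_cohort,
                                        planted_template_set):
        ep = small_cohort.epochs[0]
        a = backfit(ep, planted_template_set)
        b = backfit(ep.copy_with(data=ep.data * 1e3), planted_template_set)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_no_peaks_yields_unlabeled(self, planted_template_set):
        data = np.tile(np.linspace(0, 1, 50), (19, 1))
        data[0] *= 2                            # monotone GFP, no local max
        ep = EEGEpoch(data=data, channels=planted_template_set.channels,
                      fs=100.0)
        seq = backfit(ep, planted_template_set)
        assert seq.unlabeled

    def test_channel_mismatch_rejected(self, small_cohort,
                                       planted_template_set):
        ep = small_cohort.epochs[0]
        bad = ep.copy_with(channels=list(reversed(ep.channels)))
        with pytest.raises(ValueError, match="channel order"):
            backfit(bad, planted_template_set)

    def test_peak_label_accuracy_on_planted_cohort(self, small_cohort,
                                                   planted_template_set):
        correct = total = 0
        for ep, true_lab in zip(small_cohort.epochs,
                                small_cohort.true_labels):
            seq = backfit(ep, planted_template_set)
            p = seq.peak_indices
            correct += np.sum(seq.labels[p] == true_lab[p])
            total += p.size
        assert correct / total >= 0.90


class TestGEV:
    def test_noiseless_single_template_is_100(self, planted_templates,
                                              planted_template_set):
        env = np.sin(np.pi * (np.arange(600) % 60) / 60)
        ep = EEGEpoch(data=np.outer(planted_templates[0], env * 10),
                      channels=planted_template_set.channels, fs=100.0)
        seq = backfit(ep, planted_template_set)
        total, per = gev(ep, planted_template_set, seq)
        assert total == pytest.approx(100.0, abs=1e-6)
        assert per[0] == pytest.approx(100.0, abs=1e-6)

    def test_orthogonal_assignment_is_zero(self):
        rng = np.random.default_rng(0)
        # orthonormal basis of the zero-sum (average-referenced) subspace
        q, _ = np.linalg.qr(np.column_stack([np.ones(6),
                                             rng.standard_normal((6, 5))]))
        base = q[:, 1:].T
        # maps follow base[0]; templates deliberately exclude it
        tset = TemplateSet(maps=base[1:3],
                           channels=[f"CH{i}" for i in range(6)])
        env = np.sin(np.pi * (np.arange(100) % 20) / 20)
        ep = EEGEpoch(data=np.outer(base[0], env),
                      channels=tset.channels, fs=100.0)
        seq = backfit(ep, tset)
        total, _ = gev(ep, tset, seq)
        assert total == pytest.approx(0.0, abs=1e-6)

    def test_matches_direct_summation_oracle(self, small_cohort,
                                             planted_template_set):
        ep = small_cohort.epochs[0]
        seq = backfit(ep, planted_template_set)
        total, per = gev(ep, planted_template_set, seq, domain="peaks")
        # term-by-term re-computation
        num = 0.0
        den = 0.0
        for t in seq.peak_indices:
            v = ep.data[:, t] - ep.data[:, t].mean()
            g = np.sqrt(np.mean(v ** 2))
            tm = planted_template_set.maps[seq.labels[t]]
            tm = tm - tm.mean()
            r = v @ tm / (np.linalg.norm(v) * np.linalg.norm(tm))
            num += (g * r) ** 2
            den += g ** 2
        assert total == pytest.approx(100 * num / den, abs=1e-9)
        assert per.sum() == pytest.approx(total, abs=1e-9)


class TestMetrics:
    def test_constant_sequence(self):
        seq = _seq(np.zeros(1000), n_templates=2, peaks=[500])
        df = metrics(seq)                       # truncation rule on
        a = df[df.template == "A"].iloc[0]
        assert np.isnan(a.duration_ms)          # single truncated run
        assert a.occurrence_hz == pytest.approx(0.1)
        assert a.coverage_pct == pytest.approx(100.0)
        df_off = metrics(seq, exclude_truncated=False)
        assert df_off[df_off.template == "A"].duration_ms.iloc[0] == \
            pytest.approx(10_000.0)

    def test_hand_worked_three_run_sequence(self):
        labels = np.concatenate([np.zeros(30), np.ones(20), np.zeros(50)])
        seq = _seq(labels, peaks=[10, 40, 70])
        df = metrics(seq, exclude_truncated=False).set_index("template")
        assert df.loc["A", "duration_ms"] == pytest.approx(400.0)
        assert df.loc["B", "duration_ms"] == pytest.approx(200.0)
        assert df.loc["A", "coverage_pct"] == pytest.approx(80.0)
        assert df.loc["A", "occurrence_hz"] == pytest.approx(2.0)

    def test_absent_template_reported_missing(self):
        labels = np.concatenate([np.zeros(50), np.ones(50)])
        seq = _seq(labels, n_templates=3, peaks=[25, 75])
        df = metrics(seq).set_index("template")
        assert np.isnan(df.loc["C", "duration_ms"])
        assert df.loc["C", "occurrence_hz"] == 0.0
        assert df.loc["C", "coverage_pct"] == 0.0

    def test_coverage_partition(self, small_cohort, planted_template_set):
        mdf, _, _ = cohort_metrics(small_cohort.epochs, planted_template_set)
        sums = mdf.groupby(["subject_id", "state_tag"]).coverage_pct.sum()
        np.testing.assert_allclose(sums.to_numpy(), 100.0, atol=1e-6)

    def test_conservation_identity(self, rng):
        # sum_k occurrence_k * duration_k = 1000 ms/s for a fully labeled
        # sequence with the truncation rule off
        labels = rng.integers(0, 3, 40).repeat(rng.integers(5, 30, 40))
        seq = _seq(labels, n_templates=3, peaks=[1])
        df = metrics(seq, exclude_truncated=False).fillna(0.0)
        total = (df.occurrence_hz * df.duration_ms).sum()
        assert total == pytest.approx(1000.0, abs=1e-6)


class TestOrdering:
    def test_order_by_coverage_descending(self, small_cohort,
                                          planted_template_set):
        _, _, labelings = cohort_metrics(small_cohort.epochs,
                                         planted_template_set)
        ordered = order_by_coverage(planted_template_set, labelings)
        mdf, _, _ = cohort_metrics(small_cohort.epochs, ordered)
        cov = mdf.groupby("template").coverage_pct.mean()
        vals = cov.loc[list("ABCDE")].to_numpy()
        assert np.all(np.diff(vals) <= 1e-9)
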