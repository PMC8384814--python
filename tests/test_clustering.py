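"""GFP, peak detection, modified k-means, KL selection, two-step clustering."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from neoms import synthetic as syn
from neoms.clustering import (TemplateSet, explained_variance, find_gfp_peaks,
                              gfp, gfp_trace, kl_select, match_templates,
                              modified_kmeans, peak_maps, two_step_cluster)
from neoms.io import EEGEpoch

from conftest import make_truth, random_zero_mean_maps


class TestGFP:
    def test_constant_map_is_zero(self):
        assert gfp(np.full((4, 1), 1.0))[0] == 0.0

    def test_antisymmetric_two_channel(self):
        assert gfp(np.array([[1.0], [-1.0]]))[0] == pytest.approx(1.0)

    def test_matches_direct_summation(self, rng):
        data = rng.normal(0, 20, (19, 50))
        got = gfp(data)
        for t in range(50):
            v = data[:, t]
            expect = np.sqrt(np.sum((v - v.mean()) ** 2) / 19)
            assert got[t] == pytest.approx(expect, abs=1e-12)


class TestFindPeaks:
    def test_monotone_trace_has_no_peaks(self):
        assert find_gfp_peaks(np.arange(100.0), fs=100).size == 0

    def test_triangular_bump_gives_apex(self):
        trace = np.concatenate([np.arange(50.0), np.arange(49.0)[::-1]])
        peaks = find_gfp_peaks(trace, fs=100)
        assert list(peaks) == [49]

    def test_half_sine_envelopes_peak_at_segment_centers(self,
                                                         planted_templates):
        truth = make_truth(planted_templates, snr=np.inf, epoch_length_s=10.0,
                           duration_law={"name": "fixed", "mean_ms": 100.0})
        ep, labels = syn.simulate_epoch(truth, rng=np.random.default_rng(0))
        trace = gfp_trace(ep)
        changes = np.flatnonzero(np.diff(labels)) + 1
        starts = np.concatenate([[0], changes])
        centers = starts + 5                     # 10-sample segments
        for c in centers[1:-1]:
            assert np.abs(trace.peak_indices - c).min() <= 2


def _planted_maps(k, n_per, snr, rng, c=19, min_gd=0.8, seed=None):
    templates = syn.make_templates(k, c, min_pairwise_dissimilarity=min_gd,
                                   seed=seed if seed is not None else 0)
    maps = []
    for j in range(k):
        noise = random_zero_mean_maps(n_per, c, rng)
        noise *= np.sqrt(np.mean(templates[j] ** 2)) / (
            snr * np.sqrt(np.mean(noise ** 2, axis=1, keepdims=True)))
        sign = np.where(rng.random(n_per) < 0.5, -1.0, 1.0)[:, None]
        maps.append(sign * (templates[j][None, :] + noise))
    return templates, np.vstack(maps)


def _abs_corr(a, b):
    a = a - a.mean(axis=-1, keepdims=True)
    b = b - b.mean(axis=-1, keepdims=True)
    a = a / np.linalg.norm(a, axis=-1, keepdims=True)
    b = b / np.linalg.norm(b, axis=-1, keepdims=True)
    return np.abs(np.sum(a * b, axis=-1))


def _exhaustive_two_cluster_ev(maps):
    """Best polarity-invariant 2-partition by brute force over 2^n splits."""
    vhat = maps - maps.mean(axis=1, keepdims=True)
    vhat /= np.linalg.norm(vhat, axis=1, keepdims=True)
    n = vhat.shape[0]
    best = -np.inf
    for bits in itertools.product([0, 1], repeat=n - 1):
        assign = np.array((0,) + bits)
        ev_total = 0.0
        ok = True
        for j in (0, 1):
            sel = vhat[assign == j]
            if sel.shape[0] == 0:
                ok = False
                break
            ev_total += np.linalg.eigvalsh(sel.T @ sel)[-1]
        if ok:
            best = max(best, ev_total / n)
    return best


class TestModifiedKmeans:
    def test_recovers_orthogonal_templates_with_random_signs(self, rng):
        base = np.linalg.qr(rng.standard_normal((12, 12)))[0][:4]
        base -= base.mean(axis=1, keepdims=True)
        maps = np.vstack([
            s * base[j] for j in range(4)
            for s in np.where(rng.random(50) < 0.5, -1.0, 1.0)])
        tset, _, ev = modified_kmeans(maps, 4, n_restarts=10, seed=0)
        assert ev == pytest.approx(1.0, abs=1e-9)
        perm = match_templates(base, tset.maps)
        assert np.all(_abs_corr(base, tset.maps[perm]) > 1 - 1e-9)

    def test_matches_exhaustive_partition_optimum(self, rng):
        for _ in range(10):
            maps = random_zero_mean_maps(8, 6, rng)
            _, _, ev = modified_kmeans(maps, 2, n_restarts=30, seed=1)
            brute = _exhaustive_two_cluster_ev(maps)
            assert ev == pytest.approx(brute, abs=1e-8)

    def test_deterministic_under_seed(self, rng):
        maps = random_zero_mean_maps(60, 10, rng)
        a, _, _ = modified_kmeans(maps, 3, seed=7)
        b, _, _ = modified_kmeans(maps, 3, seed=7)
        np.testing.assert_array_equal(a.maps, b.maps)

    def test_polarity_invariance(self, rng):
        maps = random_zero_mean_maps(40, 8, rng)
        flip = np.where(np.random.default_rng(5).random(40) < 0.5,
                        -1.0, 1.0)[:, None]
        a, _, ev_a = modified_kmeans(maps, 3, seed=11)
        b, _, ev_b = modified_kmeans(maps * flip, 3, seed=11)
        assert ev_a == pytest.approx(ev_b, abs=1e-10)
        perm = match_templates(a.maps, b.maps)
        assert np.all(_abs_corr(a.maps, b.maps[perm]) > 1 - 1e-9)

    def test_k_larger_than_n_rejected(self, rng):
        with pytest.raises(ValueError, match="exceeds"):
            modified_kmeans(random_zero_mean_maps(3, 5, rng), 4)

    def test_templates_zero_mean_unit_gfp(self, rng):
        maps = random_zero_mean_maps(50, 9, rng)
        tset, _, _ = modified_kmeans(maps, 4, seed=2)
        np.testing.assert_allclose(tset.maps.sum(axis=1), 0, atol=1e-9)
        np.testing.assert_allclose(np.sqrt(np.mean(tset.maps ** 2, axis=1)),
                                   1.0, atol=1e-9)

    def test_explained_variance_nondecreasing_in_k(self, rng):
        _, maps = _planted_maps(4, 40, snr=2.0, rng=rng)
        evs = [modified_kmeans(maps, k, n_restarts=20, seed=3)[2]
               for k in range(3, 11)]
        assert np.all(np.diff(evs) > -1e-9)


class TestKLSelect:
    def test_dispersion_non_increasing(self, rng):
        _, maps = _planted_maps(4, 30, snr=3.0, rng=rng)
        curve = kl_select(maps, 3, 8, rule="first_max", n_restarts=20, seed=0)
        assert np.all(np.diff(curve.dispersion) <= 1e-9)

    def test_planted_k_recovered_first_max(self, rng):
        templates, maps = _planted_maps(7, 50, snr=10.0, rng=rng, seed=13)
        curve = kl_select(maps, 3, 10, rule="first_max", n_restarts=10,
                          seed=1)
        assert curve.chosen_k == 7

    def test_second_max_fallback_warns(self, rng):
        # a single dominant maximum: planted structure with one spike
        templates, maps = _planted_maps(5, 40, snr=10.0, rng=rng, seed=17)
        with pytest.warns(UserWarning, match="falling back"):
            kl_select(maps, 3, 8, rule="second_max", n_restarts=10, seed=2)

    def test_kl_defined_on_interior_only(self, rng):
        _, maps = _planted_maps(4, 30, snr=5.0, rng=rng)
        curve = kl_select(maps, 3, 8, rule="first_max", n_restarts=10, seed=3)
        assert np.isnan(curve.kl[0]) and np.isnan(curve.kl[-1])
        assert np.isfinite(curve.kl[1:-1]).all()


class TestTwoStepCluster:
    def test_identical_noiseless_subjects_recover_templates(
            self, planted_templates, planted_template_set):
        truth = make_truth(planted_templates, snr=np.inf, n_subjects=3,
                           epoch_length_s=10.0)
        cohort = syn.simulate_cohort(truth, make_truth(
            planted_templates, snr=np.inf, n_subjects=3, epoch_length_s=10.0,
            seed=5))
        group = two_step_cluster(cohort.epochs, k=5, n_restarts=10, seed=0)
        perm = match_templates(planted_templates, group.maps)
        assert np.all(_abs_corr(planted_templates, group.maps[perm]) > 0.999)

    def test_one_subject_equals_individual_clustering(self, planted_templates):
        truth = make_truth(planted_templates, snr=5.0, n_subjects=1,
                           epoch_length_s=20.0)
        ep, _ = syn.simulate_epoch(truth, subject_id="S00",
                                   rng=np.random.default_rng(2))
        group = two_step_cluster([ep], k=5, n_restarts=10, seed=9)
        maps = peak_maps(ep)
        indiv, _, _ = modified_kmeans(maps, 5, n_restarts=10, seed=9)
        # step 2 re-clusters step 1's k templates into k singletons
        perm = match_templates(indiv.maps, group.maps)
        assert np.all(_abs_corr(indiv.maps, group.maps[perm]) > 1 - 1e-6)


@settings(deadline=None, max_examples=15)
@given(st.integers(min_value=0, max_value=10_000))
def test_gfp_scale_invariance_of_clustering(seed):
    """Scaling all maps by a positive constant leaves templates unchanged."""
    rng = np.random.default_rng(seed)
    maps = rng.standard_normal((20, 6))
    maps -= maps.mean(axis=1, keepdims=True)
    a, _, ev_a = modified_kmeans(maps, 2, n_restarts=5, seed=0)
    b, _, ev_b = modified_kmeans(maps * 37.5, 2, n_restarts=5, seed=0)
    assert ev_a == pytest.approx(ev_b, abs=1e-9)
    perm = match_templates(a.maps, b.maps)
    assert np.all(_abs_corr(a.maps, b.maps[perm]) > 1 - 1e-9)
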