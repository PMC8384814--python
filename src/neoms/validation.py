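"""Recovery and calibration experiments on planted synthetic cohorts.

Since no neonatal EEG cohort of the kind this pipeline targets is publicly
deposited, the package validates itself on cohorts with known ground truth:
every experiment here plants a structure (templates, durations, syntax,
topographic differences), runs the analysis end to end, and measures how
well the structure is recovered or how well a null test calibrates.  The
same experiments back the acceptance checks in ``scripts/acceptance.py``
and the heavier end of the test suite.
"""

from __future__ import annotations

import hashlib
import itertools
import json

import numpy as np

from . import synthetic as syn
from .backfit import cohort_metrics
from .clustering import (TemplateSet, kl_select, match_templates,
                         modified_kmeans, two_step_cluster, _normalize_maps)
from .groupstats import rm_anova_2way
from .narrowband import (DEFAULT_BANDS, band_metric_means, band_pipeline,
                         loglog_fit)
from .syntax import randomization_test, transition_stats
from .topography import tanova


def _make_truth(templates, *, seed, snr, mean_ms, n_subjects, epoch_length_s,
                markov=None, duration_law=None, amplitude_law=None):
    k = templates.shape[0]
    channels = syn.montage_channels("10-20", templates.shape[1])
    return syn.SyntheticGroundTruth(
        templates=templates,
        markov=syn.uniform_markov(k) if markov is None else markov,
        channels=channels,
        duration_law=duration_law or {"name": "lognormal", "mean_ms": mean_ms,
                                      "sigma": 0.4, "min_ms": 30.0},
        amplitude_law=amplitude_law or {"base_gfp": 10.0, "jitter": 0.2,
                                        "oscillation_hz": None},
        noise={"alpha": 1.0, "snr": snr, "spatial_decay": 0.3},
        n_subjects=n_subjects, epoch_length_s=epoch_length_s, seed=seed)


def _planted_map_cloud(k, n_per, snr, c, rng, template_seed):
    templates = syn.make_templates(k, c, min_pairwise_dissimilarity=0.8,
                                   seed=template_seed)
    maps = []
    for j in range(k):
        noise = rng.standard_normal((n_per, c))
        noise -= noise.mean(axis=1, keepdims=True)
        noise *= np.sqrt(np.mean(templates[j] ** 2)) / (
            snr * np.sqrt(np.mean(noise ** 2, axis=1, keepdims=True)))
        sign = np.where(rng.random(n_per) < 0.5, -1.0, 1.0)[:, None]
        maps.append(sign * (templates[j][None, :] + noise))
    return templates, np.vstack(maps)


def template_recovery(seed: int = 0, n_subjects: int = 20,
                      epoch_length_s: float = 60.0, snr: float = 5.0,
                      k: int = 7) -> dict:
    """Two-step clustering on a 19-channel, two-state cohort with planted
    templates; returns the mean |spatial correlation| against the truth."""
    templates = syn.make_templates(k, 19, "10-20", 0.8, seed=seed)
    t_as = _make_truth(templates, seed=seed * 10 + 1, snr=snr, mean_ms=110.0,
                       n_subjects=n_subjects, epoch_length_s=epoch_length_s)
    t_qs = _make_truth(templates, seed=seed * 10 + 2, snr=snr, mean_ms=150.0,
                       n_subjects=n_subjects, epoch_length_s=epoch_length_s)
    cohort = syn.simulate_cohort(t_as, t_qs)
    group = two_step_cluster(cohort.epochs, k=k, n_restarts=20, seed=seed)
    perm = match_templates(templates, group.maps)
    ref = _normalize_maps(templates)
    got = _normalize_maps(group.maps[perm])
    corr = np.abs(np.sum(ref * got, axis=1))
    return {"mean_abs_correlation": float(corr.mean()),
            "min_abs_correlation": float(corr.min()),
            "n": n_subjects * 2}


def kl_selection_rate(seed: int = 0, n_runs: int = 20, k_true: int = 7,
                      snr: float = 10.0, n_per: int = 50) -> dict:
    """Fraction of seeded runs in which the KL first-max rule picks the
    planted number of well-separated clusters."""
    hits = 0
    for i in range(n_runs):
        rng = np.random.default_rng(seed * 1000 + i)
        _, maps = _planted_map_cloud(k_true, n_per, snr, 19, rng,
                                     template_seed=seed * 1000 + i)
        curve = kl_select(maps, k_min=3, k_max=10, rule="first_max",
                          n_restarts=10, seed=seed * 1000 + i)
        hits += curve.chosen_k == k_true
    return {"rate": hits / n_runs, "n": n_runs}


def kmeans_oracle_gap(seed: int = 0, n_instances: int = 50) -> dict:
    """Max |objective gap| between modified k-means (k=2, <=8 maps) and the
    exhaustive sign-agnostic partition optimum."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_instances):
        n = int(rng.integers(5, 9))
        maps = rng.standard_normal((n, 6))
        maps -= maps.mean(axis=1, keepdims=True)
        _, _, ev = modified_kmeans(maps, 2, n_restarts=30,
                                   seed=int(rng.integers(2 ** 31)))
        vhat = _normalize_maps(maps)
        best = -np.inf
        for bits in itertools.product([0, 1], repeat=n - 1):
            assign = np.array((0,) + bits)
            total, ok = 0.0, True
            for j in (0, 1):
                sel = vhat[assign == j]
                if sel.shape[0] == 0:
                    ok = False
                    break
                total += np.linalg.eigvalsh(sel.T @ sel)[-1]
            if ok:
                best = max(best, total / n)
        worst = max(worst, abs(best - ev))
    return {"max_gap": worst, "n": n_instances}


def syntax_calibration(seed: int = 0, n_cohorts: int = 200,
                       n_epochs: int = 20, n_segments: int = 200,
                       k: int = 4, n_reps: int = 500,
                       alpha: float = 0.05) -> dict:
    """Type-I error of the randomization syntax test under the
    occurrence-driven (uniform-chain) null."""
    rng = np.random.default_rng(seed)
    markov = syn.uniform_markov(k)
    cum = np.cumsum(markov, axis=1)

    def gen(n):
        s = np.empty(n, dtype=int)
        s[0] = rng.integers(k)
        for i in range(1, n):
            s[i] = np.searchsorted(cum[s[i - 1]], rng.random(), side="right")
        return s

    rej = 0
    for _ in range(n_cohorts):
        stats = [transition_stats(gen(n_segments), n_templates=k)
                 for _ in range(n_epochs)]
        p = randomization_test(stats, n_reps=n_reps,
                               seed=int(rng.integers(2 ** 31))).p_value
        rej += p < alpha
    return {"rate": rej / n_cohorts, "n": n_cohorts}


def syntax_power(seed: int = 0, n_epochs: int = 30,
                 n_segments: int = 200, n_reps: int = 1000) -> dict:
    """p-value for a strongly cyclic planted syntax (A->B->C->A at 0.8)."""
    rng = np.random.default_rng(seed)
    m = np.array([[0.0, 0.8, 0.2],
                  [0.2, 0.0, 0.8],
                  [0.8, 0.2, 0.0]])
    cum = np.cumsum(m, axis=1)

    def gen(n):
        s = np.empty(n, dtype=int)
        s[0] = rng.integers(3)
        for i in range(1, n):
            s[i] = np.searchsorted(cum[s[i - 1]], rng.random(), side="right")
        return s

    stats = [transition_stats(gen(n_segments), n_templates=3)
             for _ in range(n_epochs)]
    res = randomization_test(stats, n_reps=n_reps, seed=seed + 1)
    return {"p_value": res.p_value, "n": n_epochs}


def _noisy_maps(template, n, snr, rng):
    c = template.size
    noise = rng.standard_normal((n, c))
    noise -= noise.mean(axis=1, keepdims=True)
    noise *= np.sqrt(np.mean(template ** 2)) / (
        snr * np.sqrt(np.mean(noise ** 2, axis=1, keepdims=True)))
    sign = np.where(rng.random(n) < 0.5, -1.0, 1.0)[:, None]
    return sign * (template[None, :] + noise)


def tanova_calibration(seed: int = 0, n_cohorts: int = 200,
                       n_subjects: int = 20, snr: float = 10.0,
                       n_permutations: int = 500,
                       alpha: float = 0.05) -> dict:
    """Type-I error of paired TANOVA when both conditions share a map."""
    rng = np.random.default_rng(seed)
    template = syn.make_templates(2, 19, seed=seed)[0]
    rej = 0
    for _ in range(n_cohorts):
        a = _noisy_maps(template, n_subjects, snr, rng)
        b = _noisy_maps(template, n_subjects, snr, rng)
        res = tanova(a, b, n_permutations=n_permutations, paired=True,
                     seed=int(rng.integers(2 ** 31)))
        rej += res.p_value < alpha
    return {"rate": rej / n_cohorts, "n": n_cohorts}


def tanova_power(seed: int = 0, n_subjects: int = 20, snr: float = 10.0,
                 gd_planted: float = 0.8,
                 n_permutations: int = 1000) -> dict:
    """p-value for two groups built from maps a fixed GD apart."""
    rng = np.random.default_rng(seed)
    u = syn.make_templates(2, 19, seed=seed)[0]
    w = rng.standard_normal(19)
    w -= w.mean()
    w -= np.mean(w * u) / np.mean(u * u) * u
    w /= np.sqrt(np.mean(w ** 2))
    r = 1.0 - gd_planted ** 2 / 2.0
    v = r * u + np.sqrt(1 - r ** 2) * w
    a = _noisy_maps(u, n_subjects, snr, rng)
    b = _noisy_maps(v, n_subjects, snr, rng)
    res = tanova(a, b, n_permutations=n_permutations, paired=True,
                 seed=seed + 1)
    return {"p_value": res.p_value, "observed_gd": res.observed_gd,
            "n": n_subjects}


def sleep_state_effect(seed: int = 0, n_subjects: int = 30, k: int = 5,
                       epoch_length_s: float = 30.0, snr: float = 10.0,
                       dur_as_ms: float = 110.0,
                       dur_qs_ms: float = 150.0) -> dict:
    """Recover the planted AS/QS dynamics difference through the full
    pipeline (clustering included) and test it with the RM-ANOVA."""
    templates = syn.make_templates(k, 19, "10-20", 0.8, seed=seed)
    t_as = _make_truth(templates, seed=seed * 10 + 3, snr=snr,
                       mean_ms=dur_as_ms, n_subjects=n_subjects,
                       epoch_length_s=epoch_length_s)
    t_qs = _make_truth(templates, seed=seed * 10 + 4, snr=snr,
                       mean_ms=dur_qs_ms, n_subjects=n_subjects,
                       epoch_length_s=epoch_length_s)
    cohort = syn.simulate_cohort(t_as, t_qs)
    group = two_step_cluster(cohort.epochs, k=k, n_restarts=10, seed=seed)
    mdf, gdf, _ = cohort_metrics(cohort.epochs, group)
    means = mdf.groupby("state_tag")[["duration_ms", "occurrence_hz"]].mean()
    out = {"duration_as_ms": float(means.loc["AS", "duration_ms"]),
           "duration_qs_ms": float(means.loc["QS", "duration_ms"]),
           "occurrence_as_hz": float(means.loc["AS", "occurrence_hz"]),
           "occurrence_qs_hz": float(means.loc["QS", "occurrence_hz"]),
           "gev_pct": float(gdf.gev_pct.mean()),
           "n": n_subjects}
    for metric in ("duration_ms", "occurrence_hz"):
        piv = mdf.pivot_table(index="subject_id",
                              columns=["state_tag", "template"],
                              values=metric)
        cube = piv.to_numpy().reshape(len(piv), 2, k)
        res = {r.effect: r for r in rm_anova_2way(
            cube, factor_names=("state", "template"))}
        out[f"anova_state_p_{metric}"] = res["state"].p
    return out


def duration_scaling(seed: int = 0, n_subjects: int = 5, k: int = 4,
                     epoch_length_s: float = 30.0, snr: float = 10.0,
                     scale_ms_hz: float = 1800.0) -> dict:
    """Plant duration proportional to 1/f across the five bands, re-run the
    per-band pipeline with clustering, and fit the log-log slope."""
    templates = syn.make_templates(k, 19, "10-20", 0.8, seed=seed)
    results = {}
    for i, band in enumerate(DEFAULT_BANDS):
        truth = _make_truth(
            templates, seed=seed * 100 + i, snr=snr, mean_ms=0.0,
            n_subjects=n_subjects, epoch_length_s=epoch_length_s,
            duration_law={"name": "fixed",
                          "mean_ms": scale_ms_hz / band.median_freq},
            amplitude_law={"base_gfp": 10.0, "jitter": 0.1,
                           "oscillation_hz": band.median_freq})
        epochs = []
        children = np.random.SeedSequence(truth.seed).spawn(n_subjects)
        for s in range(n_subjects):
            ep, _ = syn.simulate_epoch(truth, subject_id=f"S{s:02d}",
                                       rng=np.random.default_rng(children[s]))
            epochs.append(ep)
        res = band_pipeline(epochs, [band], k=k, seed=seed + i, n_restarts=5)
        results[band.name] = res[band.name]
    fits = {}
    for metric in ("duration_ms", "occurrence_hz"):
        fit = loglog_fit(band_metric_means(results, metric), DEFAULT_BANDS,
                         metric=metric)
        fits[metric] = fit
    return {"duration_slope": fits["duration_ms"].slope,
            "duration_r_squared": fits["duration_ms"].r_squared,
            "occurrence_slope": fits["occurrence_hz"].slope,
            "n": n_subjects * len(DEFAULT_BANDS)}


def determinism_check(seed: int = 0) -> dict:
    """Hash the outputs of every seeded stage twice; 1.0 means identical."""
    def one_pass():
        templates = syn.make_templates(4, 19, "10-20", 0.6, seed=seed)
        truth = _make_truth(templates, seed=seed + 1, snr=5.0, mean_ms=120.0,
                            n_subjects=2, epoch_length_s=15.0)
        cohort = syn.simulate_cohort(
            truth, _make_truth(templates, seed=seed + 2, snr=5.0,
                               mean_ms=150.0, n_subjects=2,
                               epoch_length_s=15.0))
        group = two_step_cluster(cohort.epochs, k=4, n_restarts=5, seed=seed)
        mdf, gdf, labelings = cohort_metrics(cohort.epochs, group)
        stats = [transition_stats(l) for l in labelings]
        rt = randomization_test(stats, n_reps=300, seed=seed)
        h = hashlib.sha256()
        for ep in cohort.epochs:
            h.update(ep.data.tobytes())
        h.update(group.maps.tobytes())
        h.update(mdf.to_csv().encode())
        h.update(json.dumps([rt.chi_square_distance, rt.p_value]).encode())
        return h.hexdigest()

    return {"identical": float(one_pass() == one_pass()), "n": 2}
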