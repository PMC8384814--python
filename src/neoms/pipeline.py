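"""End-to-end study replica: simulate/load -> preprocess -> cluster ->
backfit -> metrics -> syntax -> TANOVA -> narrow bands -> group statistics.

Driven by a single :class:`PipelineConfig`; every stage writes its
intermediate next to the final ``report.json`` so each reported number is
traceable, and all randomness derives from one master seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import synthetic
from .backfit import cohort_metrics, order_by_coverage
from .clustering import match_templates, two_step_cluster
from .groupstats import anova_table, rm_anova_2way
from .io import EEGEpoch, read_epoch
from .narrowband import (DEFAULT_BANDS, band_metric_means, band_pipeline,
                         loglog_fit)
from .preprocess import BROADBAND, FilterSpec, preprocess
from .syntax import directional_predominance, randomization_test, \
    transition_stats
from .topography import tanova

log = logging.getLogger("neoms")


@dataclass
class PipelineConfig:
    """Everything needed to run the study replica once, deterministically."""

    out_dir: str = "neoms_out"
    # input: either a directory of epochs or a simulation scenario
    input_dir: str | None = None
    input_format: str = "matrix"
    simulate: dict | None = None          # kwargs for the default scenario
    # preprocessing
    low_cut: float = 0.15
    high_cut: float = 45.0
    filter_order: int = 7
    target_fs: float = 100.0
    skip_preprocess: bool = False
    # clustering
    k: int = 7
    n_restarts: int = 20
    min_separation_ms: float = 10.0
    # pooling decision
    pool_states: str = "auto"             # "auto" | "always" | "never"
    tanova_alpha: float = 0.05
    tanova_permutations: int = 1000
    # syntax
    syntax_reps: int = 5000
    # bands
    run_bands: bool = True
    band_k: int | None = None
    seed: int = 0

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        return cls(**(yaml.safe_load(text) or {}))


def default_scenario(seed: int = 0, n_subjects: int = 10,
                     epoch_length_s: float = 60.0, snr: float = 5.0,
                     k: int = 7, n_channels: int = 19,
                     duration_as_ms: float = 110.0,
                     duration_qs_ms: float = 150.0,
                     ) -> synthetic.SyntheticCohort:
    """The bundled two-state scenario: shared topographies, state-specific
    dynamics (QS-like slower, longer microstates than AS-like)."""
    templates = synthetic.make_templates(k, n_channels, geometry="10-20",
                                         min_pairwise_dissimilarity=0.8,
                                         seed=seed)
    channels = synthetic.montage_channels("10-20", n_channels)
    markov = synthetic.uniform_markov(k)
    common = dict(templates=templates, markov=markov, channels=channels,
                  n_subjects=n_subjects, epoch_length_s=epoch_length_s,
                  noise={"alpha": 1.0, "snr": snr, "spatial_decay": 0.3})
    truth_as = synthetic.SyntheticGroundTruth(
        duration_law={"name": "lognormal", "mean_ms": duration_as_ms,
                      "sigma": 0.4, "min_ms": 30.0},
        seed=seed * 2 + 1, **common)
    truth_qs = synthetic.SyntheticGroundTruth(
        duration_law={"name": "lognormal", "mean_ms": duration_qs_ms,
                      "sigma": 0.4, "min_ms": 30.0},
        seed=seed * 2 + 2, **common)
    return synthetic.simulate_cohort(truth_as, truth_qs)


def _load_epochs(config: PipelineConfig) -> list[EEGEpoch]:
    if config.simulate is not None:
        cohort = default_scenario(seed=config.seed, **config.simulate)
        return cohort.epochs
    if config.input_dir is None:
        raise ValueError("config needs either input_dir or simulate")
    paths = sorted(Path(config.input_dir).glob(
        "*.edf" if config.input_format == "edf" else "*.txt"))
    epochs = []
    for p in paths:
        if p.name.endswith(".labels.txt"):
            continue
        parts = p.stem.split("_")
        tags = dict(subject_id=parts[0] if parts else p.stem,
                    state_tag=parts[1] if len(parts) > 1 else "")
        epochs.append(read_epoch(p, format=config.input_format, **tags))
    if not epochs:
        raise ValueError(f"no epochs found in {config.input_dir}")
    return epochs


def run_all(config: PipelineConfig) -> dict:
    """Execute the full pipeline; returns the report dict (also written
    to ``<out_dir>/report.json``)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    rng = np.random.default_rng(config.seed)
    report: dict = {"seed": config.seed}

    log.info("stage: load/simulate")
    epochs = _load_epochs(config)
    if not config.skip_preprocess and config.simulate is None:
        log.info("stage: preprocess")
        spec = FilterSpec(config.low_cut, config.high_cut, config.filter_order)
        epochs = [preprocess(ep, spec, config.target_fs) for ep in epochs]

    states = sorted({ep.state_tag for ep in epochs if ep.state_tag})
    log.info("stage: cluster per state (%s)", states)
    peak_kwargs = dict(min_separation_ms=config.min_separation_ms)
    state_templates = {
        s: two_step_cluster([e for e in epochs if e.state_tag == s],
                            k=config.k, n_restarts=config.n_restarts,
                            seed=int(rng.integers(2 ** 31)), **peak_kwargs)
        for s in states}

    pooled = config.pool_states == "always" or len(states) < 2
    tanova_rows = []
    if len(states) == 2 and config.pool_states in ("auto", "never"):
        log.info("stage: TANOVA between state templates")
        a, b = states
        ta, tb = state_templates[a], state_templates[b]
        perm = match_templates(ta.maps, tb.maps)
        subj_a = _per_subject_maps(epochs, a, ta, config, rng)
        subj_b = _per_subject_maps(epochs, b, tb, config, rng)
        ps = []
        for i in range(ta.k):
            res = tanova(subj_a[:, i, :], subj_b[:, perm[i], :],
                         n_permutations=config.tanova_permutations,
                         paired=True, seed=int(rng.integers(2 ** 31)))
            ps.append(res.p_value)
            tanova_rows.append(dict(template=ta.labels[i],
                                    observed_gd=res.observed_gd,
                                    p=res.p_value))
        if config.pool_states == "auto":
            pooled = all(p > config.tanova_alpha for p in ps)
    report["state_template_tanova"] = tanova_rows
    report["pooled_templates"] = pooled

    log.info("stage: group templates (pooled=%s)", pooled)
    if pooled:
        templates = two_step_cluster(epochs, k=config.k,
                                     n_restarts=config.n_restarts,
                                     seed=int(rng.integers(2 ** 31)),
                                     **peak_kwargs)
    else:
        templates = state_templates[states[0]]

    log.info("stage: backfit + metrics")
    mdf, gdf, labelings = cohort_metrics(epochs, templates, **peak_kwargs)
    templates = order_by_coverage(templates, labelings)
    mdf, gdf, labelings = cohort_metrics(epochs, templates, **peak_kwargs)
    mdf.to_csv(out / "metrics.tsv", sep="\t", index=False)
    gdf.to_csv(out / "gev.tsv", sep="\t", index=False)
    _write_templates(templates, out / "templates.json")
    report["gev_pct_mean"] = float(gdf.gev_pct.mean())

    log.info("stage: syntax")
    syntax_report = {}
    for s in states or [""]:
        seqs = [l for l in labelings if l.state_tag == s]
        stats_list = [transition_stats(l) for l in seqs
                      if l.segment_labels.size >= 2]
        if len(stats_list) >= 2:
            rt = randomization_test(
                stats_list, n_reps=config.syntax_reps,
                seed=int(rng.integers(2 ** 31)),
                subject_ids=[l.subject_id for l in labelings
                             if l.state_tag == s])
            pred = directional_predominance(stats_list,
                                            template_names=templates.labels)
            syntax_report[s or "all"] = dict(
                chi_square_distance=rt.chi_square_distance,
                p_value=rt.p_value,
                n_randomizations=rt.n_randomizations,
                predominance=pred.to_dict(orient="records"))
    report["syntax"] = syntax_report

    if config.run_bands:
        log.info("stage: narrow bands")
        band_res = band_pipeline(epochs, DEFAULT_BANDS,
                                 k=config.band_k or config.k,
                                 seed=int(rng.integers(2 ** 31)),
                                 **peak_kwargs)
        scaling = {}
        for metric in ("duration_ms", "occurrence_hz", "coverage_pct"):
            fit = loglog_fit(band_metric_means(band_res, metric),
                             DEFAULT_BANDS, metric=metric)
            scaling[metric] = dict(slope=fit.slope, intercept=fit.intercept,
                                   r_squared=fit.r_squared,
                                   bands_used=fit.bands_used)
        report["scaling"] = scaling
        report["band_gev_pct"] = {
            name: float(res["gev"].gev_pct.mean())
            for name, res in band_res.items()}

    if len(states) == 2:
        log.info("stage: group statistics")
        stats_report = {}
        for metric in ("duration_ms", "occurrence_hz", "coverage_pct"):
            piv = mdf.pivot_table(index="subject_id",
                                  columns=["state_tag", "template"],
                                  values=metric, aggfunc="mean")
            if piv.isna().any().any():
                continue
            cube = piv.to_numpy().reshape(
                len(piv), len(states), templates.k)
            res = rm_anova_2way(cube, factor_names=("sleep_state", "template"))
            tab = anova_table(res)
            if metric == "coverage_pct":
                # total coverage is 100% for every subject and state, so a
                # sleep-state main effect is not applicable
                tab.loc[tab.effect == "sleep_state",
                        ["F", "p", "partial_eta_squared"]] = np.nan
            stats_report[metric] = tab.to_dict(orient="records")
        report["anova"] = stats_report

    (out / "report.json").write_text(json.dumps(report, indent=1,
                                                default=_jsonify))
    (out / "config.yaml").write_text(config.to_yaml())
    log.info("done; report at %s", out / "report.json")
    return report


def _per_subject_maps(epochs: list[EEGEpoch], state: str, templates,
                      config: PipelineConfig, rng) -> np.ndarray:
    """One map per subject per template: each subject's individual
    clustering matched onto the state's group templates."""
    from .clustering import modified_kmeans, peak_maps

    subjects = sorted({e.subject_id for e in epochs if e.state_tag == state})
    out = np.empty((len(subjects), templates.k, templates.maps.shape[1]))
    for i, sid in enumerate(subjects):
        maps = np.vstack([peak_maps(
            e, min_separation_ms=config.min_separation_ms)
            for e in epochs if e.subject_id == sid and e.state_tag == state])
        tset, _, _ = modified_kmeans(maps, templates.k,
                                     n_restarts=config.n_restarts,
                                     seed=int(rng.integers(2 ** 31)))
        perm = match_templates(templates.maps, tset.maps)
        out[i] = tset.maps[perm]
    return out


def _write_templates(templates, path: Path) -> None:
    path.write_text(json.dumps(dict(
        labels=templates.labels, channels=templates.channels,
        level=templates.level, band_tag=templates.band_tag,
        maps={lab: row.tolist()
              for lab, row in zip(templates.labels, templates.maps)}),
        indent=1))


def _jsonify(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
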