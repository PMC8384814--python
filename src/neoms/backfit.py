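"""Backfitting templates to the EEG time course; GEV and microstate metrics.

Each GFP peak is labeled with the template of highest absolute spatial
correlation (polarity ignored); every other sample inherits the label of
its nearest peak, so label boundaries fall at the midpoints between
consecutive peaks (ties go to the earlier peak).  Runs that touch the
epoch edges (before the first or after the last peak) are flagged as
boundary-truncated and excluded from mean duration by default, since a
clipped run biases duration downward.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clustering import GFPTrace, TemplateSet, _normalize_maps, gfp, gfp_trace
from .io import EEGEpoch

UNLABELED = -1


@dataclass
class Segment:
    label: int
    start: int
    length: int
    boundary_truncated: bool = False


@dataclass
class LabelSequence:
    """Per-sample template assignment for one epoch, with run structure."""

    labels: np.ndarray                      # (T,) int, UNLABELED allowed
    fs: float
    n_templates: int
    peak_indices: np.ndarray = field(default_factory=lambda: np.array([], int))
    subject_id: str = ""
    state_tag: str = ""
    band_tag: str = "broad"

    @property
    def unlabeled(self) -> bool:
        return bool(np.all(self.labels == UNLABELED))

    @property
    def segments(self) -> list[Segment]:
        """Maximal runs of the labeled samples."""
        labels = self.labels
        segs: list[Segment] = []
        t = len(labels)
        start = 0
        for i in range(1, t + 1):
            if i == t or labels[i] != labels[start]:
                if labels[start] != UNLABELED:
                    segs.append(Segment(int(labels[start]), start, i - start))
                start = i
        # the first and last runs are clipped by the epoch edges
        if segs:
            segs[0].boundary_truncated = True
            segs[-1].boundary_truncated = True
        return segs

    @property
    def segment_labels(self) -> np.ndarray:
        return np.array([s.label for s in self.segments], dtype=int)


def backfit(epoch: EEGEpoch, templates: TemplateSet,
            trace: GFPTrace | None = None, **peak_kwargs) -> LabelSequence:
    """Assign templates to an epoch through its GFP peaks."""
    if list(epoch.channels) != list(templates.channels):
        raise ValueError("epoch and templates disagree on channel order")
    if trace is None:
        trace = gfp_trace(epoch, **peak_kwargs)
    t_total = epoch.n_samples
    peaks = trace.peak_indices
    if peaks.size == 0:
        return LabelSequence(labels=np.full(t_total, UNLABELED), fs=epoch.fs,
                             n_templates=templates.k,
                             subject_id=epoch.subject_id,
                             state_tag=epoch.state_tag,
                             band_tag=epoch.band_tag)

    maps = epoch.data[:, peaks].T
    vhat = _normalize_maps(maps)
    that = _normalize_maps(templates.maps)
    corr = vhat @ that.T
    peak_labels = np.argmax(np.abs(corr), axis=1)

    # nearest-peak label spread; equidistant samples go to the earlier peak
    samples = np.arange(t_total)
    right = np.searchsorted(peaks, samples)        # first peak >= sample
    left = np.clip(right - 1, 0, peaks.size - 1)
    right = np.clip(right, 0, peaks.size - 1)
    d_left = np.abs(samples - peaks[left])
    d_right = np.abs(peaks[right] - samples)
    nearest = np.where(d_left <= d_right, left, right)
    labels = peak_labels[nearest]
    return LabelSequence(labels=labels, fs=epoch.fs, n_templates=templates.k,
                         peak_indices=peaks, subject_id=epoch.subject_id,
                         state_tag=epoch.state_tag, band_tag=epoch.band_tag)


def gev(epoch: EEGEpoch, templates: TemplateSet, labels: LabelSequence,
        domain: str = "peaks") -> tuple[float, np.ndarray]:
    """Global explained variance (percent), total and per template.

    GEV = 100 * sum_t (GFP_t r_t)^2 / sum_t GFP_t^2 over the chosen domain
    (``"peaks"`` — consistent with how templates are fitted — or
    ``"all_samples"``), where r_t is the spatial correlation between the
    sample's topography and its assigned template.
    """
    if domain == "peaks":
        idx = labels.peak_indices
    elif domain == "all_samples":
        idx = np.arange(epoch.n_samples)
    else:
        raise ValueError("domain must be 'peaks' or 'all_samples'")
    idx = idx[labels.labels[idx] != UNLABELED] if idx.size else idx
    per_template = np.zeros(templates.k)
    if idx.size == 0:
        return 0.0, per_template
    maps = epoch.data[:, idx].T
    g = gfp(epoch)[idx]
    vhat = _normalize_maps(maps)
    that = _normalize_maps(templates.maps)
    assigned = labels.labels[idx]
    r = np.einsum("ij,ij->i", vhat, that[assigned])
    contrib = (g * r) ** 2
    denom = float(np.sum(g ** 2))
    for k in range(templates.k):
        per_template[k] = contrib[assigned == k].sum()
    per_template = 100.0 * per_template / denom
    return float(per_template.sum()), per_template


def metrics(labels: LabelSequence, exclude_truncated: bool = True,
            template_names: list[str] | None = None) -> pd.DataFrame:
    """Duration, occurrence and coverage per template.

    * duration_ms — mean run length; boundary-truncated runs excluded by
      default (NaN when a template has no untruncated run);
    * occurrence_hz — runs started per second of labeled signal (all runs);
    * coverage_pct — share of labeled samples, summing to 100 exactly.
    """
    segs = labels.segments
    k = labels.n_templates
    names = template_names or [chr(ord("A") + i) for i in range(k)]
    labeled_samples = int(np.sum(labels.labels != UNLABELED))
    labeled_s = labeled_samples / labels.fs
    rows = []
    for j in range(k):
        runs = [s for s in segs if s.label == j]
        dur_runs = [s for s in runs
                    if not (exclude_truncated and s.boundary_truncated)]
        duration = (1000.0 * np.mean([s.length for s in dur_runs]) / labels.fs
                    if dur_runs else np.nan)
        occurrence = len(runs) / labeled_s if labeled_s > 0 else 0.0
        cov_samples = sum(s.length for s in runs)
        coverage = 100.0 * cov_samples / labeled_samples if labeled_samples else 0.0
        rows.append(dict(subject_id=labels.subject_id,
                         state_tag=labels.state_tag, band_tag=labels.band_tag,
                         template=names[j], duration_ms=duration,
                         occurrence_hz=occurrence, coverage_pct=coverage))
    return pd.DataFrame(rows)


def cohort_metrics(epochs: list[EEGEpoch], templates: TemplateSet,
                   exclude_truncated: bool = True,
                   gev_domain: str = "peaks",
                   **peak_kwargs) -> tuple[pd.DataFrame, pd.DataFrame,
                                           list[LabelSequence]]:
    """Backfit a whole cohort; returns (metrics table, GEV table, labelings)."""
    all_metrics, gev_rows, labelings = [], [], []
    for ep in epochs:
        seq = backfit(ep, templates, **peak_kwargs)
        labelings.append(seq)
        all_metrics.append(metrics(seq, exclude_truncated=exclude_truncated,
                                   template_names=templates.labels))
        total, per = gev(ep, templates, seq, domain=gev_domain)
        gev_rows.append(dict(subject_id=ep.subject_id, state_tag=ep.state_tag,
                             band_tag=ep.band_tag, gev_pct=total,
                             **{f"gev_{l}": v
                                for l, v in zip(templates.labels, per)}))
    return (pd.concat(all_metrics, ignore_index=True),
            pd.DataFrame(gev_rows), labelings)


def order_by_coverage(templates: TemplateSet,
                      labelings: list[LabelSequence]) -> TemplateSet:
    """Relabel templates A, B, ... by descending total coverage."""
    counts = np.zeros(templates.k)
    for seq in labelings:
        lab = seq.labels[seq.labels != UNLABELED]
        counts += np.bincount(lab, minlength=templates.k)
    order = np.argsort(-counts, kind="stable")
    return templates.reordered(order)
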