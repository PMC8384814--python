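"""Narrow-band microstate analysis and log-log frequency scaling.

The whole pipeline (GFP-peak detection, clustering, backfitting, metrics,
GEV) is re-run on the preprocessed broad-band signals filtered into the
five conventional bands — delta (0.5-4 Hz), theta (4-8 Hz), alpha
(8-13 Hz), beta (13-25 Hz) and gamma (25-45 Hz) — using the same 7th-order
forward-backward Butterworth cascade.  Band-mean metrics are regressed on
band midpoint frequency in log-log coordinates to quantify scale-free
behavior (a slope of -1 for duration means duration is proportional to 1/f).
Note the gamma band's upper edge (45 Hz) coincides with the broad-band
edge and sits just below the 50 Hz Nyquist of the 100 Hz pipeline rate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats as sstats

from .backfit import cohort_metrics
from .clustering import TemplateSet, two_step_cluster
from .io import EEGEpoch
from .preprocess import FilterSpec, bandpass


@dataclass(frozen=True)
class BandDefinition:
    name: str
    low: float
    high: float
    median_freq: float                    # band midpoint, in Hz

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValueError("band low edge must be below high edge")


DEFAULT_BANDS = [
    BandDefinition("delta", 0.5, 4.0, 2.25),
    BandDefinition("theta", 4.0, 8.0, 6.0),
    BandDefinition("alpha", 8.0, 13.0, 10.5),
    BandDefinition("beta", 13.0, 25.0, 19.0),
    BandDefinition("gamma", 25.0, 45.0, 35.0),
]


def band_decompose(epoch: EEGEpoch,
                   bands: list[BandDefinition] = DEFAULT_BANDS,
                   order: int = 7) -> list[EEGEpoch]:
    """Filter one epoch into each band; returns one tagged epoch per band."""
    out = []
    for band in bands:
        if band.high >= epoch.fs / 2:
            raise ValueError(
                f"band {band.name} ({band.high} Hz) reaches Nyquist "
                f"({epoch.fs / 2} Hz)")
        spec = FilterSpec(low_cut=band.low, high_cut=band.high, order=order)
        filtered = bandpass(epoch, spec)
        out.append(filtered.copy_with(band_tag=band.name))
    return out


def band_pipeline(epochs: list[EEGEpoch],
                  bands: list[BandDefinition] = DEFAULT_BANDS,
                  k: int = 7,
                  templates: TemplateSet | None = None,
                  seed: int | None = None,
                  n_restarts: int = 10,
                  exclude_truncated: bool = True,
                  **peak_kwargs) -> dict[str, dict]:
    """Run the full microstate pipeline per band.

    For each band: filter every epoch, extract band-specific group
    templates with the two-step clustering (or backfit the supplied
    ``templates`` instead), then backfit and compute metrics and GEV.

    Returns a dict ``band name -> {"templates", "metrics", "gev",
    "labelings"}`` where ``metrics``/``gev`` are the tables of
    :func:`neoms.backfit.cohort_metrics` with ``band_tag`` set.
    """
    rng = np.random.default_rng(seed)
    results: dict[str, dict] = {}
    for band in bands:
        band_epochs = [band_decompose(ep, [band])[0] for ep in epochs]
        if templates is None:
            tset = two_step_cluster(band_epochs, k=k, n_restarts=n_restarts,
                                    seed=int(rng.integers(2 ** 31)),
                                    **peak_kwargs)
        else:
            tset = TemplateSet(maps=templates.maps.copy(),
                               channels=list(templates.channels),
                               labels=list(templates.labels),
                               level=templates.level, band_tag=band.name)
        tset.band_tag = band.name
        mdf, gdf, labelings = cohort_metrics(
            band_epochs, tset, exclude_truncated=exclude_truncated,
            **peak_kwargs)
        results[band.name] = dict(templates=tset, metrics=mdf, gev=gdf,
                                  labelings=labelings)
    return results


@dataclass
class ScalingFit:
    """OLS fit of log band-mean metric on log band midpoint frequency."""

    metric: str
    slope: float
    intercept: float
    r_squared: float
    points: list[tuple[float, float]]      # (log f, log metric) per band
    bands_used: list[str]


def loglog_fit(band_means: dict[str, float],
               bands: list[BandDefinition] = DEFAULT_BANDS,
               metric: str = "") -> ScalingFit:
    """Regress log metric means on log band midpoint frequencies.

    Bands with non-positive or non-finite means are excluded with a
    warning; at least 3 usable bands are required.
    """
    xs, ys, used = [], [], []
    for band in bands:
        if band.name not in band_means:
            continue
        v = band_means[band.name]
        if not np.isfinite(v) or v <= 0:
            warnings.warn(f"band {band.name}: non-positive metric mean "
                          f"({v}); excluded from the log-log fit")
            continue
        xs.append(np.log(band.median_freq))
        ys.append(np.log(v))
        used.append(band.name)
    if len(xs) < 3:
        raise ValueError("need at least 3 bands with positive means")
    res = sstats.linregress(xs, ys)
    return ScalingFit(metric=metric, slope=float(res.slope),
                      intercept=float(res.intercept),
                      r_squared=float(res.rvalue ** 2),
                      points=list(zip(xs, ys)), bands_used=used)


def band_metric_means(results: dict[str, dict], metric: str,
                      state_tag: str | None = None) -> dict[str, float]:
    """Mean of one metric per band (averaged over templates and epochs)."""
    means = {}
    for name, res in results.items():
        df = res["metrics"]
        if state_tag is not None:
            df = df[df.state_tag == state_tag]
        means[name] = float(df[metric].mean())
    return means


def psd(epoch: EEGEpoch, window_s: float = 2.0,
        overlap: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
    """Welch power spectral density per channel, in µV²/Hz.

    Returns ``(freqs, psd)`` with psd of shape (C, n_freqs).
    """
    nperseg = int(round(window_s * epoch.fs))
    if nperseg > epoch.n_samples:
        raise ValueError("window longer than the epoch")
    noverlap = int(round(overlap * nperseg))
    freqs, p = sps.welch(epoch.data, fs=epoch.fs, nperseg=nperseg,
                         noverlap=noverlap, axis=-1)
    return freqs, p
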