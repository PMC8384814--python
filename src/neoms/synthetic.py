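"""Synthetic neonatal-EEG cohorts with planted microstate structure.

Every downstream stage (clustering, backfitting, syntax, topographic and
narrow-band statistics) is validated against cohorts generated here, since
the kind of cohort the method targets — multi-minute, multi-subject scalp
EEG scored into active (AS) and quiet (QS) sleep — is not publicly
deposited.  An epoch is built as a sequence of quasi-stable segments:

* segment labels follow a planted first-order Markov chain with zero
  diagonal (microstates are maximal runs, so self-transitions cannot occur);
* segment durations are drawn from a configurable law (truncated lognormal
  by default: strictly positive and right-skewed, as empirical microstate
  durations are);
* within a segment the scalp topography is a fixed template scaled by a
  half-sine amplitude envelope, so the GFP peaks near the segment center —
  the structure GFP-peak-based clustering relies on — optionally multiplied
  by a sinusoidal carrier for narrow-band scenarios;
* each segment's polarity is flipped with probability 1/2, exercising the
  polarity-invariance contract of the analysis;
* spatially correlated 1/f^alpha background noise is added at a stated SNR
  (ratio of signal RMS to noise RMS), mirroring the 1/f shape of the
  neonatal EEG power spectrum.

No biophysical forward model is attempted: templates are random zero-mean
unit-GFP vectors with a guaranteed minimum pairwise global dissimilarity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import linalg

from .io import CHANNELS_1020_19, EEGEpoch, write_matrix
from .topography import dissimilarity_matrix


def make_templates(n_templates: int, n_channels: int,
                   geometry: str = "random",
                   min_pairwise_dissimilarity: float = 0.0,
                   seed: int | None = None,
                   max_restarts: int = 200) -> np.ndarray:
    """Draw ``n_templates`` zero-mean unit-GFP maps with guaranteed separation.

    Pairwise separation is enforced on the polarity-invariant global
    dissimilarity ``min(GD(u, v), GD(u, -v))`` (which lower-bounds the plain
    GD), because templates that are near-collinear up to sign are
    indistinguishable to the sign-agnostic clustering.

    Raises
    ------
    ValueError
        If ``n_templates`` is out of range or the requested separation is
        infeasible after ``max_restarts`` greedy restarts.
    """
    if not 2 <= n_templates <= n_channels:
        raise ValueError("need 2 <= n_templates <= n_channels")
    if not 0 <= min_pairwise_dissimilarity < 2:
        raise ValueError("min_pairwise_dissimilarity must be in [0, 2)")
    rng = np.random.default_rng(seed)
    for _ in range(max_restarts):
        maps: list[np.ndarray] = []
        tries = 0
        while len(maps) < n_templates and tries < 200 * n_templates:
            tries += 1
            v = rng.standard_normal(n_channels)
            v -= v.mean()
            g = np.sqrt(np.mean(v ** 2))
            if g <= 0:
                continue
            v /= g
            if maps and min_pairwise_dissimilarity > 0:
                gd = dissimilarity_matrix(np.array(maps), v[None, :],
                                          polarity_invariant=True)
                if gd.min() < min_pairwise_dissimilarity:
                    continue
            maps.append(v)
        if len(maps) == n_templates:
            return np.array(maps)
    raise ValueError(
        f"could not draw {n_templates} maps with pairwise GD >= "
        f"{min_pairwise_dissimilarity} in {max_restarts} restarts")


def montage_channels(geometry: str, n_channels: int) -> list[str]:
    """Channel names for a montage: the 19-channel 10-20 layout or generic."""
    if geometry in ("10-20", "1020") and n_channels == 19:
        return list(CHANNELS_1020_19)
    return [f"CH{i + 1:02d}" for i in range(n_channels)]


@dataclass
class SyntheticGroundTruth:
    """Everything needed to simulate (and later score recovery on) a cohort.

    ``duration_law`` is ``{"name": "lognormal", "mean_ms", "sigma", "min_ms"}``
    (sigma in log-space) or ``{"name": "fixed", "mean_ms"}``.
    ``amplitude_law`` is ``{"base_gfp", "jitter", "oscillation_hz"}`` — µV
    envelope peak, lognormal per-segment jitter (log-sd), optional carrier.
    ``noise`` is ``{"alpha", "snr", "spatial_decay"}`` — spectral exponent of
    the 1/f^alpha background, signal-to-noise RMS ratio (``inf`` allowed),
    and the lag-1 coefficient of the Toeplitz inter-channel correlation.
    """

    templates: np.ndarray
    markov: np.ndarray
    duration_law: dict = field(default_factory=lambda: {
        "name": "lognormal", "mean_ms": 120.0, "sigma": 0.4, "min_ms": 30.0})
    amplitude_law: dict = field(default_factory=lambda: {
        "base_gfp": 10.0, "jitter": 0.2, "oscillation_hz": None})
    noise: dict = field(default_factory=lambda: {
        "alpha": 1.0, "snr": 5.0, "spatial_decay": 0.3})
    fs: float = 100.0
    n_subjects: int = 10
    n_epochs: int = 1
    epoch_length_s: float = 60.0
    channels: list[str] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        self.templates = np.asarray(self.templates, dtype=float)
        self.markov = np.asarray(self.markov, dtype=float)
        k, c = self.templates.shape
        if not np.allclose(self.templates.sum(axis=1), 0, atol=1e-9):
            raise ValueError("templates must be zero-mean across channels")
        if self.markov.shape != (k, k):
            raise ValueError("markov matrix shape must match template count")
        if np.any(np.diag(self.markov) != 0):
            raise ValueError("markov diagonal must be exactly 0")
        if np.any(self.markov < 0) or not np.allclose(
                self.markov.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("markov rows must sum to 1")
        if not self.noise.get("snr", 1.0) > 0:
            raise ValueError("SNR must be positive")
        if not (self.fs > 0 and self.epoch_length_s > 0):
            raise ValueError("fs and epoch_length_s must be positive")
        if not self.channels:
            self.channels = montage_channels("generic", c)
        if len(self.channels) != c:
            raise ValueError("channel-name count must match template columns")

    @property
    def n_templates(self) -> int:
        return self.templates.shape[0]

    def to_json(self) -> str:
        d = asdict(self)
        d["templates"] = self.templates.tolist()
        d["markov"] = self.markov.tolist()
        return json.dumps(d, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticGroundTruth":
        return cls(**json.loads(text))


def uniform_markov(k: int) -> np.ndarray:
    """Uniform off-diagonal transition matrix (maximum-entropy syntax)."""
    m = np.full((k, k), 1.0 / (k - 1))
    np.fill_diagonal(m, 0.0)
    return m


def occurrence_markov(occ: np.ndarray) -> np.ndarray:
    """Occurrence-driven (null-syntax) chain: P(Y|X) = P_Y / (1 - P_X).

    This is exactly the null model of the expected-transition formula, so
    sequences drawn from it have chi-square distance -> 0 as length grows.
    """
    occ = np.asarray(occ, dtype=float)
    occ = occ / occ.sum()
    m = np.tile(occ, (len(occ), 1))
    np.fill_diagonal(m, 0.0)
    m /= m.sum(axis=1, keepdims=True)
    return m


def sample_segments(truth: SyntheticGroundTruth, n_samples: int,
                    rng: np.random.Generator) -> list[tuple[int, int]]:
    """Draw (label, length_in_samples) runs until ``n_samples`` is covered.

    The last run is truncated at the epoch end.  The chain starts from a
    uniform draw over templates.
    """
    law = truth.duration_law
    k = truth.n_templates
    cum = np.cumsum(truth.markov, axis=1)
    segs: list[tuple[int, int]] = []
    total = 0
    label = int(rng.integers(k))
    while total < n_samples:
        if law["name"] == "fixed":
            dur_ms = law["mean_ms"]
        elif law["name"] == "lognormal":
            sigma = law.get("sigma", 0.4)
            mu = np.log(law["mean_ms"]) - sigma ** 2 / 2  # mean of LN = mean_ms
            dur_ms = max(law.get("min_ms", 30.0),
                         float(np.exp(rng.normal(mu, sigma))))
        else:
            raise ValueError(f"unknown duration law {law['name']!r}")
        length = max(1, int(round(dur_ms * truth.fs / 1000.0)))
        length = min(length, n_samples - total)
        segs.append((label, length))
        total += length
        label = int(np.searchsorted(cum[label], rng.random(), side="right"))
    return segs


def _pink_noise(shape: tuple[int, int], alpha: float,
                rng: np.random.Generator) -> np.ndarray:
    """Per-channel noise with a 1/f^alpha power spectrum (FFT shaping)."""
    c, t = shape
    white = rng.standard_normal((c, t))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(t)
    scale = np.ones_like(freqs)
    scale[1:] = freqs[1:] ** (-alpha / 2.0)
    scale[0] = 0.0                              # no DC
    return np.fft.irfft(spec * scale, n=t, axis=1)


def simulate_epoch(truth: SyntheticGroundTruth, subject_id: str = "S00",
                   state_tag: str = "AS",
                   rng: np.random.Generator | None = None,
                   ) -> tuple[EEGEpoch, np.ndarray]:
    """Simulate one epoch; returns the epoch and the planted per-sample labels."""
    if rng is None:
        rng = np.random.default_rng(truth.seed)
    t_total = int(round(truth.fs * truth.epoch_length_s))
    c = truth.templates.shape[1]
    segs = sample_segments(truth, t_total, rng)

    amp_law = truth.amplitude_law
    base = amp_law.get("base_gfp", 10.0)
    jitter = amp_law.get("jitter", 0.2)
    osc = amp_law.get("oscillation_hz")

    signal = np.zeros((c, t_total))
    labels = np.empty(t_total, dtype=int)
    pos = 0
    for label, length in segs:
        env = np.sin(np.pi * (np.arange(length) + 0.5) / length)
        if osc:
            tt = (pos + np.arange(length)) / truth.fs
            env = env * np.sin(2 * np.pi * osc * tt + rng.uniform(0, 2 * np.pi))
        sign = -1.0 if rng.random() < 0.5 else 1.0
        amp = base * (np.exp(rng.normal(0.0, jitter)) if jitter > 0 else 1.0)
        signal[:, pos:pos + length] = np.outer(
            truth.templates[label], sign * amp * env)
        labels[pos:pos + length] = label
        pos += length

    snr = truth.noise.get("snr", np.inf)
    if np.isfinite(snr):
        noise = _pink_noise((c, t_total), truth.noise.get("alpha", 1.0), rng)
        decay = truth.noise.get("spatial_decay", 0.3)
        if decay > 0:
            cov = linalg.toeplitz(decay ** np.arange(c))
            noise = np.linalg.cholesky(cov) @ noise
        noise -= noise.mean(axis=0, keepdims=True)   # keep average reference
        sig_rms = np.sqrt(np.mean(signal ** 2))
        noise_rms = np.sqrt(np.mean(noise ** 2))
        if noise_rms > 0:
            noise *= sig_rms / (snr * noise_rms)
        signal = signal + noise

    epoch = EEGEpoch(data=signal, channels=list(truth.channels), fs=truth.fs,
                     subject_id=subject_id, state_tag=state_tag)
    return epoch, labels


@dataclass
class SyntheticCohort:
    """A simulated two-state cohort plus everything needed to score recovery."""

    epochs: list[EEGEpoch]
    true_labels: list[np.ndarray]
    truth_as: SyntheticGroundTruth
    truth_qs: SyntheticGroundTruth

    def epochs_for(self, state: str) -> list[EEGEpoch]:
        return [e for e in self.epochs if e.state_tag == state]


def simulate_cohort(truth_as: SyntheticGroundTruth,
                    truth_qs: SyntheticGroundTruth) -> SyntheticCohort:
    """Simulate all subjects under both sleep-state parameterizations.

    Both truths must share the planted templates and channel layout (the
    study design: states differ in dynamics, not in topography).  Epoch
    seeds are spawned deterministically from each truth's master seed.
    """
    if truth_as.templates.shape != truth_qs.templates.shape or \
            not np.allclose(truth_as.templates, truth_qs.templates):
        raise ValueError("AS and QS truths must share the same templates")
    if truth_as.channels != truth_qs.channels:
        raise ValueError("AS and QS truths must share the channel layout")
    if truth_as.n_subjects != truth_qs.n_subjects:
        raise ValueError("AS and QS truths must cover the same subjects")

    epochs: list[EEGEpoch] = []
    true_labels: list[np.ndarray] = []
    for truth, state in ((truth_as, "AS"), (truth_qs, "QS")):
        children = np.random.SeedSequence(truth.seed).spawn(
            truth.n_subjects * truth.n_epochs)
        i = 0
        for s in range(truth.n_subjects):
            for _ in range(truth.n_epochs):
                rng = np.random.default_rng(children[i])
                i += 1
                ep, lab = simulate_epoch(truth, subject_id=f"S{s:02d}",
                                         state_tag=state, rng=rng)
                epochs.append(ep)
                true_labels.append(lab)
    return SyntheticCohort(epochs, true_labels, truth_as, truth_qs)


def write_cohort(cohort: SyntheticCohort, out_dir: str | Path,
                 format: str = "matrix") -> None:
    """Write epochs (matrix dialect or EDF) plus a ground-truth JSON sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    from .io import write_edf
    for i, (ep, lab) in enumerate(zip(cohort.epochs, cohort.true_labels)):
        stem = f"{ep.subject_id}_{ep.state_tag}_{i:03d}"
        if format == "edf":
            write_edf(ep, out / f"{stem}.edf")
        else:
            write_matrix(ep, out / f"{stem}.txt")
        np.savetxt(out / f"{stem}.labels.txt", lab, fmt="%d")
    (out / "ground_truth_AS.json").write_text(cohort.truth_as.to_json())
    (out / "ground_truth_QS.json").write_text(cohort.truth_qs.to_json())
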