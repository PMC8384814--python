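"""Dominant-template identification: GFP peaks, modified k-means, KL criterion.

The global field power (GFP) at one time sample is the population standard
deviation of the scalp potential across channels,

    GFP_t = sqrt( sum_j (v_jt - vbar_t)^2 / C ).

Topographies at local GFP maxima — the samples with the highest topographic
signal-to-noise ratio — are clustered with the polarity-invariant modified
k-means: maps are assigned to the template with the highest *squared*
spatial correlation (so a map and its sign-flip are equivalent), and each
template is re-estimated as the dominant eigenvector of the outer-product
sum of its assigned (normalized) maps, the closed-form maximizer of the
summed squared correlation.  The number of templates is chosen with the
Krzanowski–Lai index computed on the within-cluster dispersion curve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .io import EEGEpoch


# ---------------------------------------------------------------------------
# GFP
# ---------------------------------------------------------------------------

@dataclass
class GFPTrace:
    """Per-sample GFP values and the indices of its local maxima."""

    values: np.ndarray
    peak_indices: np.ndarray
    fs: float


def gfp(data: np.ndarray | EEGEpoch) -> np.ndarray:
    """GFP of a (C, T) array or epoch: population std across channels."""
    if isinstance(data, EEGEpoch):
        data = data.data
    data = np.asarray(data, dtype=float)
    return np.sqrt(np.mean(
        (data - data.mean(axis=0, keepdims=True)) ** 2, axis=0))


def find_gfp_peaks(values: np.ndarray, fs: float,
                   min_separation_ms: float = 10.0,
                   min_prominence: float | None = None) -> np.ndarray:
    """Local maxima of the GFP trace.

    ``min_separation_ms`` maps to a minimum inter-peak distance in samples;
    there is no prominence threshold by default.  A flat-topped maximum is
    reported at its plateau midpoint (it must still rise strictly above the
    samples flanking the plateau).  An empty result is legal (e.g. a
    monotone trace).
    """
    values = np.asarray(values, dtype=float)
    if values.size < 3:
        return np.array([], dtype=int)
    distance = max(1, int(round(min_separation_ms * fs / 1000.0)))
    peaks, _ = sps.find_peaks(values, distance=distance,
                              prominence=min_prominence)
    return peaks


def gfp_trace(epoch: EEGEpoch, min_separation_ms: float = 10.0,
              min_prominence: float | None = None) -> GFPTrace:
    values = gfp(epoch)
    peaks = find_gfp_peaks(values, epoch.fs, min_separation_ms, min_prominence)
    return GFPTrace(values=values, peak_indices=peaks, fs=epoch.fs)


def peak_maps(epoch: EEGEpoch, trace: GFPTrace | None = None,
              **peak_kwargs) -> np.ndarray:
    """Average-referenced topographies at the GFP peaks, shape (n_peaks, C)."""
    if trace is None:
        trace = gfp_trace(epoch, **peak_kwargs)
    maps = epoch.data[:, trace.peak_indices].T
    return maps - maps.mean(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# modified k-means
# ---------------------------------------------------------------------------

@dataclass
class TemplateSet:
    """An ordered set of K unit-GFP microstate template maps."""

    maps: np.ndarray                       # (K, C), zero-mean, unit-GFP rows
    channels: list[str] = field(default_factory=list)
    labels: list[str] = field(default_factory=list)
    level: str = "group"                   # "individual" | "group"
    band_tag: str = "broad"
    gev: float | None = None

    def __post_init__(self) -> None:
        self.maps = np.atleast_2d(np.asarray(self.maps, dtype=float))
        if self.maps.shape[0] < 2:
            raise ValueError("a template set needs K >= 2 maps")
        if not self.labels:
            self.labels = [chr(ord("A") + i) for i in range(self.maps.shape[0])]
        if not self.channels:
            self.channels = [f"CH{i + 1:02d}" for i in range(self.maps.shape[1])]

    @property
    def k(self) -> int:
        return self.maps.shape[0]

    def reordered(self, order: np.ndarray | list[int]) -> "TemplateSet":
        """Same set with rows permuted; labels are re-assigned A, B, ..."""
        order = list(order)
        return TemplateSet(maps=self.maps[order], channels=list(self.channels),
                           labels=[chr(ord("A") + i) for i in range(self.k)],
                           level=self.level, band_tag=self.band_tag,
                           gev=self.gev)


def _normalize_maps(maps: np.ndarray) -> np.ndarray:
    maps = np.atleast_2d(np.asarray(maps, dtype=float))
    maps = maps - maps.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(maps, axis=1)
    if np.any(norms <= 0):
        raise ValueError("flat (zero-GFP) map cannot be clustered")
    return maps / norms[:, None]


def _unit_gfp(maps: np.ndarray) -> np.ndarray:
    maps = maps - maps.mean(axis=1, keepdims=True)
    g = np.sqrt(np.mean(maps ** 2, axis=1))
    return maps / g[:, None]


def _dominant_eigvec(vhat: np.ndarray) -> np.ndarray:
    s = vhat.T @ vhat
    _, vecs = np.linalg.eigh(s)
    return vecs[:, -1]


def _plusplus_init(vhat: np.ndarray, k: int,
                   rng: np.random.Generator) -> np.ndarray:
    """k-means++ seeding with the sign-agnostic distance 1 - r^2."""
    n = vhat.shape[0]
    idx = np.empty(k, dtype=int)
    idx[0] = rng.integers(n)
    dist = 1.0 - (vhat @ vhat[idx[0]]) ** 2
    for j in range(1, k):
        total = dist.sum()
        if total <= 0:
            idx[j] = rng.integers(n)
        else:
            idx[j] = np.searchsorted(np.cumsum(dist), rng.random() * total)
        dist = np.minimum(dist, 1.0 - (vhat @ vhat[idx[j]]) ** 2)
    return idx


def _exchange_refine(vhat: np.ndarray, assign: np.ndarray, k: int,
                     max_sweeps: int = 20) -> tuple[np.ndarray, float]:
    """Hartigan-style single-map exchange refinement of a partition.

    Repeatedly moves one map to another cluster whenever that increases the
    summed dominant eigenvalues (the clustering objective).  Unlike the
    Lloyd alternation, this searches partition space directly, so it can
    reach optima whose partition is not consistent with its own templates'
    nearest-template assignment.  Cost is O(n k) eigendecompositions per
    sweep, so it is only worthwhile for small map sets.
    """
    n = vhat.shape[0]
    s = [vhat[assign == j].T @ vhat[assign == j] for j in range(k)]
    lam = [float(np.linalg.eigvalsh(m)[-1]) for m in s]
    for _ in range(max_sweeps):
        improved = False
        for i in range(n):
            a = assign[i]
            if np.sum(assign == a) <= 1:
                continue
            vv = np.outer(vhat[i], vhat[i])
            sa = s[a] - vv
            la = float(np.linalg.eigvalsh(sa)[-1])
            best_gain, best_j, best_lj = 1e-12, -1, 0.0
            for j in range(k):
                if j == a:
                    continue
                lj = float(np.linalg.eigvalsh(s[j] + vv)[-1])
                gain = la + lj - lam[a] - lam[j]
                if gain > best_gain:
                    best_gain, best_j, best_lj = gain, j, lj
            if best_j >= 0:
                s[a], lam[a] = sa, la
                s[best_j] = s[best_j] + vv
                lam[best_j] = best_lj
                assign[i] = best_j
                improved = True
        if not improved:
            break
    return assign, float(sum(lam) / n)


def modified_kmeans(maps: np.ndarray, k: int, n_restarts: int = 20,
                    max_iter: int = 300, tol: float = 1e-6,
                    seed: int | None = None,
                    polish: bool | str = "auto",
                    ) -> tuple[TemplateSet, np.ndarray, float]:
    """Polarity-invariant modified k-means on a stack of topographies.

    Parameters
    ----------
    maps : ndarray, shape (n, C)
        Zero-mean topographies (they are re-centered and norm-normalized
        internally; the polarity-invariant objective is scale-free).
    k : int
        Number of templates; must not exceed the number of maps.

    Returns
    -------
    (templates, assignment, explained_variance)
        ``templates.maps`` are unit-GFP; ``explained_variance`` is the mean
        over maps of the squared spatial correlation with the assigned
        template — the quantity maximized, reported for the best restart.

    Notes
    -----
    Each iteration alternates (a) assignment of every map to the template
    with maximal squared correlation and (b) template re-estimation as the
    dominant eigenvector of the assigned maps' outer-product sum.  An
    emptied cluster is re-seeded from the currently worst-fit map.
    Restarts are initialized k-means++-style in the polarity-invariant
    geometry: each seed map is drawn with probability proportional to
    ``1 - max r^2`` against the seeds already chosen, which makes covering
    all well-separated clusters overwhelmingly likely.

    With ``polish`` enabled (``"auto"``: on when ``n * k <= 512``), each
    restart's converged partition is refined by Hartigan-style single-map
    exchanges, which can escape fixed points of the plain alternation; on
    small inputs this reliably attains the exhaustive-partition optimum.
    It is skipped for large map sets, where a single map cannot move the
    dominant eigenvector appreciably and restarts dominate.
    """
    vhat = _normalize_maps(maps)
    n = vhat.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds the number of maps ({n})")
    rng = np.random.default_rng(seed)
    do_polish = (n * k <= 512) if polish == "auto" else bool(polish)

    best_ev = -np.inf
    best_templates = None
    best_assign = None
    for _ in range(n_restarts):
        templates = vhat[_plusplus_init(vhat, k, rng)].copy()
        prev_ev = -np.inf
        for _ in range(max_iter):
            corr = vhat @ templates.T               # (n, k)
            corr2 = corr ** 2
            assign = np.argmax(corr2, axis=1)
            fit = corr2[np.arange(n), assign]
            for j in range(k):
                sel = assign == j
                if not np.any(sel):
                    worst = int(np.argmin(fit))
                    templates[j] = vhat[worst]
                    assign[worst] = j
                    fit[worst] = 1.0
                    sel = assign == j
                templates[j] = _dominant_eigvec(vhat[sel])
            corr2 = (vhat @ templates.T) ** 2
            assign = np.argmax(corr2, axis=1)
            ev = float(np.mean(corr2[np.arange(n), assign]))
            if ev - prev_ev < tol * max(prev_ev, tol):
                prev_ev = ev
                break
            prev_ev = ev
        if do_polish:
            assign, ev_ref = _exchange_refine(vhat, assign.copy(), k)
            if ev_ref > prev_ev:
                prev_ev = ev_ref
                for j in range(k):
                    templates[j] = _dominant_eigvec(vhat[assign == j])
        if prev_ev > best_ev:
            best_ev = prev_ev
            best_templates = templates.copy()
            best_assign = assign.copy()

    tset = TemplateSet(maps=_unit_gfp(best_templates))
    return tset, best_assign, best_ev


def explained_variance(maps: np.ndarray, templates: np.ndarray) -> float:
    """Mean squared spatial correlation of maps with their best template."""
    vhat = _normalize_maps(maps)
    that = _normalize_maps(templates)
    return float(np.mean(np.max((vhat @ that.T) ** 2, axis=1)))


# ---------------------------------------------------------------------------
# Krzanowski-Lai model selection
# ---------------------------------------------------------------------------

@dataclass
class KLCurve:
    """Dispersion curve and KL index over candidate template counts."""

    k_values: np.ndarray
    dispersion: np.ndarray                 # W(k)
    kl: np.ndarray                         # NaN where undefined (edges)
    chosen_k: int
    rule: str


def kl_select(maps: np.ndarray, k_min: int = 3, k_max: int = 15,
              rule: str = "second_max", n_restarts: int = 20,
              seed: int | None = None, **kmeans_kwargs) -> KLCurve:
    """Choose the number of templates with the Krzanowski–Lai criterion.

    The dispersion ``W(k)`` is the summed within-cluster ``1 - r^2`` over
    maps (the same polarity-invariant geometry the clustering minimizes).
    With C channels,

        DIFF(k) = (k-1)^(2/C) W(k-1) - k^(2/C) W(k)
        KL(k)   = | DIFF(k) / DIFF(k+1) |,

    and the chosen k is a local maximum of KL ranked by value:
    ``rule="first_max"`` takes the largest local-maximum value,
    ``"second_max"`` the second-largest.  With fewer than two local maxima
    the second-max rule falls back to first-max with a warning.
    """
    if rule not in ("first_max", "second_max"):
        raise ValueError("rule must be 'first_max' or 'second_max'")
    maps = np.atleast_2d(np.asarray(maps, dtype=float))
    n, c = maps.shape
    if k_max >= n:
        raise ValueError("k_max must be below the number of maps")
    rng = np.random.default_rng(seed)
    ks = np.arange(k_min, k_max + 1)
    w = np.empty(len(ks))
    for i, k in enumerate(ks):
        _, _, ev = modified_kmeans(maps, k, n_restarts=n_restarts,
                                   seed=int(rng.integers(2 ** 31)),
                                   **kmeans_kwargs)
        w[i] = n * (1.0 - ev)

    expo = 2.0 / c
    kl = np.full(len(ks), np.nan)
    diff = np.full(len(ks), np.nan)        # DIFF(k) defined for k>k_min
    for i in range(1, len(ks)):
        diff[i] = (ks[i] - 1) ** expo * w[i - 1] - ks[i] ** expo * w[i]
    for i in range(1, len(ks) - 1):
        if diff[i + 1] != 0:
            kl[i] = abs(diff[i] / diff[i + 1])

    interior = np.arange(1, len(ks) - 1)
    maxima = [i for i in interior
              if np.isfinite(kl[i])
              and (i - 1 < 1 or not np.isfinite(kl[i - 1]) or kl[i] > kl[i - 1])
              and (i + 1 > len(ks) - 2 or not np.isfinite(kl[i + 1])
                   or kl[i] >= kl[i + 1])]
    eff_rule = rule
    if rule == "second_max" and len(maxima) < 2:
        warnings.warn("fewer than 2 local KL maxima; falling back to first_max")
        eff_rule = "first_max"
    ranked = sorted(maxima, key=lambda i: kl[i], reverse=True)
    if not ranked:
        chosen = int(ks[interior[np.nanargmax(kl[interior])]])
    elif eff_rule == "first_max":
        chosen = int(ks[ranked[0]])
    else:
        chosen = int(ks[ranked[1]])
    return KLCurve(k_values=ks, dispersion=w, kl=kl, chosen_k=chosen, rule=rule)


# ---------------------------------------------------------------------------
# two-step (individual -> group) clustering
# ---------------------------------------------------------------------------

def two_step_cluster(epochs: list[EEGEpoch], k: int,
                     n_restarts: int = 20, seed: int | None = None,
                     min_separation_ms: float = 10.0,
                     min_prominence: float | None = None,
                     **kmeans_kwargs) -> TemplateSet:
    """Individual-then-group clustering of GFP-peak topographies.

    Step 1 pools each subject's GFP-peak maps (across that subject's epochs
    in the input) and extracts ``k`` individual templates; step 2 clusters
    the pooled individual templates of all subjects with the same
    polarity-invariant algorithm.  Pass per-state epoch lists for
    state-specific templates or the full cohort for pooled templates.
    """
    if not epochs:
        raise ValueError("no epochs supplied")
    rng = np.random.default_rng(seed)
    subjects: dict[str, list[EEGEpoch]] = {}
    for ep in epochs:
        subjects.setdefault(ep.subject_id, []).append(ep)

    individual = []
    for sid in sorted(subjects):
        maps = np.vstack([
            peak_maps(ep, min_separation_ms=min_separation_ms,
                      min_prominence=min_prominence)
            for ep in subjects[sid]])
        tset, _, _ = modified_kmeans(maps, k, n_restarts=n_restarts,
                                     seed=int(rng.integers(2 ** 31)),
                                     **kmeans_kwargs)
        individual.append(tset.maps)
    pooled = np.vstack(individual)
    group, _, _ = modified_kmeans(pooled, k, n_restarts=n_restarts,
                                  seed=int(rng.integers(2 ** 31)),
                                  **kmeans_kwargs)
    group.channels = list(epochs[0].channels)
    group.level = "group"
    group.band_tag = epochs[0].band_tag
    return group


def match_templates(reference: np.ndarray, other: np.ndarray) -> np.ndarray:
    """Greedy sign-agnostic matching: order ``other``'s rows onto ``reference``.

    Returns the permutation ``perm`` such that ``other[perm[i]]`` is the
    best remaining |correlation| match for ``reference[i]``.
    """
    ref = _normalize_maps(reference)
    oth = _normalize_maps(other)
    corr = np.abs(ref @ oth.T)
    perm = np.full(ref.shape[0], -1, dtype=int)
    used: set[int] = set()
    for _ in range(min(corr.shape)):
        i, j = np.unravel_index(np.argmax(corr), corr.shape)
        perm[i] = j
        used.add(j)
        corr[i, :] = -1
        corr[:, j] = -1
    return perm
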