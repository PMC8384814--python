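"""Topographic comparisons: global dissimilarity (GD) and TANOVA.

GD between two average-referenced maps u, v is the root-mean-square
difference of their GFP-normalized forms,

    GD(u, v) = sqrt( (1/N) * sum_i (u_i/GFP_u - v_i/GFP_v)^2 ),

which for zero-mean maps satisfies the identity GD^2 = 2 (1 - r) with r
the Pearson spatial correlation, so GD ranges over [0, 2].

TANOVA is a nonparametric permutation test on the GD between group-mean
normalized maps: the null distribution is built by exchanging group
(or, for paired designs, within-subject condition) assignments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


def _center(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    return v - v.mean(axis=-1, keepdims=True)


def map_gfp(v: np.ndarray) -> np.ndarray:
    """Spatial GFP of one or more maps (population std across channels)."""
    v = np.asarray(v, dtype=float)
    return np.sqrt(np.mean((v - v.mean(axis=-1, keepdims=True)) ** 2, axis=-1))


def global_dissimilarity(u: np.ndarray, v: np.ndarray) -> float:
    """GD between two maps after average-referencing each."""
    u = _center(u)
    v = _center(v)
    if u.shape != v.shape:
        raise ValueError("maps must have the same channel count")
    gu, gv = map_gfp(u), map_gfp(v)
    if gu <= 0 or gv <= 0:
        raise ValueError("GD undefined for a zero-GFP (flat) map")
    return float(np.sqrt(np.mean((u / gu - v / gv) ** 2)))


def dissimilarity_matrix(maps1: np.ndarray, maps2: np.ndarray,
                         polarity_invariant: bool = False) -> np.ndarray:
    """GD between all pairs of rows of two (K, C) map stacks.

    With ``polarity_invariant=True`` each entry is
    ``min(GD(u, v), GD(u, -v))``, matching the sign-agnostic geometry of
    the clustering.
    """
    maps1 = np.atleast_2d(np.asarray(maps1, dtype=float))
    maps2 = np.atleast_2d(np.asarray(maps2, dtype=float))
    if maps1.shape[1] != maps2.shape[1]:
        raise ValueError("channel counts differ between template sets")
    u = _center(maps1)
    v = _center(maps2)
    gu = map_gfp(u)
    gv = map_gfp(v)
    if np.any(gu <= 0) or np.any(gv <= 0):
        raise ValueError("GD undefined for a zero-GFP (flat) map")
    un = u / gu[:, None]
    vn = v / gv[:, None]
    # GD^2 = mean(un^2) + mean(vn^2) - 2 mean(un*vn) = 2 - 2 r
    r = un @ vn.T / un.shape[1]
    if polarity_invariant:
        r = np.abs(r)
    return np.sqrt(np.clip(2.0 - 2.0 * r, 0.0, None))


@dataclass
class TanovaResult:
    """Observed topographic effect size and its permutation p-value."""

    observed_gd: float
    p_value: float
    n_permutations: int
    paired: bool
    null_distribution: np.ndarray | None = None


def _normalize_rows(maps: np.ndarray) -> np.ndarray:
    maps = _center(np.atleast_2d(maps))
    g = map_gfp(maps)
    if np.any(g <= 0):
        raise ValueError("flat map in TANOVA input")
    return maps / g[:, None]


def _sign_align(maps: np.ndarray) -> np.ndarray:
    """Flip each row's sign toward the stack's dominant spatial axis.

    Polarity-invariant clustering leaves each subject's template with an
    arbitrary sign; without alignment the group mean would cancel.  The
    reference axis is the dominant eigenvector of the pooled outer-product
    sum, which does not depend on group labels, so the alignment is
    permutation-invariant (a requirement for an exact permutation test).
    """
    _, vecs = np.linalg.eigh(maps.T @ maps)
    ref = vecs[:, -1]
    signs = np.where(maps @ ref < 0, -1.0, 1.0)
    return maps * signs[:, None]


def tanova(maps_a: np.ndarray, maps_b: np.ndarray,
           n_permutations: int = 5000, paired: bool = True,
           seed: int | None = None,
           return_null: bool = False) -> TanovaResult:
    """Permutation test for a topographic difference between two groups.

    Parameters
    ----------
    maps_a, maps_b : ndarray, shape (n_subjects, C)
        One map per subject per group; for ``paired=True`` rows must be
        matched by subject and group sizes equal.
    n_permutations : int
        Number of random label exchanges for the null distribution.
    paired : bool
        Within-subject condition swaps (the study design) vs full
        reshuffling of group membership.

    Notes
    -----
    The effect size is the GD between the two group means of GFP-normalized,
    sign-aligned maps; ``p = #(null >= observed) / n_permutations``.
    Degenerate input whose group means are flat yields ``p = 1``.
    """
    rng = np.random.default_rng(seed)
    a = _normalize_rows(maps_a)
    b = _normalize_rows(maps_b)
    # one common alignment reference for both groups: per-group references
    # carry an arbitrary eigenvector sign that can anti-align the means
    pooled_aligned = _sign_align(np.vstack([a, b]))
    a = pooled_aligned[: a.shape[0]]
    b = pooled_aligned[a.shape[0]:]
    if paired and a.shape[0] != b.shape[0]:
        raise ValueError("paired TANOVA needs equal, subject-matched groups")
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("need at least 2 subjects per group")

    def effect(ma: np.ndarray, mb: np.ndarray) -> float:
        if map_gfp(ma) <= 0 or map_gfp(mb) <= 0:
            return 0.0
        return global_dissimilarity(ma, mb)

    observed = effect(a.mean(axis=0), b.mean(axis=0))
    if observed == 0.0 and np.allclose(a, b):
        return TanovaResult(0.0, 1.0, n_permutations, paired)

    if paired:
        n = a.shape[0]
        delta = b - a                             # (n, C)
        sum_a, sum_b = a.sum(axis=0), b.sum(axis=0)
        swap = rng.random((n_permutations, n)) < 0.5
        mean_a = (sum_a[None, :] + swap @ delta) / n
        mean_b = (sum_b[None, :] - swap @ delta) / n
        null = np.array([effect(ma, mb) for ma, mb in zip(mean_a, mean_b)])
    else:
        pooled = np.vstack([a, b])
        na = a.shape[0]
        null = np.empty(n_permutations)
        for i in range(n_permutations):
            idx = rng.permutation(pooled.shape[0])
            null[i] = effect(pooled[idx[:na]].mean(axis=0),
                             pooled[idx[na:]].mean(axis=0))
    p = float(np.mean(null >= observed))
    return TanovaResult(observed, p, n_permutations, paired,
                        null if return_null else None)
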