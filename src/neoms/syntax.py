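"""Microstate syntax: observed vs expected transitions, randomization test,
directional predominance.

Transitions are counted on the run (segment) sequence, so self-transitions
are structurally impossible.  With P_X the share of runs belonging to
template X, the occurrence-driven null predicts

    P*_{X->Y} = P_X * P_Y / (1 - P_X),

the no-self-transition normalization of "the next state is drawn by
occurrence alone".  The observed-vs-expected discrepancy is summarized by
the chi-square distance

    D = sum_{X != Y} (P_{X->Y} - P*_{X->Y})^2 / P*_{X->Y},

whose group-level significance is assessed with a label-swap randomization
test: within each epoch the roles "observed"/"expected" are exchanged with
probability 1/2, the group-mean D recomputed, and the p-value is the share
of randomized distances exceeding the observed one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .backfit import LabelSequence


@dataclass
class TransitionStats:
    """Observed and expected transition probabilities for one epoch."""

    occurrence_probs: np.ndarray           # (K,) run-count shares
    observed: np.ndarray                   # (K, K), zero diagonal
    expected: np.ndarray                   # (K, K), zero diagonal
    n_transitions: int


def transition_stats(labels: LabelSequence | np.ndarray,
                     n_templates: int | None = None) -> TransitionStats:
    """Count run-sequence transitions and the occurrence-driven expectation."""
    if isinstance(labels, LabelSequence):
        seq = labels.segment_labels
        k = labels.n_templates
    else:
        seq = np.asarray(labels, dtype=int)
        if n_templates is None:
            raise ValueError("n_templates required for a bare label sequence")
        k = n_templates
    if seq.size < 2:
        raise ValueError("need at least 2 segments to count transitions")
    if np.any(seq[:-1] == seq[1:]):
        raise ValueError("segment sequence contains a self-transition")

    occ = np.bincount(seq, minlength=k).astype(float)
    p = occ / occ.sum()
    observed = np.zeros((k, k))
    np.add.at(observed, (seq[:-1], seq[1:]), 1.0)
    n_trans = int(observed.sum())
    observed /= n_trans
    expected = np.outer(p, p) / np.where(p < 1.0, 1.0 - p, np.inf)[:, None]
    np.fill_diagonal(expected, 0.0)
    return TransitionStats(occurrence_probs=p, observed=observed,
                           expected=expected, n_transitions=n_trans)


def chi_square_distance(observed: np.ndarray, expected: np.ndarray,
                        eps: float = 1e-15) -> float:
    """Chi-square distance over all ordered pairs of distinct templates.

    A pair with zero expected and zero observed probability is skipped; a
    zero expected with nonzero observed probability is an error (the
    discrepancy is unbounded).
    """
    observed = np.asarray(observed, dtype=float)
    expected = np.asarray(expected, dtype=float)
    off = ~np.eye(observed.shape[0], dtype=bool)
    o, e = observed[off], expected[off]
    bad = (e <= eps) & (o > eps)
    if np.any(bad):
        raise ValueError("observed transition with zero expected probability")
    use = e > eps
    return float(np.sum((o[use] - e[use]) ** 2 / e[use]))


def _chi2_vectorized(obs: np.ndarray, exp: np.ndarray,
                     eps: float = 1e-15) -> np.ndarray:
    """Chi-square distance per leading index of (R, K, K) stacks."""
    k = obs.shape[-1]
    off = ~np.eye(k, dtype=bool)
    o = obs[..., off]
    e = exp[..., off]
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(e > eps, (o - e) ** 2 / np.where(e > eps, e, 1.0), 0.0)
        term = np.where((e <= eps) & (o > eps), np.inf, term)
    return term.sum(axis=-1)


def group_mean_stats(stats_list: list[TransitionStats],
                     subject_ids: list[str] | None = None,
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Across-epoch means of observed and expected probability matrices.

    When ``subject_ids`` are given and epochs per subject are unbalanced,
    matrices are first averaged within subject.
    """
    obs = np.array([s.observed for s in stats_list])
    exp = np.array([s.expected for s in stats_list])
    if subject_ids is not None:
        ids = np.asarray(subject_ids)
        uniq = np.unique(ids)
        obs = np.array([obs[ids == u].mean(axis=0) for u in uniq])
        exp = np.array([exp[ids == u].mean(axis=0) for u in uniq])
    return obs.mean(axis=0), exp.mean(axis=0)


@dataclass
class SyntaxTestResult:
    chi_square_distance: float
    p_value: float
    n_randomizations: int


def randomization_test(stats_list: list[TransitionStats],
                       n_reps: int = 5000, seed: int | None = None,
                       subject_ids: list[str] | None = None,
                       conservative: bool = False) -> SyntaxTestResult:
    """Randomization test of the group-level chi-square distance.

    The observed effect is D between the group-mean observed and group-mean
    expected matrices.  Each of ``n_reps`` randomizations swaps the
    observed/expected pair within each epoch with probability 1/2 and
    recomputes D; ``p`` is the share of randomized D values at or above the
    observed one (``conservative=True`` uses (r+1)/(n+1) instead).
    """
    if len(stats_list) < 2:
        raise ValueError("need at least 2 epochs")
    if n_reps < 100:
        warnings.warn("fewer than 100 randomizations gives a coarse p-value")
    rng = np.random.default_rng(seed)
    obs = np.array([s.observed for s in stats_list])
    exp = np.array([s.expected for s in stats_list])
    if subject_ids is not None:
        ids = np.asarray(subject_ids)
        uniq = np.unique(ids)
        obs = np.array([obs[ids == u].mean(axis=0) for u in uniq])
        exp = np.array([exp[ids == u].mean(axis=0) for u in uniq])
    n_ep = obs.shape[0]
    d_obs = chi_square_distance(obs.mean(axis=0), exp.mean(axis=0))
    if not np.isfinite(d_obs):
        raise ValueError("non-finite observed chi-square distance")

    delta = exp - obs                                   # (E, K, K)
    swap = rng.random((n_reps, n_ep)) < 0.5             # (R, E)
    shift = np.tensordot(swap, delta, axes=(1, 0)) / n_ep
    obs_mean = obs.mean(axis=0)[None] + shift
    exp_mean = exp.mean(axis=0)[None] - shift
    d_rand = _chi2_vectorized(obs_mean, exp_mean)
    if conservative:
        p = (np.sum(d_rand >= d_obs) + 1) / (n_reps + 1)
    else:
        p = np.sum(d_rand >= d_obs) / n_reps
    return SyntaxTestResult(chi_square_distance=d_obs, p_value=float(p),
                            n_randomizations=n_reps)


def directional_predominance(stats_list: list[TransitionStats],
                             template_names: list[str] | None = None,
                             alpha: float = 0.05) -> pd.DataFrame:
    """Per-pair forward-minus-reverse transition asymmetry with FDR testing.

    For each unordered pair (X, Y), X < Y, the per-epoch predominance is
    ``P_{X->Y} - P_{Y->X}``; the group-level test is a two-sided one-sample
    t against zero, Benjamini–Hochberg corrected across the K(K-1)/2 pairs.
    Pairs with zero variance across epochs are reported as degenerate
    (NaN t and p).
    """
    from .groupstats import fdr_adjust

    k = stats_list[0].observed.shape[0]
    names = template_names or [chr(ord("A") + i) for i in range(k)]
    pairs = list(combinations(range(k), 2))
    diffs = np.array([[s.observed[x, y] - s.observed[y, x] for x, y in pairs]
                      for s in stats_list])                  # (E, P)
    rows = []
    raw_p = np.full(len(pairs), np.nan)
    tvals = np.full(len(pairs), np.nan)
    for j, (x, y) in enumerate(pairs):
        d = diffs[:, j]
        if len(d) >= 2 and np.std(d, ddof=1) > 0:
            t, p = sstats.ttest_1samp(d, 0.0)
            tvals[j], raw_p[j] = t, p
    finite = np.isfinite(raw_p)
    adj = np.full(len(pairs), np.nan)
    if finite.any():
        adj[finite] = fdr_adjust(raw_p[finite])
    for j, (x, y) in enumerate(pairs):
        rows.append(dict(pair=f"{names[x]}->{names[y]}",
                         mean_predominance=float(diffs[:, j].mean()),
                         t=tvals[j], p_raw=raw_p[j], p_fdr=adj[j],
                         significant=bool(adj[j] < alpha)
                         if np.isfinite(adj[j]) else False,
                         degenerate=not np.isfinite(raw_p[j])))
    return pd.DataFrame(rows)
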