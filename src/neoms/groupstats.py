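"""Inferential layer: two-way repeated-measures ANOVA with Greenhouse–Geisser
correction, Bonferroni-corrected paired post-hocs, FDR adjustment, one-sample
t-tests.

The ANOVA is computed directly from the sums-of-squares decomposition of a
fully balanced subject x A x B within-subject table: each within factor's
error term is its interaction with subjects.  When an effect has more than
one numerator degree of freedom, the Greenhouse–Geisser epsilon is
estimated from the covariance matrix of the effect's contrast scores and
both degrees of freedom are multiplied by it; effects with df = 1 need no
sphericity correction (epsilon = 1).  Effect size is partial eta squared,
SS_effect / (SS_effect + SS_error).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats
from statsmodels.stats.multitest import multipletests


@dataclass
class AnovaResult:
    effect: str
    df1: float                      # GG-corrected numerator df
    df2: float                      # GG-corrected denominator df
    F: float
    p: float
    partial_eta_squared: float
    epsilon: float


def _gg_epsilon(scores: np.ndarray) -> float:
    """Greenhouse–Geisser epsilon from subject x condition scores.

    Uses the standard formula on the covariance of orthonormal-contrast
    projections: with M (m x m-1) an orthonormal basis of the contrast
    space and S the condition covariance, eps =
    tr(M'SM)^2 / ((m-1) * tr((M'SM)^2)).
    """
    m = scores.shape[1]
    if m < 2:
        return 1.0
    s = np.cov(scores, rowvar=False)
    # orthonormal basis of the space orthogonal to the unit vector
    q, _ = np.linalg.qr(np.column_stack(
        [np.ones(m), np.eye(m)[:, : m - 1]]))
    mmat = q[:, 1:]
    w = mmat.T @ s @ mmat
    tr = np.trace(w)
    denom = (m - 1) * np.trace(w @ w)
    if denom <= 0:
        return 1.0
    return float(min(1.0, tr ** 2 / denom))


def rm_anova_2way(cube: np.ndarray | pd.DataFrame,
                  factor_names: tuple[str, str] = ("A", "B"),
                  subject: str = "subject",
                  dv: str = "value") -> list[AnovaResult]:
    """Two-way fully-within repeated-measures ANOVA.

    Parameters
    ----------
    cube : ndarray (n_subjects, a, b) or long DataFrame
        A long table needs columns ``subject``, the two factors and ``dv``;
        it must be complete and balanced (one observation per cell —
        missing cells raise).
    """
    if isinstance(cube, pd.DataFrame):
        piv = cube.pivot_table(index=subject, columns=list(factor_names),
                               values=dv, aggfunc="mean")
        if piv.isna().any().any():
            raise ValueError("missing cells in the within-subject table")
        a_levels = piv.columns.get_level_values(0).unique()
        b_levels = piv.columns.get_level_values(1).unique()
        cube = piv.to_numpy().reshape(len(piv), len(a_levels), len(b_levels))
    cube = np.asarray(cube, dtype=float)
    if cube.ndim != 3:
        raise ValueError("expected a (subjects, A, B) data cube")
    if np.isnan(cube).any():
        raise ValueError("missing cells in the within-subject table")
    n, a, b = cube.shape
    if n < 3:
        raise ValueError("need at least 3 subjects")

    grand = cube.mean()
    m_s = cube.mean(axis=(1, 2))           # subject means
    m_a = cube.mean(axis=(0, 2))
    m_b = cube.mean(axis=(0, 1))
    m_sa = cube.mean(axis=2)               # (n, a)
    m_sb = cube.mean(axis=1)               # (n, b)
    m_ab = cube.mean(axis=0)               # (a, b)

    ss_a = n * b * np.sum((m_a - grand) ** 2)
    ss_b = n * a * np.sum((m_b - grand) ** 2)
    ss_ab = n * np.sum((m_ab - m_a[:, None] - m_b[None, :] + grand) ** 2)
    ss_sa = b * np.sum((m_sa - m_s[:, None] - m_a[None, :] + grand) ** 2)
    ss_sb = a * np.sum((m_sb - m_s[:, None] - m_b[None, :] + grand) ** 2)
    resid = (cube - m_sa[:, :, None] - m_sb[:, None, :] - m_ab[None, :, :]
             + m_s[:, None, None] + m_a[None, :, None] + m_b[None, None, :]
             - grand)
    ss_sab = np.sum(resid ** 2)

    # contrast scores for epsilon: collapse over the other factor;
    # interaction uses the full a*b cell scores with the Kronecker contrast,
    # which the trace formula handles via double centering of cells
    def eps_interaction() -> float:
        cells = cube.reshape(n, a * b)
        # interaction contrast space: Kronecker product of the two
        # main-effect contrast bases
        qa, _ = np.linalg.qr(np.column_stack([np.ones(a), np.eye(a)[:, :a - 1]]))
        qb, _ = np.linalg.qr(np.column_stack([np.ones(b), np.eye(b)[:, :b - 1]]))
        c = np.kron(qa[:, 1:], qb[:, 1:])          # (a*b, (a-1)(b-1))
        s = np.cov(cells, rowvar=False)
        w = c.T @ s @ c
        tr = np.trace(w)
        denom = (a - 1) * (b - 1) * np.trace(w @ w)
        return float(min(1.0, tr ** 2 / denom)) if denom > 0 else 1.0

    effects = [
        (factor_names[0], ss_a, a - 1, ss_sa, (a - 1) * (n - 1),
         _gg_epsilon(m_sa) if a > 2 else 1.0),
        (factor_names[1], ss_b, b - 1, ss_sb, (b - 1) * (n - 1),
         _gg_epsilon(m_sb) if b > 2 else 1.0),
        (f"{factor_names[0]} * {factor_names[1]}", ss_ab, (a - 1) * (b - 1),
         ss_sab, (a - 1) * (b - 1) * (n - 1),
         eps_interaction() if (a - 1) * (b - 1) > 1 else 1.0),
    ]
    results = []
    for name, ss_eff, df1, ss_err, df2, eps in effects:
        if ss_err <= 0:
            f = 0.0 if ss_eff <= 0 else np.inf
            p = 1.0 if ss_eff <= 0 else 0.0
        else:
            f = (ss_eff / df1) / (ss_err / df2)
            p = float(sstats.f.sf(f, df1 * eps, df2 * eps))
        pes = ss_eff / (ss_eff + ss_err) if (ss_eff + ss_err) > 0 else 0.0
        results.append(AnovaResult(effect=name, df1=df1 * eps, df2=df2 * eps,
                                   F=float(f), p=p,
                                   partial_eta_squared=float(pes),
                                   epsilon=float(eps)))
    return results


def anova_table(results: list[AnovaResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])


@dataclass
class PosthocResult:
    contrast: str
    t: float
    p_raw: float
    p_adjusted: float
    method: str
    degenerate: bool = False


def paired_posthoc(pairs: dict[str, tuple[np.ndarray, np.ndarray]],
                   method: str = "bonferroni") -> list[PosthocResult]:
    """Two-sided paired t-tests with Bonferroni or BH adjustment.

    ``pairs`` maps a contrast name to its two matched observation vectors.
    Zero-variance differences are reported degenerate (NaN t, p = 1).
    """
    if method not in ("bonferroni", "fdr"):
        raise ValueError("method must be 'bonferroni' or 'fdr'")
    m = len(pairs)
    names, tvals, praw, degen = [], [], [], []
    for name, (x, y) in pairs.items():
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.shape != y.shape:
            raise ValueError(f"{name}: unmatched pair lengths")
        d = x - y
        names.append(name)
        if np.std(d, ddof=1) == 0:
            tvals.append(np.nan)
            praw.append(1.0)
            degen.append(True)
        else:
            t, p = sstats.ttest_rel(x, y)
            tvals.append(float(t))
            praw.append(float(p))
            degen.append(False)
    if method == "bonferroni":
        adj = [min(1.0, p * m) for p in praw]
    else:
        adj = list(fdr_adjust(np.array(praw)))
    return [PosthocResult(contrast=n, t=t, p_raw=p, p_adjusted=a,
                          method=method, degenerate=dg)
            for n, t, p, a, dg in zip(names, tvals, praw, adj, degen)]


def fdr_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values."""
    p_values = np.asarray(p_values, dtype=float)
    if p_values.size == 0:
        return p_values
    if np.any((p_values < 0) | (p_values > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    _, adj, _, _ = multipletests(p_values, method="fdr_bh")
    return adj


def one_sample_t(values: np.ndarray, null: float = 0.0,
                 ) -> tuple[float, float, bool]:
    """Two-sided one-sample t-test; returns (t, p, degenerate)."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 observations")
    if np.std(values, ddof=1) == 0:
        return np.nan, 1.0 if values[0] == null else 0.0, True
    t, p = sstats.ttest_1samp(values, null)
    return float(t), float(p), False
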