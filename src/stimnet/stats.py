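"""Group-level inference across stimulation levels.

Implements the within-subject comparisons used on the kinematic, power and
connectivity tables: paired t, Wilcoxon matched-pairs signed rank, a
one-within-factor repeated-measures ANOVA over the four stimulation levels,
and the Tukey HSD post hoc on the level means with the subject-by-level
interaction mean square as the error term.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "paired_t",
    "wilcoxon_signed_rank",
    "rm_anova_level",
    "tukey_hsd",
    "RMAnovaResult",
]


def paired_t(x, y) -> tuple[float, int, float]:
    """Classical paired t-test on the differences; returns (t, df, p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = x - y
    if np.allclose(d, d[0]):
        if d[0] == 0:
            return 0.0, n - 1, 1.0
        raise ValueError("zero-variance differences: t statistic undefined")
    res = sps.ttest_rel(x, y)
    return float(res.statistic), n - 1, float(res.pvalue)


def wilcoxon_signed_rank(x, y) -> tuple[float, float]:
    """Wilcoxon matched-pairs signed rank test; returns (W+, two-sided p).

    Zero differences are dropped (Wilcoxon's original treatment). The
    statistic is pinned to the positive-rank sum W+; the p-value uses the
    exact sign-pattern distribution for n <= 25 and the tie-corrected normal
    approximation above.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    d = x - y
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise ValueError("all differences are zero: test undefined")
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    method = "exact" if n <= 25 else "approx"
    res = sps.wilcoxon(d, zero_method="wilcox", alternative="two-sided",
                       method=method)
    return w_plus, float(res.pvalue)


@dataclass(frozen=True)
class RMAnovaResult:
    """One-within-factor repeated-measures ANOVA over stimulation level."""

    F: float
    df1: int
    df2: int
    p: float
    ms_error: float  # subject-by-level interaction mean square
    level_means: np.ndarray
    n_subjects: int
    gg_epsilon: float | None = None  # set when Greenhouse-Geisser applied


def _as_matrix(table) -> np.ndarray:
    m = np.asarray(table, dtype=float)
    if m.ndim != 2:
        raise ValueError("table must be subjects x levels")
    if np.isnan(m).any():
        n0 = m.shape[0]
        m = m[~np.isnan(m).any(axis=1)]
        import warnings

        warnings.warn(f"dropped {n0 - m.shape[0]} incomplete subject(s) "
                      "(listwise deletion)", stacklevel=3)
    if m.shape[0] < 2:
        raise ValueError("need >= 2 complete subjects")
    return m


def rm_anova_level(table, greenhouse_geisser: bool = False) -> RMAnovaResult:
    """RM-ANOVA with levels as the within factor.

    F = MS_level / MS_(subject x level), df = (k-1, (k-1)(n-1)); no
    sphericity correction by default, Greenhouse-Geisser on request.
    ``table`` is an (n_subjects, n_levels) array or DataFrame.
    """
    m = _as_matrix(table)
    n, k = m.shape
    grand = m.mean()
    subj_means = m.mean(axis=1)
    level_means = m.mean(axis=0)
    ss_level = n * np.sum((level_means - grand) ** 2)
    ss_subj = k * np.sum((subj_means - grand) ** 2)
    ss_total = np.sum((m - grand) ** 2)
    ss_err = ss_total - ss_level - ss_subj
    df1, df2 = k - 1, (k - 1) * (n - 1)
    ms_level = ss_level / df1
    ms_err = ss_err / df2
    gg_eps = None
    if ms_err <= 0:
        return RMAnovaResult(0.0, df1, df2, 1.0, 0.0, level_means, n)
    f_stat = ms_level / ms_err
    if greenhouse_geisser:
        # Epsilon from the double-centered covariance of the level columns.
        s = np.cov(m.T, ddof=1)
        s_dc = s - s.mean(axis=0) - s.mean(axis=1)[:, None] + s.mean()
        gg_eps = float(np.trace(s_dc) ** 2 /
                       ((k - 1) * np.sum(s_dc**2)))
        p = float(sps.f.sf(f_stat, df1 * gg_eps, df2 * gg_eps))
    else:
        p = float(sps.f.sf(f_stat, df1, df2))
    return RMAnovaResult(float(f_stat), df1, df2, p, float(ms_err),
                         level_means, n, gg_eps)


def tukey_hsd(table) -> pd.DataFrame:
    """Tukey HSD over all level pairs, using the RM-ANOVA error term.

    q = |mean_i - mean_j| / sqrt(MS_error / n) referred to the studentized
    range distribution with k groups and the interaction df.
    """
    m = _as_matrix(table)
    n, k = m.shape
    res = rm_anova_level(m)
    se = np.sqrt(res.ms_error / n)
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            diff = res.level_means[j] - res.level_means[i]
            if se == 0:
                q, p = (0.0, 1.0) if diff == 0 else (np.inf, 0.0)
            else:
                q = abs(diff) / se
                p = float(sps.studentized_range.sf(q, k, res.df2))
            rows.append({"level_a": i, "level_b": j, "diff": float(diff),
                         "q": float(q), "p_adj": min(1.0, p)})
    return pd.DataFrame(rows)
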