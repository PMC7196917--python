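"""Exact and asymptotic statistical primitives shared by the pipeline.

The tests used throughout the package — Fisher's exact test for 2x2
association tables, Benjamini-Hochberg FDR adjustment, Kruskal-Wallis /
Mann-Whitney rank tests, Pearson chi-square for r x c contingency tables,
and the upper-tail binomial test for motif enrichment — live here so that
every caller shares one set of conventions (two-sided rules, tie handling,
zero-cell corrections).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.stats as ss

__all__ = [
    "ContingencyTable",
    "FisherResult",
    "fisher_exact_2x2",
    "bh_adjust",
    "rank_group_test",
    "chi_square_independence",
    "binomial_upper_tail",
    "welch_t_test",
]


@dataclass(frozen=True)
class ContingencyTable:
    """Non-negative integer count table with optional row/column labels."""

    counts: np.ndarray
    row_labels: tuple = ()
    col_labels: tuple = ()

    def __post_init__(self):
        arr = np.asarray(self.counts)
        if np.any(arr < 0):
            raise ValueError("contingency counts must be non-negative")
        if not np.all(arr == np.floor(arr)):
            raise ValueError("contingency counts must be integers")
        if arr.sum() <= 0:
            raise ValueError("contingency table needs at least one positive margin")
        object.__setattr__(self, "counts", arr.astype(np.int64))


@dataclass(frozen=True)
class FisherResult:
    odds_ratio: float
    p_value: float
    haldane_corrected: bool = False
    table: tuple = field(default=())


def fisher_exact_2x2(table) -> FisherResult:
    """Two-sided Fisher's exact test on a 2x2 table.

    The two-sided p sums the hypergeometric probabilities of every table
    with the observed margins whose probability does not exceed that of the
    observed table (probability-mass rule). The reported odds ratio is the
    sample ad/bc; when any cell is zero, the Haldane correction of 0.5 is
    added to every cell and the result flagged.
    """
    arr = np.asarray(table, dtype=float)
    if arr.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if np.any(arr < 0) or not np.all(arr == np.floor(arr)):
        raise ValueError("cells must be non-negative integers")
    a, b, c, d = arr.ravel()
    _, p = ss.fisher_exact(arr, alternative="two-sided")
    corrected = False
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        corrected = True
    oratio = (a * d) / (b * c)
    return FisherResult(
        odds_ratio=float(oratio),
        p_value=float(min(p, 1.0)),
        haldane_corrected=corrected,
        table=tuple(map(int, np.asarray(table).ravel())),
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    # enforce monotonicity from the largest p downwards
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(n)
    q[order] = q_sorted
    return q


def rank_group_test(groups):
    """Omnibus rank test across >= 2 groups.

    Returns ``(statistic, p)``: the tie-corrected Kruskal-Wallis H with its
    chi-square (k-1 df) p value. With exactly two groups the returned p is
    the two-sided Mann-Whitney p instead — exact when both groups have
    n <= 8 and the data are tie-free, the normal approximation with tie and
    continuity correction otherwise — so that two-group calls agree with
    the field's usual pairwise test.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(g.size == 0 for g in groups):
        raise ValueError("every group must be non-empty")
    if sum(g.size for g in groups) < 3:
        raise ValueError("need at least three observations in total")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        # degenerate: identical observations carry no ordering information
        return 0.0, 1.0
    if len(groups) == 2:
        x, y = groups
        exact = x.size <= 8 and y.size <= 8 and np.unique(pooled).size == pooled.size
        res = ss.mannwhitneyu(
            x, y, alternative="two-sided", method="exact" if exact else "asymptotic"
        )
        h, _ = ss.kruskal(*groups)
        return float(h), float(res.pvalue)
    h, p = ss.kruskal(*groups)
    return float(h), float(p)


def chi_square_independence(table):
    """Pearson chi-square test of independence on an r x c count table.

    Rows/columns with zero margins are dropped (they cannot contribute to
    the statistic); returns ``(statistic, df, p, dropped)`` where *dropped*
    flags whether any zero-margin row or column was removed.
    """
    tab = table.counts if isinstance(table, ContingencyTable) else np.asarray(table)
    tab = np.asarray(tab, dtype=float)
    if tab.ndim != 2:
        raise ValueError("expected a 2-D table")
    row_keep = tab.sum(axis=1) > 0
    col_keep = tab.sum(axis=0) > 0
    dropped = bool((~row_keep).any() or (~col_keep).any())
    eff = tab[np.ix_(row_keep, col_keep)]
    if eff.shape[0] < 2 or eff.shape[1] < 2:
        raise ValueError("fewer than two effective rows or columns")
    stat, p, dof, _ = ss.chi2_contingency(eff, correction=False)
    return float(stat), int(dof), float(p), dropped


def binomial_upper_tail(k: int, n: int, p0: float) -> float:
    """P(X >= k) for X ~ Binomial(n, p0)."""
    if not (0 <= k <= n):
        raise ValueError("k must satisfy 0 <= k <= n")
    if not (0.0 <= p0 <= 1.0):
        raise ValueError("p0 must lie in [0, 1]")
    if k == 0:
        return 1.0
    return float(ss.binom.sf(k - 1, n, p0))


def welch_t_test(x, y):
    """Two-sided Welch t-test convenience wrapper: returns (statistic, p)."""
    res = ss.ttest_ind(np.asarray(x, float), np.asarray(y, float), equal_var=False)
    return float(res.statistic), float(res.pvalue)
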