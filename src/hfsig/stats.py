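"""Shared statistical primitives: rank-sum tests and BH adjustment.

The two-sided Wilcoxon rank-sum p-value is exact (full enumeration of group
assignments, mid-ranks for ties) when both groups have at most
``EXACT_MAX_GROUP`` observations, and uses the tie-corrected normal
approximation with continuity correction otherwise.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np
import scipy.stats
from statsmodels.stats.multitest import multipletests

EXACT_MAX_GROUP = 8

__all__ = ["EXACT_MAX_GROUP", "bh_adjust", "rank_sum_p", "rank_sum_p_many"]


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (FDR q-values)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def _exact_rank_sum_p(x: np.ndarray, y: np.ndarray) -> float:
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    # doubled mid-ranks are integers, so the enumeration is exact
    ranks2 = np.round(2 * scipy.stats.rankdata(pooled)).astype(np.int64)
    total = comb(n1 + n2, n1)
    w_obs = int(ranks2[:n1].sum())
    n_le = 0
    n_ge = 0
    for idx in combinations(range(n1 + n2), n1):
        w = int(ranks2[list(idx)].sum())
        if w <= w_obs:
            n_le += 1
        if w >= w_obs:
            n_ge += 1
    p = 2.0 * min(n_le, n_ge) / total
    return min(1.0, p)


def rank_sum_p(x, y) -> float:
    """Two-sided Wilcoxon rank-sum p-value for two samples."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("rank_sum_p requires two non-empty groups")
    if np.all(np.concatenate([x, y]) == x[0]):
        return 1.0
    if len(x) <= EXACT_MAX_GROUP and len(y) <= EXACT_MAX_GROUP:
        return _exact_rank_sum_p(x, y)
    res = scipy.stats.mannwhitneyu(
        x, y, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    return float(res.pvalue)


def rank_sum_p_many(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Row-wise two-sided rank-sum p-values.

    ``X`` is features x n1, ``Y`` features x n2.  Uses the batched asymptotic
    test when either group exceeds the exact-enumeration cutoff.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape[0] != Y.shape[0]:
        raise ValueError("row count mismatch")
    if X.shape[0] == 0:
        return np.zeros(0)
    if X.shape[1] <= EXACT_MAX_GROUP and Y.shape[1] <= EXACT_MAX_GROUP:
        return np.array([rank_sum_p(x, y) for x, y in zip(X, Y)])
    constant = np.all(np.concatenate([X, Y], axis=1) == X[:, :1], axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        res = scipy.stats.mannwhitneyu(
            X, Y, alternative="two-sided", method="asymptotic",
            use_continuity=True, axis=1,
        )
    p = np.asarray(res.pvalue, dtype=float)
    p[constant] = 1.0
    p[~np.isfinite(p)] = 1.0
    return p
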