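"""Over-representation analysis and preranked enrichment.

Over-representation uses the one-sided hypergeometric upper tail with BH
adjustment applied within each collection category; by default only sets with
q < 0.05 are returned, truncated to the top 10 per category (the defaults of
the web tool being emulated).

Preranked enrichment uses the weighted Kolmogorov-Smirnov running sum
(weight = |ranking score|, exponent 1) with a gene-permutation null.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .iolib import GeneSetCollection, ValidationError
from .stats import bh_adjust

__all__ = ["enrich_overrepresentation", "gsea_preranked", "enrichment_score"]

ENRICH_COLUMNS = ["set", "category", "overlap", "set_size", "query_size",
                  "universe_size", "p", "q"]


def enrich_overrepresentation(
    query: Sequence[str],
    collection: GeneSetCollection,
    universe: Sequence[str],
    q_max: float = 0.05,
    top_k: int | None = 10,
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` against every set in
    ``collection`` within ``universe``.

    Query genes outside the universe are dropped with a warning; set
    membership is intersected with the universe.  BH adjustment is applied
    within each category; sets with q < ``q_max`` are returned sorted by
    (q, p, name), at most ``top_k`` per category.
    """
    universe = list(dict.fromkeys(universe))
    uset = set(universe)
    query_in = [g for g in dict.fromkeys(query) if g in uset]
    dropped = len(list(dict.fromkeys(query))) - len(query_in)
    if dropped:
        warnings.warn(f"{dropped} query genes outside the universe were dropped")
    if not query_in:
        raise ValidationError("query is empty after universe filtering")
    qset = set(query_in)
    M = len(universe)
    N = len(query_in)

    rows = []
    for gs in collection.sets.values():
        members = set(gs.members) & uset
        if not members:
            continue
        k = len(members & qset)
        n = len(members)
        p = float(scipy.stats.hypergeom.sf(k - 1, M, n, N))
        rows.append({"set": gs.name, "category": gs.category, "overlap": k,
                     "set_size": n, "query_size": N, "universe_size": M, "p": p})
    if not rows:
        return pd.DataFrame(columns=ENRICH_COLUMNS)
    df = pd.DataFrame(rows)
    df["q"] = np.nan
    for cat in df["category"].unique():
        mask = df["category"] == cat
        df.loc[mask, "q"] = bh_adjust(df.loc[mask, "p"].to_numpy())
    df = df[df["q"] < q_max]
    df = df.sort_values(["q", "p", "set"]).reset_index(drop=True)
    if top_k is not None:
        df = df.groupby("category", group_keys=False, sort=False).head(top_k)
        df = df.sort_values(["q", "p", "set"]).reset_index(drop=True)
    return df[ENRICH_COLUMNS]


def _es_from_positions(pos: np.ndarray, w_members: np.ndarray, n_genes: int,
                       ) -> tuple[float, float]:
    """Largest positive and largest negative deviation of the weighted KS
    running sum, given sorted 0-based member positions and their weights."""
    m = len(pos)
    wsum = w_members.sum()
    if wsum <= 0:
        w_members = np.ones(m)
        wsum = float(m)
    hit = np.cumsum(w_members) / wsum
    miss_step = 1.0 / (n_genes - m)
    # deviation just after each member, and just before each member
    after = hit - (pos - np.arange(m)) * miss_step
    before = np.concatenate([[0.0], hit[:-1]]) - (pos - np.arange(m)) * miss_step
    max_pos = max(0.0, float(after.max()))
    min_neg = min(0.0, float(before.min()))
    return max_pos, min_neg


def enrichment_score(ranked_genes: Sequence[str], scores: Sequence[float],
                     members: Sequence[str]) -> float:
    """Signed maximum deviation of the weighted KS running sum for one set
    over a descending ranking."""
    ranked_genes = list(ranked_genes)
    n = len(ranked_genes)
    w = np.abs(np.asarray(scores, dtype=float))
    mset = set(members)
    pos = np.array([i for i, g in enumerate(ranked_genes) if g in mset], dtype=int)
    if len(pos) == 0 or len(pos) >= n:
        raise ValidationError("set must hit a strict, non-empty subset of the ranking")
    max_pos, min_neg = _es_from_positions(pos, w[pos], n)
    return max_pos if max_pos >= -min_neg else min_neg


def gsea_preranked(
    ranked_genes: Sequence[str],
    scores: Sequence[float],
    collection: GeneSetCollection,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Preranked enrichment of every set against a descending gene ranking.

    Returns a DataFrame with columns set, category, size, es, nes, p, q.
    p-values come from a seeded gene-permutation null (two-sided on |ES|);
    q is BH over the tested sets.  Sets with < 2 members in the ranking, or
    spanning the entire ranking, are skipped with a warning.
    """
    ranked_genes = list(ranked_genes)
    if len(set(ranked_genes)) != len(ranked_genes):
        raise ValidationError("ranked list contains duplicate gene ids")
    scores = np.asarray(scores, dtype=float)
    if scores.shape != (len(ranked_genes),):
        raise ValidationError("scores must align with ranked_genes")
    if not np.all(np.isfinite(scores)):
        raise ValidationError("ranking scores must be finite")
    if n_perm < 100:
        raise ValidationError("n_perm must be >= 100")
    n = len(ranked_genes)
    w = np.abs(scores)
    gene_pos = {g: i for i, g in enumerate(ranked_genes)}
    rng = np.random.default_rng(seed)

    rows = []
    for gs in collection.sets.values():
        pos = np.array(sorted(gene_pos[g] for g in set(gs.members) if g in gene_pos),
                       dtype=int)
        m = len(pos)
        if m < 2:
            warnings.warn(f"set {gs.name!r} has < 2 members in the ranking; skipped")
            continue
        if m >= n:
            warnings.warn(f"set {gs.name!r} spans the entire ranking; skipped")
            continue
        max_pos, min_neg = _es_from_positions(pos, w[pos], n)
        es = max_pos if max_pos >= -min_neg else min_neg

        # gene-permutation null: m uniformly random positions per draw
        perm_pos = np.argsort(rng.random((n_perm, n)), axis=1)[:, :m]
        perm_pos.sort(axis=1)
        wp = w[perm_pos]
        wsum = wp.sum(axis=1, keepdims=True)
        bad = (wsum[:, 0] <= 0)
        if bad.any():
            wp[bad] = 1.0
            wsum = wp.sum(axis=1, keepdims=True)
        hit = np.cumsum(wp, axis=1) / wsum
        miss = (perm_pos - np.arange(m)[None, :]) / (n - m)
        after = hit - miss
        before = np.concatenate([np.zeros((n_perm, 1)), hit[:, :-1]], axis=1) - miss
        mx = np.maximum(after.max(axis=1), 0.0)
        mn = np.minimum(before.min(axis=1), 0.0)
        es_perm = np.where(mx >= -mn, mx, mn)

        p = (1.0 + np.sum(np.abs(es_perm) >= abs(es))) / (n_perm + 1.0)
        denom = np.abs(es_perm).mean()
        nes = es / denom if denom > 0 else 0.0
        rows.append({"set": gs.name, "category": gs.category, "size": m,
                     "es": es, "nes": nes, "p": p})
    if not rows:
        return pd.DataFrame(columns=["set", "category", "size", "es", "nes", "p", "q"])
    df = pd.DataFrame(rows)
    df["q"] = bh_adjust(df["p"].to_numpy())
    return df.sort_values(["p", "set"]).reset_index(drop=True)
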