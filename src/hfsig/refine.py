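"""Cyclic leave-one-out, AUC-maximizing signature refinement.

Starting from a candidate pool of n genes, each cycle evaluates all n
leave-one-out subsets of size n-1 under nearest-centroid multiple random
validation, retains the subset with the highest pooled AUC, and recurses
until no more than ``stop_size`` genes remain.  Within a cycle every subset
is evaluated against the same pre-drawn split sequence so AUC differences
reflect gene content rather than split noise; fresh splits are drawn for
each cycle from the seeded stream.

The selected signature is, by default, the smallest size attaining the
global maximum AUC over all cycles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .classval import draw_stratified_splits, multiple_random_validation
from .iolib import BulkCohort, GeneSetCollection, ValidationError

__all__ = ["RefinementCycle", "RefinementTrace", "build_candidate_pool",
           "refine_signature", "plot_auc_by_size"]


@dataclass
class RefinementCycle:
    cycle_index: int
    input_genes: list[str]
    left_out: list[str]           # candidate left-out gene per subset
    aucs: list[float]             # AUC of each leave-one-out subset
    winner_genes: list[str]
    max_auc: float


@dataclass
class RefinementTrace:
    cycles: list[RefinementCycle]
    auc_by_size: dict[int, float]           # size -> best AUC observed
    t_by_size: dict[int, float]             # size -> |Welch t| of the winner's pooled scores
    genes_by_size: dict[int, list[str]]
    selected_signature: list[str]
    selected_size: int
    selection_rule_applied: str
    n_splits: int
    train_fraction: float
    seed: int

    def to_dict(self) -> dict:
        return {
            "cycles": [vars(c) for c in self.cycles],
            "auc_by_size": {str(k): float(v) for k, v in self.auc_by_size.items()},
            "t_by_size": {str(k): float(v) for k, v in self.t_by_size.items()},
            "genes_by_size": {str(k): list(v) for k, v in self.genes_by_size.items()},
            "selected_signature": list(self.selected_signature),
            "selected_size": int(self.selected_size),
            "selection_rule_applied": self.selection_rule_applied,
            "n_splits": int(self.n_splits),
            "train_fraction": float(self.train_fraction),
            "seed": int(self.seed),
        }


def build_candidate_pool(
    enriched_sets: pd.DataFrame,
    collection: GeneSetCollection,
    alpha: float = 0.05,
    p_column: str = "p_adj",
) -> list[str]:
    """Union of member genes of all sets with adjusted p below ``alpha``,
    deduplicated and lexicographically ordered.

    ``enriched_sets`` must carry a ``set`` column and the adjusted-p column
    (default ``p_adj``; pass e.g. ``"fdr"`` for ROC FDRs)."""
    if "set" not in enriched_sets.columns or p_column not in enriched_sets.columns:
        raise ValidationError(f"enriched_sets needs columns 'set' and {p_column!r}")
    qualifying = enriched_sets.loc[enriched_sets[p_column] < alpha, "set"].tolist()
    if not qualifying:
        raise ValidationError(f"no set with {p_column} < {alpha}")
    pool: set[str] = set()
    for name in qualifying:
        pool.update(collection[name].members)
    if not pool:
        raise ValidationError("candidate pool is empty")
    return sorted(pool)


def _auc_rows(scores: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Row-wise mid-rank AUC; exact Mann-Whitney with half-credit ties."""
    n1 = int(labels.sum())
    n2 = int((~labels).sum())
    ranks = scipy.stats.rankdata(scores, axis=1)
    u2 = np.round(2.0 * ranks[:, labels].sum(axis=1)).astype(np.int64) - n1 * (n1 + 1)
    return u2 / (2.0 * n1 * n2)


def _welch_t_abs(scores: np.ndarray, labels: np.ndarray) -> float:
    pos, neg = scores[labels], scores[~labels]
    if len(pos) < 2 or len(neg) < 2:
        return 0.0
    with np.errstate(invalid="ignore", divide="ignore"):
        t = scipy.stats.ttest_ind(pos, neg, equal_var=False).statistic
    return float(abs(t)) if np.isfinite(t) else 0.0


def _welch_t_rows(scores: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Row-wise |Welch t| of pooled scores by class."""
    pos, neg = scores[:, labels], scores[:, ~labels]
    n1, n2 = pos.shape[1], neg.shape[1]
    if n1 < 2 or n2 < 2:
        return np.zeros(scores.shape[0])
    se2 = pos.var(axis=1, ddof=1) / n1 + neg.var(axis=1, ddof=1) / n2
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.abs(pos.mean(axis=1) - neg.mean(axis=1)) / np.sqrt(se2)
    return np.nan_to_num(t, nan=0.0, posinf=0.0, neginf=0.0)


def _cycle_loo_aucs(X: np.ndarray, y: np.ndarray,
                    splits: list[tuple[np.ndarray, np.ndarray]]
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """AUC of every leave-one-gene-out subset of the rows of ``X`` under the
    shared ``splits``, pooling held-out nearest-centroid scores.

    Removing gene i from the euclidean distance only removes its squared term
    from the per-sample sums, so all n subsets are scored in one pass.
    Returns (aucs, pooled score matrix, pooled labels).
    """
    score_blocks: list[np.ndarray] = []
    label_blocks: list[np.ndarray] = []
    for train, test in splits:
        ytr = y[train]
        c_pos = X[:, train[ytr]].mean(axis=1)
        c_neg = X[:, train[~ytr]].mean(axis=1)
        a = (X[:, test] - c_neg[:, None]) ** 2   # g x t, negative-centroid terms
        b = (X[:, test] - c_pos[:, None]) ** 2
        sa = a.sum(axis=0)
        sb = b.sum(axis=0)
        d_neg = np.sqrt(np.maximum(sa[None, :] - a, 0.0))
        d_pos = np.sqrt(np.maximum(sb[None, :] - b, 0.0))
        score_blocks.append(d_neg - d_pos)
        label_blocks.append(y[test])
    scores = np.concatenate(score_blocks, axis=1)
    labels = np.concatenate(label_blocks)
    return _auc_rows(scores, labels), scores, labels


def _select_winner(aucs: np.ndarray, genes: Sequence[str],
                   gene_t: dict[str, float], auc_tol: float) -> int:
    """Index of the leave-one-out subset retained by a cycle.

    Subsets within ``auc_tol`` of the best AUC are treated as tied (the
    pooled AUC is a Monte-Carlo estimate; differences below its resolution
    are split noise).  Ties are broken by dropping the gene with the weakest
    univariate class separation — feature selection and centroid
    classification are sequential in this framework — and residual ties drop
    the lexicographically largest left-out gene.
    """
    aucs = np.asarray(aucs, dtype=float)
    best = aucs.max()
    tied = [i for i, a in enumerate(aucs) if a >= best - auc_tol]
    if len(tied) > 1:
        tg = np.array([gene_t[genes[i]] for i in tied])
        min_t = tg.min()
        tied = [tied[i] for i in range(len(tied)) if tg[i] == min_t]
    return max(tied, key=lambda i: genes[i])


def _subset_pooled_scores(X: np.ndarray, y: np.ndarray,
                          splits: list[tuple[np.ndarray, np.ndarray]]
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Pooled held-out nearest-centroid scores of one gene subset."""
    score_blocks, label_blocks = [], []
    for train, test in splits:
        ytr = y[train]
        c_pos = X[:, train[ytr]].mean(axis=1)
        c_neg = X[:, train[~ytr]].mean(axis=1)
        d_pos = np.sqrt(((X[:, test] - c_pos[:, None]) ** 2).sum(axis=0))
        d_neg = np.sqrt(((X[:, test] - c_neg[:, None]) ** 2).sum(axis=0))
        score_blocks.append(d_neg - d_pos)
        label_blocks.append(y[test])
    return np.concatenate(score_blocks), np.concatenate(label_blocks)


def refine_signature(
    pool: Sequence[str],
    cohort: BulkCohort,
    n_splits: int = 200,
    train_fraction: float = 2.0 / 3.0,
    stop_size: int = 3,
    seed: int = 0,
    selection: str = "max_auc_max_t",
    auc_tol: float = 0.005,
) -> RefinementTrace:
    """Greedy leave-one-out elimination from ``pool`` down to ``stop_size``.

    AUC ties between subsets within a cycle are broken toward the subset
    whose left-out gene is lexicographically largest.

    ``selection`` picks the final size among all cycles:

    * ``max_auc_max_t`` (default): sizes attaining the global maximum AUC,
      ranked by the |Welch t| of their pooled scores (the statistic behind
      the ROC p-value, which ranks classifiers of equal AUC by reliability);
      remaining ties go to the smallest size.  On cohorts where the pooled
      AUC saturates at 1 over many sizes this picks the most reliably
      separated panel rather than an arbitrarily truncated one.
    * ``smallest_max`` / ``largest_max``: smallest / largest size attaining
      the global maximum AUC.
    """
    pool = sorted(dict.fromkeys(pool))
    if len(pool) <= stop_size:
        raise ValidationError(f"pool size ({len(pool)}) must exceed stop_size ({stop_size})")
    if stop_size < 1:
        raise ValidationError("stop_size must be >= 1")
    if selection not in ("max_auc_max_t", "smallest_max", "largest_max"):
        raise ValidationError(f"unknown selection rule {selection!r}")
    missing = [g for g in pool if g not in set(cohort.matrix.gene_ids)]
    if missing:
        raise ValidationError(f"pool genes not in cohort: {missing[:10]}")

    y = cohort.y
    rng = np.random.default_rng(seed)
    pool_idx = cohort.matrix.gene_index(pool)
    gene_t = dict(zip(pool, _welch_t_rows(cohort.matrix.values[pool_idx, :], y)))

    # AUC of the full pool, with its own split draw, anchors auc_by_size
    full_splits = draw_stratified_splits(y, n_splits, train_fraction, rng)
    full_res = multiple_random_validation(
        cohort, pool, train_fraction=train_fraction, seed=seed, splits=full_splits
    )
    auc_by_size: dict[int, float] = {len(pool): full_res.auc}
    t_by_size: dict[int, float] = {
        len(pool): _welch_t_abs(full_res.pooled_scores, full_res.pooled_labels)
    }
    genes_by_size: dict[int, list[str]] = {len(pool): list(pool)}

    current = list(pool)
    cycles: list[RefinementCycle] = []
    cycle_index = 0
    while len(current) > stop_size:
        cycle_index += 1
        splits = draw_stratified_splits(y, n_splits, train_fraction, rng)
        gidx = cohort.matrix.gene_index(current)
        aucs, scores, labels = _cycle_loo_aucs(cohort.matrix.values[gidx, :], y, splits)
        best = float(aucs.max())
        win_i = _select_winner(aucs, current, gene_t, auc_tol)
        winner = [g for i, g in enumerate(current) if i != win_i]
        cycles.append(RefinementCycle(
            cycle_index=cycle_index,
            input_genes=list(current),
            left_out=list(current),
            aucs=[float(a) for a in aucs],
            winner_genes=list(winner),
            max_auc=best,
        ))
        auc_by_size[len(winner)] = best
        t_by_size[len(winner)] = _welch_t_abs(scores[win_i], labels)
        genes_by_size[len(winner)] = list(winner)
        current = winner

    global_max = max(auc_by_size.values())
    attaining = [s for s, a in auc_by_size.items() if a == global_max]
    if selection == "smallest_max":
        selected_size = min(attaining)
    elif selection == "largest_max":
        selected_size = max(attaining)
    else:
        # selection pass: re-score every per-size winner on one shared split
        # sequence, so size comparisons reflect gene content, not the fresh
        # split noise of each cycle; among sizes whose re-scored AUC is
        # within auc_tol of the best, pick the largest |Welch t| (the ROC
        # p-value statistic, which ranks classifiers of equal AUC), ties
        # toward the smallest size.
        sel_splits = draw_stratified_splits(y, n_splits, train_fraction, rng)
        sel_auc: dict[int, float] = {}
        sel_t: dict[int, float] = {}
        for size, genes in genes_by_size.items():
            gidx = cohort.matrix.gene_index(genes)
            sc, lb = _subset_pooled_scores(cohort.matrix.values[gidx, :], y, sel_splits)
            sel_auc[size] = float(_auc_rows(sc[None, :], lb)[0])
            sel_t[size] = _welch_t_abs(sc, lb)
        best_auc = max(sel_auc.values())
        candidates = [s for s, a in sel_auc.items() if a >= best_auc - auc_tol]
        selected_size = max(candidates, key=lambda s: (sel_t[s], -s))
        t_by_size = sel_t
    return RefinementTrace(
        cycles=cycles,
        auc_by_size=auc_by_size,
        t_by_size=t_by_size,
        genes_by_size=genes_by_size,
        selected_signature=list(genes_by_size[selected_size]),
        selected_size=selected_size,
        selection_rule_applied=selection,
        n_splits=n_splits,
        train_fraction=train_fraction,
        seed=seed,
    )


def plot_auc_by_size(trace: RefinementTrace, tsv_path: str | Path,
                     fig_path: str | Path | None = None) -> pd.DataFrame:
    """Write the size -> best-AUC table (selected size marked); optionally
    render a bar figure when matplotlib is available."""
    sizes = sorted(trace.auc_by_size)
    df = pd.DataFrame({
        "size": sizes,
        "best_auc": [trace.auc_by_size[s] for s in sizes],
        "selected": [int(s == trace.selected_size) for s in sizes],
    })
    df.to_csv(tsv_path, sep="\t", index=False)
    if fig_path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        fig, ax = plt.subplots(figsize=(8, 3))
        ax.bar(df["size"], df["best_auc"], color=np.where(df["selected"] == 1, "C3", "C0"))
        ax.axvline(trace.selected_size, ls="--", c="k", lw=0.8)
        ax.set_xlabel("panel size")
        ax.set_ylabel("best AUC")
        fig.tight_layout()
        fig.savefig(fig_path, dpi=120)
        plt.close(fig)
    return df
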