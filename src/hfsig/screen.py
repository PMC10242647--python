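"""Cell-type screening: which cell types' differential-expression programs
predict the bulk phenotype.

Per cell type and cohort: the top up-regulated genes by |log_fc| are
submitted to over-representation analysis; every enriched set is evaluated as
a nearest-centroid classifier on the cohort; the per-set ROC p-values are BH
adjusted within the (cell type, cohort) set list; the cell type passes the
cohort when at least half of its enriched sets reach FDR < alpha.  The final
screened cell types are the intersection of the per-cohort passing lists.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .classval import evaluate_gene_set
from .diffexpr import top_n_by_abs_logfc
from .genesets import enrich_overrepresentation
from .iolib import BulkCohort, GeneSetCollection, ValidationError
from .stats import bh_adjust

__all__ = ["ScreenParams", "ScreenReport", "half_rule", "screen_cell_types",
           "compare_collections"]


@dataclass(frozen=True)
class ScreenParams:
    top_n: int = 500          # genes submitted to enrichment
    q_max: float = 0.05       # enrichment FDR cutoff
    top_k: int | None = 10    # enrichment truncation (None disables)
    alpha: float = 0.05       # ROC FDR cutoff in the >= half rule
    n_splits: int = 200
    train_fraction: float = 2.0 / 3.0
    seed: int = 0


@dataclass
class ScreenCell:
    """Screening outcome for one (cell type, cohort) pair."""

    cell_type: str
    cohort: str
    sets: list[str]
    auc: list[float]
    roc_p: list[float]
    fdr: list[float]
    n_enriched: int
    n_significant: int
    passed: bool
    reason: str = ""


@dataclass
class ScreenReport:
    cells: list[ScreenCell]
    passing: dict[str, list[str]]          # cohort -> passing cell types
    intersection: list[str]
    params: ScreenParams = field(default_factory=ScreenParams)

    def cell(self, cell_type: str, cohort: str) -> ScreenCell:
        for c in self.cells:
            if c.cell_type == cell_type and c.cohort == cohort:
                return c
        raise KeyError((cell_type, cohort))

    def to_dict(self) -> dict:
        return {
            "cells": [vars(c) for c in self.cells],
            "passing": {k: list(v) for k, v in self.passing.items()},
            "intersection": list(self.intersection),
            "params": vars(self.params),
        }


def half_rule(n_significant: int, n_enriched: int) -> bool:
    """The screening decision: at least half of the enriched sets reach the
    ROC-FDR cutoff (1 of 2 passes; 2 of 5 fails); no enriched sets fails."""
    return n_enriched > 0 and n_significant / n_enriched >= 0.5


def _set_seed(master: int, *parts: str) -> int:
    """Deterministic, order-independent per-evaluation seed."""
    return (int(master) + zlib.crc32("|".join(parts).encode())) % (2 ** 31)


def screen_cell_types(
    de_lists: Mapping[str, pd.DataFrame],
    collection: GeneSetCollection,
    cohorts: Mapping[str, BulkCohort],
    params: ScreenParams = ScreenParams(),
    universe: Sequence[str] | None = None,
) -> ScreenReport:
    """Apply the >= half FDR < alpha screening rule to every cell type on
    every cohort and intersect the per-cohort passing lists.

    ``de_lists`` maps cell type to an up-regulated DE table (gene, log_fc,
    ...).  ``universe`` defaults to the union of collection genes and each
    query.  A cell type with no enriched sets fails with reason recorded
    (not an exception).
    """
    if not de_lists:
        raise ValidationError("no DE lists supplied")
    if not cohorts:
        raise ValidationError("no cohorts supplied")
    cells: list[ScreenCell] = []
    passing: dict[str, list[str]] = {name: [] for name in cohorts}

    for cell_type in sorted(de_lists):
        de = de_lists[cell_type]
        if len(de) == 0:
            for cohort_name in cohorts:
                cells.append(ScreenCell(cell_type, cohort_name, [], [], [], [],
                                        0, 0, False, "empty DE list"))
            continue
        query = top_n_by_abs_logfc(de, params.top_n)
        uni = list(universe) if universe is not None else \
            sorted(collection.all_genes() | set(query))
        enriched = enrich_overrepresentation(
            query, collection, uni, q_max=params.q_max, top_k=params.top_k
        )
        set_names = sorted(enriched["set"].tolist())
        for cohort_name, cohort in cohorts.items():
            if not set_names:
                cells.append(ScreenCell(cell_type, cohort_name, [], [], [], [],
                                        0, 0, False, "no enriched sets"))
                continue
            aucs, ps = [], []
            for sname in set_names:
                res = evaluate_gene_set(
                    cohort, collection[sname].members,
                    n_splits=params.n_splits, train_fraction=params.train_fraction,
                    seed=_set_seed(params.seed, cell_type, sname, cohort_name),
                )
                aucs.append(res.auc)
                ps.append(res.roc_p)
            fdr = bh_adjust(np.array(ps))
            n_sig = int(np.sum(fdr < params.alpha))
            ok = half_rule(n_sig, len(set_names))
            cells.append(ScreenCell(cell_type, cohort_name, set_names, aucs,
                                    [float(v) for v in ps], [float(v) for v in fdr],
                                    len(set_names), n_sig, ok))
            if ok:
                passing[cohort_name].append(cell_type)

    inter = sorted(set.intersection(*(set(v) for v in passing.values())))
    return ScreenReport(cells=cells, passing=passing, intersection=inter, params=params)


def compare_collections(
    de_lists: Mapping[str, pd.DataFrame],
    collections: Mapping[str, GeneSetCollection],
    cohort: BulkCohort,
    params: ScreenParams = ScreenParams(),
    universe: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Descriptive per-category summary (median and IQR of enriched-set AUCs)
    across all supplied DE lists on one cohort.  No decision is attached."""
    if len(collections) < 2:
        raise ValidationError("compare_collections needs >= 2 categories")
    rows = []
    for cat in sorted(collections):
        coll = collections[cat]
        aucs: list[float] = []
        for cell_type in sorted(de_lists):
            de = de_lists[cell_type]
            if len(de) == 0:
                continue
            query = top_n_by_abs_logfc(de, params.top_n)
            uni = list(universe) if universe is not None else \
                sorted(coll.all_genes() | set(query))
            enriched = enrich_overrepresentation(
                query, coll, uni, q_max=params.q_max, top_k=params.top_k
            )
            for sname in sorted(enriched["set"].tolist()):
                res = evaluate_gene_set(
                    cohort, coll[sname].members,
                    n_splits=params.n_splits, train_fraction=params.train_fraction,
                    seed=_set_seed(params.seed, cell_type, sname, cat),
                )
                aucs.append(res.auc)
        if aucs:
            arr = np.array(aucs)
            rows.append({"category": cat, "n_sets": len(aucs),
                         "median_auc": float(np.median(arr)),
                         "iqr_low": float(np.percentile(arr, 25)),
                         "iqr_high": float(np.percentile(arr, 75))})
        else:
            rows.append({"category": cat, "n_sets": 0, "median_auc": np.nan,
                         "iqr_low": np.nan, "iqr_high": np.nan})
    return pd.DataFrame(rows)
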