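"""Normalization, two-group differential expression, and cluster marker
detection.

The DE engine is a two-sided Wilcoxon rank-sum test on log-normalized values
with expression-fraction (``min_pct``) and log-fold-change gates applied
before testing, and BH adjustment over the tested genes only.  Results are
ordered by |log_fc| descending (ties broken lexicographically by gene id),
which is the ordering consumed by enrichment submission.

``log_fc`` is the natural-log fold change of de-logged means:
``ln(mean(expm1(x1)) + 1) - ln(mean(expm1(x2)) + 1)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .iolib import ExpressionMatrix, ValidationError
from .stats import bh_adjust, rank_sum_p_many

__all__ = ["DEParams", "lognormalize", "de_two_group", "find_cluster_markers",
           "top_n_by_abs_logfc"]

SCALE_FACTOR = 10_000.0

DE_COLUMNS = ["gene", "log_fc", "pct_1", "pct_2", "p", "p_adj"]


@dataclass(frozen=True)
class DEParams:
    min_pct: float = 0.1
    logfc_threshold: float = 0.25
    alpha: float = 0.05
    direction: str = "both"

    def __post_init__(self) -> None:
        if not (0.0 <= self.min_pct <= 1.0):
            raise ValidationError(f"min_pct must be in [0,1], got {self.min_pct}")
        if self.logfc_threshold < 0:
            raise ValidationError("logfc_threshold must be >= 0")
        if not (0.0 < self.alpha <= 1.0):
            raise ValidationError(f"alpha must be in (0,1], got {self.alpha}")
        if self.direction not in ("up", "down", "both"):
            raise ValidationError(f"direction must be up/down/both, got {self.direction!r}")


def lognormalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Library-size normalize to a fixed scale factor and log-transform:
    value v in column c maps to ``ln(1 + 10000 * v / colsum(c))``."""
    if m.layer != "counts":
        raise ValidationError(f"lognormalize expects a counts layer, got {m.layer!r}")
    colsums = m.values.sum(axis=0)
    zero = np.where(colsums <= 0)[0]
    if len(zero):
        names = [m.column_ids[i] for i in zero[:10]]
        raise ValidationError(f"zero-total columns cannot be normalized: {names}")
    values = np.log1p(SCALE_FACTOR * m.values / colsums[None, :])
    return ExpressionMatrix(list(m.gene_ids), list(m.column_ids), values, layer="lognorm")


def _log_fc(x1: np.ndarray, x2: np.ndarray) -> np.ndarray:
    return np.log(np.expm1(x1).mean(axis=1) + 1.0) - np.log(np.expm1(x2).mean(axis=1) + 1.0)


def de_two_group(
    m: ExpressionMatrix,
    group1: Sequence[str],
    group2: Sequence[str],
    params: DEParams = DEParams(),
) -> pd.DataFrame:
    """Differential expression of group1 vs group2 (positive log_fc = higher
    in group1).  Returns a DataFrame with columns
    gene, log_fc, pct_1, pct_2, p, p_adj, sorted by |log_fc| descending."""
    if len(group1) == 0 or len(group2) == 0:
        raise ValidationError("both groups must be non-empty")
    if m.layer != "lognorm":
        raise ValidationError(f"de_two_group expects a lognorm layer, got {m.layer!r}")
    i1 = m.column_index(group1)
    i2 = m.column_index(group2)
    x1 = m.values[:, i1]
    x2 = m.values[:, i2]

    pct_1 = (x1 > 0).mean(axis=1)
    pct_2 = (x2 > 0).mean(axis=1)
    log_fc = _log_fc(x1, x2)

    gate = np.maximum(pct_1, pct_2) >= params.min_pct
    if params.direction == "up":
        gate &= log_fc >= params.logfc_threshold
    elif params.direction == "down":
        gate &= log_fc <= -params.logfc_threshold
    else:
        gate &= np.abs(log_fc) >= params.logfc_threshold

    idx = np.where(gate)[0]
    p = rank_sum_p_many(x1[idx], x2[idx]) if len(idx) else np.zeros(0)
    p_adj = bh_adjust(p)

    df = pd.DataFrame({
        "gene": [m.gene_ids[i] for i in idx],
        "log_fc": log_fc[idx],
        "pct_1": pct_1[idx],
        "pct_2": pct_2[idx],
        "p": p,
        "p_adj": p_adj,
    })
    df = df.sort_values(
        by=["log_fc", "gene"], key=lambda s: -s.abs() if s.name == "log_fc" else s
    ).reset_index(drop=True)
    return df[DE_COLUMNS]


def find_cluster_markers(
    m: ExpressionMatrix,
    clusters: pd.Series | Mapping[str, str],
    params: DEParams = DEParams(min_pct=0.1, logfc_threshold=0.25, alpha=0.05, direction="up"),
) -> dict[str, pd.DataFrame]:
    """One-vs-rest up-regulated marker detection for every cluster.

    ``clusters`` maps column ids to cluster labels.  Only genes with
    ``p_adj < alpha`` are retained.  Singleton clusters are skipped with a
    warning and reported as an empty marker table.
    """
    clusters = pd.Series(clusters)
    clusters = clusters.loc[[c for c in m.column_ids if c in clusters.index]]
    if len(clusters) != m.n_columns:
        missing = sorted(set(m.column_ids) - set(clusters.index))
        raise ValidationError(f"columns without cluster label: {missing[:10]}")
    labels = sorted(clusters.unique())
    if len(labels) < 2:
        raise ValidationError("find_cluster_markers requires >= 2 clusters")
    if params.direction != "up":
        params = DEParams(params.min_pct, params.logfc_threshold, params.alpha, "up")
    out: dict[str, pd.DataFrame] = {}
    for label in labels:
        in_cluster = clusters.index[clusters == label].tolist()
        rest = clusters.index[clusters != label].tolist()
        if len(in_cluster) < 2:
            warnings.warn(f"cluster {label!r} has fewer than 2 cells; skipped")
            out[label] = pd.DataFrame(columns=DE_COLUMNS)
            continue
        de = de_two_group(m, in_cluster, rest, params)
        out[label] = de[de["p_adj"] < params.alpha].reset_index(drop=True)
    return out


def top_n_by_abs_logfc(de: pd.DataFrame, n: int) -> list[str]:
    """First ``min(n, len)`` genes by |log_fc| descending; ties broken
    lexicographically by gene id.  All genes are returned when fewer than
    ``n`` are present."""
    if n <= 0:
        raise ValidationError("n must be > 0")
    ordered = de.sort_values(
        by=["log_fc", "gene"], key=lambda s: -s.abs() if s.name == "log_fc" else s
    )
    return ordered["gene"].head(n).tolist()
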