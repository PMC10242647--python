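"""Nearest-centroid classification under multiple random validation.

The continuous prediction score of a sample is
``d(x, negative centroid) - d(x, positive centroid)``: positive scores mean
the sample sits closer to the positive-class centroid.  Repeated stratified
random train/test splits are drawn, held-out scores are pooled across splits,
and a single ROC/AUC is computed on the pooled scores.  AUC is computed via
mid-ranks and therefore equals the Mann-Whitney pairwise-count statistic with
half credit for ties, exactly.  The ROC p-value is a two-sided Welch t-test
on the pooled scores by true class; sensitivity/specificity are reported at
the maximum-Youden threshold with Wilson 95% intervals, and the AUC carries a
Hanley-McNeil binomial 95% interval.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.metrics import roc_curve

from .iolib import BulkCohort, ValidationError

__all__ = [
    "CentroidModel",
    "ValidationResult",
    "fit_centroid",
    "predict_score",
    "predict_scores",
    "auc_mann_whitney",
    "multiple_random_validation",
    "evaluate_gene_set",
    "wilson_ci",
    "draw_stratified_splits",
]

DEFAULT_N_SPLITS = 200
DEFAULT_TRAIN_FRACTION = 2.0 / 3.0


@dataclass
class CentroidModel:
    features: list[str]
    centroid_positive: np.ndarray
    centroid_negative: np.ndarray
    distance: str = "euclidean"

    def __post_init__(self) -> None:
        if self.distance not in ("euclidean", "correlation"):
            raise ValidationError(f"unknown distance {self.distance!r}")
        k = len(self.features)
        if self.centroid_positive.shape != (k,) or self.centroid_negative.shape != (k,):
            raise ValidationError("centroid length must equal feature count")


@dataclass
class ValidationResult:
    """Pooled multiple-random-validation outcome for one feature set."""

    sample_ids: list[str]
    mean_score: np.ndarray          # per-sample mean held-out score
    holdout_count: np.ndarray       # splits each sample was held out in
    pooled_scores: np.ndarray       # all held-out scores, split-major order
    pooled_labels: np.ndarray       # boolean, True = positive class
    roc_points: np.ndarray          # (n, 2) array of (FPR, TPR)
    auc: float
    auc_ci: tuple[float, float]
    roc_p: float
    threshold: float
    sens: float
    sens_ci: tuple[float, float]
    spec: float
    spec_ci: tuple[float, float]
    n_splits: int
    train_fraction: float
    seed: int
    features: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "sample_ids": list(self.sample_ids),
            "mean_score": [float(v) for v in self.mean_score],
            "holdout_count": [int(v) for v in self.holdout_count],
            "auc": float(self.auc),
            "auc_ci": [float(v) for v in self.auc_ci],
            "roc_p": float(self.roc_p),
            "threshold": float(self.threshold),
            "sens": float(self.sens),
            "sens_ci": [float(v) for v in self.sens_ci],
            "spec": float(self.spec),
            "spec_ci": [float(v) for v in self.spec_ci],
            "n_splits": int(self.n_splits),
            "train_fraction": float(self.train_fraction),
            "seed": int(self.seed),
            "features": list(self.features),
            "roc_points": [[float(a), float(b)] for a, b in self.roc_points],
        }


def wilson_ci(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Closed-form Wilson score interval for a binomial proportion."""
    if n <= 0:
        raise ValidationError("wilson_ci requires n > 0")
    if not (0 <= k <= n):
        raise ValidationError(f"k must be in [0, n], got k={k}, n={n}")
    z = scipy.stats.norm.ppf(0.5 + level / 2.0)
    phat = k / n
    denom = 1.0 + z * z / n
    center = (phat + z * z / (2.0 * n)) / denom
    half = (z / denom) * math.sqrt(phat * (1.0 - phat) / n + z * z / (4.0 * n * n))
    lo = 0.0 if k == 0 else max(0.0, center - half)   # closed-form boundaries
    hi = 1.0 if k == n else min(1.0, center + half)
    return (lo, hi)


def fit_centroid(cohort: BulkCohort, features: Sequence[str],
                 distance: str = "euclidean",
                 train_columns: Sequence[str] | None = None) -> CentroidModel:
    """Per-class per-gene mean expression over (a subset of) the cohort."""
    features = list(features)
    gidx = cohort.matrix.gene_index(features)
    if train_columns is None:
        cidx = np.arange(cohort.matrix.n_columns)
    else:
        cidx = cohort.matrix.column_index(train_columns)
    y = cohort.y[cidx]
    if not y.any() or y.all():
        raise ValidationError("training set must contain both classes")
    X = cohort.matrix.values[np.ix_(gidx, cidx)]
    return CentroidModel(
        features=features,
        centroid_positive=X[:, y].mean(axis=1),
        centroid_negative=X[:, ~y].mean(axis=1),
        distance=distance,
    )


def _distances(model: CentroidModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    if model.distance == "euclidean":
        d_pos = np.sqrt(((X - model.centroid_positive[:, None]) ** 2).sum(axis=0))
        d_neg = np.sqrt(((X - model.centroid_negative[:, None]) ** 2).sum(axis=0))
    else:  # correlation distance: 1 - Pearson r
        def corr_dist(c):
            xc = X - X.mean(axis=0, keepdims=True)
            cc = c - c.mean()
            denom = np.sqrt((xc ** 2).sum(axis=0)) * np.sqrt((cc ** 2).sum())
            denom = np.where(denom == 0, np.nan, denom)
            r = (xc * cc[:, None]).sum(axis=0) / denom
            return 1.0 - np.nan_to_num(r, nan=0.0)
        d_pos = corr_dist(model.centroid_positive)
        d_neg = corr_dist(model.centroid_negative)
    return d_pos, d_neg


def predict_score(model: CentroidModel, x: np.ndarray) -> float:
    """Continuous prediction score of one sample vector (aligned to
    ``model.features``): d(x, negative centroid) - d(x, positive centroid)."""
    x = np.asarray(x, dtype=float)
    if x.shape != (len(model.features),):
        raise ValidationError("sample vector length must equal feature count")
    if not np.all(np.isfinite(x)):
        raise ValidationError("sample vector contains non-finite values")
    d_pos, d_neg = _distances(model, x[:, None])
    return float(d_neg[0] - d_pos[0])


def predict_scores(model: CentroidModel, cohort: BulkCohort,
                   columns: Sequence[str]) -> np.ndarray:
    gidx = cohort.matrix.gene_index(model.features)
    cidx = cohort.matrix.column_index(columns)
    X = cohort.matrix.values[np.ix_(gidx, cidx)]
    if not np.all(np.isfinite(X)):
        raise ValidationError("non-finite values in prediction input")
    d_pos, d_neg = _distances(model, X)
    return d_neg - d_pos


def auc_mann_whitney(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC of ``scores`` against boolean ``labels`` via mid-ranks.

    Computed as (2*U)/(2*n1*n2) with an integer-valued numerator, so the
    result is bit-identical to the pairwise count with half-credit ties.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n1 = int(labels.sum())
    n2 = int((~labels).sum())
    if n1 == 0 or n2 == 0:
        raise ValidationError("AUC requires both classes present")
    ranks = scipy.stats.rankdata(scores)
    u2 = np.round(2.0 * ranks[labels].sum()).astype(np.int64) - n1 * (n1 + 1)
    return float(u2 / (2 * n1 * n2))


def _hanley_mcneil_ci(auc: float, n1: int, n2: int, level: float = 0.95) -> tuple[float, float]:
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc * auc / (1.0 + auc)
    var = (auc * (1 - auc) + (n1 - 1) * (q1 - auc * auc) + (n2 - 1) * (q2 - auc * auc))
    var = max(var / (n1 * n2), 0.0)
    z = scipy.stats.norm.ppf(0.5 + level / 2.0)
    se = math.sqrt(var)
    return (max(0.0, auc - z * se), min(1.0, auc + z * se))


def _welch_p(pos: np.ndarray, neg: np.ndarray) -> float:
    if len(pos) < 2 or len(neg) < 2:
        return 1.0
    if np.std(pos) == 0 and np.std(neg) == 0:
        return 1.0 if pos.mean() == neg.mean() else 0.0
    with np.errstate(invalid="ignore", divide="ignore"):
        res = scipy.stats.ttest_ind(pos, neg, equal_var=False)
    p = float(res.pvalue)
    return p if np.isfinite(p) else 1.0


def draw_stratified_splits(y: np.ndarray, n_splits: int, train_fraction: float,
                           rng: np.random.Generator) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified random train/test partitions preserving class proportions
    within one sample; each class keeps at least one sample on each side."""
    if not (0.0 < train_fraction < 1.0):
        raise ValidationError("train_fraction must be in (0, 1)")
    if n_splits < 1:
        raise ValidationError("n_splits must be >= 1")
    pos_idx = np.where(y)[0]
    neg_idx = np.where(~y)[0]
    if len(pos_idx) < 2 or len(neg_idx) < 2:
        raise ValidationError("each class needs >= 2 samples for splitting")
    splits = []
    for _ in range(n_splits):
        train_parts, test_parts = [], []
        for idx in (pos_idx, neg_idx):
            n_train = int(round(train_fraction * len(idx)))
            n_train = min(max(n_train, 1), len(idx) - 1)
            perm = rng.permutation(idx)
            train_parts.append(perm[:n_train])
            test_parts.append(perm[n_train:])
        splits.append((np.concatenate(train_parts), np.concatenate(test_parts)))
    return splits


def multiple_random_validation(
    cohort: BulkCohort,
    features: Sequence[str],
    n_splits: int = DEFAULT_N_SPLITS,
    train_fraction: float = DEFAULT_TRAIN_FRACTION,
    seed: int = 0,
    distance: str = "euclidean",
    splits: list[tuple[np.ndarray, np.ndarray]] | None = None,
) -> ValidationResult:
    """Nearest-centroid classification under repeated stratified random
    splits; held-out scores are pooled into one ROC.

    ``splits`` may be supplied explicitly (index pairs into the cohort's
    columns) to share a split sequence across evaluations; otherwise they are
    drawn from a generator seeded with ``seed``.
    """
    features = list(features)
    if not features:
        raise ValidationError("feature list is empty")
    gidx = cohort.matrix.gene_index(features)
    y = cohort.y
    if splits is None:
        rng = np.random.default_rng(seed)
        splits = draw_stratified_splits(y, n_splits, train_fraction, rng)
    n_splits = len(splits)

    X = cohort.matrix.values[gidx, :]
    pooled_scores: list[np.ndarray] = []
    pooled_labels: list[np.ndarray] = []
    sum_score = np.zeros(cohort.matrix.n_columns)
    count = np.zeros(cohort.matrix.n_columns, dtype=int)
    for train, test in splits:
        ytr = y[train]
        if not ytr.any() or ytr.all():
            raise ValidationError("training fold lacks a class")
        c_pos = X[:, train[ytr]].mean(axis=1)
        c_neg = X[:, train[~ytr]].mean(axis=1)
        Xt = X[:, test]
        if distance == "euclidean":
            d_pos = np.sqrt(((Xt - c_pos[:, None]) ** 2).sum(axis=0))
            d_neg = np.sqrt(((Xt - c_neg[:, None]) ** 2).sum(axis=0))
            s = d_neg - d_pos
        else:
            model = CentroidModel(features, c_pos, c_neg, distance)
            d_pos, d_neg = _distances(model, Xt)
            s = d_neg - d_pos
        pooled_scores.append(s)
        pooled_labels.append(y[test])
        sum_score[test] += s
        count[test] += 1

    scores = np.concatenate(pooled_scores)
    labels = np.concatenate(pooled_labels)
    auc = auc_mann_whitney(scores, labels)
    n1 = int(labels.sum())
    n2 = int((~labels).sum())
    auc_ci = _hanley_mcneil_ci(auc, n1, n2)
    roc_p = _welch_p(scores[labels], scores[~labels])

    fpr, tpr, thresholds = roc_curve(labels.astype(int), scores, drop_intermediate=False)
    j = int(np.argmax(tpr - fpr))
    threshold = float(thresholds[j])
    pred_pos = scores >= threshold
    tp = int((pred_pos & labels).sum())
    tn = int((~pred_pos & ~labels).sum())
    sens = tp / n1
    spec = tn / n2

    with np.errstate(invalid="ignore"):
        mean_score = np.where(count > 0, sum_score / np.maximum(count, 1), np.nan)

    return ValidationResult(
        sample_ids=list(cohort.matrix.column_ids),
        mean_score=mean_score,
        holdout_count=count,
        pooled_scores=scores,
        pooled_labels=labels,
        roc_points=np.column_stack([fpr, tpr]),
        auc=auc,
        auc_ci=auc_ci,
        roc_p=roc_p,
        threshold=threshold,
        sens=sens,
        sens_ci=wilson_ci(tp, n1),
        spec=spec,
        spec_ci=wilson_ci(tn, n2),
        n_splits=n_splits,
        train_fraction=train_fraction,
        seed=seed,
        features=features,
    )


def evaluate_gene_set(
    cohort: BulkCohort,
    set_members: Sequence[str],
    n_splits: int = DEFAULT_N_SPLITS,
    train_fraction: float = DEFAULT_TRAIN_FRACTION,
    seed: int = 0,
    distance: str = "euclidean",
) -> ValidationResult:
    """Multiple random validation restricted to the measured members of one
    gene set.  Members missing from the cohort are dropped with a warning."""
    measured = set(cohort.matrix.gene_ids)
    features = [g for g in set_members if g in measured]
    lost = [g for g in set_members if g not in measured]
    if not features:
        raise ValidationError("no gene-set member is measured in the cohort")
    if lost:
        warnings.warn(f"{len(lost)} gene-set members not measured in cohort; dropped")
    return multiple_random_validation(
        cohort, features, n_splits=n_splits, train_fraction=train_fraction,
        seed=seed, distance=distance,
    )
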