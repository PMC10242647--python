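"""Synthetic single-cell and bulk cohorts with planted ground truth.

The generator plants three kinds of structure so every downstream stage has
a known answer:

* per-cluster marker genes (additive shifts on the log2 scale, multiplicative
  on the raw scale),
* a discriminative bulk gene panel shifted by ``panel_effect`` standard
  deviations in the positive class, with the same panel optionally planted as
  a condition response in designated "signal" cell types of the cell cohort,
* gene-set collections mixing sets built on planted genes with random sets.

Reproducibility: one master seed; each component draws from a child stream
derived by a fixed offset, so sub-simulations are independently reproducible
and identical (spec, seed) pairs give bit-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .iolib import (
    BulkCohort,
    CellCohort,
    ExpressionMatrix,
    GeneSet,
    GeneSetCollection,
    ValidationError,
)

__all__ = ["SyntheticSpec", "GroundTruth", "simulate_cell_cohort",
           "simulate_bulk_cohort", "simulate_geneset_collection", "simulate_all"]

# fixed child-stream offsets (never renumber: reproducibility contract)
_STREAMS = {"assign": 0, "cell": 1, "bulk": 2, "sets": 3, "donor": 4}


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic cohorts; validated, hashable, frozen."""

    n_genes: int = 1000
    n_cells_per_cluster: int = 100
    clusters: tuple[tuple[str, str], ...] = (
        ("B", "C1"), ("B", "C2"), ("B", "C3"), ("NK", "C1"), ("Mono", "C1"),
    )
    n_markers_per_cluster: int = 20
    marker_log2_shift: float = 1.0
    n_bulk_samples_per_class: int = 40
    panel_size: int = 13
    panel_effect: float = 2.0
    baseline_model: str = "lognormal"
    lognormal_mu_range: tuple[float, float] = (2.0, 8.0)
    lognormal_sigma_range: tuple[float, float] = (0.3, 1.0)
    nb_mean_range: tuple[float, float] = (0.5, 20.0)
    nb_dispersion: float = 0.5
    n_true_sets: int = 3
    n_null_sets: int = 20
    set_size: int = 25
    true_set_purity: float = 0.8
    signal_cell_types: tuple[str, ...] = ()
    signal_subcluster: str | None = None
    condition_log2_shift: float = 0.0
    n_donors_per_condition: int = 2
    seed: int = 0

    def validate(self) -> "SyntheticSpec":
        for name in ("n_genes", "n_cells_per_cluster", "n_markers_per_cluster",
                     "n_bulk_samples_per_class", "panel_size", "set_size",
                     "n_donors_per_condition"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v <= 0:
                raise ValidationError(f"{name} must be a positive integer, got {v!r}")
        for name in ("n_true_sets", "n_null_sets"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if not self.clusters:
            raise ValidationError("clusters must be non-empty")
        if len(set(self.clusters)) != len(self.clusters):
            raise ValidationError("clusters contains duplicate (cell_type, subcluster) labels")
        if self.panel_size > self.n_genes:
            raise ValidationError(
                f"panel_size ({self.panel_size}) exceeds n_genes ({self.n_genes})"
            )
        if self.n_markers_per_cluster * len(self.clusters) + self.panel_size > self.n_genes:
            raise ValidationError(
                "n_markers_per_cluster x n_clusters + panel_size exceeds n_genes"
            )
        if self.baseline_model not in ("lognormal", "negative_binomial"):
            raise ValidationError(
                f"baseline_model must be lognormal or negative_binomial, got {self.baseline_model!r}"
            )
        if self.set_size > self.n_genes:
            raise ValidationError(f"set_size ({self.set_size}) exceeds n_genes ({self.n_genes})")
        if not (0.0 <= self.true_set_purity <= 1.0):
            raise ValidationError("true_set_purity must be in [0, 1]")
        if self.nb_dispersion <= 0:
            raise ValidationError("nb_dispersion must be > 0")
        return self

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticSpec":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(d) - known)
        if unknown:
            raise ValidationError(f"unknown SyntheticSpec keys: {unknown}")
        d = dict(d)
        if "clusters" in d:
            d["clusters"] = tuple((str(a), str(b)) for a, b in d["clusters"])
        for key in ("lognormal_mu_range", "lognormal_sigma_range", "nb_mean_range",
                    "signal_cell_types"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d).validate()


@dataclass(frozen=True)
class GroundTruth:
    """Planted structure: marker genes per cluster, the discriminative panel,
    and (once a collection has been generated) the names of the true sets."""

    marker_map: dict[str, tuple[str, ...]]
    panel: tuple[str, ...]
    true_sets: tuple[str, ...] = ()

    def all_planted_genes(self) -> set[str]:
        out = set(self.panel)
        for genes in self.marker_map.values():
            out.update(genes)
        return out

    def to_json(self, path: str | Path) -> None:
        payload = {
            "marker_map": {k: list(v) for k, v in self.marker_map.items()},
            "panel": list(self.panel),
            "true_sets": list(self.true_sets),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, sort_keys=True, indent=2)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            marker_map={k: tuple(v) for k, v in d["marker_map"].items()},
            panel=tuple(d["panel"]),
            true_sets=tuple(d["true_sets"]),
        )


def _rng(spec: SyntheticSpec, stream: str, extra: int = 0) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(spec.seed), spawn_key=(_STREAMS[stream], extra))
    )


def gene_ids(spec: SyntheticSpec) -> list[str]:
    return [f"G{i:05d}" for i in range(spec.n_genes)]


def cluster_label(cell_type: str, subcluster: str) -> str:
    return f"{cell_type}_{subcluster}"


def _plant_assignments(spec: SyntheticSpec) -> GroundTruth:
    """Deterministic assignment of marker blocks and the panel (shared by the
    cell and bulk generators so the same ground truth spans both)."""
    rng = _rng(spec, "assign")
    genes = gene_ids(spec)
    perm = rng.permutation(spec.n_genes)
    marker_map: dict[str, tuple[str, ...]] = {}
    pos = 0
    for ct, sc in spec.clusters:
        block = perm[pos:pos + spec.n_markers_per_cluster]
        marker_map[cluster_label(ct, sc)] = tuple(genes[i] for i in block)
        pos += spec.n_markers_per_cluster
    panel = tuple(genes[i] for i in perm[pos:pos + spec.panel_size])
    return GroundTruth(marker_map=marker_map, panel=panel)


def simulate_cell_cohort(spec: SyntheticSpec) -> tuple[CellCohort, GroundTruth]:
    """Raw-count single-cell-like cohort with planted cluster markers.

    Conditions ("disease"/"normal") are assigned at the donor level and cells
    inherit their donor's condition.  If ``signal_cell_types`` is non-empty,
    the panel genes additionally receive ``condition_log2_shift`` in disease
    cells of those cell types (restricted to ``signal_subcluster`` when set).
    """
    spec.validate()
    truth = _plant_assignments(spec)
    rng = _rng(spec, "cell")
    genes = gene_ids(spec)
    gene_pos = {g: i for i, g in enumerate(genes)}

    mu = rng.uniform(*spec.lognormal_mu_range, spec.n_genes)
    sigma = rng.uniform(*spec.lognormal_sigma_range, spec.n_genes)
    nb_mean = rng.uniform(*spec.nb_mean_range, spec.n_genes)

    donors = [f"D_disease_{k}" for k in range(spec.n_donors_per_condition)] + \
             [f"D_normal_{k}" for k in range(spec.n_donors_per_condition)]
    donor_cond = {d: ("disease" if d.startswith("D_disease") else "normal") for d in donors}

    panel_idx = np.array([gene_pos[g] for g in truth.panel], dtype=int)

    cell_ids: list[str] = []
    meta_rows: list[dict] = []
    blocks: list[np.ndarray] = []
    rng_donor = _rng(spec, "donor")
    for ct, sc in spec.clusters:
        label = cluster_label(ct, sc)
        n = spec.n_cells_per_cluster
        cell_donors = [donors[i] for i in rng_donor.integers(0, len(donors), n)]
        conds = np.array([donor_cond[d] for d in cell_donors])
        shift = np.zeros((spec.n_genes, n))
        midx = np.array([gene_pos[g] for g in truth.marker_map[label]], dtype=int)
        shift[midx, :] += spec.marker_log2_shift
        if (spec.condition_log2_shift != 0.0 and ct in spec.signal_cell_types
                and (spec.signal_subcluster is None or sc == spec.signal_subcluster)):
            disease_cols = np.where(conds == "disease")[0]
            shift[np.ix_(panel_idx, disease_cols)] += spec.condition_log2_shift
        if spec.baseline_model == "lognormal":
            noise = rng.standard_normal((spec.n_genes, n)) * sigma[:, None]
            block = np.power(2.0, mu[:, None] + shift + noise)
        else:
            mean = nb_mean[:, None] * np.power(2.0, shift)
            r = 1.0 / spec.nb_dispersion
            p = r / (r + mean)
            block = rng.negative_binomial(r, p).astype(float)
        blocks.append(block)
        for j in range(n):
            cid = f"{label}_{len(cell_ids):05d}"
            cell_ids.append(cid)
            meta_rows.append({
                "id": cid, "cell_type": ct, "subcluster": sc,
                "condition": conds[j], "donor": cell_donors[j],
            })
    values = np.concatenate(blocks, axis=1)
    obs = pd.DataFrame(meta_rows).set_index("id")
    matrix = ExpressionMatrix(genes, cell_ids, values, layer="counts")
    return CellCohort(matrix, obs), truth


def simulate_bulk_cohort(spec: SyntheticSpec, cohort_key: int = 0) -> tuple[BulkCohort, GroundTruth]:
    """Two-class bulk cohort on the log2/array scale (layer ``lognorm``).

    Panel genes are shifted by ``panel_effect`` per-gene standard deviations
    in the positive class.  ``cohort_key`` selects an independent replicate
    cohort under the same ground-truth assignments.
    """
    spec.validate()
    truth = _plant_assignments(spec)
    rng = _rng(spec, "bulk", extra=int(cohort_key))
    genes = gene_ids(spec)
    gene_pos = {g: i for i, g in enumerate(genes)}
    n = spec.n_bulk_samples_per_class

    mu = rng.uniform(*spec.lognormal_mu_range, spec.n_genes)
    sigma = rng.uniform(*spec.lognormal_sigma_range, spec.n_genes)
    values = mu[:, None] + rng.standard_normal((spec.n_genes, 2 * n)) * sigma[:, None]
    panel_idx = np.array([gene_pos[g] for g in truth.panel], dtype=int)
    # first n columns are the positive class
    values[np.ix_(panel_idx, np.arange(n))] += spec.panel_effect * sigma[panel_idx, None]
    values = np.clip(values, 0.0, None)

    sample_ids = [f"S{cohort_key}_pos_{j:03d}" for j in range(n)] + \
                 [f"S{cohort_key}_neg_{j:03d}" for j in range(n)]
    labels = pd.Series(["positive"] * n + ["negative"] * n, index=sample_ids)
    matrix = ExpressionMatrix(genes, sample_ids, values, layer="lognorm")
    return BulkCohort(matrix, labels), truth


def simulate_geneset_collection(spec: SyntheticSpec, truth: GroundTruth,
                                category: str = "GOBP") -> GeneSetCollection:
    """Collection of ``n_true_sets`` sets enriched for planted genes (at least
    ``true_set_purity`` of each set's members are planted) plus ``n_null_sets``
    sets drawn uniformly from non-planted genes."""
    spec.validate()
    rng = _rng(spec, "sets")
    genes = gene_ids(spec)
    planted = sorted(truth.all_planted_genes())
    non_planted = sorted(set(genes) - set(planted))
    if spec.set_size > len(non_planted):
        raise ValidationError(
            f"set_size ({spec.set_size}) exceeds available non-planted genes ({len(non_planted)})"
        )
    coll = GeneSetCollection()
    marker_pool = sorted(set(planted) - set(truth.panel))
    for i in range(spec.n_true_sets):
        n_planted = min(math.ceil(spec.true_set_purity * spec.set_size), len(planted),
                        spec.set_size)
        # panel genes first so planted sets carry the discriminative panel,
        # then cluster markers to fill the planted quota
        n_panel = min(n_planted, len(truth.panel))
        members = list(rng.choice(sorted(truth.panel), size=n_panel, replace=False))
        n_marker = min(n_planted - n_panel, len(marker_pool))
        if n_marker:
            members += list(rng.choice(marker_pool, size=n_marker, replace=False))
        n_fill = spec.set_size - len(members)
        if n_fill:
            members += list(rng.choice(non_planted, size=n_fill, replace=False))
        coll.add(GeneSet(f"TRUE_SET_{i + 1}", category, tuple(sorted(members))))
    for i in range(spec.n_null_sets):
        members = rng.choice(non_planted, size=spec.set_size, replace=False)
        coll.add(GeneSet(f"NULL_SET_{i + 1}", category, tuple(sorted(members))))
    return coll


def simulate_all(spec: SyntheticSpec, n_cohorts: int = 1
                 ) -> tuple[CellCohort, list[BulkCohort], GeneSetCollection, GroundTruth]:
    """Convenience wrapper: cell cohort, bulk cohort replicates, gene sets,
    and the completed ground truth (with true-set names filled in)."""
    cells, truth = simulate_cell_cohort(spec)
    cohorts = [simulate_bulk_cohort(spec, cohort_key=k)[0] for k in range(n_cohorts)]
    coll = simulate_geneset_collection(spec, truth)
    truth = dataclasses.replace(
        truth, true_sets=tuple(n for n in coll.names() if n.startswith("TRUE_SET_"))
    )
    return cells, cohorts, coll, truth
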