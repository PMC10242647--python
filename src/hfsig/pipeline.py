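"""End-to-end orchestration: simulate -> DE -> enrichment -> screening ->
subcluster attribution -> candidate pool -> refinement -> final validation.

Stage outputs are written as files under one run directory so any stage can
be re-run standalone; a manifest records the config, seeds, and a checksum
registry.  The headline AUC of the selected signature is computed on an
independent synthetic cohort never seen by any selection step; the in-sample
(discovery-cohort) AUC is reported too but flagged as in-sample.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import classval, diffexpr, refine, screen, ssscore
from .iolib import (
    BulkCohort,
    GeneSetCollection,
    ValidationError,
    sha256_file,
    write_bulk_cohort,
    write_gmt,
    write_matrix_tsv,
    write_metadata_tsv,
    write_report,
)
from .synthdata import GroundTruth, SyntheticSpec, simulate_all, simulate_bulk_cohort

__all__ = ["PipelineConfig", "validate_config", "run_full_pipeline"]

HELDOUT_COHORT_KEY = 9999


def _default_synthetic() -> SyntheticSpec:
    return SyntheticSpec(
        n_genes=800,
        n_cells_per_cluster=60,
        clusters=(("B", "C1"), ("B", "C2"), ("B", "C3"), ("NK", "C1"), ("Mono", "C1")),
        n_markers_per_cluster=15,
        marker_log2_shift=2.0,
        n_bulk_samples_per_class=30,
        panel_size=13,
        panel_effect=2.0,
        n_true_sets=4,
        n_null_sets=16,
        set_size=20,
        signal_cell_types=("B",),
        signal_subcluster="C2",
        condition_log2_shift=2.0,
        seed=0,
    )


@dataclass(frozen=True)
class PipelineConfig:
    """All stage parameters; defaults follow the documented stage defaults
    (min_pct 0.1, logfc_threshold 0.25, alpha 0.05, top 500 genes, top 10
    sets, stop size 3)."""

    synthetic: SyntheticSpec = field(default_factory=_default_synthetic)
    min_pct: float = 0.1
    logfc_threshold: float = 0.25
    alpha: float = 0.05
    top_n: int = 500
    q_max: float = 0.05
    top_k: int = 10
    n_perm: int = 1000
    n_splits: int = 100
    train_fraction: float = 2.0 / 3.0
    stop_size: int = 3
    n_cohorts: int = 2
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["synthetic"] = self.synthetic.to_dict()
        return d


def validate_config(raw: Mapping | PipelineConfig) -> PipelineConfig:
    """Fill defaults, reject unknown keys, range-check; idempotent."""
    if isinstance(raw, PipelineConfig):
        raw = raw.to_dict()
    raw = dict(raw or {})
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = sorted(set(raw) - known)
    if unknown:
        raise ValidationError(f"unknown config keys: {unknown}")
    if "synthetic" in raw and raw["synthetic"] is not None:
        synth = raw["synthetic"]
        raw["synthetic"] = synth if isinstance(synth, SyntheticSpec) \
            else SyntheticSpec.from_dict(dict(synth))
    cfg = PipelineConfig(**raw)
    if not (0.0 <= cfg.min_pct <= 1.0):
        raise ValidationError(f"min_pct out of range [0,1]: {cfg.min_pct}")
    if cfg.logfc_threshold < 0:
        raise ValidationError("logfc_threshold must be >= 0")
    for name in ("alpha", "q_max"):
        v = getattr(cfg, name)
        if not (0.0 < v <= 1.0):
            raise ValidationError(f"{name} out of range (0,1]: {v}")
    if not (0.0 < cfg.train_fraction < 1.0):
        raise ValidationError(f"train_fraction out of range (0,1): {cfg.train_fraction}")
    for name in ("top_n", "top_k", "n_perm", "n_splits", "stop_size", "n_cohorts"):
        if getattr(cfg, name) < 1:
            raise ValidationError(f"{name} must be >= 1")
    cfg.synthetic.validate()
    return cfg


@dataclass
class RunManifest:
    config: dict
    seed: int
    package_version: str
    stages: list[str]
    outputs: dict[str, str]     # relative path -> sha256

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _write_de_tsv(de: pd.DataFrame, path: Path) -> None:
    de.to_csv(path, sep="\t", index=False)


def run_full_pipeline(config: PipelineConfig | Mapping, out_dir: str | Path) -> RunManifest:
    """Execute every stage on synthetic input and write all artifacts under
    ``out_dir``.  Returns the run manifest (also written as manifest.json)."""
    cfg = validate_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages: list[str] = []
    timings: dict[str, float] = {}
    t_all = time.perf_counter()

    def stage(name):
        stages.append(name)
        timings[name] = time.perf_counter()

    def stage_done(name):
        timings[name] = time.perf_counter() - timings[name]

    spec = dataclasses.replace(cfg.synthetic, seed=cfg.seed)
    de_params = diffexpr.DEParams(cfg.min_pct, cfg.logfc_threshold, cfg.alpha, "up")

    # ---- simulate -------------------------------------------------------
    stage("simulate")
    cells, cohorts, collection, truth = simulate_all(spec, n_cohorts=cfg.n_cohorts)
    write_matrix_tsv(cells.matrix, out / "cell_counts.tsv")
    write_metadata_tsv(cells.obs, out / "cell_metadata.tsv")
    for k, cohort in enumerate(cohorts):
        write_bulk_cohort(cohort, out / f"bulk_{k}.tsv", out / f"bulk_{k}_labels.tsv")
    write_gmt(collection, out / "genesets.gmt")
    truth.to_json(out / "ground_truth.json")
    stage_done("simulate")

    # ---- normalize + per-cell-type DE ----------------------------------
    stage("de")
    lognorm = diffexpr.lognormalize(cells.matrix)
    de_lists: dict[str, pd.DataFrame] = {}
    for cell_type in sorted(cells.obs["cell_type"].unique()):
        mask = cells.obs["cell_type"] == cell_type
        disease = cells.obs.index[mask & (cells.obs["condition"] == "disease")].tolist()
        normal = cells.obs.index[mask & (cells.obs["condition"] == "normal")].tolist()
        if len(disease) == 0 or len(normal) == 0:
            continue
        de = diffexpr.de_two_group(lognorm, disease, normal, de_params)
        de_lists[cell_type] = de
        _write_de_tsv(de, out / f"de_{cell_type}.tsv")
    stage_done("de")

    # ---- screening ------------------------------------------------------
    stage("screen")
    cohort_map = {f"cohort_{k}": c for k, c in enumerate(cohorts)}
    sp = screen.ScreenParams(
        top_n=cfg.top_n, q_max=cfg.q_max, top_k=cfg.top_k, alpha=cfg.alpha,
        n_splits=cfg.n_splits, train_fraction=cfg.train_fraction, seed=cfg.seed,
    )
    report = screen.screen_cell_types(
        de_lists, collection, cohort_map, sp, universe=list(cells.matrix.gene_ids)
    )
    write_report(report.to_dict(), out / "screen_report.json", kind="ScreenReport")
    if report.intersection:
        chosen = report.intersection[0]
        chosen_how = "cross-cohort intersection"
    else:
        # fall back to the cell type with the most significant sets overall
        totals = {ct: sum(c.n_significant for c in report.cells if c.cell_type == ct)
                  for ct in de_lists}
        chosen = max(sorted(totals), key=lambda ct: totals[ct])
        chosen_how = "fallback: most significant sets (empty intersection)"
    stage_done("screen")

    # ---- subcluster markers + GSVA attribution -------------------------
    stage("attribution")
    ct_cells = cells.obs.index[cells.obs["cell_type"] == chosen].tolist()
    sub_matrix = lognorm.subset_columns(ct_cells)
    sub_labels = cells.obs.loc[ct_cells, "subcluster"]
    markers = diffexpr.find_cluster_markers(sub_matrix, sub_labels, de_params)
    for label, mk in markers.items():
        _write_de_tsv(mk, out / f"markers_{chosen}_{label}.tsv")

    first_cohort = "cohort_0"
    cell_rec = report.cell(chosen, first_cohort)
    candidate_sets = list(cell_rec.sets)
    attribution: dict = {"cell_type": chosen, "chosen_how": chosen_how}
    if candidate_sets:
        sub_coll = GeneSetCollection({n: collection[n] for n in candidate_sets})
        gsva = ssscore.gsva_score(sub_matrix, sub_coll)
        gsva.scores.to_csv(out / "gsva_subcluster_scores.tsv", sep="\t")
        med = gsva.scores.T.groupby(sub_labels).median().T  # sets x subclusters
        attributed = med.mean(axis=0).idxmax()
        attribution["attributed_subcluster"] = str(attributed)
        attribution["median_scores"] = {
            str(c): [float(v) for v in med[c]] for c in med.columns}
        disease = cells.obs.loc[ct_cells][cells.obs.loc[ct_cells, "condition"] == "disease"]
        normal = cells.obs.loc[ct_cells][cells.obs.loc[ct_cells, "condition"] == "normal"]
        if len(disease) >= 2 and len(normal) >= 2:
            cmp_df = ssscore.score_group_compare(
                gsva, disease.index.tolist(), normal.index.tolist())
            cmp_df.to_csv(out / "gsva_condition_compare.tsv", sep="\t", index=False)
    write_report(attribution, out / "attribution.json", kind="Attribution")
    stage_done("attribution")

    # ---- candidate pool -------------------------------------------------
    stage("pool")
    roc_df = pd.DataFrame({"set": cell_rec.sets, "p_adj": cell_rec.fdr})
    try:
        pool = refine.build_candidate_pool(roc_df, collection, alpha=cfg.alpha)
    except ValidationError:
        # no set with ROC FDR below alpha: fall back to all enriched sets
        pool = sorted({g for s in candidate_sets for g in collection[s].members})
    pool = [g for g in pool if g in set(cohorts[0].matrix.gene_ids)]
    if len(pool) <= cfg.stop_size:
        raise ValidationError(
            f"stage pool: candidate pool has {len(pool)} genes "
            f"(need > stop_size {cfg.stop_size}); completed stages: {stages[:-1]}"
        )
    with open(out / "candidate_pool.txt", "w") as fh:
        fh.write("\n".join(pool) + "\n")
    stage_done("pool")

    # ---- refinement -----------------------------------------------------
    stage("refine")
    trace = refine.refine_signature(
        pool, cohorts[0], n_splits=cfg.n_splits, train_fraction=cfg.train_fraction,
        stop_size=cfg.stop_size, seed=cfg.seed,
    )
    write_report(trace.to_dict(), out / "refinement_trace.json", kind="RefinementTrace")
    refine.plot_auc_by_size(trace, out / "auc_by_size.tsv")
    with open(out / "signature.txt", "w") as fh:
        fh.write("\n".join(trace.selected_signature) + "\n")
    stage_done("refine")

    # ---- final validation ----------------------------------------------
    stage("validate")
    in_sample = classval.multiple_random_validation(
        cohorts[0], trace.selected_signature, n_splits=cfg.n_splits,
        train_fraction=cfg.train_fraction, seed=cfg.seed + 1,
    )
    heldout_cohort, _ = simulate_bulk_cohort(spec, cohort_key=HELDOUT_COHORT_KEY)
    heldout = classval.multiple_random_validation(
        heldout_cohort, trace.selected_signature, n_splits=cfg.n_splits,
        train_fraction=cfg.train_fraction, seed=cfg.seed + 2,
    )
    write_report(in_sample.to_dict(), out / "validation_in_sample.json",
                 kind="ValidationResult", extra={"note": "in-sample (discovery cohort)"})
    write_report(heldout.to_dict(), out / "validation_heldout.json",
                 kind="ValidationResult", extra={"note": "held-out synthetic cohort"})
    stage_done("validate")

    # ---- concordance with ground truth ---------------------------------
    stage("concordance")
    recovery = {}
    for label, mk in markers.items():
        planted = set(truth.marker_map.get(f"{chosen}_{label}", ()))
        found = set(mk["gene"])
        recovery[label] = {
            "n_planted": len(planted),
            "n_recovered": len(planted & found),
            "n_false": len(found - planted),
        }
    sig = set(trace.selected_signature)
    concordance = {
        "chosen_cell_type": chosen,
        "signal_cell_types": list(spec.signal_cell_types),
        "screen_correct": (not spec.signal_cell_types)
                          or chosen in spec.signal_cell_types,
        "marker_recovery": recovery,
        "panel_size": len(truth.panel),
        "panel_recovered": len(sig & set(truth.panel)),
        "signature_size": len(sig),
        "in_sample_auc": in_sample.auc,
        "heldout_auc": heldout.auc,
    }
    write_report(concordance, out / "concordance.json", kind="Concordance")
    stage_done("concordance")

    # ---- manifest -------------------------------------------------------
    outputs = {p.name: sha256_file(p)
               for p in sorted(out.iterdir()) if p.is_file() and p.name != "manifest.json"}
    manifest = RunManifest(
        config=cfg.to_dict(),
        seed=cfg.seed,
        package_version=_version(),
        stages=stages,
        outputs=outputs,
    )
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest.to_dict(), fh, sort_keys=True, indent=2)
        fh.write("\n")
    timings["total"] = time.perf_counter() - t_all
    with open(out / "run_log.json", "w") as fh:   # timings kept out of the manifest
        json.dump({"stage_timings_s": timings}, fh, indent=2)
        fh.write("\n")
    return manifest


def _version() -> str:
    try:
        from importlib.metadata import version
        return version("hfsig")
    except Exception:
        return "unknown"
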