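# hfsig

Blood transcriptomic gene-signature discovery pipeline: per-cell-type
differential expression → gene-set over-representation / preranked
enrichment → prediction-power screening of cell types → single-sample
gene-set variation scoring → cyclic leave-one-out refinement of a compact
gene panel that maximizes classification AUC under nearest-centroid
multiple random validation.

A synthetic-data generator with planted ground truth (cluster markers, a
discriminative bulk panel, enriched gene sets) stands in for external
cohorts, so every stage can be exercised and evaluated offline.

## Modules

| module | role |
| --- | --- |
| `hfsig.synthdata` | synthetic single-cell / bulk cohorts and gene-set collections with planted structure |
| `hfsig.iolib` | validated containers + TSV/MTX/GMT/metadata/JSON readers & writers |
| `hfsig.diffexpr` | log-normalization, Wilcoxon rank-sum DE with min-pct / log-FC gates, cluster markers |
| `hfsig.genesets` | hypergeometric over-representation, weighted-KS preranked enrichment |
| `hfsig.ssscore` | GSVA-style single-sample scoring (Gaussian/Poisson/ECDF kernel CDFs) |
| `hfsig.classval` | nearest-centroid classifier, multiple random validation, ROC/AUC, Wilson CIs |
| `hfsig.screen` | the ≥-half ROC-FDR cell-type screening rule and cross-cohort intersection |
| `hfsig.refine` | cyclic leave-one-out AUC-maximizing signature refinement |
| `hfsig.pipeline` | end-to-end orchestration with config validation and a reproducible manifest |

## CLI

Every stage is exposed as a subcommand reading/writing plain-text artifacts:

```bash
hfsig simulate --spec spec.yaml --out data/ --seed 1 --n-cohorts 2
hfsig de       --matrix data/cell_counts.tsv --meta data/cell_metadata.tsv \
               --group-column condition --group1 disease --group2 normal \
               --direction up --out de.tsv
hfsig markers  --matrix data/cell_counts.tsv --meta data/cell_metadata.tsv \
               --cluster-column subcluster --out-dir markers/
hfsig enrich   --query genes.txt --gmt sets.gmt --out enrich.tsv
hfsig gsea     --ranked ranked.tsv --gmt sets.gmt --nperm 1000 --seed 1 --out gsea.tsv
hfsig gsva     --matrix bulk.tsv --gmt sets.gmt --out gsva.tsv
hfsig classify --matrix bulk.tsv --labels labels.tsv --genes panel.txt \
               --n-splits 200 --seed 1 --out validation.json
hfsig screen   --de-dir de/ --gmt sets.gmt \
               --cohort c0=bulk0.tsv:labels0.tsv --cohort c1=bulk1.tsv:labels1.tsv \
               --out screen.json
hfsig refine   --pool pool.txt --matrix bulk.tsv --labels labels.tsv \
               --stop-size 3 --seed 1 --out-dir refined/
hfsig pipeline --config config.yaml --out run/ --seed 1
```

`hfsig pipeline` runs the whole synthetic-input flow (simulate → DE →
screen → GSVA attribution → pool → refine → validation) and writes every
stage artifact plus `manifest.json` (config, seed, sha256 registry) and a
ground-truth concordance report. Re-running with the same config and seed
reproduces every output byte-identically (wall-clock timings live in the
separate `run_log.json`).

## Conventions

* Expression matrices are genes × columns; TSV has gene ids in the first
  column and sample/cell ids in the header. `layer` distinguishes raw
  `counts` from `lognorm` (`ln(1 + 10⁴·v/colsum)`).
* Gene identifiers are opaque case-sensitive strings.
* Bulk class labels are `positive`/`negative`; the continuous prediction
  score is `d(x, negative centroid) − d(x, positive centroid)`.
* All randomness flows from explicit integer seeds; identical inputs and
  seeds give bit-identical outputs.
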