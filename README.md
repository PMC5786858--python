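# modenrich

Disease- and syndrome-module detection on weighted interaction networks.

The pipeline: load a confidence-score-filtered protein interaction network
(links dialect: `protein1 protein2 combined_score`, scores 0–1000, default
filter `> 700`), partition it into topological modules by greedy two-phase
modularity maximization (Louvain/BGLL), score every module for hypergeometric
enrichment of a disease gene set, select **disease modules** (p < 0.01 AND
module gene proportion ≥ 3× the background proportion), intersect with
symptom-gene enrichment to get **syndrome modules**, overlay drug/formula
target sets, and run Bonferroni-corrected over-representation analysis (ORA)
against GMT annotation collections. A synthetic-data module (stochastic block
model + planted gene sets) makes every stage testable without any database
download.

## Command line

```sh
# generate a synthetic scenario (network, disease genes, symptom map, targets)
modenrich simulate --blocks 16x25 --p-in 0.3 --p-out 0.002 \
    --q-in 0.8 --q-out 0.05 --seed 5 --out data/

# partition a network
modenrich partition --network data/network.tsv --min-score 700 \
    --seed 5 --out partition.tsv

# module enrichment of a gene set (covered-modules background by default)
modenrich enrich --partition partition.tsv --genes data/disease_genes.tsv \
    --out enrichment.tsv

# ORA against a GMT collection
modenrich ora --query genes.tsv --gmt collection.gmt --out ora.tsv

# full pipeline from a YAML config
modenrich run --config config.yaml
```

A minimal config (defaults: `min_score: 700`, `strict: true`, `alpha: 0.01`,
`rr_multiplier: 3.0`, `background: covered_modules`):

```yaml
network: data/network.tsv     # or an `sbm:` block to simulate one in-run
seed: 5
disease_genes: data/disease_genes.tsv
symptom_map: data/symptom_map.tsv          # optional
targets:                                   # optional overlays
  ihd_targets: data/targets.tsv
gmt: data/collection.gmt                   # optional, per-module ORA
out_dir: out/
```

`modenrich run` writes, deterministically for a fixed config and seed:
`partition.tsv` (node, module), `disease_enrichment.tsv` and
`symptom_enrichment.tsv` (module, k, n, K, N, p_value, proportion,
background_proportion), `report.tsv`/`report.json` (one row per disease
module: module, disease k/n and p, symptom k/n and p, three target-overlay
counts, selection flags), `ora_module_<label>.tsv` per disease module, and
`summary.json` (stage counts: nodes, edges, modules, potential modules,
universe size, K, background proportion, selected module labels).

## Library overview

| module | contents |
| --- | --- |
| `modenrich.graph_io` | `WeightedGraph`, `GeneSet`, `BipartiteMap`; loaders for links files, gene-set TSV, GMT, bipartite TSV |
| `modenrich.community` | `modularity`, `louvain_partition` (deterministic, seeded), `partition_summary` |
| `modenrich.enrichment` | `hypergeom_upper_tail` (log-space), `select_potential_modules`, `enrich_modules`, `select_disease_modules`, `select_syndrome_modules`, `Background` policies |
| `modenrich.curation` | `merge_sources` (union + overlap ledger), `exclusion_report` |
| `modenrich.ora` | `ora` with Bonferroni correction over testable terms |
| `modenrich.report` | `overlay_targets`, `build_report`, `write_report` (byte-stable TSV/JSON) |
| `modenrich.synthetic` | `generate_sbm`, `plant_gene_set`, `generate_symptom_map`, `generate_target_sets` |
| `modenrich.pipeline` | `validate_config`, `run_pipeline` |
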