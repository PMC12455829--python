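# ipqms

Bait-normalized immunoprecipitation quantitative mass spectrometry (IP-QMS)
interactome analysis, built around comparative profiling of SWI/SNF (BAF)
chromatin remodeling complexes.

The package implements the full processing chain for TMT reporter-ion
abundance tables:

1. **Ingestion & QC** (`ipqms.ingest`) — unique-peptide aggregation,
   quantification filtering (under-quantified and IgG-control-only
   proteins), lowest-detected-value imputation, and a per-replicate
   core-component enrichment gate for every bait IP.
2. **Differential enrichment** (`ipqms.enrichment`) — IgG-background
   fold-change filtering (default cutoff 1.5), per-replicate bait
   normalization, fold change as the ratio of group means, two-sided Welch
   t-test, Benjamini–Hochberg FDR, and the significance rule
   *fold change > 1.2 and p < 0.05* on either side.
3. **Composition summaries** (`ipqms.composition`) — catalog/gene-list
   annotation, subtype-specific mean enrichment, bait-per-complex
   stoichiometry, interactome-wide mean enrichment, and overlap between
   regulated gene sets and IP-enriched proteins.
4. **Subunit catalog** (`ipqms.catalog`) — a versioned 29-gene SWI/SNF
   catalog (core, cBAF/PBAF-shared, subtype-specific and ATPase-module
   classes; mutually exclusive paralog groups; HGNC/BAF-style aliases).
   Override it with your own TSV.
5. **TF evidence integration** (`ipqms.tf_integration`) — 2-of-3
   same-direction classification of transcription factors from motif, IP
   and RNA evidence streams, with explicit conflict (`mixed`) and
   `shared` open-chromatin handling.
6. **Single-cell co-expression** (`ipqms.sc_coexpression`) —
   positive-cell fractions, per-cell subtype detection, components-per-cell
   histograms and a Fisher-exact / permutation test of pairwise
   co-detection against the independence expectation.
7. **Synthetic data** (`ipqms.simulate`) — log-normal IP-QMS experiments
   with planted per-class enrichment factors, IgG background,
   detection-floor censoring (missing-not-at-random) and replicate noise;
   binary single-cell matrices with exact planted odds ratios; TF evidence
   tables with known labels. Every downstream stage is testable without
   external downloads.
8. **Pipeline** (`ipqms.pipeline`) — YAML-driven end-to-end run with a
   reproducibility manifest (config hash, per-stage counts, thresholds).

## Command line

```bash
# synthetic experiment with ground truth
ipqms simulate ip --seed 1 --out sim/

# QC gate for every bait IP (exit code 3 when a gate fails)
ipqms qc --matrix sim/abundance.tsv --design sim/design.tsv

# one differential comparison
ipqms compare --matrix sim/abundance.tsv --design sim/design.tsv \
    --bait BRG1 --a DDIT3:MLS --b BRG1:MLS --out cmp/

# annotate an enrichment table
ipqms annotate --table cmp/enrichment_DDIT3-MLS_vs_BRG1-MLS.tsv \
    --tf-list tfs.txt --out annotated.tsv

# TF evidence integration and single-cell analysis
ipqms integrate --evidence evidence.tsv --out tf_out/
ipqms sc --matrix sc_counts.tsv --pairs pairs.tsv --out sc_out/

# full pipeline from one config
ipqms run --config config.yaml
```

A minimal pipeline config:

```yaml
matrix: abundance.tsv
design: design.tsv
bait: BRG1
comparisons:
  - side_a: [BRG1, MLS]
    side_b: [BRG1, EWS]
    label: mls_vs_ews
  - side_a: [DDIT3, MLS]
    side_b: [BRG1, MLS]
    label: fop_vs_all
out_dir: results/
```

## File formats

- **Abundance matrix**: TSV/CSV, first column protein symbols, one column
  per sample; missing cells empty.
- **Design**: TSV with `sample_id`, `ip_target` (gene symbol or `IgG`),
  `cell_context`, `replicate`, `is_control`.
- **Catalog**: TSV with `gene_symbol`, `subunit_class`, `paralog_group`,
  `aliases` (pipe-separated).
- **Gene lists**: one symbol per line, `#` lines are provenance headers.
- **Single-cell matrix**: genes × cells TSV, or MatrixMarket `.mtx` plus
  gene/cell name files.

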