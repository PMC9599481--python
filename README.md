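# liprom

Integrated quantitative lipidomics–proteomics analysis pipeline:

- **synthetic** — synthetic multi-omics cohort generator with planted ground
  truth (lognormal concentrations, group-level effects, latent
  particle-number factors driving protein–lipid correlation blocks, MCAR
  missingness, QC replicate tables).
- **ingest** — wide CSV/TSV concentration tables + feature metadata +
  sample→group designs; quantifiability filtering (remove features with
  >30% missing values or QC CV >30%; boundaries retained) and half-minimum
  imputation.
- **lipids** — lipid species name parsing (`PC(16:0/20:4)`,
  `PE(P-18:1/20:4)`, `TAG(52:2-FA16:0)`, …) and fatty-acyl saturation
  categorization (ODD / SFA_MUFA / DUFA / PUFA), class totals and
  per-sample %Abundance sub-class summaries.
- **differential** — two-sided Wilcoxon rank-sum vs the reference group
  (exact for combined n ≤ 12 without ties, tie-corrected normal
  approximation otherwise), Kruskal–Wallis, one-way ANOVA, Benjamini–
  Hochberg FDR, log2 fold changes, volcano/Venn/z-score tables and
  Ward/Euclidean clustering.
- **network** — per-group Pearson correlations of every protein×lipid pair
  (p from the t transform, df = n−2; BH within the pair family), the dual
  filter (|r| > 0.5 strict, p < 0.002, endpoint dysregulation p < 0.05 with
  configurable `lipid`/`either`/`both` endpoint rule), hub-protein ranking,
  SIF/GraphML/TSV export and local hypergeometric over-representation
  analysis over GMT gene sets.
- **classifier** — stratified 70/30 split (largest-remainder rounding),
  repeated bootstrap-forest predictor screening into a fixed-size pool,
  greedy "leading predictor" forward search over MLP classifiers with five
  Gaussian (`exp(-z²)`) hidden nodes, confusion matrices and one-vs-rest
  ROC AUCs. Selection metric is cross-validated training accuracy by
  default (`selection_mode="cv"`); `"paper"` mode scores candidates on the
  held-out test set to replicate the original protocol (which leaks the
  test set into selection) and is labeled as such.
- **pipeline / cli** — one-config orchestration of all stages with a
  manifest of seeds, thresholds and content hashes.

## CLI

```bash
liprom simulate --out sim --seed 1            # synthetic cohort + QC + truth
liprom ingest   --data sim/cohort.csv --meta sim/meta.csv \
                --design sim/design.csv --qc sim/qc.csv --out run
liprom annotate --names names.txt             # saturation categories
liprom diff     --data run/filtered.csv --meta run/filtered_meta.csv \
                --design sim/design.csv --out run
liprom network  --data run/filtered.csv --meta run/filtered_meta.csv \
                --design sim/design.csv --group HL --out run \
                --r-min 0.5 --p-corr 0.002 --p-diff 0.05 --endpoint-rule either
liprom enrich   --query hubs.txt --gmt sets.gmt --universe panel.txt --out ora.tsv
liprom classify --config run.yaml
liprom run-all  --demo --out demo_run --seed 1   # everything end-to-end
liprom run-all  --config run.yaml
```

`run-all` writes, per stage: `qc_summary.tsv`, `class_cv_summary.tsv`,
`lipid_annotation.tsv`, `class_totals.tsv`, `subclass_abundance.tsv`,
`abundance_group_summary.tsv`, `differential.tsv` (feature_id, group,
layer, log2_fold_change, p_value, q_value, direction),
`class_comparison.tsv` (group means with min/max, ANOVA p, BH-adjusted p),
`venn_up.tsv`/`venn_down.tsv` (group-combination membership),
`class_zscores.tsv` (clustered row/column order), per-group
`network_<G>.sif/.graphml/.tsv`, `hub_proteins.tsv`, optional
`enrichment_<G>.tsv`, `screening.tsv`, `search_trace.json`,
`confusion_train.tsv`, `confusion_test.tsv`, `accuracy_curve.tsv`, and
`manifest.json` (seeds, thresholds, SHA-256 of every output).

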