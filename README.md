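# immunopipe

Immune-signature subtyping and prognostic scoring for bulk expression
cohorts. The pipeline:

1. **Score** — per-sample gene-set enrichment (ssGSEA-style rank-weighted
   ECDF difference) of an immune signature collection.
2. **Modules** — signed topological-overlap network over signature-score
   Spearman correlations (default power 20); average-linkage clustering
   with a modularity-optimal tree cut; each module represented by its
   most intramodularly connected "eigen-signature". Representative
   robustness can be checked by Tibshirani–Walther prediction strength.
3. **Cluster** — Gaussian-mixture subtyping on eigen-signature scores
   across four covariance families, selected by maximal BIC
   (`2·loglik − p·ln n`), components tested from 2 to 28 by default.
4. **Markers** — subtype-specific genes by one-vs-rest Wilcoxon tests
   with joint Benjamini–Hochberg correction and a log-fold-change floor;
   optional LASSO-filtered logistic/SVM/random-forest classifier
   comparison with fivefold CV on a stratified 7:3 split.
5. **ITB score** — per-gene univariate Cox screening (Efron ties), PCA on
   the z-scored marker panel, and a per-sample score summing PC1
   contributions of hazard-increasing genes minus hazard-decreasing ones;
   survival stratification at a maximally selected log-rank cutpoint,
   Kaplan–Meier curves, log-rank test and hazard ratios.
6. **Evaluate** — ROC/AUC of the score, tumor mutational burden and their
   logistic combination; nested-model likelihood-ratio tests.
7. **Mutational signatures** (optional) — ARD-regularized KL-NMF of
   96-trinucleotide-context catalogs with data-driven effective rank and
   per-signature SNV fractions.

A synthetic-cohort generator plants subtype, module, prognosis and
mutational-signature structure with known ground truth, so every stage is
validated by recovery tests.

## CLI

Every stage is a subcommand of `immunopipe` (`simulate`, `score`,
`modules`, `cluster`, `markers`, `itb`, `stratify`, `mutsig`, `evaluate`,
`run`). Exit codes: 0 success, 2 validation error, 1 runtime error.

```sh
# generate a synthetic cohort
immunopipe simulate --out cohort/ --seed 17

# run the full pipeline from a YAML profile
immunopipe run --config configs/paper_defaults.yaml --seed 17 --out results/

# or stage by stage
immunopipe score --expr cohort/expression.tsv --gmt cohort/gene_sets.gmt --out scores.tsv
immunopipe modules --scores scores.tsv --power 20 --min-size 3 --out modules.json
immunopipe cluster --scores repr_scores.tsv --kmin 2 --kmax 28 --out subtypes.json
immunopipe mutsig --catalog cohort/catalog.tsv --max-rank 10 --out sigs.json
```

All formats are plain text: TSV expression/survival/score/catalog tables,
GMT gene sets, JSON models. Catalog rows use the 96 COSMIC trinucleotide
contexts in canonical order. Reruns with an identical config and seed are
byte-identical; each run writes a `manifest.json` with artifact hashes.

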