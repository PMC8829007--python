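# Pipeline profile pinning every parameter the source analysis states:
# signed-TOM power 20, minimum module size 3, mixture components tested
# from 2 to 28, 7:3 train/test split, fivefold CV, FDR 0.05.
# Point the input paths at your cohort (e.g. output of `immunopipe simulate`).
expression: cohort/expression.tsv
gene_sets: cohort/gene_sets.gmt
survival: cohort/survival.tsv
catalog: cohort/catalog.tsv
out_dir: results
seed: 0
alpha: 0.25
ssgsea_normalize: false
power: 20.0
min_module_size: 3
k_min: 2
k_max: 28
gmm_n_init: 10
standardize_scores: true
fdr: 0.05
lfc: 1.0
train_fraction: 0.7
cv_folds: 5
run_classifiers: true
minprop: 0.1
pca_mode: pooled
run_mutsig: true
max_rank: 10
nmf_restarts: 10
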