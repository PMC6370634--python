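# hepatox

Classification of chemically induced liver-injury endpoints — biliary
hyperplasia, fibrosis and necrosis — from bulk transcriptomic responses.

Repeat-dose rat-liver screens pair whole-genome expression profiles with
graded histopathology calls across chemical × dose × time exposure
conditions. `hepatox` turns such data into per-animal binary endpoint
predictions and quantifies what matters along the way: how features are
built (gene-level fold changes vs pathway activity scores), how severe
class imbalance is handled (SMOTE), which classifier is used (single- or
multi-task neural networks, random forest, SVM), and whether the learned
signal is real (label-shuffle controls, endpoint-combination specificity,
external condition-level correlation). A bundled synthetic-screen
generator makes every stage testable without any data download.

## The statistics at the core

**Features.** For treated sample *i* and gene *g*, the input is the log2
fold change `x_ig − mean(control cohort)_g`. Pathway-level inputs score a
gene set *S* (|S| = n present genes) on a profile by

    z = (X̄ − μ₀) / (σ / √n)

where X̄ is the mean |log2 FC| over *S* and μ₀, σ describe the |log2 FC|
distribution over all genes (population σ). Under the Central Limit
Theorem z ~ N(0, 1) for an unremarkable set.

**Imbalance.** Positive calls are rare (≲ 1:10). SMOTE appends synthetic
minority points drawn on segments between a minority sample and one of its
k = 5 nearest minority neighbors, to parity by default — training folds
only, never held-out data.

**Models.** Single-task networks are ReLU multilayer perceptrons with a
sigmoid output, Adam, binary cross-entropy, dropout and early stopping;
the multi-task variant shares a trunk across the three endpoints with
task-specific heads and a weighted sum of task losses. Random-forest and
RBF-SVM baselines expose the same predict contract. Hyper-parameters are
tuned by grid / randomized search on cross-validated F1.

**Evaluation.** Stratified 10-fold cross validation; confusion-matrix
metrics with imbalance-robust MCC

    MCC = (TP·TN − FP·FN) / √((TP+FP)(TP+FN)(TN+FP)(TN+FN))

and F1 = 2TP/(2TP+FN+FP); endpoint-combination specificity (exact match
of the predicted presence/absence triple, on pooled out-of-fold
predictions); y-randomization nulls; and Spearman correlation between
per-condition predicted positive counts and observed mean injury scores.

## Worked example

```python
import hepatox as hx

# a synthetic screen: 50 chemicals x 3 doses x 4 times x 5 animals,
# 500 genes with five planted 20-gene injury modules, ~1:10 imbalance
study, truth = hx.generate_study(hx.SimulationConfig(seed=1))

feats = hx.gene_feature_matrix(
    hx.compute_fold_changes(study), truth.all_signal_genes(), "planted")

def dnn(X, y, seed):
    return hx.build_and_train_single(X, y, hx.SingleTaskNetConfig(
        max_epochs=60, early_stopping_patience=8, seed=seed))

pipe = hx.Pipeline(lambda s: feats.values, dnn, endpoint=2,  # necrosis
                   smote=hx.SmoteConfig(seed=11))
res = hx.kfold_cv(pipe, study, k=10, seed=2)
print(f"mean CV MCC {res.mean_metric('mcc'):.3f}  "
      f"F1 {res.mean_metric('f1'):.3f}")

null = hx.y_randomization(pipe, study, endpoint=2, n_shuffles=10,
                          seed=5, k=5)
print(f"label-shuffle null |MCC| {null['mean_mcc'].abs().mean():.3f}")
```

prints

```
mean CV MCC 0.781  F1 0.801
label-shuffle null |MCC| 0.016
```

i.e. the network recovers the planted injury signal far above the chance
level established by retraining on permuted labels. The same study run
through the endpoint-combination analysis shows the characteristic
failure of the rarest single-endpoint category (fibrosis-only, a handful
of positives against ~2,800 negatives scores MCC ≈ 0) while the
better-populated categories score well — rarity, not the model, is the
bottleneck.

The same pipeline is scriptable from the shell:

```
hepatox simulate --seed 1 --out runs/study
hepatox evaluate --study runs/study --ground-truth runs/study/ground_truth.json \
    --model dnn --endpoint 2 --out runs/eval
hepatox yshuffle --study runs/study --ground-truth runs/study/ground_truth.json \
    --model dnn --endpoint 2 --k-folds 5 --out runs/null
```

Subcommands: `simulate`, `features`, `evaluate`, `specificity`,
`yshuffle`, `correlate`, `compare`. Every run writes a `manifest.json`
sufficient to reproduce its reports.

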