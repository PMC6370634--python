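# Methods

`hepatox` is a tested re-implementation of a transcriptomic classification
pipeline for chemically induced liver injury: given log2 expression
profiles of treated and control rat-liver cohorts, it predicts three binary
histopathology endpoints — biliary hyperplasia, fibrosis and necrosis —
and quantifies how feature selection, class rebalancing and model choice
affect performance. Because the original training compendia (large
repeat-dose screens) cannot be bundled, every analysis is exercised on a
synthetic generator that reproduces their statistical structure.

## Feature construction

**Gene-level features.** For a treated sample (default) or a treated
cohort, the feature for gene *g* is the log2 fold change: the sample's
log2 expression minus the mean log2 expression of the matched control
cohort. Per-sample mode is the default because endpoint labels are
per-animal; per-cohort mode (treated-cohort mean minus control mean) is
retained as an explicit option, and averaging per-sample rows within a
cohort reproduces the per-cohort row exactly.

**Pathway-level features.** A gene set *S* is scored on a profile by
standardizing its mean absolute log2 fold change against the profile-wide
distribution:

    z = (X̄ − μ₀) / (σ / √n)

with X̄ the mean |log2 FC| over the n set genes present in the profile,
and μ₀, σ the mean and *population* (ddof = 0) standard deviation of
|log2 FC| over all genes. σ/√n is the Central Limit Theorem standard
error of a mean of n draws, so z is approximately N(0, 1) for an
unremarkable set; the upper-tail normal p-value is reported alongside but
not used as a feature. Two consequences are pinned by tests: the
whole-universe set scores exactly 0, and z is invariant under positive
rescaling of the profile. Genes missing from the universe are dropped
(logged), and n is the post-filter set size. A degenerate profile
(σ = 0) scores 0 with a warning rather than erroring, so an all-zero
fold-change row yields an all-zero pathway row.

Gene identifiers are matched exactly and case-sensitively; symbol/probe
conversion is the caller's responsibility (an alias map can be applied
before building features). Gene sets travel as GMT, gene lists as
one-id-per-line text.

## Class rebalancing

Positive endpoint calls are rare (a few percent to ~12% of samples), so
minority classes are oversampled with SMOTE: each synthetic point lies on
the segment between a minority sample and one of its k = 5 nearest
minority neighbors (Euclidean, uniform interpolation factor). The
default target is parity (minority/majority = 1.0) since the achieved
ratio in the source protocol is unstated and parity is the technique's
original default. Distances are computed on the features as given —
log2 fold changes and z-scores are already commensurate, so no rescaling
is applied. SMOTE is applied **inside training folds only**; held-out
folds are never oversampled, which is enforced structurally by the CV
driver and asserted in tests.

## Models

Four classifiers share one predict contract (per-endpoint probability in
[0, 1], thresholded at 0.5 with ties positive):

* **Single-task network** — fully connected ReLU layers with one sigmoid
  output, binary cross-entropy, Adam (lr 1e-3), normal (He-scaled) kernel
  initialization, inverted dropout on the input and every hidden
  activation, and early stopping. Defaults: 2 × 64 hidden units, dropout
  0.3, batch 64, up to 200 epochs, patience 10 — small enough to train on
  a desk CPU, and loss curves flatten well within the epoch budget.
* **Multi-task network** — hard parameter sharing: a shared trunk
  (default 2 × 64) feeding three task branches (default 1 × 64 + sigmoid
  head); the loss is the task-weighted sum of per-task binary
  cross-entropies (equal weights by default). With a single nonzero task
  weight it reproduces single-task behaviour, which is tested.
* **Random forest** and **SVM (RBF)** baselines via scikit-learn, exposed
  through the same contract.

The networks are implemented directly in NumPy; a single `Generator`
drives initialization, dropout, shuffling and the validation split, so
training is bit-reproducible per seed, single-threaded. Early stopping
monitors the loss on a 10% stratified split of the training data (the
monitored quantity is otherwise a free choice) and always restores the
best checkpoint, so the returned model is never worse than the best seen.
Non-finite losses abort with diagnostics.

Hyper-parameters are tuned by exhaustive grid search or seeded randomized
search with k-fold cross validation and mean F1 as the objective; ties go
to the earliest candidate in enumeration order. Searches accept an
optional SMOTE config that is applied per training fold. When a search is
combined with outer CV evaluation it should be nested inside the outer
training folds; running it on the same folds as the reported evaluation
is possible but optimistic.

## Evaluation protocol

Metrics come from the confusion matrix: MCC, F1, sensitivity,
specificity, PPV, NPV, balanced accuracy and accuracy. Degenerate cases
follow reporting conventions: MCC is 0 whenever a denominator factor
vanishes, and 0/0 ratios are 0 with an explicit `degenerate` flag. A
decimal half-up rounding helper matches how printed tables round (e.g.
0.675 → 0.68). The metric implementations are cross-checked against
scikit-learn on exhaustive small instances.

Cross validation is stratified k-fold (default k = 10) on the target
endpoint — stratification is necessary because the rarest endpoint has
too few positives to survive unstratified splitting — with SMOTE and
model fitting confined to the training fold. Per-fold metrics, their
mean/SD, and pooled out-of-fold predictions are all retained.

**Endpoint-combination specificity.** Treated samples are partitioned by
their true endpoint triple (three single-endpoint patterns, three
double-endpoint patterns, one triple). For each pattern, a sample is
condition-positive iff its true triple matches exactly and
prediction-positive iff its jointly predicted triple matches exactly;
negatives are all other samples, so the four counts sum to the sample
count for every pattern. Metrics are computed on out-of-fold predictions
pooled across all folds.

**Y-randomization.** The full cross-validated pipeline is retrained on
uniformly permuted endpoint labels (features untouched), n_shuffles
times; per-shuffle mean MCC/F1 form the chance distribution a real model
must beat.

**Condition-level correlation.** For an external exposure series, the
predicted injury level of a condition is its count of predicted-positive
samples; agreement with the observed mean injury score is summarized by
Spearman rank correlation (average ranks for ties, two-sided asymptotic
p-value).

## Synthetic data generator

The generator emulates a repeat-dose screen: chemicals × doses × times,
each condition contributing one control and one treated cohort of
`animals_per_cohort` animals. Expression is per-gene baseline
N(8, 1) plus Gaussian noise (sd 0.35 on the log2 scale, a typical
replicate residual) plus, for treated samples, `effect_size` (1.0 log2
units) × module activation on the genes of activated co-expression
modules. Half the chemicals are toxic; a toxic chemical activates 1–2 of
the 5 planted 20-gene modules with strength U(0.7, 1), scaled by
dose/dose_max × time/time_max.

Endpoint propensity is logistic in the module activations:
p = σ(W·a − t). Each endpoint listens to 2–3 modules with partial
overlap between endpoints — the sole mechanism of endpoint co-occurrence
(no direct label–label coupling). The weight magnitude (25 per member
module) makes labels near-deterministic away from the threshold, the way
histopathology calls track graded severity; with a shallower response the
Bernoulli label noise alone would cap any classifier near MCC 0.75,
which would not represent a screen with a clearly learnable signal.
Thresholds (11.5, 16.5, 12.5) were calibrated once, at design time,
to per-endpoint positive fractions of roughly 8%, 5% and 12% — the
~1:10 imbalance regime the pipeline targets. `table1_like_config()`
provides a preset tuned to the sparser 3.9% / 1.6% / 11.8% profile of a
large public screen. Labels are sampled per animal from the condition
propensity (shared within a cohort), optionally flipped with
`label_noise` (default 0); control animals are always all-negative,
anchoring the fold changes as the dominant negative class does in real
screens.

`generate_condition_series` builds an external validation set: one
treatment at n graded exposure levels, all modules engaged at an
activation rising linearly to `max_activation`. The per-condition mean
injury score is the summed endpoint drive Σₑ(Wₑ·a − tₑ)/10 —
deterministic and strictly monotone in the gradient, as aggregate
severity grades are in dose–response studies. The module/gene layout is
derived from the config seed identically in both generators, so feature
sets learned on a study transfer to its series. For generalization
experiments the series uses `max_activation = 0.25`, which leaves about
two-thirds of conditions below the necrosis threshold; an external set
dominated by positives would let a degenerate always-positive predictor
look good.

What the generator does **not** emulate: probe-level microarray
structure, array QC/normalization artifacts, batch effects, correlated
noise between modules, dose-dependent variance, or missing labels.
Passing tests therefore demonstrate the pipeline's correctness and its
behaviour under planted signal and imbalance — not performance on real
screens.

## Problem sizes and numerical choices

The default benchmark (500 genes, 5 modules, 50 chemicals × 3 doses × 4
times × 5 animals → 3,000 treated + 3,000 control samples) runs the full
cross-validated network in seconds per fold on one CPU; benchmark tests
and the acceptance script use reduced epoch budgets (30–60 epochs,
patience 4–8) and k = 5 for the label-shuffle null, which the loss
histories show is past convergence for this data. Sub-generators are
seeded per condition from the study seed, so cohorts are independent and
insensitive to generation order. Sigmoid inputs are clipped at ±60 and
probabilities at 1e-7 before the log-loss; the early-stopping
improvement tolerance is 1e-6.

## Known limitations

* The generator's endpoint mechanism is low-dimensional (5 modules); real
  screens have hundreds of partially redundant modules and much more
  heterogeneous effect sizes.
* SVM probabilities come from scikit-learn's internal calibration, which
  is itself cross-validated and slow on large SMOTE-inflated folds; the
  network and forest are the benchmarked paths.
* Multi-task SMOTE oversamples the any-positive minority and copies the
  anchor's label triple; interpolating labels between different triples
  has no clean meaning.
* Spearman p-values are asymptotic; at n ≈ 12 conditions the permutation
  null is wide (the two-sided 5% critical value is |rho| ≈ 0.59), so
  single-series correlations should be read with that in mind.
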