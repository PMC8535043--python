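# Methods

This note documents the models, defaults and numerical choices behind
`genevote`, and what the test suite does and does not establish.

## The selection model

The pipeline treats gene selection as a *stability* question: a gene
belongs in the panel if a tree-ensemble classifier keeps finding it
informative across cross-validation folds, not merely once on the full
data. Concretely, for a stratified k-fold partition, the importance
provider is fitted k times on each training complement, each importance
row is divided by its own maximum (tree-ensemble importances have
arbitrary scale, so a threshold is only meaningful relative to the fold's
strongest gene), genes above the threshold *strictly* are retained per
fold, and a gene's vote is the number of folds that retained it. The final
panel ranks genes by (votes desc, mean importance desc, id asc) and
truncates to `n_final`.

Two threshold conventions are supported because they answer different
questions. `threshold=0` with `min_votes="auto"` (= k) keeps the genes
with non-zero importance in *every* fold — the most conservative stability
reading, and the configuration used by the recovery tests. A high fixed
threshold (default 0.84) or the accuracy-driven sweep (`threshold="sweep"`,
argmax of mean CV accuracy over a grid, smallest grid point on ties)
instead asks which relative-importance cutoff yields the best downstream
classifier; such a cutoff is a property of one dataset and should be
re-swept rather than transferred.

### Importance provider

The provider contract is `importances(X, y) -> non-negative vector` plus
`make_classifier()`. The default binding is gradient-boosted trees with
`n_estimators=200, max_depth=1, learning_rate=0.1, max_features=0.1`.
Depth-1 trees with 10% feature subsampling are deliberate: with correlated
informative genes, deep greedy trees let one gene shadow its partners, so
per-fold importance supports become erratic and voting unstable. Stumps
over random feature subspaces (the random-subspace/"rsm" idea) spread
importance across the whole signal block while noise genes rarely win a
split in all k folds. NaN importances (an ensemble whose trees never
split) are mapped to 0, tiny negative values clipped.

### mRMR

Relevance is |Pearson r(gene, label)| (an F-statistic option exists);
redundancy is the mean |Pearson r| to the already-selected set; the greedy
criterion is the quotient relevance/redundancy (denominator floored at
epsilon = 1e−6) or the difference, per config — the literature uses both
and the source formulation is ambiguous, so neither is hard-coded. Ties in
every argmax go to the lower gene index. Correlations with a constant
vector are defined as 0. The exhaustive ensemble seeds k runs at the k
most relevant genes (stable sort, so heads are distinct and deterministic);
the bootstrap ensemble resamples with replacement *within* each class so
no resample collapses to a single class at small n.

### Redundancy pruning

A greedy scan in panel order drops any gene with |r| ≥ r_max (default
0.5) to an already-kept gene; the kept set therefore has max pairwise
|r| < r_max by construction, which the tests verify post hoc. Constant
genes correlate 0 with everything except an identical constant twin
(treated as a duplicate, r = 1). An optional second pass at r_max + 0.01
reproduces a two-stage pruning variant; it is off by default. Note a
structural interaction with the simulator: two informative genes with
effect e (in noise-SD units) at class balance b share correlation
b(1−b)e² / (1 + b(1−b)e²), which is exactly 0.5 at e = 2, b = 0.5 — so at
the default effect size pruning removes roughly half of an all-planted
panel. The *voted* panel is accordingly treated as the pipeline's final
gene list, with pruning reported as a separate redundancy analysis.

### Hyperparameter search

Two built-in spaces mirror the two boosting libraries' vocabularies
(assigned by parameter-name compatibility). Learning-rate bounds are
exponents: [−3.0, −0.7] on log10 (→ rates 0.001…0.2) and
[ln 0.001, ln 0.3] on the natural log — the only readings that produce
valid rates. Backends: `random`, and `adaptive-sequential` (random warm-up
of max(10, n/3) trials, then each step scores a 16-candidate pool — half
Gaussian perturbations of the incumbent at 0.15× the parameter range, half
fresh draws — with a 3-nearest-neighbour surrogate on normalized
coordinates and evaluates the most promising). Both are exactly
reproducible from (seed, backend); a failing objective records loss 1.0
with a warning rather than aborting the search. The default budget is 30
trials. Native boosting parameters are bound to the scikit-learn
gradient-boosting estimator where an analogue exists (iterations/
n_estimators → n_estimators, depth/max_depth → max_depth, rsm/
colsample_bytree → max_features, min_child_weight → min_samples_leaf,
subsample and learning_rate directly); parameters without an analogue
(l2_leaf_reg, random_strength, bagging_temperature, scale_pos_weight,
gamma) are accepted and ignored, so a tuned config is portable even though
those dimensions are inert under this binding.

### Metrics

All rates come from hard predictions at a single operating point:
AUC = (1 + TPR − FPR)/2, i.e. balanced accuracy — not a score-ranking AUC.
Per-fold metrics are summarized as mean ± population std; because the AUC
of mean rates differs from the mean of per-fold AUCs at small folds, both
aggregations are written to `metrics.json`. Rates with a 0/0 denominator
(possible at fold sizes of 2–3) are defined as 0 and warned about. Report
rounding is two decimals, half away from zero, with the value first
quantized at 1e−10 so binary float error cannot flip a true half-point.

## The synthetic-data generator

`SimulationSpec` defaults describe the targeted regime: 28 balanced
samples × 1070 genes, 10 informative genes with an additive class-mean
shift of 2 within-class SDs, 2 redundant copies per informative gene at
target correlation 0.8, unit noise SD. Sample size, gene count and
informative count follow the targeted cohort shape; the effect size of 2
SDs is a typical "strong marker" separation (per-gene Bayes error ≈ 16%),
and rho = 0.8 with 2 copies per parent gives pruning something real to do
without dominating the matrix. Redundant copies are
`rho·parent + noise` with the noise variance chosen so the *population*
correlation equals rho exactly (the parent's variance includes the
between-class component). Planted genes are scattered over random column
positions; identifiers look like probe-set ids (`g0001_at`) so string-id
round-trips are exercised.

What the generator does **not** emulate: batch effects, probe saturation,
missing values, heavy-tailed or heteroscedastic noise, and
label-dependent correlation structure beyond the planted blocks. A green
recovery test therefore establishes that the pipeline finds additive
mean-shift signal under Gaussian noise and survives its own bookkeeping —
not that it handles real microarray artifacts.

## Degenerate inputs and tie-breaks

* Constant genes: min-max scale to 0; relevance 0; pruned only against an
  identical constant twin.
* Min-max scaling is fit on training data only (per-fold) by default;
  held-out values are not clipped. Scaling the full matrix before
  partitioning (the simpler, slightly leaky convention) is available as
  `scale_mode="global"`.
* Labels: any two distinct values are mapped to {0, 1} by sorted order
  unless a positive label is named; >2 values is an error.
* Stratification degrades to a seeded round-robin (with a warning) when a
  class has fewer members than folds, which makes leave-one-out legal.
* All argmax/sort tie-breaks are deterministic: lower index for importance
  and mRMR, lexicographic gene id for votes and SVM weights.
* The "shuffle then keep unique" merge uses a seeded shuffle, so merged
  panels are reproducible.

## Evaluation hygiene

`cross_validate` accepts a `gene_selector` callable that is re-run inside
every training fold — the leak-free nested mode used by the permutation
null test (accuracy stays at chance when labels are shuffled, n = 28,
k = 8). Selecting genes once on the full matrix and then cross-validating
on the same samples (the workflow's plain mode) is optimistic at this
sample size; the package supports both so the bias is measurable.

## Known limitations

* The boosting-style classifier families are backed by one scikit-learn
  estimator; differences between the two native libraries (ordered
  boosting, regularization terms) are not reproduced, only their search
  spaces and parameter vocabularies.
* The adaptive-sequential tuner is a modest surrogate search, not a
  tree-structured Parzen estimator; on smooth objectives it should match
  or beat random search (checked as a logged, not asserted, comparison).
* Voting assumes binary labels throughout; multi-class data is rejected at
  load time.
* With k = 8 and n = 28, per-fold test sets hold 3–4 samples, so per-fold
  rates are coarse (steps of 1/2–1/4) and mean ± std summaries are wide;
  this matches the targeted regime rather than being a defect of the
  implementation.
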