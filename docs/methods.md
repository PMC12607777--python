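# Methods

## Model and pipeline

`spectratype` classifies tumor samples into molecular subtypes in four
stages, executed in a fixed order by the pipeline driver: per-sample
gene-set enrichment → class balancing (training data only) → univariate
top-k feature selection (fit on training data only) → feed-forward
classification. The stage ordering and the restriction of balancing and
selection to the training portion are enforced contracts, not conventions:
the driver logs every stage with input/output shapes and the prediction
path is structurally unable to balance or re-select.

### Per-sample enrichment (functional spectra)

For each sample, genes are ranked by that sample's own expression values,
descending, with ties broken by gene id ascending so the ranking is
deterministic across platforms. For a gene set S with N_H measured members
in a universe of N genes, the score is the signed extremum of the
difference between a weighted hit CDF (member genes, weighted by |r_j|^p
and normalized by N_R = Σ_{members}|r_j|^p) and a uniform miss CDF
(non-members, steps 1/(N−N_H)). Both sums reach 1 at the end of the list,
so the trajectory always returns to 0; the score lies in [−1, 1] with ±1
attained exactly at extreme rankings.

Parameters and defaults:

- `weight_exponent` p = 1.0 — the canonical weighted statistic. p = 0
  degrades to a pure rank statistic, invariant under any strictly
  increasing per-sample transform of expression. Exposed because the
  appropriate weighting is a modelling choice, not a fact of the data.
- `min_set_size` = 5, `max_set_size` unbounded — sets are intersected with
  the measured universe *before* size filtering, so unmeasured genes can
  never affect a score (tested as an invariant).
- `positive_only` = False — the two-sided signed extremum is the default
  because down-regulation carries signal for the downstream selector; a
  positive-only switch is provided.
- Ties in |deviation| resolve to the earliest rank position (argmax
  convention). If every member weight is exactly zero under p > 0 the hit
  weights fall back to uniform steps so the statistic stays defined.

The vectorized implementation is verified against a literal two-loop
transcription of the two running sums on 100 random (sample, set) pairs to
1e-10 in the test suite.

### SMOTE balancing

Minority classes are raised to the majority count by interpolation:
x_new = x_i + λ(x_nn − x_i) with the base point drawn uniformly from the
minority class, the partner uniformly from its k nearest same-class
neighbours (Euclidean; enrichment scores already share the [−1, 1] range,
so no rescaling), and λ ~ U[0, 1]. `k_neighbors` defaults to 5 and is
clipped to class_size − 1 with a logged warning; a singleton class is an
error rather than a silent duplication. Originals are preserved verbatim
and synthetic rows get generated ids. This makes every synthetic point a
convex combination of two same-class originals — the property the tests
check — and the draw deterministic given the seed. Counts (every class at
the majority count) are portable across SMOTE implementations; exact
synthetic coordinates are not, and are only required to be reproducible
under a fixed seed.

### Feature selection

The default scorer is the regression F statistic
F = (r²/(1−r²))·(n−2) with r the Pearson correlation between a feature and
the class label encoded as consecutive integers 0..C−1 in sorted
class-name order. The encoding is recorded with the model bundle because
the score depends on it: with ≥3 classes the integer coding imposes an
arbitrary ordinal structure, and features tracking a middle-coded class are
structurally under-ranked. One-way ANOVA F (`method="anova_f"`) is provided
as the encoding-free scorer for categorical targets, and it is what the
synthetic-recovery experiments use; the regression scorer remains the
default for the colorectal-style workflow. Conventions: a constant feature
scores 0; a numerically perfect correlation maps to a +inf sentinel that
sorts above all finite scores; ties break by set name ascending, which
makes top-k selections nested in k (a tested invariant). Validation
matrices are aligned (subset/reorder) to the frozen training selection and
never re-scored.

### Classifier

A dense stack of widths (1024, 256, 64, 64), each layer followed by SELU,
batch normalization (ε = 1e-3, running-stat momentum 0.99) and Gaussian
dropout (multiplicative N(1, √(rate/(1−rate))) noise, rate 0.4), then a
dense softmax head. Training uses Adam (lr 0.001, β = 0.9/0.999) with
decoupled weight decay 1e-6 applied to the dense weight matrices, on
categorical cross-entropy. The forward/backward passes and the optimizer
are implemented directly on numpy; inference uses running batch-norm
statistics with dropout off, so prediction is bitwise deterministic.

Open choices made here:

- **Head width.** The head defaults to one unit per class, which is the
  well-posed choice. A wider fixed head (e.g. `output_width=10`) is
  supported for architecture fidelity experiments: surplus units train
  against all-zero targets and predicted probabilities renormalize over the
  first n_classes units.
- **Schedule.** Epochs and batch size are free parameters; defaults are
  epochs = 500 with early stopping on training loss (patience 20, best
  weights restored) and batch_size = 64. epochs = 0 returns the seeded
  initialization with an empty training log.
- **Initialization** is lecun-normal (matched to SELU's self-normalizing
  regime), seeded from the config.
- **Divergence**: a non-finite loss or logit aborts with a
  learning-rate hint rather than returning a broken model. Batch
  normalization makes the stack robust to very large steps, so only a
  genuine floating-point overflow triggers this path.

### Evaluation

Metrics are proportions in [0, 1] (a percent display flag multiplies by
100). Multiclass sensitivity/specificity collapse the confusion matrix
one-vs-rest per class and macro-average; balanced accuracy is the macro
mean of (sensitivity + specificity)/2, which reduces exactly to the
two-term form on a binary confusion. Per-class one-vs-rest AUC comes from
the predicted probability columns via the midrank (Mann–Whitney)
formulation, so score ties are handled deterministically; the tests verify
it against a brute-force concordant-pair count. A class absent from the
truth has undefined sensitivity/AUC; such entries are flagged None and
excluded from macro means. Aggregation across cohorts is the unweighted
arithmetic mean of each scalar metric (confusion counts are summed);
rounding to 2 decimals happens only at display, stored values keep full
precision. Sample-pooled aggregation is deliberately not offered: with
cohorts of very different sizes the two differ, and the per-cohort mean is
the interpretable summary of cross-dataset robustness.

## Synthetic cohorts: what they emulate and what they do not

The generator plants the exact structure the pipeline assumes: a large
background of uninformative genes, `informative_sets_per_class` gene sets
per class whose member genes are shifted by `effect_size · noise_sd` in
that class's samples (informative member pools disjoint across classes by
default, with an `overlap_fraction` knob to create confusable subtypes),
and optionally a fraction of unlabeled samples. Expression is Gaussian
additive; count noise, batch effects, platform differences and correlated
gene modules are deliberately absent, because the enrichment stage consumes
only within-sample orderings, for which a mean shift is the minimal
monotone perturbation. Passing the recovery experiments therefore shows
that the pipeline machinery is correct and leak-free — not that the
classifier will reach any particular accuracy on real cohorts, where
effect sizes are smaller, pathways overlap and labels are noisy.

Default study conditions: 2000 genes, 50 sets of 10–20 genes, 4 classes ×
40 samples, 3 informative sets per class, effect size 3 (in noise-sd
units), noise sd 1.0. These are the conditions under which the recovery
experiments run: with a 70:30 stratified split, selection at
k = n_informative recovers ≥90% of the planted sets and held-out accuracy
exceeds 0.95, averaged over three seeds. The experiments use the ANOVA
scorer for the reason documented above. At these sizes the whole
experiment (3 seeds end-to-end) completes in well under a minute per seed
on one CPU; test fixtures elsewhere use 300–400 genes and 12–25 samples
per class, which keeps the full suite in the tens of seconds.

## Numerical and degenerate-input conventions

- Expression files are validated completely before an object is built;
  duplicate ids, non-numeric cells and non-finite values are format errors
  naming the offender. Writers emit full-precision `repr` floats so
  write∘read∘write is byte-identical.
- A gene set disjoint from, or equal to, the measured universe is a
  degenerate-set error; zero surviving sets after filtering is a
  configuration error.
- Unlabeled samples are marked by an empty string ("NA" also accepted on
  read) and are dropped before any learning stage.
- The single-cohort 70:30 mode splits *before* balancing by default, so
  synthetic neighbours of test points cannot leak into training; the
  balance-before-split order is available behind an explicit flag for
  comparison with workflows that used it, with the leakage caveat
  documented.
- Model bundles (JSON metadata + npz parameter store) refuse to load on
  version or feature-vocabulary mismatch rather than predicting silently.

## Known limitations

- The regression-F default replicates an established workflow but is
  encoding-dependent for ≥3 classes; the ANOVA scorer is the statistically
  neutral choice and the two can select different feature sets.
- No normalized enrichment score or permutation null is computed: raw
  scores are the features, so scores are comparable across sets only
  through what the classifier learns, not calibrated individually.
- SMOTE interpolates in enrichment space and can place synthetic points in
  low-density regions of a non-convex class; borderline/ADASYN variants
  are out of scope.
- Training determinism is guaranteed per platform and thread count, not
  bitwise across BLAS implementations.
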