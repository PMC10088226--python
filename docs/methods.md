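# Methods

## The model

`tradervote` treats feature selection as a wrapper problem: the quality of
a candidate subset of k features is the accuracy of a classifier trained
on exactly those columns. The search space is the set of k-subsets of
{1..n}, and the optimizer is a population-based metaheuristic (Trader)
whose candidate solutions are integer index vectors. The final classifier
is a majority-voting ensemble of R models, each trained on the best subset
of one independent search run.

The fitness of a subset is the mean-based multiclass accuracy
Σᵢ TPᵢ / N of a support vector machine evaluated by internal stratified
k-fold cross-validation with predictions pooled into a single confusion
matrix. Pooling makes the accuracy formula apply unchanged for any number
of classes. The implicit assumptions are the usual ones for wrapper
selection: samples are exchangeable rows, features are real-valued after
preprocessing, and a subset that cross-validates well inside the training
data generalizes to held-out samples.

## Search algorithm

* **Encoding.** A candidate solution is a fixed-length vector of k
  distinct feature indices, 1-based internally. 1-based indexing matters
  for the retailing operator, whose perturbation
  Vⱼ ← Vⱼ + sign·U{0..Vⱼ} has the current value as its scale: index 0
  would be a fixed point. File output converts to 0-based positions.
* **Groups.** After the initial evaluation the population is randomly
  partitioned once into `n_groups` near-equal groups; masters and group
  finances are re-derived after every iteration. The default of 5 groups
  gives 20-member traders at the reference population of 100.
* **Operators.** Selected slaves undergo retailing or distributing with
  equal probability (`operator_mix`); selected masters trade with a
  uniformly chosen other master (importing–exporting). Position sets are
  drawn with per-position probability 1/k, minimum one position, so the
  expected change is a single variable — a deliberately minor move. With
  a single group a selected master has no trading partner and falls back
  to retailing, keeping the call budget exact.
* **Repair.** Out-of-range values are clamped to [1..n]; duplicates are
  replaced by uniform draws from the unused indices. This keeps k
  constant and is unbiased among unused features.
* **Acceptance.** A modified candidate replaces its originator only when
  its fitness is not worse. Elitist acceptance gives a provably
  non-decreasing best-so-far trace; a separate global-best archive
  protects the incumbent from destructive master trades.
* **Budget.** Exactly `pop + iterations · ceil(change_fraction · pop)`
  objective calls per run. Repeated subsets are served from a memoization
  cache but still count as calls, preserving budget-parity semantics
  between optimizers while saving wall clock. A uniform random search
  with the same call count is provided as the baseline comparator.

Default protocol: population 100, 50 iterations, 30 % of candidate
solutions changed per iteration. Tests and the acceptance script use
scaled-down populations (8–30) and iteration counts (2–20) chosen so each
check still has a non-trivial search space; the properties being checked
(budget exactness, monotonicity, oracle equivalence on enumerable
instances) do not depend on the protocol size.

## Preprocessing

Missing cells of a sample are completed from up to `max_neighbors = 10`
other samples that are complete and share Pearson r > 0.5 with it over
the jointly observed features (at least 3 shared positions; zero-variance
pairs are undefined and excluded). The imputed value is the
r-weighted mean of the neighbours' values in that column, which
degenerates to the neighbour's own value when only one qualifies. When
strict completeness leaves no neighbour, a second-chance pass accepts
samples complete only in the needed columns (recorded in the report);
when still none qualifies, the column mean over observed values is used
and the cell is flagged as a fallback. Samples are never dropped.
Normalization is (x − minⱼ)/(maxⱼ − minⱼ) per column; constant columns
map to 0. During cross-validation both the imputation neighbour pool and
the min/max statistics come from the training fold only; a `leak_compat`
mode preprocesses and selects once on the full table for comparability
with protocols that preprocess before splitting.

## Objective

SVM defaults: RBF kernel, C = 1, bandwidth by the standard "scale"
heuristic, 5 inner stratified folds. These are reproducible defaults, not
tuned values; both kernel and C are configurable. `inner_folds = 1` gives
resubstitution accuracy — a documented, leak-prone compatibility mode.
Fitness is invariant to index order within a subset and bounded in [0, 1].

## Voting and evaluation

Vote counts Fᵢ are the number of members predicting class i; prediction
is argmaxᵢ Fᵢ. Ties are broken by summing member fitnesses behind each
tied class (deterministic and quality-weighted), then by lowest class
index. The default ensemble is R = 5 Trader runs with distinct derived
seeds; random-search members can be mixed in for diversity studies.

Reported metrics come from one pooled confusion matrix over the outer
five folds. "Mean-based" SEN/SPC/PRE are macro one-vs-rest averages
(unweighted over classes, per-class value 0 when its denominator is 0);
F is the harmonic mean of macro precision and macro sensitivity; micro
variants are available by flag. Multiclass ROC/PR curves are macro
averages of per-class one-vs-rest curves interpolated onto the shared
grid of observed x-values (per-class step curves are first collapsed to
their upper envelope so vertical segments do not bias interpolation);
AUC is trapezoidal. For voting ensembles the class-i score is the vote
fraction Fᵢ/R, which quantizes the curve into at most R + 1 thresholds.

The Wilcoxon rank-sum comparison uses exact null enumeration when both
run sets have ≤ 10 values and no ties, and the normal approximation with
midrank tie correction otherwise (repeated runs of a strong optimizer
frequently tie at the optimum, where the exact distribution is not
available). Fully tied inputs have zero rank variance and are reported as
p = 1. Stability summaries are standard boxplot statistics (median,
quartiles, 1.5·IQR whiskers) of final fitnesses; convergence summaries
are element-wise means of best-so-far traces.

## Synthetic data

The generator emulates the benchmark tables' shapes (32–900 samples,
6–20,531 features, 2–16 classes, optional missing cells and binary
columns) with a controllable Bayes error and a defined ground truth.
Class centroids are distinct random sign patterns in the informative
subspace, rescaled so the minimum pairwise distance equals `class_sep`;
every informative coordinate is forced to split the classes, because a
coordinate on which all centroids agree would be labelled informative
while carrying no signal, making recovery metrics meaningless. Noise
columns are standard Gaussian, a configurable fraction thresholded to
{0, 1}; labels are balanced up to the remainder; missing cells are
planted uniformly without ever emptying a row or column. Preset missing
rate (3 %) and binary fraction (20 %) are fixed, field-plausible choices
for the presets whose real counterparts have those attributes.

What the generator does **not** emulate: feature correlations, batch
effects, label noise, class imbalance, and heavy-tailed marginals of real
clinical data. Passing tests therefore demonstrate algorithmic
correctness and recovery under controlled conditions, not clinical
performance.

## Numerical choices and degenerate inputs

* Retailing's random(0, Vⱼ) is an integer draw (index space), inclusive
  of both ends; δ = 0 leaves the variable unchanged.
* The importing set size is capped at the exporter's subset size.
* Constant columns normalize to 0; columns with no observed values are an
  error (no basis for imputation).
* Undefined correlations (fewer than 3 shared positions or zero variance)
  are signalled as NaN and treated as non-qualifying.
* Wilcoxon's exact/approximate switch is at n = 10 — exact where
  enumeration is cheap, standard approximation at the reference run count
  of 50.
* Sub-seeds derive from the global seed through a counter-mode
  `SeedSequence` path, so population init, operators, folds, members and
  the generator have independent reproducible streams.

## Known limitations

* With generous class separation many subsets tie at accuracy 1; the
  selected subset is then one of many optima and need not be the planted
  set (the README example shows this deliberately).
* At small budgets on small search spaces a budget-matched random search
  reaches similar optima, and the Wilcoxon comparison is frequently
  non-significant; the comparison harness is the deliverable, not a claim
  that Trader dominates on every instance.
* The accuracy landscape has resolution 1/N, so search progress stalls
  once candidate subsets differ by fewer than one pooled prediction.
* Only the Trader optimizer and the random baseline are implemented;
  other metaheuristics can be compared through the same budgeted
  objective interface.
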