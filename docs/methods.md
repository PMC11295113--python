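# Methods

This note records the modelling conventions, defaults and numerical
choices behind `codesel`, and what the synthetic experiments do and do
not establish.

## Hierarchies and depth

ICD-10-style hierarchies are table-driven (`code,parent,label` rows)
because block ranges such as `I20-I25` cannot be derived from a child
code string; ATC hierarchies are rule-driven by fixed-width prefix
truncation (7→5→4→3→1 characters).  Roots — ICD chapters, ATC
anatomical main groups — sit at depth 0 and each edge adds 1.  With
this origin the loss weight `w(F) = 1/(1+d(F))` assigns weight 1.0 to
the most general codes, which is the intended direction of the
depth adjustment: generality is rewarded.  Codes missing from a
hierarchy table are attached as depth-0 singleton roots with a logged
warning rather than rejected, because regional code extensions make
complete tables unrealistic in practice.

## Records

Aggregation windows are fixed day spans (90 or 180 days by default),
half-open intervals anchored at each patient's first event in the data
set; calendar-month arithmetic is deliberately avoided as
irreproducible across locales.  Windows with no events produce no row.
One-hot encoding adds every ancestor of every observed code (ancestor
closure) and orders columns by code string.  Train/test splitting
shuffles patient IDs with a seeded generator so every patient's rows
fall wholly in one partition; the split fraction refers to patients,
not rows.

## Selectors

All sample-graph constructions (Laplacian score, MCFS) build a binary
k-nearest-neighbour graph over **samples** with union symmetrization,
following the original formulations of those methods; a feature-graph
variant is intentionally not offered.  Binary matrices produce many
tied distances, so the neighbour tie rule is part of the contract:
among equidistant samples the lowest index wins.  Tie-breaking
everywhere else (argmax, ranking, k-means representatives) likewise
resolves to the lowest feature index.

**Laplacian score.** Features are degree-mean-centred and scored by
`(f̃ᵀLf̃)/(f̃ᵀDf̃)`; the `n_best` smallest scores are selected, and
stored negated so that "larger = more selected" holds across all
methods.  Constant features have zero denominator and are assigned the
worst score.  Edge weights are binary, the large-bandwidth limit of
the heat kernel.

**MCFS.** The generalized eigenproblem `Ly = λDy` is solved densely;
the trivial constant eigenvector is dropped and the next `n_eigvecs`
(default 5, unstated in the method's common usage regime but exposed)
are each regressed on the feature columns along a lasso-LARS path
capped at `l1_budget` (default `n_best`) active features, stopping at
the first path point that reaches the budget.  Both sides of the
regression are mean-centred (an implicit intercept) so an eigenvector
supported on one graph component relates symmetrically to a binary
feature and its complement.  Exactly duplicated columns make the lasso
solution non-unique; they are collapsed before the path and the group
coefficient is assigned to the group's first member, the
minimal-support extreme point of the solution set.

**AEFS.** A single-hidden-layer autoencoder (leaky-ReLU hidden, linear
output, squared error) with the group-sparsity penalty
`α · Σ_rows ‖W1_row‖₂` (α = 0.001) and Frobenius weight decay
(β = 0.1) over all layers.  Hidden width defaults to ⌈d/2⌉ capped at
256, 200 epochs, Adam at 10⁻³.  Because weight-row norms *are* the
scores, weights start from a small symmetric initialization (σ = 0.01)
so rows that never receive gradient (e.g. an all-zero column) stay
near zero instead of inheriting a large random norm.

**PFA.** Incremental PCA with ⌈d/2⌉ components and batch size 2d,
k-means with `n_best` clusters on the feature loading rows, one
representative per cluster (nearest the centroid).  Empty clusters
trigger a bounded re-seeded retry.

**Concrete autoencoder.** `n_best` selector neurons each hold a logit
vector over features; training samples Gumbel noise per example and
neuron, applies softmax at temperature `T(e) = 20 · (0.01/20)^(e/E)`
(exponential anneal from 20 to 0.01), and feeds the soft mixtures to a
2×64 leaky-ReLU decoder with sigmoid outputs under binary
cross-entropy; full-scale default is 1000 epochs, batch 64, Adam at
10⁻³.  After training each neuron commits to its argmax feature
without noise; duplicate choices collapse, so fewer than `n_best`
features can be returned — that duplication is a known property of the
method and is reported, not hidden.  With `weight_adjust`, each
feature's per-element BCE term is multiplied by its depth weight and
the sum is normalized by the **sum of weights** (not the feature
count), keeping the gradient scale comparable between the weighted and
unweighted variants; with all weights equal to 1 the two code paths
are bit-identical.  Logits are initialized from a small-variance
symmetric normal, seeded.

The neural components are implemented directly on numpy arrays with
manual backpropagation and Adam.  At the matrix sizes this package
targets (hundreds to a few thousand rows, ≤ a few thousand columns)
this is fast, dependency-light, and — because all randomness flows
from one `numpy.random.Generator` — bit-reproducible from the seed.

## Evaluation

The reconstruction decoder is 2×64 leaky-ReLU with 10% inverted
dropout and sigmoid outputs, trained 100 epochs (batch 64, Adam 10⁻³)
with early stopping on a loss plateau (patience 10, min-delta 10⁻⁵).
The mode baseline predicts each feature's training majority value;
exact 50/50 ties break to 0, the majority regime of sparse code data.
For the baseline's cross-entropy the clipped training frequency is
used as its predicted probability (a hard 0/1 constant would have
infinite BCE); this convention is the package's own.  Method and
baseline accuracies are compared with a paired two-sided t-test across
features (they are measured on the same columns); a Welch variant is
available by flag.  Zero-variance difference vectors are degenerate
and reported with a flag (p = 1 if all differences are zero, p bounded
by machine-tiny otherwise).  A feature-wise standard error can be
derived from the reported per-feature vectors; no bootstrap interval
is offered.

## Case study

Minority upsampling duplicates minority rows with replacement until
classes balance.  The XGBoost grid is fixed and documented: depth
{3,5,7}, learning rate {0.05,0.1,0.3}, trees {100,300}, min child
weight {1,5}; seeded stratified 5-fold CV maximizes ROC AUC, ties keep
the earliest grid point, folds shrink if a class is smaller than the
fold count.  The classification threshold for accuracy/F1/McNemar is
0.5.  DeLong's test is implemented from placement values (midranks)
with the normal two-sided p; McNemar switches from the exact binomial
to chi-square with continuity correction at `b + c ≥ 25` discordant
pairs.  Shapley attributions use the booster's exact tree-path
algorithm on the margin scale; per-feature importance is the mean
absolute attribution over test rows.  Depth and importance profiles
between methods use Welch t-tests (selections differ in size) against
a configurable reference method, `caeww` by default.

## Synthetic data

The generator emulates the structural features the pipeline assumes:
hierarchical codes (balanced tree, path-encoded names so depth is
verifiable from the string), patients carrying latent comorbidity
factors (Bernoulli activation, default 0.35) that emit fixed sets of
leaf codes with per-record emission probability 0.9, record dates
spanning multiple aggregation windows, optional deterministically
co-firing sibling codes, independent noise codes (rate 0.01/leaf), and
a rare outcome (default prevalence 5%, the middle of the 1–6% regime
of administrative mortality data) generated from a sparse logistic
model whose intercept is calibrated by bisection to the target
expected prevalence.  Outcome codes fill consecutive factors starting
from the first, modelling an outcome driven by one comorbidity
cluster; concentrating the signal this way gives the planted-recovery
experiments a clearly identifiable target.

What the generator does **not** reproduce: real marginal code
frequencies, inter-factor dependence, coding-practice drift over time,
or any clinical semantics.  Passing recovery experiments therefore
demonstrate correctness of the machinery — that each method finds
structure it is designed to find, at desk scale — not clinical
performance on real claims data.

## Experiment problem sizes

The recovery experiments run the concrete autoencoder for 200 epochs
on 512–1024-sample fixtures (the package's reduced-scale setting; the
full-scale default is 1000 epochs), the outcome case study on ~5000
aggregated records from 1500 patients with a reduced CV grid, and the
demo benchmark on 150 patients with 60-epoch autoencoders.  These
sizes were chosen so the whole suite runs in a few minutes on one CPU
while leaving each effect comfortably detectable.

## Known limitations

* The Laplacian-score/MCFS dense eigen-solvers scale as O(n²)–O(n³)
  in samples; beyond ~10⁴ rows a sparse eigensolver would be needed.
* The concrete autoencoder offers no duplicate-penalizing regularizer;
  when several neurons converge to one feature the selection simply
  shrinks.
* Outcome labels are attached per aggregated row; no survival-time or
  registry-linkage semantics are modelled.
* The benchmark's comparison report is deterministic per master seed,
  but XGBoost determinism relies on single-threaded training
  (`n_jobs=1`), which is the configured default.
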