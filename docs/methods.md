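# Methods

This note documents the statistical model, the algorithmic choices, and the
limits of what the test suite demonstrates.

## Data model and pre-processing

An `ExpressionMatrix` is a genes × samples array of signal intensities (or
relative RNA concentrations after conversion) with a boolean usability
mask.  The mask is the only channel through which flagged spots,
out-of-range intensities and missing cells propagate; no operation ever
turns a masked cell back on.  Spot-quality calls ("non-uniform" spots) are
made by scanner software and cannot be recomputed from a value matrix, so
they enter as an externally supplied flag matrix.

Pre-processing runs in a fixed order: linear-range flagging → spike-in
conversion → median normalization → presence filtering.

* **Spike-in conversion.**  Per array, ordinary least squares of
  log(known concentration) on log(observed spike-in intensity); every
  usable value x maps to exp(α + β log x).  Non-positive intensities are
  masked before fitting; fewer than two usable spike-ins on an array is an
  error naming the array.
* **Median normalization** divides each array by the median of its usable
  values (even-length medians average the central pair), so each array's
  usable median is exactly 1 afterwards.
* **Presence filtering** keeps a gene when it is usable on at least
  ⌈f·n⌉ arrays.  The ceiling makes f = 0.5 on 248 arrays the familiar
  "present on at least 124 arrays" rule.  Steps 3–4 are idempotent on
  their own output.

Classifiers need dense input; masked cells are mean-imputed per gene at the
classification boundary only (statistics always honour the mask).

## Random-variance test

The hierarchical model treats each gene's true variance as drawn from an
inverse-gamma prior, parameterized so the precision is Gamma(a, scale b).
Given residual variance s² on ν df (ν s²/σ² ~ χ²ᵥ), the shrunken estimate

    s̃² = (ν s² + 2/b) / (ν + 2a)

replaces s² in the one-way F statistic, whose null reference becomes
F(K−1, ν+2a); the two-class statistic is the squared moderated t.  The
marginal law a·b·s² ~ F(ν, 2a) gives the prior fit: the product of marginal
densities is maximized over (log a, log b) by Nelder–Mead from a
moment-based start.  Degenerate inputs (no spread in s²) fall back to an
essentially flat prior (a = 10⁻⁶, b = 10⁶) with a warning.  As a → ∞ with
the prior mean pinned, the statistic reduces to the ordinary F with a known
variance — used as a closed-form check in the tests.

## Multivariate permutation filter

For each comparison the filter computes observed p-values, then p-values
under R random relabelings (all distinct relabelings, enumerated, when
their number is below both R and 20,000).  It selects the largest cutoff
α* — searched over the observed p-values, where the count function changes —
such that the configured quantile (default 0.99) of #{permuted p ≤ α*} is
at most the allowed number of false positives (default 10), and returns the
genes with observed p ≤ α*.  The quantile uses the conservative "higher"
interpolation.  Genes untestable under the observed labels (fewer than 2
usable values in some class) are excluded outright; a gene-permutation pair
that becomes untestable contributes p = 1.  The variance prior is fitted
once on the observed labelling and reused across permutations: its inputs
(pooled within-class variances) are only weakly label-dependent, and a
fixed prior keeps the permutation null exchangeable.  Desk-scale default is
1,000 permutations (200 in the repeated-null validation runs); the
historical full-data protocol used 10,000, which is a `n_permutations`
setting away.

The comparison suite builds, per treatment compound, one pooled two-class
comparison (controls vs that compound, other compound excluded — the
ambiguity of "pooled" is resolved explicitly in the suite descriptor) and
one multi-class concentration-series comparison per experiment block.
Permutations stay within each comparison's sample subset.  The union list
records per-comparison membership for overlap summaries.

## Tree-based selection and the weight of significance

The learner suite spans the design axes that distinguish classical
decision-tree algorithms — split criterion (Gini / information gain),
cost-complexity pruning, best-first growth with a node budget, minimum leaf
size, and per-split feature subsampling — each crossed with bagging
(bootstrap + majority vote) and AdaBoost.M1 (reweighting + weighted vote,
early stop at member error 0 or ≥ ½).  The default grid is the full
6 configs × 2 ensemble modes = 12 models with 25 members each.  Two points
of rationale:

* Twelve diverse models, not fewer: classifier genes are the union of
  decision-node genes over all models, and greedy trees concentrate on a
  few dominant genes when the discriminative genes are correlated.  With a
  small suite the union can collapse to a couple dozen genes; the
  random-subspace configs (per-split `max_features`) deliberately spread
  the selection across interchangeable correlated genes, which is what a
  suite of genuinely different algorithms achieves in the original
  protocol.
* Model accuracy Aₘ comes from deterministic stratified 10-fold CV (pooled
  test-fold accuracy) on the training data, on the [0, 1] scale.

Positional weights: within one tree, a gene's weight is (L − d)/L where d
is the depth (in decision-node levels, root = 0) of its *shallowest*
occurrence and L the number of decision levels on the longest root-to-leaf
path — the simplest form satisfying "root largest (= 1), deepest smallest,
normalized to the longest path".  Multiple occurrences take the maximum,
ensemble members are averaged (absent member ⇒ 0) so w ∈ (0, 1]; boosting
iterations are not additionally weighted by their AdaBoost coefficients
(model accuracy already enters the overall weight).  The decay function is
a pluggable policy.  The overall weight W(g) = Σₘ Aₘ·w(g,m) is summed over
models (one term per model), giving the bound W(g) ≤ Σₘ Aₘ, and genes are
ranked by W descending with ties broken by gene identifier.  A hook accepts
externally supplied per-gene weights for learners that assign their own
(e.g. logistic-model trees).

## Refinement

Two evaluators score a gene set:

* **MC-SVM** — one linear soft-margin SVM per unordered class pair (libsvm's
  SMO solver, C = 1 default), features standardized with training-fold
  statistics, pairwise-vote prediction with ties going to the larger
  training class then lexicographic.  Accuracies come from pooled
  stratified CV test folds; the fold split is fixed once per curve so
  successive prefixes differ only in the gene set.
* **Clustering** — K-means (k = K classes, k-means++, best of 50 restarts)
  on per-gene standardized expression of the full data; clusters map to
  classes by the Hungarian assignment maximizing matched samples, making
  the confusion matrix invariant to cluster numbering.  No train/test split
  is meaningful for unsupervised matching, so accuracies are full-data.

The accuracy curve records per-class and class-size-weighted accuracy as
genes are added in rank order.  The prune pass computes, for each gene at
position k ≥ 2, the change in each of those series between prefixes k and
k−1, and removes — scanning bottom-up — every gene whose deltas are *all*
strictly negative; zero changes keep a gene, and the top-ranked gene is
never removed.  Curve and prune alternate until a pass removes nothing;
since per-class counts are discrete, exact-zero deltas are common at small
sample sizes and the rule is therefore deliberately conservative — on
desk-scale simulations it removes a minority of null genes rather than
collapsing the list, and when accuracy saturates at 100% it removes nothing
at all.  The refined set is always a subsequence of the input ranking and a
fixed point of the procedure.  SVM- and clustering-refined sets combine by
union (SVM order first) and intersection.

## Evaluation conventions

Confusion matrices put true classes in rows.  Accuracy (recall) divides the
diagonal by row sums, precision by column sums; weighted averages weight by
*true* class sizes for both (this is the convention under which the
weighted accuracy equals overall fraction correct, and the one consistent
with the reference tables' printed weighted precision).  ROC areas are
one-vs-rest via the midrank Mann–Whitney statistic; the clustering
evaluator reports no ROC (no per-class scores exist).  Report percentages
round half-up to 1 decimal.  Stratified folds are deterministic: within
each class, samples sort by a seed-keyed SHA-256 of their identifier and
deal round-robin, so fold proportions are within one sample of global
proportions and runs are exactly repeatable.  Nested CV re-runs every
data-dependent choice inside each outer training fold and pools outer-fold
test predictions into a single confusion matrix.

## Synthetic data

The generator emulates a soil-exposure microarray experiment: treatment
groups of class × compound × concentration × duration with replicate
animals; per-gene variances σ²_g with precision ~ Gamma(a, b) (defaults
a = 3, b = 1, matching the random-variance assumption; mean σ² = 0.5 on the
log scale); log-normal intensities exp(N(μ₀ + δ, σ²_g)) with baseline
μ₀ = 7 (≈1,100 intensity units); planted discriminative genes shifted by
`effect_size` (default 1.5 natural-log units ≈ 4.5-fold, about 2 SD at the
typical gene variance — a strong but realistic responder) in their target
class; spike-in probes on a configurable log-log standard curve with 5%
log-normal noise; spots missing independently at 5%.  The default design is
a scaled-down study: 12 groups × 8 replicates = 96 arrays (16 control / 40
TNT / 40 RDX), 2,000 genes, 30 planted per compound; `study_scale_design`
reproduces the full 31 × 8 = 248-array layout with 32/96/120 class sizes.
A single seed drives per-gene substreams (`SeedSequence` spawn keys), so
growing the gene count never reshuffles earlier genes' draws.

What the generator does **not** model: concentration-dependent effect
sizes, gene–gene correlation beyond the shared class structure, probe
sequence effects, dye chemistry, spatial artifacts, or batch effects
between experiment blocks.  Passing recovery tests therefore demonstrate
the pipeline's behaviour under its own distributional assumptions, not
performance on real arrays.

## Problem sizes and numerical choices

Validation runs use desk-scale sizes chosen so the full suite completes in
minutes: 2,000-gene × 96-array pipelines, 200–1,000 permutations, 100
repeated null datasets for the false-positive bound, 500-gene × 90-sample
nested CV.  Tolerances: the prior fit is accepted within [2.4, 3.6] on a
and 20% on b for InvGamma(3, 1) at 5,000 genes; null calibration within
[0.035, 0.065] for the fraction of p < 0.05; K-means uses 50 restarts
(fewer in fast tests); SVM dual solutions agree with a direct QP solve to
1e-6 on toys.  Ties everywhere break deterministically (gene identifier for
ranks, class prevalence then name for votes), and every stage's randomness
derives from a named SHA-256 fan-out of the single run seed, so identical
(config, seed) runs are bit-identical.

## Known limitations

* The positional-weight form (L − d)/L is one defensible reconstruction of
  "root largest, leaf smallest, normalized to the longest path"; the decay
  policy is pluggable precisely because the original algebra admits
  variants (e.g. height counted from the leaves, summing repeated
  occurrences).
* The strict all-declines prune rule interacts with accuracy granularity:
  with few samples per class many deltas are exactly zero and little is
  removed; with large sample sizes it removes aggressively.  Size of the
  refined set is therefore strongly scale-dependent.
* The clustering evaluator's accuracy is a full-data matching quantity, not
  a generalization estimate, and is expected to be much lower than the
  SVM's on weakly separated classes.
* Real-data headline numbers from the motivating study (e.g. 869
  significant genes, 354 classifier genes, 39/30/11/58 refined set sizes)
  depend on the original dataset and toolchain and are not desk-scale
  reproduction targets; the package reproduces the study's *metric* values
  exactly from its printed confusion tables and validates the procedures
  on synthetic data.
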