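# Methods

`netmark` identifies *subnetwork markers*: connected sets of genes in a
protein–protein interaction (PPI) network whose joint expression separates two
phenotype classes (cases vs. controls), even when individual members are not
differentially expressed.  This note records the model, the numerical
choices, and the reasoning behind the design decisions that were genuinely
open.

## Data model

The substrate is a genes × samples real matrix of pre-normalized expression
values with a two-class sample labelling, plus an undirected simple graph
over gene identifiers.  Probe-level inputs are collapsed to genes by
arithmetic averaging of all probe rows mapping to the same gene id, on the
provided scale (values are assumed already summarized and quantile
normalized; a classical quantile-normalization utility is included but off
by default).  Genes present in only one of expression/network are dropped
from the search space with logged counts — nothing is imputed.

## Subnetwork scoring

Each gene row is standardized to mean 0, sd 1 (sample sd, ddof = 1) across
all samples; constant genes become all-zero and are flagged.  The *activity*
of a gene set is, per sample, the arithmetic mean of its members' z-scores.
For **scoring**, the default aggregation is the *oriented* mean: each
member's z-profile is flipped, if necessary, so its class-mean difference is
non-negative, then averaged.  Disease modules routinely mix up- and
down-regulated members; with a plain mean those members cancel and the
module is invisible to any activity statistic, whereas the oriented mean
makes the module's joint signal additive.  Orientation is re-derived from
whatever labelling is being scored (observed or permuted), so permutation
nulls remain process-matched, and it leaves single-gene scores unchanged
(mutual information is invariant to a sign flip).  Plain `mean` and the
√size-normalized `sqrt_sum` remain configuration options.

The discriminative score is the plug-in mutual information, in bits, between
the discretized activity and the class label: equal-width bins spanning the
observed activity range, bin count = Sturges ⌊log2 n⌋+1 by default
(configurable), MI = Σ p(b,c) log2 [p(b,c)/(p(b)p(c))], with 0 log 0 = 0 and
constant activity defined as 0 bits.  MI is non-negative and bounded by the
label entropy (≤ 1 bit for two classes), a fact several stopping and
saturation behaviours below inherit.

## Greedy seed expansion

One search starts from every gene present in both the network and the data.
Starting from {seed}, every measured gene adjacent to the current member set
and within `max_distance_from_seed` (default 2) hops of the seed is
evaluated; the candidate with the largest resulting MI is added, ties broken
by lexicographically smallest gene id.  Growth stops when the best *relative*
gain falls below `min_improvement_rate` (default 0.05), when
`max_subnetwork_size` (default 10, matching the observed 1–10-gene range of
real modules) is reached, or when candidates run out.  The search is fully
deterministic; all randomness in the pipeline lives in the permutation
filter and the resampling design.

## Three permutation filters

A candidate is significant only if all three one-sided tests give
p ≤ α (default 0.05), each with `n_permutations` (default 100) draws and the
add-one estimator p = (1 + #{null ≥ observed}) / (1 + n_permutations), which
cannot return 0.  Configurations where p can never reach α
(n_permutations < 1/α − 1) are rejected.

1. **Gene null** — the member set's z-rows are replaced by equally many
   random rows; tests whether these particular genes beat arbitrary genes.
2. **Label null** — class labels are permuted.  By default the greedy search
   is *re-run from the candidate's seed under each permuted labelling* and
   the searched score is the null draw.  This selection-matching is the
   load-bearing choice: the observed score is a greedy maximum, and
   comparing it against un-maximized nulls is badly anti-conservative, with
   a pure-noise retention rate far above the nominal level (the bundled
   calibration check measures the matched filter's actual rate).  With
   matched re-search the observed and null scores are
   exchangeable under the null and the filter's type-I error sits at the
   nominal level.  One permuted labelling per draw is shared by all seeds of
   a run, keeping the cost at `n_permutations` search passes; a cheap
   score-level variant (`label_null_mode="score"`) remains available.
3. **Random-subnetwork null** — uniform random connected subgraphs of the
   same size (grown by seeded random frontier expansion — approximately
   uniform, exact uniformity over connected subgraphs is not tractable),
   scored on the unpermuted data; tests whether the topology matters.

Null streams are seeded independently per candidate (gene/random nulls, via
a CRC of the seed gene id) or per run (label null), so results are
bit-identical regardless of candidate evaluation order.

## Resampling consensus

To balance class sizes, case samples are split into two random halves and
each half is merged with the *full* control set; with R resamples and K
filter repetitions per merged dataset this yields 2·R·K runs (defaults R=5,
K=4 → 40 runs at study scale; the recovery tests use R=K=2).  The greedy
search is deterministic given the merged dataset, so the K repetitions
differ through the permutation filter's seeds only; candidates are computed
once per half and re-filtered per run.

Runs are first grouped by exact member-set equality.  Because the same
underlying module is typically recovered with one member swapped or tagged
on between patient halves, exact identity splits a real module's count
across near-identical variants and lets trivially stable one- and two-gene
sets win the frequency ranking.  The default consensus therefore *pools*
groups at Jaccard ≥ 0.6 (scanning in rank order, comparing against the
cluster's founding set), reports the weighted member-wise majority of the
cluster's variants (weight = each variant's run count; genes present in at
least two-thirds of the weight, which prunes one-off tag-along members
while keeping consistently recovered ones), counts frequency over the
**union** of runs
containing any variant (never exceeding the run count), and scores the
cluster by the weighted mean of variant scores.  Strict exact-identity
consensus is available with `jaccard_merge=None`.  Ranking is frequency
desc, mean score desc, lexicographic member list; selection is `top_k`
(default 19) or `min_frequency`.

## Classification evaluation

Features are subnetwork activities (plain mean of member z-scores — tree and
RBF accuracy is invariant to per-feature sign, so orientation is unnecessary
here) or per-gene z-scores for gene-list signatures.  Accuracy is estimated
by k-fold cross-validation (default 10 folds, shuffled, unstratified —
folds of near-equal size; a stratified option exists) with two dissimilar
classifiers:

- **tree** — an entropy-criterion decision tree (scikit-learn CART,
  `min_samples_leaf=2`, seeded);
- **rbf** — a radial-basis-function network built from scikit-learn
  primitives: k-means centers (min(10, ⌊√n_train⌋)), Gaussian hidden units
  with a shared width equal to the mean pairwise center distance, and a
  linear-logistic output layer.

Cross-testing trains on one patient half (merged with controls) and scores
the other; per-gene standardization parameters are learned on the training
set only and applied unchanged to the test set, which a construction test
verifies with a shifted test distribution.

## Differential-expression baseline

Per-gene Welch (unequal-variance) two-tailed t-tests (a pooled-variance flag
exists); DE flag = raw p < 0.05, deliberately uncorrected — this baseline
mirrors how single-gene signatures are conventionally drawn, and the
comparison, not the inference, is the point.  Ranks order by ascending p,
ties by descending |t|, then gene id.  The top-k genes (k = 100/200 at study
scale) feed two-way hierarchical clustering: complete linkage on
1 − Pearson correlation, genes clustered over all samples and samples over
the selected genes.  Misclassification is formalized as cutting the sample
dendrogram into two clusters at the highest merge and assigning each cluster
its majority label (ties → the cluster with more cases is "case"); the
per-class minority members are the errors.  Dendrograms serialize to Newick
with merge heights as branch lengths.

## Synthetic data

The generator emulates the statistical structure the analysis assumes — not
any particular microarray platform:

- **Interactome**: Barabási–Albert preferential attachment
  (m = round(mean_degree/2); heavy-tailed like curated PPI networks) or
  Erdős–Rényi G(n, p); smaller components are bridged to the giant one with
  single random edges so modules are always placeable.  Defaults: 300 genes,
  mean degree 4.
- **Modules**: vertex-disjoint connected sets of exactly `module_size`
  (default 5) grown by seeded random frontier expansion;
  ⌈connector_fraction·size⌉ members (default 0.2 → 1) are *connectors* with
  effect exactly 0; remaining members get ±`effect_size` with signs drawn
  per gene, so modules mix up- and down-shifted members like real ones.
- **Expression**: value(g,s) = μ_g + effect(g)·1[case] + ε with
  μ_g ~ N(0,1), ε ~ N(0, noise_sd=1); defaults 50 cases + 50 controls.
  Effect sizes are therefore in within-class SD units.

All stages draw from independent streams derived from one seed, so outputs
are bit-identical per configuration.  What the generator does *not* model:
batch and lab effects, probe-level noise, intensity-dependent variance,
correlated background expression (co-expression that does not follow the
network), or class-imbalance pathologies beyond what the user configures.
Passing recovery tests on this generator shows the machinery behaves as
designed under its own assumptions, not that real interactomes and arrays
satisfy those assumptions.

## Problem sizes in the checks

The bundled end-to-end checks run at desk scale, chosen so each scenario
still exercises the full pipeline: recovery uses a 300-node network with one
planted 5-gene module at effect 2 SD, n = 50/50, R = K = 2 (8 runs);
type-I calibration uses 200-gene pure-noise datasets at 40/40 with 100
permutations; classification checks use effect 3 SD.  Study-scale runs
(tens of thousands of genes, 40 runs) use identical code paths and scale
linearly in seeds × permutations.

## Known limitations

- The plug-in MI estimator is biased upward for small samples and many bins;
  the selection-matched label null absorbs this bias in testing, but
  reported scores remain optimistic point estimates.
- Greedy search with a relative-gain stop interacts with MI saturation
  (MI ≤ 1 bit): once a set scores near the label entropy, genuinely
  informative additions show tiny relative gains and growth stops — full
  recovery of large planted modules relies on the consensus pooling, not on
  any single search.
- The random-subnetwork sampler is approximately, not exactly, uniform over
  connected subgraphs.
- Consensus pooling at Jaccard ≥ 0.6 can, in principle, report a majority
  member set that induces a disconnected subgraph (if variants disagree on a
  bridging gene); the representative subnetwork attached to each group is
  always a genuinely searched, connected set.
- No multi-class phenotypes, edge weights, covariate-balanced splitting, or
  multiple-testing correction of the DE baseline.
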