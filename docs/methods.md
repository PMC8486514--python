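# Methods

## Problem setting

Two-class classification of high-dimensional small-sample data: a labeled
matrix Z = {(x₁, y₁), …, (x_n, y_n)} with n in the tens and p (features)
in the thousands, the typical shape of microarray or bulk expression
studies. The goal is a small, accurate and *stable* feature subset:
selections should not change wholesale when the training set is perturbed.

## The ensemble and its OOB bookkeeping

Each of m trees (default m = 200) is trained on a bootstrap sample of size
n drawn with replacement; the samples never drawn form that tree's
out-of-bag (OOB) set — in expectation a fraction (1 − 1/n)ⁿ ≈ 36.8% of the
data — and the tree's OOB accuracy C_i is computed on them. All bootstrap
draws, tree seeds and permutations derive from one integer seed, and the
fit operates in a canonical row order (samples sorted by id), so results
are bit-reproducible and invariant to how input rows are arranged.

Two base learners share this contract:

- **plain_forest** — CART trees (Gini, no pruning) on raw features with
  per-node √p feature subsampling; the standard random-forest baseline.
- **random_bits_forest** (default) — a simplified random-bits forest with
  the three published ingredients: a randomized intermediate
  representation, boosting, and bagged trees.

### Random bits

A pool of `n_candidate_bits` (default 1024) binary features is generated
from the training matrix. Each bit thresholds a random sparse linear
combination of 1–3 raw features (Gaussian weights) at a random quantile
(20th–80th percentile) of its training distribution, so every bit splits
the training set non-trivially. Features are dealt to bits by shuffled
round-robin rather than iid sampling: with iid draws at p = 2000 roughly a
third of the features would never enter the pool at all, making their
measured importance structurally zero; round-robin dealing guarantees
pool coverage whenever slots allow while keeping bit composition random.

### Per-tree boosted bit selection

Each tree keeps `n_selected_bits` (default 128) bits chosen by greedy
gradient boosting of one-bit stumps (second-order/Newton gains, L2 = 1 on
leaf values, ties to the lowest bit index) **on that tree's own bootstrap
sample**, within a random candidate subspace of 2 × `n_selected_bits`
pool bits. Selecting bits per tree rather than once per ensemble is a
deliberate design choice: a single shared 128-bit representation exposes
at most ~384 raw features to the whole ensemble, so permutation importance
is exactly zero for every other feature and elimination among those
zero-ties is arbitrary. Per-tree selection (diversified by the bootstrap
and the subspace) spreads coverage across the pool, mirrors the bagged
structure of the original architecture, and in our experiments roughly
doubles end-to-end recovery of planted features. The selection pass is
vectorized across trees in float32 — only the argmax of the gains is
consumed, which is insensitive to that precision.

## Permutation importance

For tree i and feature f, the feature's values are permuted among the
tree's OOB samples only (preserving the OOB marginal distribution) and
the OOB accuracy C_i^f recomputed; then

    E_i^f = C_i − C_i^f,   E^f = mean_i E_i^f,
    S² = Σ (E_i^f − E^f)² / (m − 1),   fip = E^f / S.

When S = 0 (no tree's accuracy moved), fip is defined as 0: no measured
influence. Trees with an empty OOB set are excluded from the average. One
fresh permutation per (tree, feature) pair is drawn, keyed
deterministically on (seed, tree index, feature index, repeat) through a
counter-based splitmix64 hash — constructing a generator object per pair
dominated runtime at p in the thousands. An averaging option
(`n_permutations`) exists; the default is a single permutation.

Exactness shortcut: a permuted feature can only change a tree's prediction
through a split the tree actually has — for plain forests, a split on the
feature itself; for the bits variant, a split on a selected bit that reads
the feature. For all other (tree, feature) pairs C_i^f = C_i exactly and
no re-evaluation is performed. This is an identity, not an approximation.

## Feature clustering

Features (as vectors across samples) are clustered by K-means under the
correlation distance D_ij = 1 − r_ij. Implementation: standardize each
feature vector to zero mean and unit sample SD and run ordinary Euclidean
k-means++ (one initialization, seeded), using the identity
‖u − v‖² = 2(n − 1)(1 − r) for standardized u, v — an exact monotone
embedding of the correlation distance, verified numerically to 1e-9 in the
tests. Constant features are defined to have distance 1 to everything
(correlation 0) with a warning rather than crashing. The default cluster
count is ⌈√p⌉ for p active features and is fully configurable.

## The elimination loop

Per round: fit the ensemble on the active features, compute fip for all of
them, score each cluster by its best member (max), and delete the
⌈drop_fraction × #clusters⌉ lowest-scoring clusters (default 10%) with all
their members. When fewer than `switch_threshold` (default 30) clusters
remain, deletion switches to individual features: the
⌈feature_drop_fraction × #features⌉ lowest-fip features are dropped per
round. The loop never deletes past `target_features`; a batch that would
overshoot is trimmed, worst scores first. Ties anywhere break
lexicographically on feature id, making runs fully deterministic.

By default the feature partition is computed once and carried through the
loop (deleted members removed) — re-clustering every round is available
via `recluster_each_round` but costs a K-means per round and changes
little in our experiments. The ensemble *is* refit every round, so
importances always reflect the surviving feature set.

The output is a full ranking of all p features: survivors ordered by
final-fit fip, then eliminated features in reverse deletion order (later
deletions were judged more important), within a batch by fip at deletion.
The selected subset is the top `target_features` of that ranking.

## Stability metrics

For two ranked lists of common length k, δ_t is the symmetric difference
of the top-t prefix *sets* divided by 2t, and IM = mean over t = 1..k of
δ_t; sim_IM = 1 − IM ∈ [0, 1]. Unequal-length lists are an error (an
explicit truncation helper exists) — silent truncation hides protocol
bugs. A stability report truncates a collection of rankings to top-k and
averages pairwise sim_IM over the strict upper triangle.

The selection priors are P(identical k-subsets) = 1/C(m, k) and
P(overlap ≥ 1) = 1 − C(m−k, k)/C(m, k) (1 when 2k > m), computed in log
space via lgamma so m in the tens of thousands neither overflows nor
loses monotonicity. Both are verified against exhaustive enumeration for
small m in the tests.

## Evaluation harness

Repeated stratified holdout: per repeat (default 10), 2/3 of each class
trains, 1/3 tests; each method ranks features on the training split; the
ensemble is refit on the selected top `target_features` and scored on the
test split; rankings feed stability curves at each k in a grid. Splits are
stratified because with n in the tens an unstratified 2/3 draw regularly
loses a class. The final classifier is the same ensemble family refit on
the selected features, so accuracy differences reflect the selection, not
a change of model class.

## Synthetic data

The generator emulates the shape of classic two-class microarray
benchmarks (defaults: 60 × 2000, 20 informative features, 50 correlated
blocks). Each feature is sqrt(ρ)·block_factor + sqrt(1−ρ)·noise (Gaussian,
ρ default 0.6), giving exact expected within-block correlation — the
feature redundancy that makes selection unstable. Labels are Bernoulli
(balance 0.5); class-1 samples get a mean shift of effect_size × noise_sd
(default 1.5) on the informative features, which sit in distinct blocks.
It does **not** model microarray-specific noise (intensity-dependent
variance, batch effects, heavy tails), so passing tests demonstrate
correct mechanics and behavior under idealized Gaussian redundancy, not
performance on any real platform.

## Problem sizes used in tests and the acceptance script

Chosen as the smallest sizes at which each property is clearly exercised:
bootstrap fraction at N = 1000 over 500 replicates; intersection-metric
oracle checks over 500 random pairs (k ≤ 8, alphabet 12); embedding
identity over 1000 vector pairs; importance separation at 60 × 500 with 10
planted features over 10 seeds; end-to-end recovery at 60 × 2000 with 20
planted features (10 seeds in the test suite, 5 in the acceptance script);
stability trend from the harness on null data (60 × 150, effect 0, two
seeds × 10 repeats × 2 methods). The stability-trend claim is a statement
about (near-)random selection overlap, so it is evaluated on null data
where rankings behave like random permutations; on strongly-informative
data the curve can legitimately dip once k exceeds the planted signal.

## Known limitations

- Binary classification is the tested path; multiclass fits fall back to a
  slower per-tree boosting loop and one-vs-rest stump gains.
- Permutation importance is marginal: correlated proxies of an informative
  feature can inherit importance (visible in the examples, where a
  block-mate of a planted gene occasionally enters the top 10).
- The bits representation gives each fit a sparse view of very
  high-dimensional inputs; recovery relies on fresh bit pools across
  elimination rounds.
- `fip` compares only features the ensemble could see; a feature can score
  0 in one round and positively the next. The elimination log records the
  score at deletion time, not a globally comparable quantity.
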