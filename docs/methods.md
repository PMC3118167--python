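# Methods

## Structure model and graph construction

Input records are sequence/structure pairs: an RNA (or DNA; T is mapped
to U) sequence and a pseudoknot-free Vienna dot-bracket string of equal
length, as produced by single-structure folding tools (UNAfold/mfold CT
output is also read, with the dot-bracket reconstructed from the
pairing column and crossing or asymmetric pairings rejected).  Records
shorter than 5 nt are rejected; `N` bases are allowed because no
feature uses base identity.

The graph of a length-*n* structure has nodes 1…*n* (1-based, matching
CT numbering), backbone edges (i, i+1) and one edge per base pair.  By
construction it is connected and simple with maximum degree 3; when the
minimal hairpin-loop length is ≥ 2 — true of all folding output — it is
also triangle-free, which forces transitivity = 0, girth ∈ {0, 4, 5, …}
(0 is the acyclic sentinel), coreness ≤ 2 and zero counts for the
triangle-containing 4-node motif classes.  These specializations are
asserted, not assumed: feature extraction raises on disconnected or
triangle-containing graphs.

## The canonical 24 features

Per-node, per-edge and per-pair quantities are reduced to population
mean and population variance (ddof = 0).  The original 18-parameter
inventory expands to exactly 24 values: four parameters (degree, node
betweenness, edge betweenness, Burt's constraint) contribute a
mean/variance pair, the shortest-path-length multiset contributes its
mean and variance, the motif census contributes three counts, and the
remainder contribute one value each.  Closeness is summarized by its
mean only; cocitation and bibliographic coupling are identical on
undirected graphs but both are kept for fidelity to the original
inventory (their equality is a tested invariant).  The fixed name order
in `hairpinnet.FEATURE_NAMES` is part of the public contract.

Numerical conventions, chosen once for determinism:

* **Betweenness** — unnormalized Freeman betweenness, fractional
  counting over tied shortest paths, endpoints excluded for nodes and
  included for edges.
* **Closeness** — (n−1) / Σ d(v, u).
* **Hub score** — the Perron eigenvector of the adjacency matrix,
  scaled so its maximum entry is 1, computed by dense symmetric
  eigendecomposition.  The generic HITS formulation (principal
  eigenvector of A²) is ill-defined on bipartite graphs, where A² has a
  degenerate leading eigenspace; the Perron vector of A is unique for
  every connected graph and agrees with HITS whenever HITS is
  well-defined.
* **Cocitation / bibliographic coupling** — mean common-neighbour count
  over all unordered distinct node pairs, zeros included.
* **Modularity** — Newman–Girvan Q of the partition found by greedy
  agglomerative (CNM) merging from singletons, tracking the best Q
  along the merge path.  Ties in ΔQ are broken toward the
  lexicographically smallest pair of community labels (a community is
  labelled by its smallest member node), making the detected partition
  deterministic.  Greedy CNM does not guarantee the globally optimal
  partition; the tests therefore check formula consistency on the
  returned partition, the exact two-communities answer on a
  two-triangle-bridge graph, and Q ≤ exhaustive maximum on small
  graphs.
* **Motif census** — counts of connected induced 4-node subgraphs by
  isomorphism class; the three classes realizable in triangle-free
  max-degree-3 graphs (P4, K1,3, C4) are reported.
* **Girth of an acyclic graph** is 0: a finite sentinel outside the
  attainable cycle range keeps feature vectors finite for classifiers.

Standard metrics are computed through igraph; the hub score and the
community detection are implemented in-package for the reasons above.
Every metric is validated in the test suite against independent
brute-force oracles (exhaustive path/subset/partition enumeration on
all connected graphs with ≤ 7 nodes and on random structure graphs).

## Redundancy filtering

Only an identity threshold (default 0.9) is inherent to the protocol;
the metric and clustering are this package's choices: global
Needleman–Wunsch alignment (match +1, mismatch 0, linear gap −1),
identity = identities / alignment length, with arguments canonically
ordered so co-optimal alignments cannot break symmetry; greedy
longest-first clustering (CD-HIT style, ties by id) keeps a record iff
it is below threshold against everything already kept.  A length-ratio
upper bound skips alignments that cannot reach the threshold.

## Synthetic data

The generator emulates the two classes structurally rather than by
folding random sequences, giving exact control and no external-folder
dependency.  Positives: one stem of U[18, 25] base pairs closed by a
U[3, 10] nt terminal loop, interrupted by 1–3 nt bulges with
probability 0.1 per stem position.  Negatives: 2–4 stem fragments of
U[3, 8] bp separated by U[5, 15] nt spacers, each fragment closed by a
large U[5, 15] nt loop, the whole wrapped in an enclosing stem
(multibranch junction) with probability 0.5, plus U[2, 8) nt dangling
ends.  Paired positions get Watson–Crick bases with a 10% G·U wobble;
unpaired positions are uniform.  Fragment-loop and dangling-end ranges
are this package's choices; the remaining bounds define the study
conditions used throughout the tests and the acceptance script.

What the generator does *not* emulate: miRBase sequence composition,
folding-energy realism, the blurry structural continuum between real
precursors and genomic pseudo hairpins.  The two synthetic classes are
cleanly separable — `degree_mean` alone classifies them with zero
out-of-bag error — so perfect SE/SP/AUC on synthetic data demonstrates
that the pipeline is correct, **not** that real pre-miRNA recognition
is solved; published accuracies on real corpora (AUC ≈ 0.95) require
the original datasets.  A corollary visible in
`scripts/acceptance.py` output: because several features are
individually sufficient, permuting any single feature costs no
accuracy and the top permutation-importance score on these conditions
is 0.  The discriminative behaviour of the importance machinery is
therefore exercised on controlled Gaussian designs in the tests (a
pure-noise feature ranks last; a duplicated feature scores lower
conditionally than marginally).

## Classification protocol

`HairpinForestClassifier` wraps a scikit-learn forest with the
protocol's conventions: fully grown trees, `mtry` split candidates,
out-of-bag error recorded at fit, prediction score = fraction of trees
voting positive, label threshold 0.5 with ties positive, and name-based
column realignment for DataFrame inputs.  Grid search maximizes mean
stratified k-fold CV accuracy over ntree ∈ {500, 1000, 1500, 2000} and
mtry ∈ 1..24 (an mtry of 0 is meaningless and excluded), with ties
broken toward the smaller ntree then smaller mtry and fold assignment
fixed by the seed across the whole grid.

Importance scores are mean decreases in accuracy under column
permutation.  The conditional variant permutes within strata formed by
jointly quartile-binning all features with |Pearson r| > 0.2 to the
feature under test; with no correlated feature it degenerates to the
marginal strategy draw-for-draw.  Confidence intervals are the 2.5/97.5
percentiles of the per-repeat scores; they describe the spread across
repeats (they do not narrow as repeats grow — the averaged score
stabilizes instead, which is what the tests check).  By default each
repeat re-trains the forest on a stratified bootstrap and measures
drops out-of-resample; a fixed-model variant is available.

Recursive elimination ranks features by the average of the two
importance scores, removes the lowest (ties to the earlier column),
re-measures SE/SP with the resampling protocol, and repeats until one
feature remains — 24 nested evaluations.

## Evaluation

SE, SP and ACC follow the standard confusion-matrix definitions; a
zero-denominator metric is NaN and is excluded from averages with a
logged count.  ROC curves sweep all distinct score thresholds;
AUC is trapezoidal and equals the Mann–Whitney pair statistic with
ties counting one half.  The resampling protocol draws a fixed number
of training records per class without replacement, tests on the
remainder, and aggregates over repeats: per-metric means, 10/25/50/75/90
percentile spreads, and ROC curves vertically averaged by linear
interpolation on a 0.00–1.00 FPR grid with 0.01 steps (the grid is this
package's choice).  All randomness in every protocol derives from a
single integer seed; identical invocations are byte-reproducible.

## Problem sizes

Default sizes used by the acceptance script — 500 records per class,
300 training records per class, 10 resampling repeats, 500-tree
forests, 20 importance repeats — keep a full from-scratch run to a few
minutes on one core while leaving hundreds of held-out records per
repeat; the original protocol's 100 repeats and 3000-per-class training
draws are available through the same parameters.

## Known limitations

* Pseudoknotted structures are rejected, as in the original protocol.
* Greedy CNM modularity is a local optimum; its value is a feature, not
  a statement about optimal community structure.
* The redundancy filter is O(n²) alignments; no k-mer prefilter is
  provided beyond the length-ratio bound.
* Synthetic data bounds realism as described above; no claim about
  real-corpus accuracy is made or tested.
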