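# Methods

## Model

`cnsnet` treats an attributed network as an undirected simple graph
G = (V, E) plus a length-M vector of categorical values per node.  The
coupled node similarity (CNS) of two nodes is a per-attribute sum of
three value-pair quantities:

* `δ_Ia(x,y) = |g(x)||g(y)| / (|g(x)| + |g(y)| + |g(x)||g(y)|)` —
  frequency-based intra-attribute similarity.  It is bounded in
  [1/3, 1): two singleton values score 1/3, frequent values approach 1.
  It is evaluated by the same formula for x = y (no special-casing);
  this matched-value behaviour is required for the worked example to
  reproduce.
* `δ_Ie(x,y)` — inter-attribute similarity.  For each other attribute n
  the subset minimisation `min_{B⊆F_n} [2 − P(B|x) − P(B̄|y)]` over
  information conditional probabilities is computed by the closed form
  `Σ_w min{P({w}|x), P({w}|y)}`: the minimising subset is
  B = {w : P(w|x) ≥ P(w|y)}, so the exponential enumeration is
  unnecessary.  The test suite keeps the exhaustive 2^|F_n| enumeration
  as an oracle and checks agreement to 1e−12 on randomized graphs.  The
  per-attribute results are averaged with weights α_n.
* `δ_AS(x,y)` — attribute-to-structure similarity: the ordered-pair edge
  density between g(x) and g(y).  For x = y the literal ordered-pair sum
  counts each internal edge twice against a denominator of |g(x)|²;
  this is the reading under which the worked example's final values
  (0.41 / 0.29) reproduce exactly.

Variant `cns1` (default) multiplies all three; `cns2` = (δ_Ia+δ_Ie)·δ_AS,
`cns3` = δ_Ia·δ_Ie+δ_AS, `cns4` = δ_Ia+δ_Ie+δ_AS.  `cas` omits the
structure factor.  Baselines: adjacency, cosine and Jaccard on neighbour
sets (isolated nodes score 0 by convention; the cosine denominator is
√(|Γi||Γj|)), and SMC (fraction of matching attributes).

**α_n schemes.** Two conventions exist for the inter-attribute weights:
uniform over the M−1 *other* attributes (α_n = 1/(M−1)) and uniform over
all M.  They differ by the constant factor (M−1)/M.  The default is
`others-uniform`, which makes δ_Ie a true average in [0, 1] and is the
convention under which the worked 7-author example reproduces; the
`all-uniform` scheme is selectable.  With M = 1 the other-attribute
average is empty and δ_Ie is defined as 1, keeping single-attribute
networks usable.

**Similarity matrices.** Value-pair tables are built once per attribute
(vectorised over the value domain), then node pairs are filled from
them.  For measures used only as edge weights (adjacency, cns1–cns4)
only adjacent pairs are materialised; a `full` mode computes all pairs
for K-medoids baselines.

## Detection

Edge weights are W(i,j) = S(i,j) on the adjacency, 0 elsewhere.  An
adjacent pair whose similarity is exactly 0 keeps its edge with weight 0
(the degenerate case is logged, not dropped).

* **SLPA** (default T = 20 iterations; the memory holds T+1 labels).
  Speakers send the modal label of their memory (ties uniform at
  random); the listener stores the label with maximal total incoming
  edge weight (ties uniform); the final label is the memory mode.  The
  output is a disjoint partition — no overlap threshold is exposed.
  T = 20 is common practice for memory-based label propagation;
  convergence is not required, only the fixed iteration budget.
* **Weighted modularity** uses the ordered-pair convention:
  m_w = Σ_{i,j} W(i,j) is twice the edge-weight sum, which makes the
  quantity identical to the conventional 2m-normalised weighted
  modularity (cross-checked against networkx in the tests).  The
  all-in-one partition scores exactly 0; m_w = 0 is an error.
* **BGLL** sweeps nodes in a seeded random order, accepts only strictly
  positive modularity gains (tolerance 1e−12), aggregates communities
  into super-nodes with internal weight as self-loops, and repeats until
  no move improves.  WQ is non-decreasing across accepted moves and
  phases; an `on_move` audit hook lets the tests verify this move by
  move.
* **K-medoids** clusters straight from the similarity matrix, with
  disconnected pairs at similarity 0.  Initial medoids are uniform
  without replacement; assignment is argmax similarity (ties to the
  lowest medoid index; a node with zero similarity to every medoid is
  assigned a random medoid and logged); the medoid update takes the
  member with maximal average similarity to its cluster; iteration stops
  when the medoid set stabilises (cap 100 rounds).  A medoid always
  belongs to its own cluster — necessary because self-similarity is 0 in
  edge-weight matrices.  With uniform initialisation a small fraction of
  restarts converges to a degenerate local optimum (e.g. both initial
  medoids inside one clique); this is intrinsic to the algorithm and the
  reason results are reported as averages over restarts.  K is set to
  the true community count when evaluating benchmarks.

**Seed policy.** Every stochastic component draws from a seed passed in
explicitly; repeated runs spawn per-restart seeds from the master seed
via `numpy.random.SeedSequence`, so averaged results are exactly
reproducible.

## Evaluation

NMI uses the arithmetic-mean normalisation 2·I(U;C)/(H(U)+H(C)) with
natural logs (the base cancels) and the 0·log 0 = 0 convention.  When
both partitions have zero entropy (both are a single community over the
same node set) NMI is defined as 1; when only one does, the mutual
information and hence NMI is 0.  F-Measure is the |U_r|/|V|-weighted
best harmonic mean of precision and recall per true community.
Accuracy resolves the underdefined notion of "correctly clustered
nodes" by the standard clustering-accuracy convention: optimal
one-to-one matching between detected and true communities
(`scipy.optimize.linear_sum_assignment` on the contingency table,
surplus communities unmatched); greedy matching would be
order-dependent.  All three metrics are label- and node-order-invariant
and are checked against brute-force formula evaluation (exhaustive
matching enumeration for accuracy) on random small partitions.

## Synthetic benchmarks

The generator emulates LFR-style planted partitions through the
parameters (N, avgk, maxk, minc, maxc, mu) rather than replicating the
reference LFR sampler: community sizes are drawn uniformly in
[minc, maxc] to sum to N; degrees follow a truncated power law with
exponent 2 whose lower cutoff is chosen so the mean matches avgk, with
individual degrees nudged so the total is exactly round(N·avgk); each
node's stubs are split internal/external by stochastic rounding of
degree·mu with the global external total pinned to mu (much lower
variance than a per-node binomial split); stubs are wired by
configuration-model pairing — internal within the community, external
across communities — rejecting self-loops and duplicates and dropping
the few irreparable stubs.  Contracts asserted in the tests: realised
mean degree within 10% of avgk and node-averaged mixing fraction within
0.05 of mu at N = 100; mu = 0 yields zero cross-community edges
exactly.

Attributes over the planted communities: **rule1** assigns each node its
community identifier (perfectly informative; distinct per community —
collisions would make the attribute uninformative, defeating its
purpose); **rule2** a uniformly random value from a domain whose size
defaults to the number of communities (the domain size is a free choice;
matching rule 1's cardinality keeps the two comparable); **rule3** is
rule1 with round(nl·size) nodes per community flipped to a uniformly
chosen *other* community's identifier.  The default trio is
(rule1, rule2, rule3@nl = 0.3).

The default benchmark scale is N = 100, avgk = 5, maxk = 10, minc = 10,
maxc = 30, the scale at which the recovery properties are tested: at
mu = 0.1 CNS-weighted BGLL recovers the planted partition with mean NMI
≥ 0.9 over 10 seeds, and mean accuracy is non-increasing in mu over the
0.1–0.9 grid (Spearman rank correlation ≤ 0, 10 seeds per point).

**What the generator does not emulate:** real attributed networks have
correlated attributes, heavy-tailed community sizes beyond [minc, maxc],
degree–attribute correlations and overlapping communities.  Passing the
recovery tests shows the pipeline works when attributes and structure
share a planted signal with controllable noise; it does not certify
performance on any particular real network.

## Numerical choices

Double precision throughout; no exact rational arithmetic (tests use
1e−9..1e−12 tolerances, and the worked example's printed values are
checked after rounding to 2 decimals).  Modularity gain acceptance and
weight-tie detection use a 1e−12 tolerance.  Directed or weighted input
graphs can be collapsed by `simplify_to_undirected` (drop direction,
collapse parallels, discard weights, remove self-loops) — the simplest
faithful conversion rule, documented here because alternatives (e.g.
keeping reciprocated edges only) exist.

## Limitations

Continuous or ordinal attributes, missing values, attribute-weight
learning, overlapping communities, resolution-parameter modularity and
weighted input graphs are out of scope.  The inter-attribute similarity
assumes attribute independence is *not* required — it explicitly
exploits co-occurrence — but all attributes are treated as equally
weighted a priori.
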