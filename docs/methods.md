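# Methods

This note documents the models, conventions and numerical choices behind
`ppihub`, and what its synthetic benchmarks do and do not demonstrate.

## Network assembly

Interaction records are curated into a simple undirected gene-level graph:
identifiers are mapped through an optional isoform/alias table and then
uppercased; duplicate edges collapse (their source tags are unioned);
self-interactions are dropped. The simple-graph restriction is deliberate:
every centrality index below is defined on simple graphs, and PPI edge
direction is not meaningful here. Unmapped identifiers pass through
unchanged with a logged warning — curation of real interaction indexes is
never complete, and silently dropping records would bias the network.
Disconnected networks are retained whole; per-component conventions are
handled index by index.

## Centrality ensemble

All indexes are computed on the unweighted graph; shortest paths are BFS
distances; unordered node pairs count once. Definitions follow the
CytoHubba conventions:

| index | definition | isolated node |
|---|---|---|
| degree | neighbor count | 0 |
| betweenness | Σ over pairs s≠t≠v of σ_st(v)/σ_st (unnormalized) | 0 |
| stress | number of shortest paths through v | 0 |
| eccentricity | 1 / max distance within v's component | 1 |
| radiality | Σ_w (Δ+1 − d(v,w)) / (n_c − 1), Δ = component diameter | 0 |
| bottleneck | # roots s≠v whose BFS-tree subtree at v exceeds n_c/4 | 0 |
| MNC | size of the largest connected component of v's neighborhood | 0 |
| DMNC | edges/nodes^ε of that component, ε = 1.7 | 0 |
| MCC | Σ over maximal cliques C ∋ v of (|C|−1)! | 0 |
| EPC | mean component size of v over random edge-percolated copies | ≥ 1 |

Conventions worth spelling out:

- **Eccentricity is reported as its reciprocal.** Raw eccentricity is
  *small* for central nodes, while the composite score rewards large
  values; the reciprocal makes "higher = more hub-like" uniform across all
  ten columns. This is a deliberate divergence risk against tools that rank
  raw eccentricity some other way.
- **Bottleneck trees are made deterministic** by assigning each node the
  lexicographically smallest BFS predecessor as parent. Shortest-path trees
  are otherwise not unique and the index would depend on hash order. The
  cost of determinism is that on graphs with non-unique shortest paths
  (e.g. even cycles) the index is label-dependent and not invariant under
  graph automorphisms — an inherent property of any deterministic
  tie-break, covered explicitly in the tests.
- **Stress** uses a Brandes-style accumulation
  δ(v) = σ_s(v)·Σ_{w: v→w} (1 + δ(w)/σ_s(w)) per root, halved to count
  unordered pairs once; betweenness and pair-based sums are restricted to
  within-component pairs.
- **EPC** retains each edge independently with probability 0.5 (default)
  for T = 1000 iterations. Edges are processed in sorted order and the
  generator is seeded, so results are bit-reproducible. The estimator's
  Monte-Carlo error is ~n/√T per node; tests compare it against exact
  subset-enumeration expectations on small graphs and exact values at
  retain probabilities 0 and 1.
- **DMNC ties** (two neighborhood components of equal node count) are
  broken by edge count, then by sorted node labels, for determinism.

Complexities are O(n·m) for the path-based indexes (betweenness, stress,
bottleneck, radiality) and output-sensitive for MCC (Bron–Kerbosch); the
ensemble on a 500-node, 1100-edge scale-free graph takes ~3 s on one core.

## Composite score

Each index column is min–max normalized to [0, 100] over *all* network
nodes; the composite score of a node is the sum over the Nc columns, hence
bounded by 100·Nc. Normalizing over the full network (rather than a seed
subset) means a seed gene's score reflects its standing in the whole
interactome; restriction to a seed list happens only at ranking time, which
also reports high scorers *outside* the seed list. A degenerate column
(max = min) contributes 0 everywhere — a constant index carries no ranking
information and the normalization would otherwise divide by zero. Ranking
ties break lexicographically by gene symbol.

The score is invariant under column permutation and under strictly
increasing affine rescaling of any raw column, and is monotone in each
index. No index weighting is applied: all ten count equally.

## Communities

k-clique percolation (CPM): communities are unions of k-cliques connected
through adjacency "share k−1 nodes"; nodes may belong to several
communities, and the per-gene overlap count is reported. k defaults to 3
(triangle percolation), the smallest k that yields dense modules on sparse
PPI-like graphs. Percolation is over all k-cliques as in the original CPM
definition; the implementation (via maximal-clique overlap) is verified
exactly against a union-find-over-k-cliques oracle. Communities are
reported as lexicographically sorted node tuples, largest first.

## Model-based clustering

Nodes are clustered on their *normalized* (0–100) centrality columns — raw
columns differ by orders of magnitude and would dominate the likelihood.
Gaussian mixtures are fitted by EM over four covariance families
(sklearn naming): `spherical` (per-component isotropic), `diag`
(axis-aligned), `tied` (one full covariance shared across components) and
`full` (per-component full covariance — the family able to express
ellipsoidal clusters with variable orientation). Constrained
equal-volume/equal-shape families of the mclust taxonomy are not
implemented; `full` is the closest available super-family and is what the
selection uses in practice.

Numerical choices: k-means initialization with an explicit seed, covariance
regularization 1e-6·I, convergence when the total log-likelihood gain
drops below 1e-6, at most 500 iterations. EM is stepped one iteration at a
time so the log-likelihood trajectory is recorded; it must be
non-decreasing (asserted in tests). Model selection maximizes
BIC = 2·logL − m·log n (higher is better); failed fits stay in the BIC
table, flagged, and are excluded from selection. Clusters are relabelled
C1…CG by ascending mean composite score, so the most hub-like cluster is
always the last label.

## Enrichment

Over-representation of a query gene list against a GMT collection. With
universe size N, annotated set size K, query size n and overlap k, the
p-value is the hypergeometric upper tail P(X ≥ k); the default **EASE**
variant recomputes the tail with overlap k−1 (p = 1 when k ≤ 1), a
conservative penalty that damps single-gene hits in small sets. Set-level
p-values are Benjamini–Hochberg adjusted. Sets carrying a class label in
the GMT description column are also aggregated into class-level rows
(class set = union of member sets), adjusted within the class table.

The default test universe is the *annotated* universe — background genes
appearing in ≥ 1 set — because un-annotated genes cannot contribute
overlap and would dilute N; the full background is selectable
(`universe_mode="all"`). Annotation coverage of the background is always
reported so users can judge how partial their collections are.

## Differential-expression prefilter

Per gene, the statistic is the difference of case/control means of log2
values; significance comes from B random label permutations with the
add-one estimator p = (1 + #{|T*| ≥ |T|}) / (B + 1), which is valid for
any B and never exactly zero. "Resampling depth" defaults to B = 10000
when the design has ≥ 20 samples and 1000 otherwise, overridable. A
bootstrap-of-mean-differences null (groups centered to the pooled mean,
resampled with replacement) is available behind a flag. Fold change is
computed on linear-scale group means and filtered symmetrically
(max(fc, 1/fc) ≥ threshold, default 2), so 2-fold down-regulation counts
like 2-fold up; the test statistic lives on the log scale for variance
stability. A gene is selected when BH-adjusted p ≤ α (default 0.05) AND the
fold-change filter passes. Both raw- and adjusted-significant counts are
reported; the adjusted count can never exceed the raw count. Multiple
experiments are analyzed independently and their selections unioned before
merging with external ranked gene lists (top-k heads, provenance retained).

## Synthetic data

The generators produce inputs with the statistical structure the analysis
assumes, plus ground-truth JSON:

- **Networks.** Barabási–Albert preferential attachment (default m = 2)
  gives the scale-free degree distribution typical of curated PPI networks;
  the edge count is exactly m·(n − m). Planted hubs are fresh nodes wired
  to a stated fraction (default 20%) of uniformly chosen nodes; planted
  cliques are made pairwise adjacent on disjoint samples (or fresh nodes).
  An Erdős–Rényi backbone is available for community benchmarks. After
  construction, *all* node labels are randomly permuted so a node's name
  carries no information about its role — without this, planted nodes
  would occupy a fixed lexicographic rank and bias the label-tie-breaking
  bottleneck index.
- **Gene sets.** Uniform samples from the universe; a designated query
  over-samples one target set at a stated fraction (0.8 by default;
  setting it to the base rate yields a null collection).
- **Expression.** Per-gene log-normal baselines around 100, multiplicative
  mean-one log-normal noise at a stated coefficient of variation (default
  10%), and a block of spiked genes whose case-group mean is multiplied by
  the true fold change (default 4; down-regulation is obtained by swapping
  group labels). Default design: 10 cases vs 10 controls, 200 genes, 10
  spiked.

What passing tests on these generators shows — and what it does not: the
generators reproduce heavy-tailed degree structure, planted dense modules,
planted over-representation and spiked fold changes, so they exercise
ranking, percolation, enrichment and error control under known truth. They
do *not* reproduce study-specific properties of real interactomes
(ascertainment bias toward well-studied genes, correlated annotation,
batch effects, probe-level noise), so quantitative results on real data —
community counts, cluster counts, absolute scores — will differ from the
synthetic figures.

## Pipeline determinism and problem sizes

A single master seed derives per-stage seeds by fixed offsets (DEG +101,
EPC +202, clustering +303, modulo 2³¹), so any stage can be rerun in
isolation; reruns with the same config are byte-identical. The benchmark
problem sizes used by the test suite and `scripts/acceptance.py` — the
995 connected-graph isomorphism classes on ≤ 7 nodes plus random ≤ 12-node
graphs for oracle equivalence, 500-node backgrounds for hub
prioritization (50 replicates), 300-node backgrounds for clique recovery
(20 replicates), 20 replicates for the expression and clustering
experiments — were chosen as the smallest sizes at which the measured
properties are stable.

## Known limitations

- The planted-hub benchmark measures ~94–96% rank-1 rate across replicate
  sets: in heavy-tail draws of the preferential-attachment background the
  top background node approaches the hub's degree while keeping a denser
  neighborhood (higher MNC/DMNC), and occasionally outranks it. This is a
  property of uniform hub wiring, not an implementation defect — the
  composite score correctly prefers the node with the stronger all-round
  profile.
- Bottleneck's deterministic tie-break is label-dependent where shortest
  paths are non-unique (see above).
- EPC is a Monte-Carlo estimate; two runs agree only under the same seed.
- Mixture clustering offers no constrained equal-volume/equal-shape
  covariance families; `tied`/`full` bracket them.
- Enrichment assumes gene symbols already harmonized between query,
  universe and GMT; no identifier mapping is attempted there.
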