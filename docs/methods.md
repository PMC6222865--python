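# Methods

## Problem and model

Given an undirected gene network with probability-like edge weights
`w_ij ∈ [0, 1]`, a list of fusion gene pairs, and (for evaluation) a list
of susceptible genes, the package ranks fusions by the destructiveness of
their partners: a gene is important exactly insofar as deleting it damages
the network after noise has been filtered out. The pipeline is

1. *stabilize* — filter the network to its synchronously stable state;
2. *importance* — score each gene by the drop in a global network metric
   when the gene is deleted and the remainder re-stabilized;
3. *score* — combine partner importances into a fusion significance and
   rank;
4. *benchmark* — compare the ranking with degree- and betweenness-based
   fusion centrality on synthetic data.

### Stability condition

For a connected component of `n` nodes, a coupled ring lattice of
`2K`-adjacent nodes is synchronously stable when every coupling weight
exceeds

    ε = (a/n) · (n/2K)^3 · (1 + (65/4)·K/n),      a = s·λ2,  0 < s < 1,

with `λ2` the algebraic connectivity. The printed form of this inequality
in the source literature is typographically ambiguous; the implementation
uses the unique reading whose fully connected limit `n = 2K` at `s = 0.28`
reproduces the published coefficient `ε = 2.555·λ2/n` (because
`0.28·(1 + 65/8) = 2.555` exactly). That coefficient is the package's
pinned acceptance quantity. Components that are not cliques substitute
`m = (greedy maximum clique size)/2` for `K`, which can only raise `ε` and
therefore stays a valid stability condition; odd clique sizes keep the
exact half (no rounding), as `m` only enters analytically.

`λ2` is computed per connected component on the weighted Laplacian by
default (the coupling acts through interaction strengths); a 0/1 Laplacian
is available as `lambda2_mode="unweighted"`. Neither choice is dictated by
the theory for real weighted networks, so both are exposed; note that with
either mode a uniform-weight clique always violates the condition
(`ε = 2.555·w̄ > w_min`), so dense components dissolve at `s = 0.28` —
an aggressive but faithful property of the threshold. The comparison
`w > ε` is strict, with no tolerance: edges at exactly `ε` are deleted,
and the threshold itself is approximate so a numerical fudge factor would
add nothing.

### Stabilization loop

Per iteration and per *unstable* component (stable components are never
touched, which makes the procedure idempotent):

* clique → batch-delete all edges with `w ≤ ε`;
* otherwise, if hanging nodes (degree exactly 1) exist → delete them
  (node and incident edge);
* otherwise → batch-delete all edges with `w ≤ ε`.

`ε` is recomputed for every component at every iteration, since `n`, `λ2`
and the clique size all change as the graph shrinks. Hanging-node deletion
removes the gene; genes isolated by *edge* deletion are kept as singleton
components (they still exist as genes) unless `drop_singletons` is set.
Every iteration removes at least one edge or node, so termination is
guaranteed. The trace records every edit and can replay the input into the
output, which the tests assert.

### Coupling factor

`s = 0.28` is the default, the depression point where the gradient of the
mean information-loss curve first approaches zero on an `s`-sweep over
`{0.01, …, 0.99}`. `select_coupling_factor` re-derives it for any network
collection: information loss is measured as the stabilized fraction of
total edge weight removed (weight mass is the natural "information" of a
probability-weighted network; an edge-count variant is an option), the
mean curve over networks is differentiated by central finite differences,
and the smallest grid point with `|gradient| ≤ 0.05` (per unit `s`) is
returned — flagged, with the flattest point as fallback, if none
qualifies. The tolerance is a package default; no value is prescribed by
the theory.

### Greedy maximum clique

Maximum clique is NP-hard; the implementation is a deterministic greedy
heuristic with one restart per seed node: order nodes by descending
weighted degree (ties lexicographic), grow a clique from each seed by
scanning that order, keep the largest result. A single pass from the top
of the ordering alone was evaluated first and rejected: whenever the
top-degree node's first compatible successor lies outside its own dense
module the pass stops at size 2, halving `m` and inflating `ε` eightfold,
which dissolved essentially every modular component. The restart variant
costs `O(n·m)` per component and is insensitive to that trap. Tests bound
it by exhaustive enumeration on graphs of up to 8 nodes.

### Importance

`M(G)` is the ordered-pair double sum of edge weights divided by the
number of components; the factor 2 cancels in the ratio `H = D/M`, which
tests assert against a single-counted reimplementation. `D` deletes the
node from the *stabilized* baseline and re-stabilizes before comparing —
the operative definition used by the algorithm's step list (the source
also prints a no-re-stabilization variant of `D`; the discrepancy is noted
rather than resolved). The baseline is stabilized once and shared by all
node evaluations. Two policy decisions close degenerate corners:

* isolated baseline nodes get `H = 0` (removing a singleton component
  would make `D` negative purely through the `m_G` denominator, but a node
  that destroys nothing is not important);
* genes requested for scoring but absent from the network — or pruned from
  the stabilized baseline — get `H = 0` (with a warning for the former),
  so fusion scoring is total over its vocabulary.

`H` is invariant under uniform weight rescaling in weighted-λ2 mode
(both `w` and `ε` scale together), which is tested.

### Fusion significance and baselines

`S(f) = (1 + w_ij)(H_i + H_j)`, with `w_ij = 0` when no edge joins the
partners. `w_ij` is read from the original network by default: the
partners' interaction tendency is a property of the data that the
stability filtering should not erase (`weight_source="stabilized"`
switches this). Ties in `S` break on the canonical fusion name, making
ranks a deterministic permutation.

Baselines merge the two partner nodes into one burden node on the
*original* network (they involve no stability machinery). Overlapped
edges keep the larger weight (`max`; `sum`, capped at 1, is an option —
the literature notes the overlap information is usually ignored without
prescribing a rule). DEG is the weighted degree of the burden node over
`N − 1`. BET uses hop-count shortest paths by default (inverse-weight
distances optional) with the convention pinned by the package's oracle
tests: `g` counts all geodesics over all unordered pairs of distinct
nodes — including pairs joined by a direct edge, whose geodesics cannot
pass through anything — and `g(v)` counts those with `v` strictly
interior, so a path A–B–C gives `B(B) = 1/3`. Published toy arithmetic
for this statistic is ambiguous; the convention here is fixed by
brute-force enumeration oracles over every connected graph of ≤ 6 nodes.
Production scoring runs through a vectorized engine (sparse quotient
projection for the merge, a compiled breadth-first geodesic counter);
tests assert it is numerically identical to the definitional
merge-then-score route.

## Synthetic data

The generator encodes the premise the ranking is built on — susceptible
genes are network-important hubs — in a form that survives the stability
filter:

* planted susceptible genes (default fraction 0.15 of `n_genes = 200`)
  form a chain of triangle modules (weights U(0.75, 0.95)) joined by
  single bridges (U(0.55, 0.75)): a sparse, elongated core whose `λ2` is
  small enough to satisfy `w > ε` at `s = 0.28`, while each member's
  deletion removes heavy edges and can fragment the chain;
* every background gene attaches by exactly one edge, to a planted hub
  with probability 0.6 (weights U(0.35, 0.70)) or to an earlier background
  gene (U(0.05, 0.45)), forming a random attachment forest. Planted genes
  therefore have stochastically larger weighted degree (Monte-Carlo
  checked over 500 replicates), and the periphery is exactly what
  hanging-node pruning removes;
* `edge_density` optionally adds random background-background edges on
  top of the structural minimum. Cyclic background regions then enter the
  2-core, inflate `ε` of the merged component, and can dissolve it
  entirely — real behavior of the threshold, so the default density stays
  at the structural minimum.

Datasets draw `2·Ni` susceptible partners without replacement from the
planted pool and `2·No` ordinary partners from the *whole* gene pool
(susceptible genes included, as in the evaluation protocol this emulates),
pairing each draw in order; an ordinary fusion colliding with a
susceptible one triggers a complete re-draw of the ordinary set on a fresh
child seed. All randomness derives from one master seed through named
`SeedSequence` child streams (network, susceptible draw, each ordinary
attempt, each dataset), honoring per-process seed isolation.

What the generator does **not** model: cyclic periphery and cross-module
shortcuts, heterogeneous hub degrees (scale-free tails), weight noise on
the core, missing genes, and the sheer scale of curated whole-genome
networks. Passing benchmarks therefore demonstrate correct mechanics and
recovery of a clear planted signal, not performance on real networks. In
particular, because hub weighted-degree *is* the planted signal, DEG is
near-ceiling on this family (mean AUC ≈ 0.98 vs ≈ 0.95 for SYN at the
default benchmark); the destructiveness ranking's claimed advantage on
real, noisier networks is outside what this synthetic family can show,
and the acceptance bar is accordingly "within 0.05 of each baseline and
≥ 0.8", not dominance.

## Evaluation

Fusions are sorted by descending score; positives are counted over ten
rank deciles `I_i = ((i−1)·Nf/10, i·Nf/10]` (real-valued edges when `Nf`
is not a multiple of ten; integer ranks on an edge fall in the
lower-indexed interval). The recognition rate `P(i)` is the cumulative
count over the first `i` deciles divided by `Ni` (`P(10) = 1` and interval
counts sum to `Ni`, both asserted on every run). ROC curves sweep distinct
score thresholds descending (ties move as one step; scikit-learn's
`roc_curve` with trapezoidal AUC), which makes AUC equal the Mann-Whitney
pair statistic with ties counted ½ — cross-checked against brute-force
pair counting.

The experiment grid runs `Nf ∈ {150, 200, 250} × Ni ∈ {15, 25} × 20`
replicates (120 datasets) on one network, with per-dataset failure
isolation and mean-over-replicates aggregation.

## Problem sizes and defaults

* Grid-scale synthetic network: `n_genes = 560`, fraction 0.1 — the
  smallest round size whose pools support `2·Ni = 50` susceptible and
  `2·No = 470` ordinary partner draws at the largest grid cell.
* Default planted-hub benchmark: `n_genes = 200`, fraction 0.15,
  `Nf = 60`, `Ni = 12`, 20 replicates — pool-feasible at 200 genes while
  keeping the susceptible share of ordinary draws realistic.
* Small worked examples use 20–80 genes; oracle tests enumerate all
  connected graphs of ≤ 6 nodes and random graphs of ≤ 8.

## Known limitations

* The stability threshold grows like `n³/m³` within a component, so large
  sparse components with small cliques dissolve wholesale once their
  hanging nodes are gone; only elongated, modular, small-`λ2` cores
  survive at `s = 0.28`. This is a property of the model, not a bug, but
  it means the importance scores of a real network depend heavily on what
  its stabilized core happens to be.
* Whether `λ2` should be weighted or 0/1, and whether it should be frozen
  or recomputed across iterations, is under-determined by the theory;
  this implementation recomputes the weighted form (flowchart-faithful)
  and exposes the unweighted alternative without claiming either is
  canonical.
* Betweenness uses a global-ratio convention (`g(k)/g`) rather than the
  per-pair-normalized Freeman statistic; values are comparable within a
  network but not across conventions.
* Fusions with more than two partners are out of scope.
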