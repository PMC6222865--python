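# synstable

Prioritizing **driver partner genes in gene-fusion structures** from a
weighted gene network.

A fusion gene joins two partner genes; usually only one of them (the
*driver*) matters for carcinogenesis, and validating drivers experimentally
is slow. `synstable` ranks candidate fusions computationally from a single
piece of prior knowledge: an undirected gene network whose edge weights
`w_ij ∈ [0, 1]` score the tendency of two genes to act together. It
implements a destructiveness-based ranking (SYN) built on a network
synchronization-stability model, together with the two classical
fusion-centrality baselines (weighted degree, DEG; betweenness, BET) and a
synthetic planted-hub benchmark that compares all three.

## The model

**Stability filter.** For a connected component with `n` nodes, algebraic
connectivity `λ2` (second-smallest eigenvalue of the weighted Laplacian)
and a coupling parameter `a = s·λ2` with `0 < s < 1`, synchronization
theory for ring lattices of `2K`-adjacent nodes gives an edge-weight lower
limit

    w > ε = (a/n) · (n/2K)³ · (1 + (65/4)·K/n)

For a fully connected component (`n = 2K`) with the default `s = 0.28`
(the depression point of the mean information-loss curve over an s-sweep)
this collapses to `ε = 2.555·λ2/n`; otherwise `K` is replaced by `m`, half
the size of a greedily found maximum clique, which only raises the limit.
A network is made *synchronously stable* by iterating per component:
cliques batch-delete edges with `w ≤ ε`; other components first shed
hanging (degree-1) nodes, then sub-threshold edges; `ε` is recomputed every
iteration until every component satisfies the condition. The surviving
core is the noise-filtered skeleton of the network.

**Node importance.** With `M(G) = (Σ_i Σ_{j≠i} w_ij) / m_G` (total
ordered-pair edge weight over the number of components `m_G`), the
importance of gene `v` is the relative damage of deleting it from the
stabilized network `G_s` and re-stabilizing:

    H(G, v) = [M(G_s) − M((G_s − v)_s)] / M(G_s)

**Fusion significance.** A fusion `f = (i, j)` scores
`S(f) = (1 + w_ij)·(H(i) + H(j))`, with `w_ij` looked up in the original
network; fusions are ranked by descending `S`. Baselines instead merge the
partner nodes into a single burden node and score its weighted degree
`K(i) = Σ_j a_ij/(N−1)` or betweenness `B(k) = g(k)/g`.

## Worked example

```
$ synstable simulate-network --n-genes 40 --susceptible-fraction 0.3 \
      --seed 7 --out edges.tsv --genes-out susceptible.txt
wrote 40 genes, 43 edges to edges.tsv; 12 susceptible genes to susceptible.txt

$ synstable stabilize --network edges.tsv --out stable.tsv --trace trace.tsv
stabilized: 14/40 nodes, 17/43 edges kept (2 edits)

$ synstable importance --network edges.tsv --out importance.tsv
scored 40 genes (baseline M = 26.4893)
```

The stability filter pruned the 26 tree-like background genes and kept the
densely wired 14-node core; `importance.tsv` lists `H`, `D` and the
baseline `M` per gene. The five most destructive genes are all planted
susceptible hubs — for example `g0018` (H = 0.9004) and `g0028`
(H = 0.8928), whose deletion fragments the stabilized core, against
H ≈ 0.04 or 0 for peripheral genes. Ranking a 12-fusion dataset (4
susceptible) with these scores:

```
rank  fusion         S       label
1     g0021-g0028    3.2966  susceptible
2     g0008-g0038    1.6575  susceptible
3     g0018-g0034    1.0407  ordinary
4     g0002-g0026    0.9652  susceptible
...
AUC: 0.844
```

The full three-algorithm comparison over replicate datasets:

```
$ synstable benchmark --grid-nf 20 --grid-ni 5 --replicates 5 --seed 3 \
      --n-genes 60 --susceptible-fraction 0.2 --out bench
5 datasets, 15 result rows, 0 failures -> bench
mean AUC BET: 0.9520
mean AUC DEG: 0.9600
mean AUC SYN: 0.9387
```

`bench/` contains per-dataset metrics (`results.tsv`), per-configuration
means (`summary.tsv`) and the exact configuration run (`config.yaml`);
identical seeds reproduce identical files.

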