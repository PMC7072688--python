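# ckds — kernel differential subgraph extraction

`ckds` finds the *kernel differential subgraph* (KDS) between two
weighted gene networks representing two biological states — for
example, tumour and normal single-cell co-expression networks built on
a protein–protein interaction backbone. The KDS is the small connected
subgraph that concentrates the genes whose local wiring changes most
between the states; its members are candidate drivers, biomarkers and
therapeutic targets. The package is aimed at computational biologists
doing differential network analysis on scRNA-seq (or any paired
expression) data, and at methods researchers who need a reproducible
planted-module benchmark for module-recovery algorithms.

## Method

For two networks G(V, E) and G′(V, E′) over a shared gene universe:

1. **Graphlet signatures.** Every node gets a 15-vector counting how
   often each automorphism orbit of the 2–4-node graphlets (orbits
   0–14) touches it; counting is exact (ESU enumeration of connected
   induced subgraphs).
2. **Signature distance.** Per common gene *u*, the orbit-wise distance

   D_i(u, u′) = w_i · |log(u_i + 1) − log(u′_i + 1)| / log(max(u_i, u′_i) + 2)

   is aggregated into a *d-value* = Σᵢ D_i / Σᵢ w_i ∈ [0, 1), where
   w_i = 1 − log(o_i)/log(15) down-weights redundant orbits. Genes
   with d ≥ 0.4 form the differential node set.
3. **Greedy extraction.** Per network, the subgraph grows from the
   highest-d gene; each further selected gene joins directly when
   adjacent, otherwise the minimum-hop candidate paths to the current
   subgraph are ranked by

   Score_path = a · Σ d_v + b · Σ W_e   (default a = b, i.e. Σd + ΣW)

   and the best path is added whole. The two per-network subgraphs
   are then intersected (nodes by intersection, edges by restricted
   union). The procedure is a greedy approximation to a
   Steiner-tree-type problem.
4. **Ranking.** KDS genes are scored by the sum of min-max-normalised
   degree, betweenness, closeness and eigenvector centralities; the
   top 10% are reported as the topologically pivotal genes.

A synthetic benchmark (`ckds.simulate`) plants a connected module of
*m* essential genes in a clustered scale-free network, rewires exactly
⌈ρ·|E|⌉ module-incident edges into a second state, emulates per-state
expression, and scores recovered subgraphs against the planted truth
(accuracy / precision / recall / F1 at the gene level).

## Worked example

Extract a KDS from a simulated pair and rank its genes:

```python
from ckds import (SimulationConfig, generate_pair, differential_nodes,
                  extract_kds, compute_centralities, combined_score, top_nodes)

pair = generate_pair(SimulationConfig(seed=7))
diff = differential_nodes(pair.net_a, pair.net_b)       # d-values, cut at 0.4
kds = extract_kds(pair.net_a, pair.net_b, diff)
table = combined_score(compute_centralities(kds.graph))
print(sorted(kds.nodes))
print("planted:", pair.essential)
print("top genes:", top_nodes(table, 0.10))
```

Output:

```
['g041', 'g043', 'g067', 'g069']
planted: ['g029', 'g041', 'g043', 'g052', 'g065', 'g067', 'g069', 'g070', 'g072', 'g079']
top genes: ['g067']
```

Four of the ten planted essential genes are recovered with no false
positives (the rest were barely perturbed in this pair — the generator
deliberately mixes focal and passenger genes), and the centrality
ranking flags `g067` as the subgraph's pivotal gene.

The same flow is available from the shell for real data:

```
ckds pipeline --expr tumour_counts.tsv --expr-b normal_counts.tsv \
              --backbone ppi_edges.tsv --out-dir run/
```

which chains CPM normalisation, DEG calling (Welch's t on log2(CPM+1),
BH-adjusted, |log2FC| > 2 — a documented stand-in for a
negative-binomial exact test; precomputed DEG lists are accepted via
`--degs`), co-expression network construction (top-10% |PCC| ≥ 0.6 on
backbone edges), d-values, extraction and centrality ranking, writing
`kds.json`, `kds.sif` (Cytoscape), `dvalues.tsv` and `centrality.tsv`.

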