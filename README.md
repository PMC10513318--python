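# netrewire

Hierarchical graph embedding for quantifying rewiring between biological
networks and prioritizing the genes that drive it.

Gene regulatory networks (GRNs — directed TF-to-TF regulation inferred
from ChIP-seq binding) and gene co-expression networks (GCNs — undirected,
weighted by unsigned Pearson correlation of expression) reorganize between
conditions: tumor vs. normal cell lines, one brain cell type vs. another,
control vs. disease. `netrewire` is for computational biologists who have
two such networks over a shared gene set and want (i) a per-gene rewiring
score, (ii) a ranking of candidate driver genes, and (iii) a readout of
*when* in the network hierarchy each driver diverges — across pathway-scale
communities (early) or only within its local community (late).

## Method

Given two networks G<sub>s1</sub>, G<sub>s2</sub> on shared nodes, the
pipeline runs four stages:

1. **Coarsen.** Louvain community detection maximizes modularity
   Q = (1/2m) Σ<sub>ij</sub> [A<sub>ij</sub> − k<sub>i</sub>k<sub>j</sub>/2m]
   and each community collapses into a super-node (edge weights summed
   across communities), repeated up to k<sub>h</sub> times (default 2) or
   until the modularity gain fades:
   G⁰ ≻ G¹ ≻ … ≻ G<sup>k_h</sup>. The second condition's finest partition
   is warm-started from the first's, so community flips reflect rewiring
   rather than local-optimum noise.
2. **Embed the coarsest graph.** A closed-form random-walk factorization
   (expected window co-occurrence → positive PMI → truncated SVD) gives
   each super-node a d-dimensional coordinate, Z<sup>k_h</sup> = GRL(G<sup>k_h</sup>).
3. **Refine level by level.** A layer-wise linear GraphSAGE model
   h<sub>v</sub> ← W·concat(h<sub>v</sub>, AGG{h<sub>u</sub> : u ∈ N(v)})
   is trained once on the coarsest graph to reproduce Z<sup>k_h</sup>
   (loss = (1/|V|)·‖Z − H(Z, G)‖<sub>F</sub>), then applied downward:
   every finer node starts as an exact copy of its super-node vector and
   one forward pass mixes in its neighbors, giving Z<sup>i</sup> at every
   level down to the full graph.
4. **Align and score.** Orthogonal Procrustes on the finest level finds
   U minimizing ‖M₁ − M₂U‖<sub>F</sub>; the same U rotates every level of
   condition 2. Each gene's rewiring score at level i is the L2 distance
   between its (super-)node vectors, max-normalized per level
   (`dl2norm` ∈ [0, 1]). Genes high at both coarse and fine levels are
   **early divergent (EDG)**; genes high only at the finest level are
   **late divergent (LDG)**.

Four baselines (degree change ΔD, clustering-coefficient change ΔC,
PageRank change ΔPR, contrastive-learning embedding distance ΔE) and two
simulation schemes with planted ground truth (single-TF rewiring in GRNs;
template-gene weight copying for LDG/EDG construction in GCNs) are included
for benchmarking, together with R@n recall, EDG-vs-LDG accuracy and a
false-positive analysis.

## Worked example

Simulate a tumor-to-normal style comparison — two 40-TF networks with
three regulatory communities, one TF (`g29`) rewired toward the other
condition's wiring — then recover the driver:

```python
import warnings; warnings.filterwarnings("ignore")
from netrewire import compare_networks, RunConfig
from netrewire.simulate import generate_grn_pairs

sim = generate_grn_pairs(1, n_nodes=40, n_blocks=3, seed=4)[0]
print("rewired TF:", sim.target_node)

result = compare_networks(sim.original, sim.modified, RunConfig(mode="grn", seed=4))
print("hierarchy levels:", [lv.n_nodes for lv in result.h1.levels])
scores = result.node_scores(level=0)
for n in result.ranked(0)[:3]:
    print(f"  {n}  raw={scores[n]:.4f}")
prof = result.profiles
print(prof[prof["class"] != "conserved"].round(3))
```

prints

```
rewired TF: g29
hierarchy levels: [40, 3]
  g29  raw=0.0658
  g04  raw=0.0447
  g39  raw=0.0298
      dl2norm_late  dl2norm_early class  rank
gene
g29           1.00          1.000   EDG     3
g04           0.68          0.551   LDG    14
```

The planted driver `g29` tops the displacement ranking (0.0658, half again
the runner-up) and is called an early divergent gene: its rewiring moved it
across community boundaries, so it is displaced at the coarse (pathway)
level and at the fine level alike. `g04` — a neighbor that lost edges to
`g29` — shifts only at the fine level and is called late divergent.

The same pipeline is available from the shell:

```bash
netrewire compare --g1 normal.tsv --g2 tumor.tsv --mode grn --kh 2 --seed 7 --out run1/
netrewire benchmark --scheme grn-rewire --pairs 30 --seed 0 --out bench/
netrewire roles --g1 normal.tsv --g2 tumor.tsv --out roles/   # commander/messenger/soldier
```

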