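# Methods

This note documents the models and procedures implemented in `netrewire`,
the parameters that matter, the numerical choices behind them, what the
synthetic fixtures do and do not emulate, and the known limitations.

## Problem setting

Two biological networks are observed over a shared (or overlapping) gene
set — either directed, unweighted TF-to-TF regulatory networks (GRN mode)
or undirected co-expression networks weighted by unsigned Pearson
correlation (GCN mode). The goal is a per-gene *rewiring index* that ranks
genes by how much their network context changed between the two
conditions, plus a classification of each high-scoring gene as early
divergent (rewired across pathway-scale communities) or late divergent
(rewired only within its local community).

The central difficulty is that single-cell-derived networks are sparse and
noisy, so direct edge-count comparisons are brittle, and that genes act in
correlated modules, so a useful score has to be resolution-aware. The
pipeline addresses both by comparing the networks at several scales of a
community-coarsened hierarchy in a single aligned embedding space.

## Pipeline stages

### 1. Graph coarsening

Communities are detected by greedy Louvain local moving on the
(symmetrized) weighted graph, maximizing Newman–Girvan modularity

  Q = (1/2m) Σ_{ij in same community} [A_ij − k_i k_j / 2m],

where A is the symmetric weight matrix, k the weighted degrees, and m the
total edge weight. Directed GRNs are symmetrized (weights summed over both
orientations) *for partitioning only*; the directed graph is kept for
embeddings and degree analyses, since the modularity above is the
undirected form.

Each Louvain pass runs local moving to a single-node local optimum and
then aggregates communities into super-nodes so the next pass can move
whole communities; `max_passes = 2` phase pairs capture nearly all of the
attainable modularity at the network sizes handled here (tens to a few
thousand nodes). A final node-level refinement phase on the original graph
guarantees the returned partition is a genuine single-node local optimum —
without it, the post-aggregation state can leave individually profitable
moves unexercised, which makes re-partitions of a slightly perturbed graph
inconsistent with the original.

Reconstruction collapses each community into a super-node; the super-edge
weight is the sum of all member-edge weights crossing the two communities.
Intra-community weight is dropped by default (`keep_self_loops=False`):
the refinement layer aggregates *neighbor* vectors, and a self-loop adds
no neighbor information. Coarsening repeats up to `k_h` times (default 2 —
modularity gains plateau after two coarsening steps on the networks this
tool targets) and stops early when a step would not reduce the node count
or when the partition's modularity improves by less than
`min_gain = 1e-4` over the previous level ("no obvious gain").

**Coupled partitioning for comparisons.** When two conditions of one
network are compared, the second condition's finest partition is
warm-started from the first's, and warm-started moves require a modularity
gain of at least one mean-edge-weight's worth of evidence
(`hysteresis_frac = 1.0`). Rationale: marginal nodes sitting almost
exactly on a community boundary otherwise flip on numerically negligible
gain differences, and such a flip moves the node's entire coarse
coordinate, producing a spurious top-ranked "driver". With the hysteresis,
a community flip in the comparison reflects at least one full edge of
rewiring evidence. Both behaviours are plain function arguments
(`init`, `hysteresis_frac`) and switch off cleanly (`warm_start=False`).

### 2. Base embedding of the coarsest graph

Two embedders are provided; which one is right depends on what "similar"
should mean.

- `neighborhood` (pipeline default): the *expected* window co-occurrence
  of truncated random walks, S = (1/T) Σ_{r≤T} P^r with P the
  row-stochastic transition matrix and T the window (default 5), converted
  to positive PMI and factorized by truncated SVD (U·√Σ, rows unit-
  normalized). This is the closed-form counterpart of skip-gram random-walk
  embedders, computed without sampling noise; `walk_params={"sampled":
  True}` switches to seeded Monte-Carlo walks for the classical variant.
  Crucially for this pipeline, it is *positional*: distinct communities of
  the coarsest graph receive well-separated coordinates, which is what the
  downstream displacement scores require. A structural-role embedder would
  map the near-symmetric communities of a modular network almost on top of
  each other and erase the signal.
- `structural`: log-transformed degree-profile features (in/out degree and
  strength, neighbor-degree summaries at radius ≤ 2), standardized and
  SVD-reduced. Automorphically equivalent nodes map to identical vectors.
  This is the right notion of identity for TF hierarchy-role analysis
  (commanders / messengers / soldiers) and is what the `roles` command
  uses.

SVD signs are fixed deterministically (largest-magnitude entry of each
right singular vector made positive), so embeddings are bit-reproducible.

### 3. Level-wise refinement

A layer-wise linear GraphSAGE model — per layer
h_v ← σ(W·concat(h_v, AGG{h_u : u ∈ N(v)})) with identity σ by default —
is trained once on the coarsest graph to reproduce the base embedding from
itself, minimizing (1/|V|)·‖Z − H(Z, G)‖_F by gradient descent. The step
size halves whenever a step would increase the loss, so the recorded loss
trajectory is monotone; training aborts on non-finite loss.

This objective has a degenerate global optimum: W = [I; 0] (copy the self
half, ignore neighbors) reaches loss 0 exactly. The neighbor-mixing
capacity that makes refined embeddings informative at finer levels
therefore comes from the *initialization*: weights start at
[(1−a)·I; a·I] with `neighbor_mix a = 0.5`, plus seeded Gaussian noise of
scale `init_noise = 1e-3`, and the reconstruction objective pulls them
only as far as reconstruction requires. The noise scale is deliberately
small: it is the only stochastic ingredient of the whole embedding stack,
and the false-positive analysis (below) measures precisely how much
distance it injects into a self-comparison.

Defaults `n_layers = 1` and `aggregator = "sum"` (edge-weighted, over
in- plus out-neighbors; empty neighborhoods aggregate to the zero vector):
with a copy-initialization from super-nodes, a single summing layer makes
each node's fine-level coordinate respond to every added or deleted edge
with a full neighbor-vector's worth of displacement while keeping the
response local to the changed node. A second layer propagates the
neighbor sums of neighbors, which concentrates mass on hubs and was found
to drown the per-node signal; the mean aggregator divides the displacement
by degree, attenuating exactly the signal of interest. Both remain
available (`n_layers`, `aggregator="mean"`).

Refinement proceeds downward: each finer node is initialized with an
*exact copy* of its super-node's vector (this copy is a contract, tested
to zero deviation) and one forward pass through the trained model produces
that level's embedding; the coarsest level itself reports the refined
H(Z^kh) for consistency across levels. An optional profile channel
(`profile_weight > 0`) adds each gene's own unit-normalized degree-profile
vector to its finest-level output — outside the aggregation, so untouched
genes gain exactly nothing. It is off by default: on the fixture
benchmarks it raised the scores of the rewired gene's *partners* (whose
profiles also change) more than it helped the gene itself.

### 4. Alignment and scoring

Embeddings of the two conditions live in arbitrarily different latent
bases, so condition 2 is mapped onto condition 1 by orthogonal Procrustes:
U = argmin ‖M₁ − M₂U‖_F over orthogonal U, fitted on the finest level's
shared nodes only, solved in closed form from the SVD of M₂ᵀM₁, and the
same U applied at every coarser level.

When the cross-product is rank-deficient (embedding rank below d, the
usual case when the coarsest graph has few communities), the optimum is
not unique — any rotation of the null space fits equally well. The
implementation returns the optimum *closest to the identity* (the
null-space blocks are themselves Procrustes-fitted to I). This makes
self-alignment return exactly U = I, so a network compared against itself
with the same seed scores exactly zero everywhere — the null the
false-positive analysis relies on — and coarse-level vectors that leave
the fitted subspace are never rotated arbitrarily. The trade-off: a
planted global rotation is only guaranteed to be removed exactly at all
levels when the finest-level embedding has full rank d.

A gene's raw score at level i is ‖z¹_{c₁(v)} − z²_{c₂(v)}U‖₂, where
c_s(v) is the gene's own condition-s super-node at that level (the two
hierarchies may partition differently; each gene is looked up through its
own condition's membership chain). `dl2norm` divides by the level's
maximum over genes, bounding scores to [0, 1] and making levels
comparable; a level whose maximum is numerically zero normalizes to zero.
Driver rankings use the *raw* finest-level score (max-normalization only
rescales a single comparison, so ranking is unchanged; raw values remain
comparable across comparisons).

**EDG/LDG calls.** "High" at a level means a dl2norm in the top
`high_quantile = 0.05` of genes at that level (floored at one gene; a gene
with zero displacement is never "high"). EDG: high at the finest level,
high at the coarsest, and coarse ≥ `approx_ratio = 0.8` × fine (the
coarse-fine "approximately equal" condition needs a numeric tolerance; 0.8
asks the coarse displacement to retain at least 80 % of the fine one).
LDG: high at the finest level with the coarsest below the high cutoff.
Everything else is conserved. For k_h = 2 the levels are labeled late
(G⁰), middle, early (coarsest). The per-gene `rank` column orders by the
maximum dl2norm over levels, per the profile-table convention; note that
at coarse levels all members of a community share one displacement, so
this rank is coarser-grained than the raw finest-level ranking used for
driver recovery.

### TF hierarchy roles

For directed GRNs, k-means (k = 3, seeded, 10 restarts) clusters the
finest-level embeddings; clusters are labeled by ascending mean in/out
degree ratio — commanders (in < out), messengers (in ≈ out), soldiers
(in > out). Per-node ratios floor the denominator at one so pure
out-hubs get a finite ratio of in-degree. Ties between clusters break by
larger size, then cluster id. Role switches between two conditions are
reported per TF, with a one-sided rank-sum test of whether switching TFs
have higher finest-level dl2norm than non-switching TFs.

## Baselines

- **Degree change** ΔD = |Δd_in| + |Δd_out| (directed counts).
- **Clustering-coefficient change** ΔC = |C_v(G₁) − C_v(G₂)| with
  C_v = 2e_v/(k_v(k_v−1)) on the underlying undirected simple graph;
  C_v = 0 for k_v < 2.
- **PageRank change** ΔPR with PR(v) = (1−d)/N + d·Σ PR(u)/L(u),
  damping d = 0.85, uniform start, dangling mass redistributed uniformly,
  power iteration to an L1 tolerance of 1e-8 (cap 100 iterations).
- **Contrastive learning** ΔE: per graph, Louvain clusters; embeddings
  (seeded Gaussian init, scale 0.1 so initial distances sit below the
  margin) trained 100 epochs at lr 0.05 on the hinge
  max(0, margin + intra − inter) with margin 1.0, where intra/inter are
  mean pairwise distances within/between clusters; the two graphs'
  embeddings are then Procrustes-aligned on shared nodes and ΔE is the
  per-node row distance. The loss form, optimizer and cross-graph
  alignment are this package's concretization of a contrastive baseline
  described only at the idea level elsewhere; they are recorded here as
  such.

## Synthetic fixtures and what they show

`make_planted_graph` draws stochastic-block-model networks with contiguous
planted blocks; weighted mode mimics unsigned-correlation weights
(Uniform(0.6, 0.95) within blocks, Uniform(0.1, 0.4) between). Defaults
for the benchmark fixtures: 40 nodes / 3 blocks / p_in = 0.4 /
p_out = 0.05 for directed GRN fixtures (matching the scale of a
40-TF regulatory network with ~3 regulatory communities), 60 nodes for the
weighted GCN fixtures.

**GRN rewiring scheme.** Condition A is one SBM draw; the edge-donor
condition B is an independent draw whose block assignment is a seeded
permutation of A's — two cell types whose regulatory communities genuinely
differ, the regime in which borrowed edges rewire a TF across community
boundaries. For a chosen TF, a uniform 1..deg-sized sample of its incident
edges is deleted and an equal-sized sample of its B-only incident edges is
added; edges not incident to the TF are never touched. Draws that change
nothing or isolate a node are discarded (a typed `Discard`, not an
exception). R@n is the fraction of pairs whose planted TF ranks in the
top n by a method's score, ties broken by descending score then node id.

**GCN divergence scheme.** A modified gene adopts the full weighted
neighborhood profile of a template gene from its own Louvain cluster (late
divergence) or from a different cluster (early divergence); genes in
singleton clusters are excluded as either role; the modified–template slot
keeps the weight the template had toward the modified gene, when present.
Accuracy is the fraction of matched (LDG, EDG) pairs in which the
modified gene's early-divergence score strictly exceeds its
late-divergence score. The hierarchical score used is the **raw**
coarsest-level displacement: dl2norm is max-normalized within each
comparison, so the normalized variant saturates at 1.0 whenever the
modified gene tops its own pair and cannot be compared across the two
pairs (it remains available via `score="dl2norm"`).

**False-positive analysis.** Foreground: mean per-gene distance between a
network and its rewired counterpart. Background: the same network compared
with *itself* under independent refiner-training seeds, with identical
coarsening — so the background isolates training stochasticity, the one
random ingredient. Reported with a two-sided Welch t-test (no
equal-variance assumption).

What passing these fixtures shows: that the pipeline detects single-gene
rewiring against SBM noise, orders early vs. late divergence correctly,
and that its training noise floor sits an order of magnitude below genuine
rewiring signal. What it does not show: performance on real ChIP-seq or
single-cell-derived networks, whose degree distributions are heavier-
tailed, whose communities are less balanced, and whose edges carry
correlated measurement noise that the SBM does not model; nor robustness
to gene-identifier mismatches or to conditions whose shared node set is
small.

## Expression preprocessing (GCN construction)

`aggregate_metacells` de-sparsifies single-cell expression before
correlation: each metacell sums one seed cell and its 99 nearest neighbors
(`metacell_size = 100`) in a reduced coordinate space (typically 20 PCA
dimensions), never crossing cell-type/sex/condition strata; strata smaller
than the metacell size are skipped with a warning. The aggregate matrix is
depth-normalized per metacell, then z-scored per gene.
`build_coexpression_graph` computes unsigned Pearson correlations on that
matrix; edges are kept either by absolute threshold t or by top-fraction q
of all pairwise |ρ| (default rule: top fraction, q = 0.05 — a fixed
fraction keeps edge density comparable across conditions, which matters
because modularity and coarsening depth are density-sensitive). Constant
genes are rejected by name. |ρ| is retained as the edge weight rather than
binarized, so the GCN schemes can match weight profiles.

## Numerical choices, in brief

- Undirected edges canonicalized as (min-id, max-id); duplicate symmetric
  rows tolerated if weights agree to 1e-9; weights strictly positive.
- Louvain ΔQ ties break to the lowest community id; node visit order is a
  seeded shuffle; community ids are contiguous, ordered by first
  appearance in `node_ids`. Same seed ⇒ identical partition.
- Gradient descent uses adaptive step halving (30 attempts per epoch)
  instead of a fixed schedule; descent is therefore monotone by
  construction and the final loss is reported on the model actually
  returned.
- Degenerate inputs: single-node graphs embed to the zero vector with a
  warning; zero-total-weight graphs cannot be partitioned or scored;
  empty neighborhoods aggregate to the zero vector; a 0/0 in dl2norm
  normalization is 0.
- All randomness flows through `numpy.random.default_rng` seeds carried in
  `RunConfig`; coarsening seeds and embedding seeds are separable
  (`seed2`, `embed_seed`, `embed_seed2`) so the false-positive background
  can vary training stochasticity alone.

## Problem sizes used in the shipped analyses

The test suite and `scripts/acceptance.py` run the benchmark at 30
GRN pairs (40 nodes, 3 blocks), 50 GCN triples (60 nodes, 3 blocks),
20 + 20 false-positive comparisons, 100 hierarchy draws and 10,000
Monte-Carlo rotations, with embedding dimension d = 32 for pipeline runs
(d ≤ 16 in unit fixtures). These sizes give stable statistics while
keeping a full run in the tens of seconds on one CPU; the pipeline itself
scales to thousands of nodes (runtime is dominated by dense SVD and the
per-level forward passes, both O(n·d) to O(n²) at these densities).

## Known limitations

- The reconstruction loss's degenerate optimum means the refiner's
  neighbor sensitivity is initialization-borne, not learned; a contrastive
  or reconstruction-with-corruption objective would make it learned, at
  the cost of more hyper-parameters.
- Procrustes alignment removes only orthogonal discrepancies; differences
  in per-condition training that are not orthogonal leave a noise floor
  (measured by the false-positive background).
- With per-level max-normalization, dl2norm is comparable across levels
  within one comparison but not across comparisons; cross-comparison
  analyses should use raw distances (as the benchmark metrics do).
- Coarse-level displacement is shared by all members of a community, so
  coarse-level rankings cannot separate genes within one community.
- A gene whose rewiring swaps one same-community neighbor for another of
  identical weight is invisible at community resolution; the optional
  profile channel mitigates but does not eliminate this.
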