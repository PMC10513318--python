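"""Synthetic fixtures, rewiring simulations, and benchmark metrics.

Two simulation schemes provide ground truth where real networks have none:

* **GRN rewiring** — for a chosen TF, delete a random subset of its
  incident edges in condition A and add a random subset of edges it has
  only in condition B; every other node's edges are untouched, so the
  chosen TF is the one true driver and a good method should rank it first.
* **GCN divergence** — a "modified gene" adopts the weighted neighborhood
  profile of a "template gene" drawn from its own Louvain cluster (late
  divergence: local rewiring) or from a different cluster (early
  divergence: cross-community rewiring).

Metrics: ``R@n`` (recall of the planted driver in the top-n ranking),
EDG-vs-LDG accuracy (fraction of triples where the early-divergent
modification scores higher than the late one at the coarse level), and a
false-positive analysis comparing foreground (different networks) to
background (self-comparison) mean node distances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import ttest_ind

from .baselines import BASELINES, NodeScoreTable
from .coarsen import Partition, partition_louvain
from .graphs import AttributedGraph
from .pipeline import RunConfig, compare_networks, mean_node_distance

__all__ = [
    "SimulatedPair",
    "Discard",
    "BenchmarkResult",
    "make_planted_graph",
    "simulate_grn_rewiring",
    "simulate_gcn_divergent",
    "recall_at_n",
    "edg_vs_ldg_accuracy",
    "false_positive_test",
    "rewiring_scorer",
    "planted_blocks",
    "generate_grn_pairs",
    "generate_gcn_triples",
    "run_grn_benchmark",
    "run_gcn_benchmark",
]


@dataclass
class SimulatedPair:
    """An (original, modified) network pair with its planted driver node."""

    original: AttributedGraph
    modified: AttributedGraph
    target_node: str
    scheme: str
    seed: int
    manifest: dict = field(default_factory=dict)


@dataclass
class Discard:
    """A simulation draw rejected by the validity rules (not an error)."""

    reason: str


@dataclass
class BenchmarkResult:
    """Recall table / accuracy plus false-positive statistics."""

    recalls: dict[str, dict[int, float]] | None = None
    accuracy: dict[str, float] | None = None
    n_pairs: int = 0
    target_ranks: dict[str, list[int]] | None = None
    foreground_mean: float = np.nan
    background_mean: float = np.nan
    p_value: float = np.nan


# ---------------------------------------------------------------------------
# Fixture generators
# ---------------------------------------------------------------------------

def make_planted_graph(
    n_nodes: int = 40,
    n_blocks: int = 3,
    p_in: float = 0.4,
    p_out: float = 0.05,
    directed: bool = True,
    weighted: bool = False,
    seed: int = 0,
) -> AttributedGraph:
    """Stochastic-block-model graph with planted communities.

    Blocks are contiguous runs of nodes.  In weighted mode (GCN stand-in)
    edge weights mimic unsigned correlations: Uniform(0.6, 0.95) within a
    block, Uniform(0.1, 0.4) between blocks.
    """
    if not p_in > p_out:
        raise ValueError(f"p_in must exceed p_out (got {p_in} <= {p_out})")
    rng = np.random.default_rng(seed)
    width = max(2, len(str(n_nodes - 1)))
    nodes = [f"g{i:0{width}d}" for i in range(n_nodes)]
    block = np.array([min(i * n_blocks // n_nodes, n_blocks - 1) for i in range(n_nodes)])
    # expected isolation check (undirected approximation)
    per_block = n_nodes / n_blocks
    exp_deg = p_in * (per_block - 1) + p_out * (n_nodes - per_block)
    if directed:
        exp_deg *= 2
    if np.exp(-exp_deg) > 0.10:
        warnings.warn(
            f"expected isolated-node fraction {np.exp(-exp_deg):.2f} > 10%"
        )
    edges: list[tuple[str, str, float]] = []
    for i in range(n_nodes):
        js = range(n_nodes) if directed else range(i + 1, n_nodes)
        for j in js:
            if i == j:
                continue
            same = block[i] == block[j]
            if rng.random() < (p_in if same else p_out):
                if weighted:
                    w = rng.uniform(0.6, 0.95) if same else rng.uniform(0.1, 0.4)
                else:
                    w = 1.0
                edges.append((nodes[i], nodes[j], float(w)))
    return AttributedGraph(nodes, edges, directed=directed)


def planted_blocks(n_nodes: int, n_blocks: int) -> dict[str, int]:
    """The generator's planted membership map (same naming convention)."""
    width = max(2, len(str(n_nodes - 1)))
    return {
        f"g{i:0{width}d}": min(i * n_blocks // n_nodes, n_blocks - 1)
        for i in range(n_nodes)
    }


# ---------------------------------------------------------------------------
# Simulation schemes
# ---------------------------------------------------------------------------

def _incident(g: AttributedGraph, node: str) -> list[tuple[str, str, float]]:
    return [(u, v, w) for u, v, w in g.edges if u == node or v == node]


def _degrees(edges: list[tuple[str, str, float]], nodes: list[str]) -> dict[str, int]:
    deg = {n: 0 for n in nodes}
    for u, v, _ in edges:
        deg[u] += 1
        deg[v] += 1
    return deg


def simulate_grn_rewiring(
    g_a: AttributedGraph,
    g_b: AttributedGraph,
    node: str,
    del_frac: float | None = None,
    seed: int = 0,
) -> SimulatedPair | Discard:
    """Rewire one TF of ``g_a`` toward its ``g_b`` wiring.

    Deletes a seeded random subset of ``node``'s incident edges (a uniform
    1..deg count by default, or ``round(del_frac * deg)``) and adds an
    equal-sized seeded sample of edges incident to ``node`` that exist only
    in ``g_b``.  Edges not incident to ``node`` are never touched.  The draw
    is discarded (typed outcome) if it changes nothing or isolates any node.
    """
    if node not in g_a.node_ids or node not in g_b.node_ids:
        raise ValueError(f"node {node!r} absent from one of the graphs")
    rng = np.random.default_rng(seed)
    inc_a = _incident(g_a, node)
    a_set = {(u, v) for u, v, _ in g_a.edges}
    candidates = [e for e in _incident(g_b, node) if (e[0], e[1]) not in a_set]
    if not inc_a and not candidates:
        return Discard("no incident edges to modify")
    if inc_a:
        if del_frac is None:
            k_del = int(rng.integers(1, len(inc_a) + 1))
        else:
            k_del = min(len(inc_a), max(0, int(round(del_frac * len(inc_a)))))
    else:
        k_del = 0
    del_idx = rng.choice(len(inc_a), size=k_del, replace=False) if k_del else []
    deleted = {(inc_a[i][0], inc_a[i][1]) for i in del_idx}
    k_add = min(k_del if k_del else 1, len(candidates))
    add_idx = rng.choice(len(candidates), size=k_add, replace=False) if k_add else []
    added = [candidates[i] for i in add_idx]
    # rebuild node's edge set in g_a's namespace (weights 1.0 in GRN mode kept)
    new_edges = [e for e in g_a.edges if (e[0], e[1]) not in deleted]
    existing = {(u, v) for u, v, _ in new_edges}
    for u, v, w in added:
        if (u, v) not in existing:
            new_edges.append((u, v, w))
            existing.add((u, v))
    if {(u, v) for u, v, _ in new_edges} == a_set:
        return Discard("no difference between original and modified")
    deg = _degrees(new_edges, g_a.node_ids)
    isolated = [n for n, k in deg.items() if k == 0 and _degrees(g_a.edges, [n])[n] > 0]
    if isolated:
        return Discard(f"modification isolates node(s) {isolated[:3]}")
    modified = AttributedGraph(list(g_a.node_ids), new_edges, directed=g_a.directed)
    return SimulatedPair(
        original=g_a,
        modified=modified,
        target_node=node,
        scheme="grn-rewire",
        seed=seed,
        manifest={"deleted": sorted(deleted), "added": sorted((u, v) for u, v, _ in added)},
    )


def simulate_gcn_divergent(
    g: AttributedGraph,
    partition: Partition,
    scheme: str = "ldg",
    seed: int = 0,
    target: str | None = None,
) -> SimulatedPair | Discard:
    """Make one gene adopt a template gene's weighted neighborhood profile.

    ``scheme='ldg'`` draws the template from the modified gene's own Louvain
    cluster (late divergence); ``'edg'`` from a different cluster (early
    divergence).  Genes sitting in singleton clusters are excluded both as
    modified genes and as templates.  The modified gene's incident edges are
    replaced by edges to the template's neighbors carrying the template's
    weights; the modified-template slot keeps the weight the template had
    toward the modified gene, when present.
    """
    if scheme not in ("ldg", "edg"):
        raise ValueError(f"scheme must be 'ldg' or 'edg', got {scheme!r}")
    rng = np.random.default_rng(seed)
    comms = partition.communities()
    eligible = {n for ns in comms.values() if len(ns) >= 2 for n in ns}
    if target is None:
        pool = sorted(eligible)
        if not pool:
            return Discard("no gene outside singleton clusters")
        target = pool[int(rng.integers(len(pool)))]
    elif target not in eligible:
        return Discard(f"target {target!r} sits in a singleton cluster")
    c_m = partition.membership[target]
    if scheme == "ldg":
        pool = [n for n in comms[c_m] if n != target]
    else:
        pool = sorted(
            n for c, ns in comms.items() if c != c_m and len(ns) >= 2 for n in ns
        )
    if not pool:
        return Discard(f"no eligible {scheme} template for {target!r}")
    template = sorted(pool)[int(rng.integers(len(pool)))]

    nxg = g.to_networkx()
    new_edges = [e for e in g.edges if target not in (e[0], e[1])]
    for x in sorted(nxg.neighbors(template)):
        if x == target:
            continue
        w = nxg[template][x]["weight"]
        u, v = (target, x) if target < x else (x, target)
        new_edges.append((u, v, float(w)))
    if nxg.has_edge(template, target):
        w = nxg[template][target]["weight"]
        u, v = (target, template) if target < template else (template, target)
        new_edges.append((u, v, float(w)))
    deg = _degrees(new_edges, g.node_ids)
    orig_deg = _degrees(g.edges, g.node_ids)
    isolated = [n for n, k in deg.items() if k == 0 and orig_deg[n] > 0]
    if isolated:
        return Discard(f"modification isolates node(s) {isolated[:3]}")
    modified = AttributedGraph(list(g.node_ids), new_edges, directed=False)
    if modified.equals(g):
        return Discard("no difference between original and modified")
    return SimulatedPair(
        original=g,
        modified=modified,
        target_node=target,
        scheme=f"gcn-{scheme}",
        seed=seed,
        manifest={"template": template},
    )


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def _ranked(scores: dict[str, float]) -> list[str]:
    return sorted(scores, key=lambda n: (-scores[n], n))


def recall_at_n(results: list[tuple[str, dict[str, float]]], n: int) -> float:
    """R@n = fraction of pairs whose planted driver ranks in the top n."""
    if not results:
        raise ValueError("empty result set")
    hits = sum(1 for target, scores in results if target in _ranked(scores)[:n])
    return hits / len(results)


def rewiring_scorer(config: RunConfig | None = None):
    """Main-method scorer: finest-level raw embedding distance per node."""
    cfg = config or RunConfig()

    def score(g1: AttributedGraph, g2: AttributedGraph) -> dict[str, float]:
        return compare_networks(g1, g2, cfg).node_scores(level=0)

    return score


def edg_vs_ldg_accuracy(
    triples: list[tuple[SimulatedPair, SimulatedPair]],
    scorer=None,
    config: RunConfig | None = None,
    score: str = "raw",
) -> float:
    """Fraction of (LDG pair, EDG pair) triples where the target's
    early-divergence score strictly exceeds its late-divergence score.

    With the default hierarchical scorer the score is the target's
    coarsest-level embedding distance (raw by default; ``score='dl2norm'``
    switches to the per-pair normalized value).  A plain per-node
    ``scorer(g1, g2) -> {node: score}`` can be supplied for baselines.
    """
    if not triples:
        raise ValueError("empty triple set")
    wins = 0
    for ldg_pair, edg_pair in triples:
        if ldg_pair.target_node != edg_pair.target_node:
            raise ValueError("LDG and EDG pairs must share the target gene")
        target = ldg_pair.target_node
        if scorer is not None:
            s_ldg = scorer(ldg_pair.original, ldg_pair.modified)[target]
            s_edg = scorer(edg_pair.original, edg_pair.modified)[target]
        else:
            cfg = config or RunConfig(mode="gcn")
            r_ldg = compare_networks(ldg_pair.original, ldg_pair.modified, cfg)
            r_edg = compare_networks(edg_pair.original, edg_pair.modified, cfg)
            normalized = score == "dl2norm"
            s_ldg = r_ldg.node_scores(r_ldg.coarse_level(), normalized)[target]
            s_edg = r_edg.node_scores(r_edg.coarse_level(), normalized)[target]
        if s_edg > s_ldg:
            wins += 1
    return wins / len(triples)


def false_positive_test(
    pairs: list[SimulatedPair],
    config: RunConfig | None = None,
    n_background_reps: int = 20,
    seed: int = 0,
) -> BenchmarkResult:
    """Foreground vs background mean node distance with a Welch t-test.

    Foreground: each pair's original compared with its modified network.
    Background: a modified network compared with *itself* using independent
    embedding seeds, so any nonzero distance is pure training stochasticity.
    """
    if n_background_reps < 2:
        raise ValueError("need at least 2 background repetitions")
    cfg = config or RunConfig()
    fg = []
    for i, pair in enumerate(pairs):
        c = replace(cfg, seed=cfg.seed + i, seed2=cfg.seed + i)
        fg.append(mean_node_distance(compare_networks(pair.original, pair.modified, c)))
    bg = []
    rng = np.random.default_rng(seed)
    for i in range(n_background_reps):
        pair = pairs[i % len(pairs)]
        s1, s2 = rng.integers(1, 2**31 - 1, size=2)
        # identical graphs, independent embedding/training seeds: any nonzero
        # distance is pure training stochasticity
        c = replace(cfg, embed_seed=int(s1), embed_seed2=int(s2))
        bg.append(mean_node_distance(compare_networks(pair.modified, pair.modified, c)))
    stat = ttest_ind(fg, bg, equal_var=False)
    return BenchmarkResult(
        n_pairs=len(pairs),
        foreground_mean=float(np.mean(fg)),
        background_mean=float(np.mean(bg)),
        p_value=float(stat.pvalue),
    )


# ---------------------------------------------------------------------------
# Benchmark orchestration
# ---------------------------------------------------------------------------

def generate_grn_pairs(
    n_pairs: int = 30,
    n_nodes: int = 40,
    n_blocks: int = 3,
    p_in: float = 0.4,
    p_out: float = 0.05,
    seed: int = 0,
) -> list[SimulatedPair]:
    """Planted-SBM analogue of the two-condition TF rewiring simulation.

    Condition A is an SBM with planted blocks; condition B (the edge donor)
    is an independent SBM whose block assignment is a seeded permutation of
    A's, mimicking two cell types whose regulatory communities genuinely
    differ — the regime in which edges borrowed from the other condition
    rewire a TF across community boundaries.
    """
    g_a = make_planted_graph(n_nodes, n_blocks, p_in, p_out, directed=True, seed=seed)
    raw = make_planted_graph(
        n_nodes, n_blocks, p_in, p_out, directed=True, seed=seed + 1_000_003
    )
    perm_rng = np.random.default_rng(seed + 7)
    relabel = dict(zip(raw.node_ids, perm_rng.permutation(raw.node_ids)))
    g_b = AttributedGraph(
        list(raw.node_ids),
        [(relabel[u], relabel[v], w) for u, v, w in raw.edges],
        directed=True,
    )
    pairs: list[SimulatedPair] = []
    rng = np.random.default_rng(seed)
    attempts = 0
    while len(pairs) < n_pairs and attempts < 20 * n_pairs:
        node = g_a.node_ids[int(rng.integers(g_a.n_nodes))]
        out = simulate_grn_rewiring(g_a, g_b, node, seed=int(rng.integers(2**31 - 1)))
        attempts += 1
        if isinstance(out, SimulatedPair):
            pairs.append(out)
    if len(pairs) < n_pairs:
        warnings.warn(f"only {len(pairs)}/{n_pairs} valid simulated pairs generated")
    return pairs


def run_grn_benchmark(
    pairs: list[SimulatedPair],
    methods: list[str] | None = None,
    n_values: tuple[int, ...] = (1, 2, 3, 4, 5),
    config: RunConfig | None = None,
) -> BenchmarkResult:
    """Score every pair with the main method plus baselines; tabulate R@n."""
    cfg = config or RunConfig(mode="grn")
    methods = methods if methods is not None else ["hierarchical", *BASELINES]
    per_method: dict[str, list[tuple[str, dict[str, float]]]] = {m: [] for m in methods}
    ranks: dict[str, list[int]] = {m: [] for m in methods}
    for i, pair in enumerate(pairs):
        for m in methods:
            if m == "hierarchical":
                c = replace(cfg, seed=cfg.seed + i, seed2=cfg.seed + i)
                scores = compare_networks(pair.original, pair.modified, c).node_scores(0)
            else:
                table: NodeScoreTable = BASELINES[m](
                    pair.original, pair.modified, **(
                        {"seed": cfg.seed + i} if m == "contrastive" else {}
                    )
                )
                scores = table.scores
            per_method[m].append((pair.target_node, scores))
            ranks[m].append(_ranked(scores).index(pair.target_node) + 1)
    recalls = {
        m: {n: recall_at_n(per_method[m], n) for n in n_values} for m in methods
    }
    return BenchmarkResult(recalls=recalls, n_pairs=len(pairs), target_ranks=ranks)


def generate_gcn_triples(
    n_triples: int = 50,
    n_nodes: int = 60,
    n_blocks: int = 3,
    p_in: float = 0.4,
    p_out: float = 0.05,
    seed: int = 0,
) -> list[tuple[SimulatedPair, SimulatedPair]]:
    """Matched (LDG, EDG) modification pairs on one planted weighted GCN."""
    g = make_planted_graph(
        n_nodes, n_blocks, p_in, p_out, directed=False, weighted=True, seed=seed
    )
    part = partition_louvain(g, seed=seed)
    rng = np.random.default_rng(seed)
    triples: list[tuple[SimulatedPair, SimulatedPair]] = []
    comms = part.communities()
    eligible = sorted(n for ns in comms.values() if len(ns) >= 2 for n in ns)
    attempts = 0
    while len(triples) < n_triples and attempts < 20 * n_triples:
        attempts += 1
        target = eligible[int(rng.integers(len(eligible)))]
        s = int(rng.integers(2**31 - 1))
        ldg = simulate_gcn_divergent(g, part, "ldg", seed=s, target=target)
        edg = simulate_gcn_divergent(g, part, "edg", seed=s, target=target)
        if isinstance(ldg, SimulatedPair) and isinstance(edg, SimulatedPair):
            triples.append((ldg, edg))
    if len(triples) < n_triples:
        warnings.warn(f"only {len(triples)}/{n_triples} valid triples generated")
    return triples


def run_gcn_benchmark(
    triples: list[tuple[SimulatedPair, SimulatedPair]],
    methods: list[str] | None = None,
    config: RunConfig | None = None,
) -> BenchmarkResult:
    """EDG-vs-LDG accuracy for the main method and each baseline."""
    cfg = config or RunConfig(mode="gcn")
    methods = methods if methods is not None else ["hierarchical", *BASELINES]
    accuracy: dict[str, float] = {}
    for m in methods:
        if m == "hierarchical":
            accuracy[m] = edg_vs_ldg_accuracy(triples, config=cfg)
        else:
            fn = BASELINES[m]
            if m == "contrastive":
                scorer = lambda a, b, fn=fn: fn(a, b, seed=cfg.seed).scores
            else:
                scorer = lambda a, b, fn=fn: fn(a, b).scores
            accuracy[m] = edg_vs_ldg_accuracy(triples, scorer=scorer)
    return BenchmarkResult(accuracy=accuracy, n_pairs=len(triples))
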