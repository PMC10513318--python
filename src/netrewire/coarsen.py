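"""Modularity-driven graph coarsening.

Each coarsening step detects non-overlapping communities by greedy Louvain
local moving (maximizing Newman-Girvan modularity Q) and collapses every
community into a super-node whose incident weights are the summed
cross-community weights.  Repeating the step yields a hierarchy
``G^0 > G^1 > ... > G^kh`` whose coarse levels expose pathway-scale
structure while the finest level retains per-gene detail.

Directed networks are symmetrized (weights summed over both orientations)
for partitioning only; the directed graph itself is preserved for
embeddings and degree analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .graphs import AttributedGraph

__all__ = [
    "Partition",
    "CoarsenHierarchy",
    "modularity",
    "partition_louvain",
    "reconstruct",
    "coarsen_hierarchy",
]


@dataclass
class Partition:
    """A non-overlapping community assignment with its modularity Q."""

    membership: dict[str, int]
    modularity: float

    def communities(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for node, c in self.membership.items():
            out.setdefault(c, []).append(node)
        return out

    @property
    def n_communities(self) -> int:
        return len(set(self.membership.values()))


@dataclass
class CoarsenHierarchy:
    """The chain of coarsened graphs plus node -> super-node maps.

    ``levels[0]`` is the finest graph G^0; ``levels[-1]`` the coarsest.
    ``memberships[i]`` maps a node id of ``levels[i]`` to its super-node id
    in ``levels[i + 1]``.  ``modularities[i]`` is Q of the partition that
    produced level ``i + 1``.
    """

    levels: list[AttributedGraph]
    memberships: list[dict[str, str]]
    modularities: list[float] = field(default_factory=list)

    @property
    def depth(self) -> int:
        return len(self.levels) - 1

    def trace(self, node: str, level: int) -> str:
        """Id of the super-node containing ``node`` (a G^0 id) at ``level``."""
        current = node
        for i in range(level):
            current = self.memberships[i][current]
        return current


def _symmetric_weights(g: AttributedGraph) -> tuple[dict[str, dict[str, float]], dict[str, float], float]:
    """Symmetrized neighbor weights, weighted degrees and total weight m."""
    adj: dict[str, dict[str, float]] = {n: {} for n in g.node_ids}
    for u, v, w in g.edges:
        if u == v:
            continue  # self-loops carry no neighbor information here
        adj[u][v] = adj[u].get(v, 0.0) + w
        adj[v][u] = adj[v].get(u, 0.0) + w
    k = {n: sum(adj[n].values()) for n in g.node_ids}
    m = sum(k.values()) / 2.0
    return adj, k, m


def modularity(g: AttributedGraph, membership: dict[str, int]) -> float:
    """Newman-Girvan modularity Q of a partition.

    Q = (1/2m) * sum_{ij in same community} [A_ij - k_i k_j / 2m], with A the
    (symmetrized) weight matrix, k weighted degrees, m the total edge weight.
    """
    missing = [n for n in g.node_ids if n not in membership]
    if missing:
        raise ValueError(f"membership missing nodes: {missing[:5]}")
    adj, k, m = _symmetric_weights(g)
    if m <= 0:
        raise ValueError("graph has zero total edge weight")
    sum_in: dict[int, float] = {}    # within-community edge weight (each pair twice)
    sum_tot: dict[int, float] = {}   # sum of degrees in community
    for n in g.node_ids:
        c = membership[n]
        sum_tot[c] = sum_tot.get(c, 0.0) + k[n]
        for nb, w in adj[n].items():
            if membership[nb] == c:
                sum_in[c] = sum_in.get(c, 0.0) + w
    q = 0.0
    for c, tot in sum_tot.items():
        q += sum_in.get(c, 0.0) / (2.0 * m) - (tot / (2.0 * m)) ** 2
    return q


def _local_moving(
    adj: dict[str, dict[str, float]],
    k: dict[str, float],
    m: float,
    nodes: list[str],
    resolution: float,
    rng: np.random.Generator,
    max_sweeps: int = 100,
    init: dict[str, int] | None = None,
    hysteresis: float = 0.0,
) -> dict[str, int]:
    """Greedy local moving to a local modularity maximum.

    Starts from all-singletons (or from ``init`` labels when warm-started).
    Each sweep visits nodes in a seeded shuffled order and re-assigns each
    to the neighboring community with the largest positive modularity gain
    (ties broken by lowest community id); sweeps repeat until no node moves.
    ``hysteresis`` (same units as edge weight) is the minimum gain required
    to move a node — a stability margin used with warm starts so that
    nodes sitting exactly on a community boundary do not flip on
    numerically negligible evidence.
    """
    if init is None:
        member = {n: i for i, n in enumerate(nodes)}
    else:
        member = dict(init)
    sum_tot: dict[int, float] = {}
    for n in nodes:
        sum_tot[member[n]] = sum_tot.get(member[n], 0.0) + k[n]
    order = list(nodes)
    for _ in range(max_sweeps):
        rng.shuffle(order)
        moved = False
        for v in order:
            cv, kv = member[v], k[v]
            w_to: dict[int, float] = {}
            for nb, w in adj[v].items():
                w_to[member[nb]] = w_to.get(member[nb], 0.0) + w
            sum_tot[cv] -= kv
            base = w_to.get(cv, 0.0) - resolution * sum_tot[cv] * kv / (2.0 * m)
            best_c, best_gain = cv, hysteresis
            for c in sorted(w_to):
                if c == cv:
                    continue
                gain = (w_to[c] - resolution * sum_tot[c] * kv / (2.0 * m)) - base
                if gain > best_gain + 1e-12:
                    best_c, best_gain = c, gain
            member[v] = best_c
            sum_tot[best_c] = sum_tot.get(best_c, 0.0) + kv
            if best_c != cv:
                moved = True
        if not moved:
            break
    return member


def partition_louvain(
    g: AttributedGraph,
    resolution: float = 1.0,
    max_passes: int = 2,
    seed: int = 0,
    init: dict[str, int] | None = None,
    hysteresis_frac: float = 1.0,
) -> Partition:
    """Seeded Louvain community detection.

    Each pass runs greedy local moving to a local modularity maximum and
    then aggregates communities into super-nodes, so that later passes can
    move whole communities at once.  ``max_passes`` caps the number of such
    phase pairs; two passes capture nearly all of the attainable
    modularity on networks of the sizes handled here.  The returned
    membership is expressed on the original nodes, with contiguous
    community ids ordered by first appearance in ``node_ids``.

    ``init`` warm-starts the first local-moving phase from an existing
    membership instead of all-singletons.  When comparing two conditions of
    one network this pins down the local optimum, so that community flips
    of marginal nodes reflect genuine rewiring rather than greedy
    tie-breaking noise.  Warm-started moves additionally require a gain of
    at least ``hysteresis_frac`` times the mean edge weight (default: one
    edge's worth of evidence) — nodes whose attachment to two communities
    is nearly tied stay where the reference partition put them.
    """
    if g.n_nodes == 0:
        raise ValueError("cannot partition an empty graph")
    adj, k, m = _symmetric_weights(g)
    if m <= 0:
        # no edges: every node its own community
        member = {n: i for i, n in enumerate(g.node_ids)}
        return Partition(member, 0.0)

    rng = np.random.default_rng(seed)
    # communities as labels on an aggregated graph; loops track internal weight
    agg_nodes = list(g.node_ids)
    agg_adj = adj
    agg_loops = {n: 0.0 for n in agg_nodes}
    assign = {n: n for n in g.node_ids}  # original node -> aggregated node
    warm = init

    mean_w = m / max(1, g.n_edges)
    for _ in range(max_passes):
        k_agg = {
            n: sum(agg_adj[n].values()) + 2.0 * agg_loops[n] for n in agg_nodes
        }
        local = _local_moving(
            agg_adj, k_agg, m, agg_nodes, resolution, rng,
            init=warm,
            hysteresis=hysteresis_frac * mean_w if warm is not None else 0.0,
        )
        warm = None  # only the first phase is warm-started
        n_comms = len(set(local.values()))
        if n_comms == len(agg_nodes):
            break  # no merge happened; local maximum reached
        # aggregate: one super-node per community
        label_of: dict[int, str] = {}
        for n in agg_nodes:
            c = local[n]
            if c not in label_of:
                label_of[c] = f"_a{len(label_of)}"
        new_nodes = [label_of[c] for c in dict.fromkeys(local[n] for n in agg_nodes)]
        new_adj: dict[str, dict[str, float]] = {s: {} for s in new_nodes}
        new_loops = {s: 0.0 for s in new_nodes}
        for n in agg_nodes:
            sn = label_of[local[n]]
            new_loops[sn] += agg_loops[n]
            for nb, w in agg_adj[n].items():
                snb = label_of[local[nb]]
                if sn == snb:
                    new_loops[sn] += w / 2.0
                else:
                    new_adj[sn][snb] = new_adj[sn].get(snb, 0.0) + w
        assign = {v: label_of[local[assign[v]]] for v in assign}
        agg_nodes, agg_adj, agg_loops = new_nodes, new_adj, new_loops
        if len(agg_nodes) == 1:
            break

    # final node-level refinement: aggregation passes move whole communities,
    # so the result may not be a local optimum for single-node moves; one
    # more local-moving phase on the original graph makes it one, which also
    # keeps warm-started re-partitions of a perturbed graph consistent
    labels = {c: i for i, c in enumerate(dict.fromkeys(assign[n] for n in g.node_ids))}
    current = {n: labels[assign[n]] for n in g.node_ids}
    refined = _local_moving(
        adj, k, m, list(g.node_ids), resolution, rng,
        init=current,
        hysteresis=hysteresis_frac * mean_w if init is not None else 0.0,
    )

    # relabel communities contiguously, ordered by first appearance in node_ids
    relabel: dict[int, int] = {}
    for n in g.node_ids:
        c = refined[n]
        if c not in relabel:
            relabel[c] = len(relabel)
    member = {n: relabel[refined[n]] for n in g.node_ids}
    return Partition(member, modularity(g, member))


def reconstruct(
    g: AttributedGraph,
    p: Partition,
    keep_self_loops: bool = False,
) -> tuple[AttributedGraph, dict[str, str]]:
    """Collapse each community into a super-node.

    Super-edge weight is the summation of all member edge weights crossing
    the two communities; intra-community weight becomes a self-loop only
    when ``keep_self_loops`` is set, otherwise it is dropped (self-loops add
    no neighbor information to the relational embeddings downstream).
    Directedness is preserved.
    """
    comms = p.communities()
    super_ids = {c: f"c{c}" for c in sorted(comms)}
    membership = {n: super_ids[c] for n, c in p.membership.items()}
    agg: dict[tuple[str, str], float] = {}
    for u, v, w in g.edges:
        su, sv = membership[u], membership[v]
        if su == sv and not keep_self_loops:
            continue
        if not g.directed and su > sv:
            su, sv = sv, su
        agg[(su, sv)] = agg.get((su, sv), 0.0) + w
    nodes = [super_ids[c] for c in sorted(comms)]
    coarse = AttributedGraph(
        nodes,
        [(u, v, w) for (u, v), w in agg.items()],
        directed=g.directed,
        allow_self_loops=keep_self_loops,
    )
    return coarse, membership


def coarsen_hierarchy(
    g: AttributedGraph,
    k_h: int = 2,
    min_gain: float = 1e-4,
    resolution: float = 1.0,
    max_passes: int = 2,
    seed: int = 0,
    keep_self_loops: bool = False,
    init_partition: dict[str, int] | None = None,
) -> CoarsenHierarchy:
    """Iteratively partition + reconstruct up to ``k_h`` levels.

    Coarsening stops early when a step would not reduce the node count or
    when the partition's modularity stops improving by at least
    ``min_gain`` over the previous level's — the "no obvious gain" rule.
    Realized depth is therefore at most ``k_h``.  ``init_partition``
    warm-starts the first (finest) partition, which couples the community
    assignments of two conditions being compared.
    """
    if k_h < 0:
        raise ValueError(f"k_h must be >= 0, got {k_h}")
    levels = [g]
    memberships: list[dict[str, str]] = []
    modularities: list[float] = []
    q_prev: float | None = None
    for i in range(k_h):
        current = levels[-1]
        if current.n_edges == 0:
            break
        p = partition_louvain(
            current, resolution=resolution, max_passes=max_passes, seed=seed + i,
            init=init_partition if i == 0 else None,
        )
        if p.n_communities >= current.n_nodes:
            break  # no reduction
        if q_prev is not None and p.modularity - q_prev < min_gain:
            break  # no obvious modularity gain
        coarse, member = reconstruct(current, p, keep_self_loops=keep_self_loops)
        levels.append(coarse)
        memberships.append(member)
        modularities.append(p.modularity)
        q_prev = p.modularity
    return CoarsenHierarchy(levels, memberships, modularities)
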