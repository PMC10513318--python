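"""Network data model, file I/O, co-expression construction and pruning.

The package operates on two flavours of biological network: directed,
unweighted TF-to-TF regulatory networks (GRNs) derived from ChIP-seq
binding, and undirected gene co-expression networks (GCNs) weighted by
unsigned Pearson correlation of (metacell-aggregated) expression.  Both are
represented by :class:`AttributedGraph`, a thin validated container that
converts to :mod:`networkx` graphs for algorithmic work.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import networkx as nx

__all__ = [
    "AttributedGraph",
    "ExpressionMatrix",
    "GraphPair",
    "read_graph",
    "write_graph",
    "build_coexpression_graph",
    "aggregate_metacells",
    "common_subgraph",
]


class GraphFormatError(ValueError):
    """Raised for malformed network files or invalid graph construction."""


@dataclass
class AttributedGraph:
    """A named network with optional node features.

    Parameters
    ----------
    node_ids
        Ordered, unique string identifiers (genes / TFs).
    edges
        ``(source, target, weight)`` triples; weights strictly positive.
        Undirected edges are canonicalized to ``(min, max)`` and stored once.
    directed
        Whether edge orientation is meaningful (GRN mode).
    features
        Optional ``n_nodes x d_x`` real matrix of node attributes.
    """

    node_ids: list[str]
    edges: list[tuple[str, str, float]]
    directed: bool
    features: np.ndarray | None = None
    allow_self_loops: bool = False
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if len(self.node_ids) == 0:
            raise GraphFormatError("graph has no nodes")
        self._index = {n: i for i, n in enumerate(self.node_ids)}
        if len(self._index) != len(self.node_ids):
            raise GraphFormatError("duplicate node ids")
        canon: dict[tuple[str, str], float] = {}
        for u, v, w in self.edges:
            if u not in self._index or v not in self._index:
                raise GraphFormatError(f"edge endpoint not in node_ids: ({u}, {v})")
            w = float(w)
            if not w > 0:
                raise GraphFormatError(f"non-positive edge weight on ({u}, {v}): {w}")
            if u == v and not self.allow_self_loops:
                raise GraphFormatError(f"self-loop on {u} not allowed")
            if not self.directed and u > v:
                u, v = v, u
            key = (u, v)
            if key in canon:
                if abs(canon[key] - w) > 1e-9:
                    raise GraphFormatError(
                        f"duplicate edge ({u}, {v}) with conflicting weights "
                        f"{canon[key]} vs {w}"
                    )
            else:
                canon[key] = w
        self.edges = [(u, v, w) for (u, v), w in canon.items()]
        if self.features is not None:
            self.features = np.asarray(self.features, dtype=float)
            if self.features.shape[0] != len(self.node_ids):
                raise GraphFormatError("feature matrix row count != node count")

    # -- basic accessors -------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def index_of(self, node: str) -> int:
        return self._index[node]

    def total_weight(self) -> float:
        return float(sum(w for _, _, w in self.edges))

    def to_networkx(self) -> nx.Graph | nx.DiGraph:
        g: nx.Graph | nx.DiGraph = nx.DiGraph() if self.directed else nx.Graph()
        g.add_nodes_from(self.node_ids)
        g.add_weighted_edges_from(self.edges)
        return g

    def symmetrized_adjacency(self) -> np.ndarray:
        """Dense symmetric weight matrix (directed weights summed both ways)."""
        n = self.n_nodes
        a = np.zeros((n, n))
        for u, v, w in self.edges:
            i, j = self._index[u], self._index[v]
            a[i, j] += w
            if i != j:
                a[j, i] += w
        return a

    def subgraph(self, nodes: list[str]) -> "AttributedGraph":
        keep = set(nodes)
        feats = None
        if self.features is not None:
            rows = [self._index[n] for n in nodes]
            feats = self.features[rows]
        return AttributedGraph(
            node_ids=list(nodes),
            edges=[(u, v, w) for u, v, w in self.edges if u in keep and v in keep],
            directed=self.directed,
            features=feats,
            allow_self_loops=self.allow_self_loops,
        )

    def equals(self, other: "AttributedGraph") -> bool:
        return (
            self.node_ids == other.node_ids
            and self.directed == other.directed
            and sorted(self.edges) == sorted(other.edges)
        )


@dataclass
class ExpressionMatrix:
    """Genes x samples (or metacells) normalized expression."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise GraphFormatError("duplicate gene ids in expression matrix")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise GraphFormatError(
                f"expression shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )


@dataclass
class GraphPair:
    """Two networks restricted to a shared node set, ready for comparison."""

    g1: AttributedGraph
    g2: AttributedGraph
    shared_nodes: list[str]

    def __post_init__(self) -> None:
        if not self.shared_nodes:
            raise GraphFormatError("graph pair has no shared nodes")
        if self.g1.directed != self.g2.directed:
            raise GraphFormatError("graph pair mixes directed and undirected graphs")


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def _sniff_delimiter(line: str) -> str:
    return "," if ("," in line and "\t" not in line) else None  # type: ignore[return-value]


def read_graph(path: str | Path, fmt: str = "edge-list", directed: bool = False) -> AttributedGraph:
    """Read a network from an edge-list or square adjacency file.

    Edge-list rows are ``source target [weight]`` (tab, comma or whitespace
    separated; ``#`` comments skipped; missing weight defaults to 1.0).
    Adjacency files are square with node ids in the header row and first
    column; undirected adjacency must be symmetric to 1e-9.
    """
    path = Path(path)
    if fmt == "edge-list":
        nodes: list[str] = []
        seen: set[str] = set()
        edges: list[tuple[str, str, float]] = []
        with open(path) as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.strip()
                if line.startswith("# nodes:"):
                    # node roster emitted by write_graph; keeps isolated
                    # nodes (and node order) across a round trip
                    for n in line[len("# nodes:"):].split():
                        if n not in seen:
                            seen.add(n)
                            nodes.append(n)
                    continue
                if not line or line.startswith("#"):
                    continue
                parts = line.replace(",", "\t").split()
                if len(parts) not in (2, 3):
                    raise GraphFormatError(
                        f"{path}:{lineno}: expected 'source target [weight]', got {raw!r}"
                    )
                u, v = parts[0], parts[1]
                try:
                    w = float(parts[2]) if len(parts) == 3 else 1.0
                except ValueError as exc:
                    raise GraphFormatError(
                        f"{path}:{lineno}: bad weight {parts[2]!r}"
                    ) from exc
                for n in (u, v):
                    if n not in seen:
                        seen.add(n)
                        nodes.append(n)
                edges.append((u, v, w))
        if not edges and not nodes:
            raise GraphFormatError(f"{path}: empty graph")
        return AttributedGraph(nodes, edges, directed)
    if fmt == "adjacency":
        df = pd.read_csv(path, sep=None, engine="python", index_col=0)
        ids = [str(c) for c in df.columns]
        if [str(i) for i in df.index] != ids:
            raise GraphFormatError(f"{path}: adjacency row and column ids differ")
        a = df.to_numpy(dtype=float)
        if not directed and np.abs(a - a.T).max() > 1e-9:
            raise GraphFormatError(f"{path}: undirected adjacency is not symmetric")
        edges = []
        for i, u in enumerate(ids):
            for j, v in enumerate(ids):
                if a[i, j] != 0 and (directed or i < j):
                    edges.append((u, v, float(a[i, j])))
        if not ids:
            raise GraphFormatError(f"{path}: empty graph")
        return AttributedGraph(ids, edges, directed)
    raise GraphFormatError(f"unknown graph format {fmt!r}")


def write_graph(g: AttributedGraph, path: str | Path, fmt: str = "edge-list") -> Path:
    """Write a network with deterministic row ordering (lexicographic)."""
    path = Path(path)
    if fmt == "edge-list":
        with open(path, "w") as fh:
            fh.write("# nodes: " + " ".join(g.node_ids) + "\n")
            for u, v, w in sorted(g.edges):
                fh.write(f"{u}\t{v}\t{w:.6f}\n")
    elif fmt == "adjacency":
        n = g.n_nodes
        a = np.zeros((n, n))
        for u, v, w in g.edges:
            i, j = g.index_of(u), g.index_of(v)
            a[i, j] = w
            if not g.directed:
                a[j, i] = w
        df = pd.DataFrame(a, index=g.node_ids, columns=g.node_ids)
        df.to_csv(path, sep="\t", float_format="%.6f")
    else:
        raise GraphFormatError(f"unknown graph format {fmt!r}")
    return path


def read_expression(path: str | Path) -> ExpressionMatrix:
    """Read a genes x samples TSV with a header row of sample ids."""
    df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    return ExpressionMatrix(
        gene_ids=[str(i) for i in df.index],
        sample_ids=[str(c) for c in df.columns],
        values=df.to_numpy(dtype=float),
    )


# ---------------------------------------------------------------------------
# Co-expression networks
# ---------------------------------------------------------------------------

def build_coexpression_graph(
    expr: ExpressionMatrix,
    edge_rule: str = "top-fraction",
    q: float = 0.05,
    t: float = 0.5,
) -> AttributedGraph:
    """Build an unsigned-Pearson co-expression network.

    Edge weight is ``|rho|`` between gene pairs.  ``edge_rule`` is either
    ``"abs-threshold"`` (keep ``|rho| >= t``) or ``"top-fraction"`` (keep the
    top ``q`` fraction of all pairwise ``|rho|`` values, which keeps edge
    density comparable across conditions).  Isolated genes stay in
    ``node_ids``.
    """
    if expr.values.shape[1] < 3:
        raise GraphFormatError("need at least 3 samples to correlate genes")
    if edge_rule == "top-fraction" and not (0 < q <= 1):
        raise GraphFormatError(f"top-fraction q must be in (0, 1], got {q}")
    if edge_rule == "abs-threshold" and not (0 <= t <= 1):
        raise GraphFormatError(f"abs-threshold t must be in [0, 1], got {t}")
    sd = expr.values.std(axis=1)
    flat = np.flatnonzero(sd == 0)
    if flat.size:
        raise GraphFormatError(
            "constant gene(s) with zero variance: "
            + ", ".join(expr.gene_ids[i] for i in flat[:5])
        )
    rho = np.abs(np.corrcoef(expr.values))
    iu, ju = np.triu_indices(len(expr.gene_ids), k=1)
    vals = rho[iu, ju]
    if edge_rule == "abs-threshold":
        keep = vals >= t
    elif edge_rule == "top-fraction":
        k = max(1, int(round(q * vals.size)))
        order = np.argsort(-vals, kind="stable")
        keep = np.zeros(vals.size, dtype=bool)
        keep[order[:k]] = True
    else:
        raise GraphFormatError(f"unknown edge rule {edge_rule!r}")
    edges = [
        (expr.gene_ids[i], expr.gene_ids[j], float(min(vals[e], 1.0)))
        for e, (i, j) in enumerate(zip(iu, ju))
        if keep[e] and vals[e] > 0
    ]
    return AttributedGraph(list(expr.gene_ids), edges, directed=False)


def aggregate_metacells(
    expr: ExpressionMatrix,
    cell_coords: np.ndarray,
    group_labels: dict[str, str] | None = None,
    metacell_size: int = 100,
) -> ExpressionMatrix:
    """Aggregate cells into metacells by nearest neighbors in reduced space.

    Each output column sums one seed cell and its ``metacell_size - 1``
    nearest neighbors (Euclidean, in ``cell_coords`` — typically 20 PCA
    dimensions) within the seed's stratum (same cell type / sex / condition
    group).  The aggregate matrix is depth-normalized per metacell and then
    z-scored per gene, de-sparsifying single-cell counts before correlation.
    """
    if metacell_size < 2:
        raise GraphFormatError(f"metacell_size must be >= 2, got {metacell_size}")
    cell_coords = np.asarray(cell_coords, dtype=float)
    if cell_coords.shape[0] != len(expr.sample_ids):
        raise GraphFormatError("cell_coords rows must match number of cells")
    labels = group_labels or {c: "all" for c in expr.sample_ids}
    strata: dict[str, list[int]] = {}
    for idx, cell in enumerate(expr.sample_ids):
        strata.setdefault(labels[cell], []).append(idx)

    cols: list[np.ndarray] = []
    names: list[str] = []
    for stratum in sorted(strata):
        members = strata[stratum]
        if len(members) < metacell_size:
            warnings.warn(
                f"stratum {stratum!r} has {len(members)} < {metacell_size} cells; skipped"
            )
            continue
        coords = cell_coords[members]
        # brute-force within-stratum neighbor search; strata are modest in size
        d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(axis=-1)
        for local, cell_idx in enumerate(members):
            order = np.lexsort((np.arange(len(members)), d2[local]))
            chosen = [members[k] for k in order[:metacell_size]]
            cols.append(expr.values[:, chosen].sum(axis=1))
            names.append(f"mc_{expr.sample_ids[cell_idx]}")
    if not cols:
        raise GraphFormatError("no stratum large enough to form a metacell")
    mat = np.column_stack(cols)
    depth = mat.sum(axis=0)
    depth[depth == 0] = 1.0
    mat = mat / depth * depth.mean()          # normalize per metacell
    mu = mat.mean(axis=1, keepdims=True)
    sd = mat.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    mat = (mat - mu) / sd                     # scale per gene
    return ExpressionMatrix(list(expr.gene_ids), names, mat)


def common_subgraph(
    g1: AttributedGraph,
    g2: AttributedGraph,
    node_whitelist: list[str] | None = None,
) -> GraphPair:
    """Restrict both networks to their shared node set (optionally whitelisted)."""
    if g1.directed != g2.directed:
        raise GraphFormatError("cannot pair directed with undirected graph")
    shared = [n for n in g1.node_ids if n in set(g2.node_ids)]
    if node_whitelist is not None:
        wl = set(node_whitelist)
        shared = [n for n in shared if n in wl]
    if not shared:
        raise GraphFormatError("node intersection is empty")
    return GraphPair(g1.subgraph(shared), g2.subgraph(shared), shared)
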