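"""Base embedding of the coarsest graph and level-wise refinement.

The coarsest graph of a hierarchy is embedded once by a classical graph
representation learner (two modes below), and a layer-wise *linear*
GraphSAGE model is trained — only on the coarsest graph — to reproduce
that base embedding from itself.  The trained model is then applied level
by level: each finer node is initialized with an exact copy of its
super-node's vector and passed through the model, which mixes in an
aggregate of its neighbors' vectors, yielding embeddings at every
hierarchy level that inherit the coarse global structure while
differentiating nodes by their local neighborhoods.

Base embedding modes
--------------------
``neighborhood`` (default for the hierarchy)
    The expected window co-occurrence of truncated random walks is
    computed in closed form from powers of the transition matrix and its
    positive PMI is factorized by truncated SVD — the deterministic,
    closed-form counterpart of skip-gram random-walk embedders.  Distinct
    communities of the coarsest graph receive well-separated coordinates,
    which is what the downstream displacement scores need.  Setting
    ``walk_params={"sampled": True}`` switches to seeded Monte-Carlo walks.
``structural``
    Nodes are described by degree-profile features (in/out degree and
    strength, neighbor-degree summaries at radius <= 2) reduced by SVD, so
    structurally equivalent nodes land on the same vector regardless of
    adjacency — the right notion of identity for TF role analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .coarsen import CoarsenHierarchy
from .graphs import AttributedGraph

__all__ = [
    "EmbeddingSet",
    "RefinerModel",
    "embed_base",
    "initialize_refined",
    "sage_forward",
    "train_refiner",
    "embed_hierarchy",
]


@dataclass
class EmbeddingSet:
    """Per-level node -> vector maps for one network.

    ``per_level[i]`` corresponds to ``hierarchy.levels[i]`` (index 0 is the
    finest graph G^0).  All vectors share dimension ``d``.
    """

    per_level: list[dict[str, np.ndarray]]
    d: int

    def matrix(self, level: int, nodes: list[str]) -> np.ndarray:
        return np.vstack([self.per_level[level][n] for n in nodes])

    def transformed(self, u: np.ndarray) -> "EmbeddingSet":
        """A copy with every vector at every level right-multiplied by ``u``."""
        return EmbeddingSet(
            [{n: v @ u for n, v in lv.items()} for lv in self.per_level], self.d
        )


# ---------------------------------------------------------------------------
# Base embedding of the coarsest graph
# ---------------------------------------------------------------------------

def _fix_svd_signs(u: np.ndarray, vt: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # deterministic sign convention: largest-|.| entry of each right vector > 0
    for r in range(vt.shape[0]):
        j = int(np.argmax(np.abs(vt[r])))
        if vt[r, j] < 0:
            vt[r] *= -1.0
            u[:, r] *= -1.0
    return u, vt


def _project_unit_rows(x: np.ndarray, d: int, scale: bool = True) -> np.ndarray:
    """SVD-project rows to <= d components, zero-pad, unit-normalize."""
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    u, vt = _fix_svd_signs(u, vt)
    r = min(d, int((s > 1e-10).sum()))
    z = np.zeros((x.shape[0], d))
    if r > 0:
        z[:, :r] = u[:, :r] * (np.sqrt(s[:r]) if scale else s[:r])
    norms = np.linalg.norm(z, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return z / norms


def _structural_features(g: AttributedGraph, standardize: bool = True) -> np.ndarray:
    """Degree-profile feature matrix; automorphic nodes get identical rows.

    With ``standardize=False`` the log-transformed raw profiles are
    returned, so a node's row depends only on its own 2-hop neighborhood —
    the form used to augment level-0 initializations, where cross-condition
    comparability of untouched nodes matters.
    """
    nxg = g.to_networkx()
    und = nxg.to_undirected() if g.directed else nxg
    feats = []
    for n in g.node_ids:
        if g.directed:
            din, dout = nxg.in_degree(n), nxg.out_degree(n)
            sin = nxg.in_degree(n, weight="weight")
            sout = nxg.out_degree(n, weight="weight")
        else:
            din = dout = nxg.degree(n)
            sin = sout = nxg.degree(n, weight="weight")
        nbrs = sorted(und.neighbors(n))
        ndeg = np.array([und.degree(u) for u in nbrs], dtype=float)
        two_hop = set()
        for u in nbrs:
            two_hop.update(und.neighbors(u))
        two_hop.discard(n)
        two_hop -= set(nbrs)
        tdeg = np.array([und.degree(u) for u in sorted(two_hop)], dtype=float)

        def stats(a: np.ndarray) -> list[float]:
            if a.size == 0:
                return [0.0, 0.0, 0.0, 0.0]
            return [a.min(), a.mean(), a.max(), float(a.size)]

        feats.append([din, dout, sin, sout, din + dout] + stats(ndeg) + stats(tdeg))
    x = np.log1p(np.array(feats, dtype=float))
    if not standardize:
        return x
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    return (x - mu) / sd


def _profile_vectors(g: AttributedGraph, d: int) -> dict[str, np.ndarray]:
    """Unit-norm degree-profile vectors padded/truncated to dimension ``d``.

    Each node's vector depends only on its own local profile (no per-graph
    standardization or SVD), so an untouched node has bit-identical vectors
    in two conditions of the same network.
    """
    x = _structural_features(g, standardize=False)
    z = np.zeros((x.shape[0], d))
    r = min(d, x.shape[1])
    z[:, :r] = x[:, :r]
    norms = np.linalg.norm(z, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    z = z / norms
    return {n: z[i].copy() for i, n in enumerate(g.node_ids)}


def _expected_cooccurrence(g: AttributedGraph, window: int) -> np.ndarray:
    """Expected walk co-occurrence: average of transition-matrix powers."""
    a = g.symmetrized_adjacency()
    np.fill_diagonal(a, 0.0)
    deg = a.sum(axis=1)
    deg_safe = np.where(deg > 0, deg, 1.0)
    m = a / deg_safe[:, None]
    s = np.zeros_like(m)
    p = np.eye(g.n_nodes)
    for _ in range(window):
        p = p @ m
        s += p
    return s / window


def _sampled_cooccurrence(
    g: AttributedGraph,
    walk_length: int,
    num_walks: int,
    window: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Monte-Carlo window co-occurrence from seeded truncated random walks."""
    n = g.n_nodes
    idx = {node: i for i, node in enumerate(g.node_ids)}
    nxg = g.to_networkx()
    und = nxg.to_undirected() if g.directed else nxg
    nbrs: list[list[int]] = [[] for _ in range(n)]
    probs: list[np.ndarray] = [np.empty(0) for _ in range(n)]
    for node in g.node_ids:
        ns = sorted(u for u in und.neighbors(node) if u != node)
        ws = np.array([und[node][u].get("weight", 1.0) for u in ns], dtype=float)
        nbrs[idx[node]] = [idx[u] for u in ns]
        probs[idx[node]] = ws / ws.sum() if ws.size else ws
    co = np.zeros((n, n))
    for start in range(n):
        for _ in range(num_walks):
            walk = [start]
            cur = start
            for _ in range(walk_length - 1):
                if not nbrs[cur]:
                    break
                cur = nbrs[cur][rng.choice(len(nbrs[cur]), p=probs[cur])]
                walk.append(cur)
            for a in range(len(walk)):
                for b in range(a + 1, min(a + window + 1, len(walk))):
                    co[walk[a], walk[b]] += 1.0
                    co[walk[b], walk[a]] += 1.0
    return co


def embed_base(
    g: AttributedGraph,
    d: int = 32,
    mode: str = "neighborhood",
    walk_params: dict | None = None,
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """Embed one graph into ``d`` dimensions (unit-norm rows)."""
    if d < 2:
        raise ValueError(f"embedding dimension must be >= 2, got {d}")
    if g.n_nodes == 1:
        warnings.warn("single-node graph: returning the zero embedding")
        return {g.node_ids[0]: np.zeros(d)}
    if mode == "structural":
        z = _project_unit_rows(_structural_features(g), d, scale=False)
    elif mode == "neighborhood":
        wp = {"window": 5, "walk_length": 20, "num_walks": 10, "sampled": False}
        wp.update(walk_params or {})
        if wp["sampled"]:
            rng = np.random.default_rng(seed)
            co = _sampled_cooccurrence(
                g, wp["walk_length"], wp["num_walks"], wp["window"], rng
            )
        else:
            co = _expected_cooccurrence(g, wp["window"])
        total = co.sum()
        if total == 0:
            z = np.zeros((g.n_nodes, d))
        else:
            row = co.sum(axis=1, keepdims=True)
            col = co.sum(axis=0, keepdims=True)
            row[row == 0] = 1.0
            col[col == 0] = 1.0
            with np.errstate(divide="ignore", invalid="ignore"):
                pmi = np.log(np.maximum(co * total / (row * col), 1e-12))
            ppmi = np.maximum(pmi, 0.0)
            z = _project_unit_rows(ppmi, d, scale=True)
    else:
        raise ValueError(f"unknown embedding mode {mode!r}")
    return {n: z[i].copy() for i, n in enumerate(g.node_ids)}


# ---------------------------------------------------------------------------
# Layer-wise linear GraphSAGE refiner
# ---------------------------------------------------------------------------

@dataclass
class RefinerModel:
    """Stack of trainable matrices applied to concat(self, aggregated-neighbors).

    Each layer maps dimension ``2d -> d`` via ``h <- act(concat(h, h_N) @ W)``.
    """

    weights: list[np.ndarray]
    aggregator: str = "sum"
    activation: str = "identity"
    final_loss: float = field(default=np.nan)

    @property
    def n_layers(self) -> int:
        return len(self.weights)

    @staticmethod
    def passthrough(d: int, n_layers: int = 1, aggregator: str = "sum") -> "RefinerModel":
        """Weights ``[I; 0]``: each layer copies the self half exactly."""
        w = np.vstack([np.eye(d), np.zeros((d, d))])
        return RefinerModel([w.copy() for _ in range(n_layers)], aggregator=aggregator)

    @staticmethod
    def mixing(
        d: int,
        n_layers: int = 1,
        neighbor_mix: float = 0.5,
        aggregator: str = "sum",
    ) -> "RefinerModel":
        """Weights ``[(1-a) I; a I]``: blend self with aggregated neighbors."""
        w = np.vstack([(1 - neighbor_mix) * np.eye(d), neighbor_mix * np.eye(d)])
        return RefinerModel([w.copy() for _ in range(n_layers)], aggregator=aggregator)


def _aggregation_matrix(g: AttributedGraph, nodes: list[str], aggregator: str) -> np.ndarray:
    """Neighbor matrix M with M[v, u] the weight of u in h_N(v).

    Neighborhoods are undirected (in- plus out-neighbors) and edge-weighted,
    so co-expression strength matters.  ``sum`` keeps raw weights (each edge
    change shifts h_N by a full neighbor vector); ``mean`` row-normalizes.
    Rows of isolated nodes are zero: an empty neighborhood contributes the
    zero vector.
    """
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    m = np.zeros((n, n))
    for u, v, w in g.edges:
        if u == v:
            continue
        m[idx[v], idx[u]] += w
        m[idx[u], idx[v]] += w
    if aggregator == "mean":
        row = m.sum(axis=1, keepdims=True)
        row[row == 0] = 1.0
        m = m / row
    elif aggregator == "sum":
        pass
    else:
        raise ValueError(f"unknown aggregator {aggregator!r}")
    return m


def _forward_matrices(
    model: RefinerModel, z: np.ndarray, m: np.ndarray
) -> tuple[np.ndarray, list[np.ndarray], list[np.ndarray]]:
    """Forward pass returning output plus per-layer inputs and pre-activations."""
    h = z
    cats: list[np.ndarray] = []
    pres: list[np.ndarray] = []
    for w in model.weights:
        cat = np.hstack([h, m @ h])
        pre = cat @ w
        cats.append(cat)
        pres.append(pre)
        h = np.maximum(pre, 0.0) if model.activation == "relu" else pre
    return h, cats, pres


def sage_forward(
    model: RefinerModel,
    z: dict[str, np.ndarray],
    g: AttributedGraph,
) -> dict[str, np.ndarray]:
    """Refine embeddings on ``g``: per layer, project concat(self, neighbors)."""
    nodes = g.node_ids
    missing = [n for n in nodes if n not in z]
    if missing:
        raise ValueError(f"embedding missing nodes: {missing[:5]}")
    zm = np.vstack([z[n] for n in nodes])
    if zm.shape[1] * 2 != model.weights[0].shape[0]:
        raise ValueError(
            f"dimension mismatch: embeddings d={zm.shape[1]} vs "
            f"layer input {model.weights[0].shape[0]}"
        )
    m = _aggregation_matrix(g, nodes, model.aggregator)
    out, _, _ = _forward_matrices(model, zm, m)
    return {n: out[i].copy() for i, n in enumerate(nodes)}


def refiner_loss(model: RefinerModel, z: np.ndarray, m: np.ndarray) -> float:
    """Reconstruction loss (1/n) * ||Z - H(Z, G)||_F."""
    out, _, _ = _forward_matrices(model, z, m)
    return float(np.linalg.norm(out - z)) / z.shape[0]


def _loss_and_grads(
    model: RefinerModel, z: np.ndarray, m: np.ndarray
) -> tuple[float, list[np.ndarray]]:
    n, d = z.shape
    out, cats, pres = _forward_matrices(model, z, m)
    diff = out - z
    fro = float(np.linalg.norm(diff))
    loss = fro / n
    if fro < 1e-15:
        return loss, [np.zeros_like(w) for w in model.weights]
    g_h = diff / (n * fro)
    grads: list[np.ndarray] = [np.empty(0)] * model.n_layers
    for l in range(model.n_layers - 1, -1, -1):
        g_pre = g_h if model.activation != "relu" else g_h * (pres[l] > 0)
        grads[l] = cats[l].T @ g_pre
        g_cat = g_pre @ model.weights[l].T
        g_h = g_cat[:, :d] + m.T @ g_cat[:, d:]
    return loss, grads


def train_refiner(
    g_coarsest: AttributedGraph,
    z_base: dict[str, np.ndarray],
    n_layers: int = 1,
    lr: float = 0.01,
    epochs: int = 200,
    aggregator: str = "sum",
    activation: str = "identity",
    neighbor_mix: float = 0.5,
    init_noise: float = 1e-3,
    seed: int = 0,
) -> tuple[RefinerModel, list[float]]:
    """Fit the refiner on the coarsest graph by gradient descent.

    The base embedding acts as the reconstruction target: the model must
    map ``(Z^kh, G^kh)`` back onto ``Z^kh``.  Weights start at the blended
    point ``[(1 - a) I; a I]`` (``a = neighbor_mix``) plus a small seeded
    Gaussian perturbation; the reconstruction objective pulls the
    neighbor-mixing half only as far as reconstruction requires, so the
    model retains genuine neighborhood sensitivity when later applied to
    finer levels.  The step size is halved whenever a step would increase
    the loss, so the recorded loss trajectory is monotone non-increasing.

    Returns the model (with ``final_loss`` set) and the per-epoch losses.
    """
    nodes = g_coarsest.node_ids
    z = np.vstack([z_base[n] for n in nodes])
    d = z.shape[1]
    rng = np.random.default_rng(seed)
    base = np.vstack([(1 - neighbor_mix) * np.eye(d), neighbor_mix * np.eye(d)])
    weights = [
        base + init_noise * rng.standard_normal((2 * d, d)) for _ in range(n_layers)
    ]
    model = RefinerModel(weights, aggregator=aggregator, activation=activation)
    m = _aggregation_matrix(g_coarsest, nodes, aggregator)

    losses: list[float] = []
    step = lr
    loss, grads = _loss_and_grads(model, z, m)
    for _ in range(epochs):
        losses.append(loss)
        if loss < 1e-14:
            break
        for _ in range(30):
            trial = [w - step * gw for w, gw in zip(model.weights, grads)]
            trial_model = RefinerModel(trial, aggregator=aggregator, activation=activation)
            new_loss, new_grads = _loss_and_grads(trial_model, z, m)
            if np.isfinite(new_loss) and new_loss <= loss:
                model = trial_model
                loss, grads = new_loss, new_grads
                break
            step *= 0.5
        else:
            break  # no admissible step; converged
    if not np.isfinite(loss):
        raise FloatingPointError(
            f"refiner training diverged (loss={loss}); lower the learning rate"
        )
    losses.append(loss)
    model.final_loss = loss
    return model, losses


def initialize_refined(
    z_coarse: dict[str, np.ndarray],
    membership: dict[str, str],
) -> dict[str, np.ndarray]:
    """Give every fine node an exact copy of its super-node's vector."""
    out: dict[str, np.ndarray] = {}
    for fine, sup in membership.items():
        if sup not in z_coarse:
            raise KeyError(f"fine node {fine!r} maps to unknown super-node {sup!r}")
        out[fine] = z_coarse[sup].copy()
    return out


def embed_hierarchy(
    h: CoarsenHierarchy,
    d: int = 32,
    mode: str = "neighborhood",
    walk_params: dict | None = None,
    n_layers: int = 1,
    lr: float = 0.01,
    epochs: int = 200,
    aggregator: str = "sum",
    activation: str = "identity",
    neighbor_mix: float = 0.5,
    init_noise: float = 1e-3,
    seed: int = 0,
    profile_weight: float = 0.0,
    use_features: bool = False,
) -> EmbeddingSet:
    """Embed every level of a hierarchy.

    The coarsest graph gets the base embedding; the refiner is trained once
    on it; the refined coarsest embedding is then propagated downward:
    ``Z^i = SAGE(initialize(Z^{i+1}, membership_i), G^i)``.

    At the finest level each node's initialization is augmented with
    ``profile_weight`` times its own degree-profile vector, so that
    rewiring which leaves a gene's community mixture unchanged (an edge
    swap within one community) still registers through the gene's own
    connectivity profile.  Set ``profile_weight=0`` for pure super-node
    copying.  ``use_features`` additionally folds user-supplied node
    features into the finest initialization.
    """
    coarsest = h.levels[-1]
    z_base = embed_base(coarsest, d=d, mode=mode, walk_params=walk_params, seed=seed)
    model, _ = train_refiner(
        coarsest,
        z_base,
        n_layers=n_layers,
        lr=lr,
        epochs=epochs,
        aggregator=aggregator,
        activation=activation,
        neighbor_mix=neighbor_mix,
        init_noise=init_noise,
        seed=seed,
    )
    per_level: list[dict[str, np.ndarray] | None] = [None] * len(h.levels)
    per_level[-1] = sage_forward(model, z_base, coarsest)
    for i in range(len(h.levels) - 2, -1, -1):
        init = initialize_refined(per_level[i + 1], h.memberships[i])
        if use_features and i == 0 and h.levels[0].features is not None:
            # optional: fold node features into the level-0 initialization
            feats = _project_unit_rows(h.levels[0].features, d, scale=False)
            for j, n in enumerate(h.levels[0].node_ids):
                init[n] = init[n] + feats[j]
        per_level[i] = sage_forward(model, init, h.levels[i])
    if profile_weight > 0:
        # profile channel added outside the aggregation: each gene's finest
        # vector carries its own connectivity profile, so rewiring that
        # leaves the community mixture unchanged still registers, while
        # untouched genes gain exactly nothing
        phi = _profile_vectors(h.levels[0], d)
        lvl0 = per_level[0]
        for n in h.levels[0].node_ids:
            lvl0[n] = lvl0[n] + profile_weight * phi[n]
    return EmbeddingSet([lv for lv in per_level if lv is not None], d)
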