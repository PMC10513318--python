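"""Four per-node network-change baselines.

Each method scores every shared node of a network pair by how much some
local or global summary changed between the two conditions: absolute
degree change, clustering-coefficient change, PageRank change, and a
contrastive-learning embedding distance.  All scores are non-negative;
larger means more changed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import networkx as nx

from .align import procrustes_map
from .coarsen import partition_louvain
from .graphs import AttributedGraph

__all__ = [
    "NodeScoreTable",
    "degree_change",
    "clustering_coeff_change",
    "pagerank_change",
    "contrastive_change",
    "BASELINES",
]


@dataclass
class NodeScoreTable:
    """node -> non-negative change score, with the producing method's name."""

    scores: dict[str, float]
    method: str

    def ranked(self) -> list[str]:
        """Nodes by descending score; ties broken by node id."""
        return sorted(self.scores, key=lambda n: (-self.scores[n], n))


def _shared(g1: AttributedGraph, g2: AttributedGraph) -> list[str]:
    s2 = set(g2.node_ids)
    shared = [n for n in g1.node_ids if n in s2]
    if not shared:
        raise ValueError("no shared nodes between the two graphs")
    return shared


def degree_change(g1: AttributedGraph, g2: AttributedGraph) -> NodeScoreTable:
    """dD = |d_in(G1) - d_in(G2)| + |d_out(G1) - d_out(G2)| per node.

    Blind to edge swaps that preserve both degrees.
    """
    n1, n2 = g1.to_networkx(), g2.to_networkx()
    scores = {}
    for n in _shared(g1, g2):
        if g1.directed:
            scores[n] = float(
                abs(n1.in_degree(n) - n2.in_degree(n))
                + abs(n1.out_degree(n) - n2.out_degree(n))
            )
        else:
            scores[n] = float(abs(n1.degree(n) - n2.degree(n)))
    return NodeScoreTable(scores, "degree")


def clustering_coeff_change(g1: AttributedGraph, g2: AttributedGraph) -> NodeScoreTable:
    """dC = |C_v(G1) - C_v(G2)| with C_v = 2 e_v / (k_v (k_v - 1)).

    Computed on the underlying undirected simple graph; C_v = 0 for k_v < 2.
    """
    c1 = nx.clustering(nx.Graph(g1.to_networkx().to_undirected()))
    c2 = nx.clustering(nx.Graph(g2.to_networkx().to_undirected()))
    scores = {n: float(abs(c1[n] - c2[n])) for n in _shared(g1, g2)}
    return NodeScoreTable(scores, "clustering")


def pagerank(
    g: AttributedGraph,
    d: float = 0.85,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> dict[str, float]:
    """Power-iteration PageRank from a uniform start.

    ``PR(v) = (1 - d)/N + d * sum_{(u,v) in E} PR(u)/L(u)`` with ``L(u)``
    the out-link count; dangling mass is redistributed uniformly.
    """
    if not 0 < d < 1:
        raise ValueError(f"damping factor must be in (0, 1), got {d}")
    nodes = g.node_ids
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    out_links: list[list[int]] = [[] for _ in range(n)]
    for u, v, _ in g.edges:
        out_links[idx[u]].append(idx[v])
        if not g.directed:
            out_links[idx[v]].append(idx[u])
    pr = np.full(n, 1.0 / n)
    for _ in range(max_iter):
        nxt = np.full(n, (1.0 - d) / n)
        dangling = sum(pr[i] for i in range(n) if not out_links[i])
        nxt += d * dangling / n
        for i in range(n):
            if out_links[i]:
                share = d * pr[i] / len(out_links[i])
                for j in out_links[i]:
                    nxt[j] += share
        delta = np.abs(nxt - pr).sum()
        pr = nxt
        if delta < tol:
            break
    else:
        warnings.warn(f"PageRank did not converge; last delta {delta:.2e}")
    return {v: float(pr[idx[v]]) for v in nodes}


def pagerank_change(
    g1: AttributedGraph,
    g2: AttributedGraph,
    d: float = 0.85,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> NodeScoreTable:
    """dPR = |PR(G1) - PR(G2)| per shared node."""
    p1 = pagerank(g1, d=d, tol=tol, max_iter=max_iter)
    p2 = pagerank(g2, d=d, tol=tol, max_iter=max_iter)
    scores = {n: float(abs(p1[n] - p2[n])) for n in _shared(g1, g2)}
    return NodeScoreTable(scores, "pagerank")


def _contrastive_embed(
    g: AttributedGraph,
    d_emb: int,
    margin: float,
    lr: float,
    epochs: int,
    seed: int,
) -> tuple[dict[str, np.ndarray], list[float]]:
    """Louvain-clustered hinge embedding: pull cluster mates, push others."""
    part = partition_louvain(g, seed=seed)
    nodes = g.node_ids
    labels = np.array([part.membership[n] for n in nodes])
    rng = np.random.default_rng(seed)
    # small init scale: starting distances sit below the margin, so the
    # hinge actively pulls cluster mates together and pushes clusters apart
    e = 0.1 * rng.standard_normal((len(nodes), d_emb))
    same = labels[:, None] == labels[None, :]
    np.fill_diagonal(same, False)
    diff_mask = ~same
    np.fill_diagonal(diff_mask, False)
    n_same = same.sum()
    n_diff = diff_mask.sum()
    if n_diff == 0:
        warnings.warn("single-cluster graph: inter-cluster term dropped")
    losses: list[float] = []
    for _ in range(epochs):
        delta = e[:, None, :] - e[None, :, :]
        dist = np.sqrt((delta**2).sum(axis=-1) + 1e-12)
        intra = dist[same].sum() / n_same if n_same else 0.0
        inter = dist[diff_mask].sum() / n_diff if n_diff else 0.0
        loss = max(0.0, margin + intra - inter) if n_diff else intra
        losses.append(float(loss))
        if loss == 0.0:
            break
        # gradient of mean pairwise distances wrt embeddings
        unit = delta / dist[..., None]
        grad = np.zeros_like(e)
        if n_same:
            g_same = np.where(same[..., None], unit, 0.0).sum(axis=1) * 2 / n_same
            grad += g_same
        if n_diff:
            g_diff = np.where(diff_mask[..., None], unit, 0.0).sum(axis=1) * 2 / n_diff
            grad -= g_diff
        e = e - lr * grad
    return {n: e[i].copy() for i, n in enumerate(nodes)}, losses


def contrastive_change(
    g1: AttributedGraph,
    g2: AttributedGraph,
    d_emb: int = 16,
    margin: float = 1.0,
    lr: float = 0.05,
    epochs: int = 100,
    seed: int = 0,
) -> NodeScoreTable:
    """dE = per-node L2 distance between Procrustes-aligned contrastive embeddings."""
    e1, _ = _contrastive_embed(g1, d_emb, margin, lr, epochs, seed)
    e2, _ = _contrastive_embed(g2, d_emb, margin, lr, epochs, seed)
    shared = _shared(g1, g2)
    m1 = np.vstack([e1[n] for n in shared])
    m2 = np.vstack([e2[n] for n in shared])
    amap = procrustes_map(m1, m2, fit_nodes=shared)
    aligned = m2 @ amap.u
    scores = {
        n: float(np.linalg.norm(m1[i] - aligned[i])) for i, n in enumerate(shared)
    }
    return NodeScoreTable(scores, "contrastive")


BASELINES = {
    "degree": degree_change,
    "clustering": clustering_coeff_change,
    "pagerank": pagerank_change,
    "contrastive": contrastive_change,
}
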