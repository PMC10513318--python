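import numpy as np
import pytest

from netrewire.graphs import AttributedGraph


@pytest.fixture
def two_triangles() -> AttributedGraph:
    """Two disjoint triangles — the classic perfectly modular graph."""
    return AttributedGraph(
        ["a", "b", "c", "d", "e", "f"],
        [("a", "b", 1.0), ("b", "c", 1.0), ("a", "c", 1.0),
         ("d", "e", 1.0), ("e", "f", 1.0), ("d", "f", 1.0)],
        directed=False,
    )


@pytest.fixture
def bridge_cliques() -> AttributedGraph:
    """Two 4-cliques joined by a single bridge edge."""
    nodes = [f"n{i}" for i in range(8)]
    edges = [(f"n{i}", f"n{j}", 1.0) for i in range(4) for j in range(i + 1, 4)]
    edges += [(f"n{i}", f"n{j}", 1.0) for i in range(4, 8) for j in range(i + 1, 8)]
    edges.append(("n0", "n4", 1.0))
    return AttributedGraph(nodes, edges, directed=False)


@pytest.fixture
def toy_digraph() -> AttributedGraph:
    return AttributedGraph(
        ["a", "b", "c", "d"],
        [("a", "b", 1.0), ("b", "c", 1.0), ("c", "a", 1.0), ("a", "d", 1.0)],
        directed=True,
    )


def random_graph(n: int, p: float, seed: int, directed: bool = False,
                 weighted: bool = False) -> AttributedGraph:
    """Erdos-Renyi helper used across test modules."""
    rng = np.random.default_rng(seed)
    nodes = [f"v{i}" for i in range(n)]
    edges = []
    for i in range(n):
        js = range(n) if directed else range(i + 1, n)
        for j in js:
            if i != j and rng.random() < p:
                w = float(rng.uniform(0.1, 1.0)) if weighted else 1.0
                edges.append((nodes[i], nodes[j], w))
    if not edges:  # guarantee non-empty for modularity computations
        edges.append((nodes[0], nodes[1], 1.0))
    return AttributedGraph(nodes, edges, directed=directed)
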