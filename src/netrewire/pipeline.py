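"""End-to-end orchestration: coarsen -> embed -> align -> score -> classify.

`compare_networks` is the main entry point: given two networks over a
shared node set it builds each condition's coarsening hierarchy, embeds
every level, aligns the second condition's embeddings onto the first via
orthogonal Procrustes (fitted at the finest level), and returns per-gene
per-level rewiring distances with EDG/LDG calls and driver ranks.
"""

from __future__ import annotations

import dataclasses
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .align import AlignmentMap, align_pair, classify_divergent, node_distances
from .coarsen import CoarsenHierarchy, coarsen_hierarchy
from .embed import EmbeddingSet, embed_hierarchy
from .graphs import AttributedGraph, GraphPair, common_subgraph

__all__ = ["RunConfig", "ComparisonResult", "compare_networks"]


@dataclass
class RunConfig:
    """All knobs of a comparison run; serializable for reproducibility."""

    mode: str = "grn"            # grn (directed TF net) | gcn (weighted undirected)
    k_h: int = 2                 # coarsening depth
    min_gain: float = 1e-4       # modularity-gain stop threshold
    resolution: float = 1.0
    max_passes: int = 2
    d: int = 32                  # embedding dimension
    embed_mode: str = "neighborhood"  # base embedder for the coarsest graph
    walk_params: dict | None = None
    n_layers: int = 1
    lr: float = 0.01
    epochs: int = 200
    aggregator: str = "sum"
    activation: str = "identity"
    neighbor_mix: float = 0.5    # refiner init: self vs aggregated-neighbor blend
    init_noise: float = 1e-3     # seeded Gaussian perturbation of refiner init
    profile_weight: float = 0.0  # optional degree-profile channel at the finest level
    high_quantile: float = 0.05  # top-fraction defining "high" dl2norm
    approx_ratio: float = 0.8    # coarse ~ fine tolerance for EDG calls
    seed: int = 0
    seed2: int | None = None         # coarsening seed for the second network
    embed_seed: int | None = None    # embedding/training seed (default: seed)
    embed_seed2: int | None = None   # embedding seed, second network
    warm_start: bool = True          # couple g2's level-0 partition to g1's

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        return cls(**(yaml.safe_load(text) or {}))


@dataclass
class ComparisonResult:
    """Everything a comparison run produces."""

    pair: GraphPair
    h1: CoarsenHierarchy
    h2: CoarsenHierarchy
    e1: EmbeddingSet
    e2_aligned: EmbeddingSet
    alignment: AlignmentMap
    distances: pd.DataFrame          # long: gene, level, raw, dl2norm
    profiles: pd.DataFrame | None    # wide with class + rank (None if 1 level)
    config: RunConfig
    timings: dict[str, float] = field(default_factory=dict)

    def node_scores(self, level: int = 0, normalized: bool = False) -> dict[str, float]:
        """Per-gene rewiring score at one level (default: finest, raw)."""
        col = "dl2norm" if normalized else "raw"
        sub = self.distances[self.distances["level"] == level]
        return dict(zip(sub["gene"], sub[col].astype(float)))

    def ranked(self, level: int = 0) -> list[str]:
        scores = self.node_scores(level)
        return sorted(scores, key=lambda n: (-scores[n], n))

    @property
    def n_levels(self) -> int:
        return int(self.distances["level"].max()) + 1

    def coarse_level(self) -> int:
        return self.n_levels - 1


def compare_networks(
    g1: AttributedGraph,
    g2: AttributedGraph,
    config: RunConfig | None = None,
) -> ComparisonResult:
    """Quantify rewiring between two conditions of one network."""
    cfg = config or RunConfig()
    timings: dict[str, float] = {}

    t0 = time.perf_counter()
    pair = common_subgraph(g1, g2)
    timings["prune"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    seed2 = cfg.seed2 if cfg.seed2 is not None else cfg.seed
    h1 = coarsen_hierarchy(
        pair.g1, k_h=cfg.k_h, min_gain=cfg.min_gain, resolution=cfg.resolution,
        max_passes=cfg.max_passes, seed=cfg.seed,
    )
    init = None
    if cfg.warm_start and h1.memberships:
        # couple the second condition's finest partition to the first's, so
        # community flips reflect rewiring rather than local-optimum noise
        labels = {s: i for i, s in enumerate(dict.fromkeys(h1.memberships[0].values()))}
        init = {n: labels[s] for n, s in h1.memberships[0].items()}
    h2 = coarsen_hierarchy(
        pair.g2, k_h=cfg.k_h, min_gain=cfg.min_gain, resolution=cfg.resolution,
        max_passes=cfg.max_passes, seed=seed2, init_partition=init,
    )
    timings["coarsen"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    kwargs = dict(
        d=cfg.d, mode=cfg.embed_mode, walk_params=cfg.walk_params,
        n_layers=cfg.n_layers, lr=cfg.lr, epochs=cfg.epochs,
        aggregator=cfg.aggregator, activation=cfg.activation,
        neighbor_mix=cfg.neighbor_mix, init_noise=cfg.init_noise,
        profile_weight=cfg.profile_weight,
    )
    es1 = cfg.embed_seed if cfg.embed_seed is not None else cfg.seed
    es2 = cfg.embed_seed2 if cfg.embed_seed2 is not None else seed2
    e1 = embed_hierarchy(h1, seed=es1, **kwargs)
    e2 = embed_hierarchy(h2, seed=es2, **kwargs)
    timings["embed"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    amap, e2a = align_pair(e1, e2, pair)
    distances = node_distances(e1, e2a, h1, h2, pair.shared_nodes)
    profiles = None
    if distances["level"].nunique() >= 2:
        profiles = classify_divergent(
            distances, high_quantile=cfg.high_quantile, approx_ratio=cfg.approx_ratio
        )
    timings["align"] = time.perf_counter() - t0

    return ComparisonResult(
        pair=pair, h1=h1, h2=h2, e1=e1, e2_aligned=e2a, alignment=amap,
        distances=distances, profiles=profiles, config=cfg, timings=timings,
    )


def mean_node_distance(result: ComparisonResult, level: int = 0) -> float:
    """Average raw per-node distance at one level (false-positive statistic)."""
    scores = result.node_scores(level=level, normalized=False)
    return float(np.mean(list(scores.values())))
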