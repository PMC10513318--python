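"""Embedding alignment, rewiring scores, EDG/LDG calling, hierarchy roles.

Embeddings trained on two conditions live in arbitrarily rotated latent
spaces, so they are first aligned by solving the orthogonal Procrustes
problem on the finest level's shared nodes; the same rotation is applied to
every coarser level.  A gene's rewiring score at a level is the L2 distance
between its (super-)node vectors in the two aligned spaces, max-normalized
per level (``dl2norm``).  Genes with high scores at both coarse and fine
levels are early divergent (EDG: rewired across pathway-scale communities);
genes high only at the finest level are late divergent (LDG: rewired within
their community).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from sklearn.cluster import KMeans

from .coarsen import CoarsenHierarchy
from .embed import EmbeddingSet
from .graphs import AttributedGraph, GraphPair

__all__ = [
    "AlignmentMap",
    "procrustes_map",
    "align_pair",
    "node_distances",
    "classify_divergent",
    "hierarchy_roles",
    "level_labels",
]

ROLE_NAMES = ("commander", "messenger", "soldier")


@dataclass
class AlignmentMap:
    """Orthogonal map fitted on the finest level: minimizes ||M1 - M2 U||_F."""

    u: np.ndarray
    residual: float
    fit_nodes: list[str]


def procrustes_map(m1: np.ndarray, m2: np.ndarray, fit_nodes: list[str] | None = None) -> AlignmentMap:
    """Closed-form orthogonal Procrustes solution mapping ``m2`` onto ``m1``.

    ``U`` maximizes ``tr(U^T m2^T m1)`` via the SVD of the cross-product.
    When the cross-product is rank-deficient the optimum is not unique: any
    rotation of the null space is equally good.  Among those optima we
    return the one closest to the identity (the null-space blocks are
    themselves Procrustes-fitted to I), so aligning a matrix to itself
    yields exactly ``U = I`` and coarse-level vectors that leave the
    fitted subspace are never rotated arbitrarily.
    """
    m1 = np.asarray(m1, dtype=float)
    m2 = np.asarray(m2, dtype=float)
    if m1.shape != m2.shape:
        raise ValueError(f"shape mismatch {m1.shape} vs {m2.shape}")
    if m1.shape[0] < 2:
        raise ValueError("need at least 2 rows to fit an alignment")
    if m1.shape[0] < m1.shape[1]:
        warnings.warn(
            f"alignment under-determined: {m1.shape[0]} rows < {m1.shape[1]} dims"
        )
    c = m2.T @ m1
    a, s, wt = np.linalg.svd(c)
    tol = max(c.shape) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    r = int((s > tol).sum())
    d = c.shape[0]
    u = a[:, :r] @ wt[:r]
    if r < d:
        # null-space completion closest to identity: Procrustes of Q_a^T Q_w
        qa, qw = a[:, r:], wt[r:].T
        ua, _, uwt = np.linalg.svd(qa.T @ qw)
        u = u + qa @ (ua @ uwt) @ qw.T
    residual = float(np.linalg.norm(m1 - m2 @ u))
    return AlignmentMap(u, residual, list(fit_nodes or []))


def align_pair(
    e1: EmbeddingSet,
    e2: EmbeddingSet,
    pair: GraphPair,
) -> tuple[AlignmentMap, EmbeddingSet]:
    """Fit U on finest-level shared nodes; rotate ``e2`` at every level."""
    shared = [n for n in pair.shared_nodes if n in e1.per_level[0] and n in e2.per_level[0]]
    if not shared:
        raise ValueError("no shared nodes with embeddings at the finest level")
    amap = procrustes_map(e1.matrix(0, shared), e2.matrix(0, shared), fit_nodes=shared)
    return amap, e2.transformed(amap.u)


def node_distances(
    e1: EmbeddingSet,
    e2_aligned: EmbeddingSet,
    h1: CoarsenHierarchy,
    h2: CoarsenHierarchy,
    genes: list[str],
) -> pd.DataFrame:
    """Per-gene per-level rewiring distances after alignment.

    At coarse levels a gene is represented by the vector of its own
    condition's super-node (the two hierarchies may partition differently).
    Returns a long DataFrame with columns ``gene, level, raw, dl2norm``
    where ``dl2norm`` is the per-level max-normalized distance in [0, 1]
    (an all-zero level normalizes to zero).
    """
    n_levels = min(len(e1.per_level), len(e2_aligned.per_level))
    rows = []
    for gene in genes:
        if gene not in e1.per_level[0] or gene not in e2_aligned.per_level[0]:
            warnings.warn(f"gene {gene!r} missing from one hierarchy; excluded")
            continue
        for level in range(n_levels):
            v1 = e1.per_level[level][h1.trace(gene, level)]
            v2 = e2_aligned.per_level[level][h2.trace(gene, level)]
            rows.append((gene, level, float(np.linalg.norm(v1 - v2))))
    df = pd.DataFrame(rows, columns=["gene", "level", "raw"])
    if df.empty:
        raise ValueError("no shared genes with embeddings")
    # levels whose largest distance is numerically zero normalize to zero
    peak = df.groupby("level")["raw"].transform("max")
    df["dl2norm"] = np.where(peak > 1e-9, df["raw"] / peak.where(peak > 0, 1.0), 0.0)
    return df


def level_labels(n_levels: int) -> list[str]:
    """Stage names, finest first: the coarsest level is the 'early' stage."""
    if n_levels == 3:
        return ["late", "middle", "early"]
    if n_levels == 2:
        return ["late", "early"]
    if n_levels == 1:
        return ["late"]
    return ["late"] + [f"mid{i}" for i in range(1, n_levels - 1)] + ["early"]


def classify_divergent(
    distances: pd.DataFrame,
    high_quantile: float = 0.05,
    approx_ratio: float = 0.8,
) -> pd.DataFrame:
    """Call each gene EDG, LDG or conserved from its per-level dl2norm profile.

    "High" at a level means a dl2norm in the top ``high_quantile`` fraction
    of genes at that level (floored at one gene).  EDG: high at the finest
    level, high at the coarsest level, and coarse >= ``approx_ratio`` x fine
    (coarse and fine distances comparable).  LDG: high at the finest level
    with the coarsest below the high cutoff.  Everything else is conserved.
    Rank 1 is the gene with the largest max-over-levels dl2norm.
    """
    levels = sorted(distances["level"].unique())
    if len(levels) < 2:
        raise ValueError("classification needs at least 2 hierarchy levels")
    finest, coarsest = levels[0], levels[-1]
    wide = distances.pivot(index="gene", columns="level", values="dl2norm")
    cutoffs = {}
    for lv in levels:
        vals = wide[lv].to_numpy()
        k = max(1, int(np.floor(high_quantile * len(vals))))
        cutoffs[lv] = float(np.sort(vals)[-k])

    labels = level_labels(len(levels))
    out = pd.DataFrame(index=wide.index)
    for lv, lab in zip(levels, labels):
        out[f"dl2norm_{lab}"] = wide[lv]
    fine = wide[finest]
    coarse = wide[coarsest]
    # a gene with zero displacement is never divergent, even when the whole
    # level is zero and the quantile cutoff degenerates to 0
    high_fine = (fine >= cutoffs[finest]) & (fine > 0)
    high_coarse = (coarse >= cutoffs[coarsest]) & (coarse > 0)
    is_edg = high_fine & high_coarse & (coarse >= approx_ratio * fine)
    is_ldg = high_fine & ~high_coarse
    out["class"] = np.where(is_edg, "EDG", np.where(is_ldg, "LDG", "conserved"))
    score = wide.max(axis=1)
    order = sorted(out.index, key=lambda g: (-score[g], g))
    out["rank"] = pd.Series({g: r + 1 for r, g in enumerate(order)})
    out.attrs["cutoffs"] = cutoffs
    out.attrs["high_quantile"] = high_quantile
    out.attrs["approx_ratio"] = approx_ratio
    return out.sort_values("rank")


# ---------------------------------------------------------------------------
# TF hierarchy roles
# ---------------------------------------------------------------------------

@dataclass
class HierarchyRoles:
    """Cluster assignments and commander/messenger/soldier labels for TFs.

    Roles are ordered by ascending mean in/out degree ratio: regulators that
    mostly regulate others (in < out) are commanders, balanced ones
    messengers, mostly-regulated ones soldiers.
    """

    table: pd.DataFrame                 # node, cluster, in_degree, out_degree, ratio, role
    cluster_ratios: dict[int, float]


def _in_out_ratio(din: int, dout: int) -> float:
    # denominator floored at 1 so pure commanders (out-hubs) get finite ratio
    return din / max(dout, 1)


def hierarchy_roles(
    g_directed: AttributedGraph,
    emb: dict[str, np.ndarray],
    k: int = 3,
    seed: int = 0,
) -> HierarchyRoles:
    """Cluster TF embeddings and label clusters by in/out-degree ratio."""
    if not g_directed.directed:
        raise ValueError("hierarchy roles require a directed regulatory network")
    if k > g_directed.n_nodes:
        raise ValueError(f"k={k} exceeds node count {g_directed.n_nodes}")
    nxg = g_directed.to_networkx()
    nodes = g_directed.node_ids
    x = np.vstack([emb[n] for n in nodes])
    km = KMeans(n_clusters=k, random_state=seed, n_init=10).fit(x)
    df = pd.DataFrame(
        {
            "node": nodes,
            "cluster": km.labels_,
            "in_degree": [nxg.in_degree(n) for n in nodes],
            "out_degree": [nxg.out_degree(n) for n in nodes],
        }
    )
    df["ratio"] = [_in_out_ratio(i, o) for i, o in zip(df.in_degree, df.out_degree)]
    means = df.groupby("cluster")["ratio"].mean()
    sizes = df.groupby("cluster").size()
    # ascending ratio; ties by larger cluster first, then cluster id
    ordered = sorted(means.index, key=lambda c: (means[c], -sizes[c], c))
    if k == 3:
        role_of = {c: ROLE_NAMES[r] for r, c in enumerate(ordered)}
    else:
        role_of = {c: f"tier{r}" for r, c in enumerate(ordered)}
    df["role"] = df["cluster"].map(role_of)
    return HierarchyRoles(df, {int(c): float(means[c]) for c in means.index})


def role_switches(roles1: HierarchyRoles, roles2: HierarchyRoles) -> pd.DataFrame:
    """Per-TF role comparison across two conditions (switched = role changed)."""
    t1 = roles1.table.set_index("node")["role"]
    t2 = roles2.table.set_index("node")["role"]
    shared = t1.index.intersection(t2.index)
    return pd.DataFrame(
        {
            "role_1": t1[shared],
            "role_2": t2[shared],
            "switched": t1[shared] != t2[shared],
        }
    )


def switch_distance_test(
    switches: pd.DataFrame, distances: pd.DataFrame
) -> tuple[float, float, float]:
    """One-sided rank-sum test: do role-switching TFs have higher finest-level
    dl2norm than non-switching TFs?  Returns (mean_switch, mean_keep, p)."""
    finest = distances[distances["level"] == distances["level"].min()]
    d = finest.set_index("gene")["dl2norm"]
    sw = d[switches.index[switches["switched"]].intersection(d.index)]
    keep = d[switches.index[~switches["switched"]].intersection(d.index)]
    if len(sw) == 0 or len(keep) == 0:
        return float(sw.mean() if len(sw) else np.nan), float(keep.mean() if len(keep) else np.nan), np.nan
    stat = mannwhitneyu(sw, keep, alternative="greater")
    return float(sw.mean()), float(keep.mean()), float(stat.pvalue)
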