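import numpy as np
import pandas as pd
import pytest
from scipy.stats import ortho_group

from netrewire.align import (
    classify_divergent,
    hierarchy_roles,
    level_labels,
    node_distances,
    procrustes_map,
    align_pair,
    role_switches,
)
from netrewire.coarsen import coarsen_hierarchy
from netrewire.embed import embed_hierarchy
from netrewire.graphs import AttributedGraph, common_subgraph
from netrewire.pipeline import RunConfig, compare_networks
from netrewire.simulate import make_planted_graph


class TestProcrustes:
    def test_self_alignment_residual_zero_and_exact_map(self):
        m = np.random.default_rng(0).normal(size=(6, 4))
        amap = procrustes_map(m, m)
        assert amap.residual == pytest.approx(0.0, abs=1e-10)
        assert np.allclose(m @ amap.u, m, atol=1e-10)

    def test_self_alignment_returns_identity_even_when_rank_deficient(self):
        rng = np.random.default_rng(1)
        m = rng.normal(size=(10, 2)) @ rng.normal(size=(2, 8))  # rank 2 in 8 dims
        amap = procrustes_map(m, m)
        assert np.allclose(amap.u, np.eye(8), atol=1e-8)

    def test_recovers_planted_rotation(self):
        rng = np.random.default_rng(2)
        m1 = rng.normal(size=(12, 5))
        r = ortho_group.rvs(5, random_state=3)
        amap = procrustes_map(m1, m1 @ r)
        assert amap.residual <= 1e-8

    def test_beats_monte_carlo_orthogonal_search(self):
        rng = np.random.default_rng(4)
        m1 = rng.normal(size=(8, 3))
        m2 = rng.normal(size=(8, 3))
        amap = procrustes_map(m1, m2)
        best_random = min(
            np.linalg.norm(m1 - m2 @ ortho_group.rvs(3, random_state=s))
            for s in range(10_000)
        )
        assert amap.residual <= best_random + 1e-12

    @pytest.mark.parametrize("shape", [(8, 3), (5, 5), (3, 6)])
    def test_map_is_orthogonal(self, shape):
        rng = np.random.default_rng(5)
        amap = procrustes_map(rng.normal(size=shape), rng.normal(size=shape))
        d = amap.u.shape[0]
        assert np.abs(amap.u.T @ amap.u - np.eye(d)).max() <= 1e-8

    def test_under_determined_fit_warns(self):
        rng = np.random.default_rng(6)
        with pytest.warns(UserWarning, match="under-determined"):
            procrustes_map(rng.normal(size=(3, 6)), rng.normal(size=(3, 6)))

    def test_single_row_rejected(self):
        with pytest.raises(ValueError, match="at least 2 rows"):
            procrustes_map(np.ones((1, 3)), np.ones((1, 3)))


@pytest.fixture
def aligned_pair():
    """Two identical planted networks embedded with the same seed."""
    g = make_planted_graph(24, 3, 0.6, 0.05, directed=False, seed=0)
    pair = common_subgraph(g, g)
    h = coarsen_hierarchy(g, k_h=2, seed=0)
    e = embed_hierarchy(h, d=8, seed=0)
    return g, pair, h, e


class TestAlignPair:
    def test_identical_embeddings_zero_distance_at_every_level(self, aligned_pair):
        g, pair, h, e = aligned_pair
        amap, e2a = align_pair(e, e, pair)
        df = node_distances(e, e2a, h, h, pair.shared_nodes)
        assert df["raw"].max() <= 1e-10
        assert (df["dl2norm"] == 0).all()

    def test_global_rotation_fully_removed(self, aligned_pair):
        # full-rank embedding dimension, so the finest-level fit pins the
        # rotation on the whole space and every level aligns exactly
        g, pair, h, _ = aligned_pair
        e = embed_hierarchy(h, d=6, seed=0)
        r = ortho_group.rvs(6, random_state=7)
        e_rot = e.transformed(r)
        amap, e2a = align_pair(e, e_rot, pair)
        df = node_distances(e, e2a, h, h, pair.shared_nodes)
        assert df["raw"].max() <= 1e-8

    def test_coarse_levels_reuse_finest_map(self, aligned_pair):
        """A level-specific Procrustes refit can only lower the coarse
        residual; the pipeline intentionally reuses the finest-level map."""
        g, pair, h, e = aligned_pair
        rng = np.random.default_rng(8)
        jitter = {
            n: v + 0.05 * rng.normal(size=v.shape)
            for n, v in e.per_level[0].items()
        }
        import dataclasses
        e2 = dataclasses.replace(e, per_level=[jitter] + e.per_level[1:])
        amap, e2a = align_pair(e, e2, pair)
        coarse_nodes = list(e.per_level[-1])
        m1 = e.matrix(len(e.per_level) - 1, coarse_nodes)
        m2a = e2a.matrix(len(e2a.per_level) - 1, coarse_nodes)
        shared_u_residual = np.linalg.norm(m1 - m2a)
        m2 = e2.matrix(len(e2.per_level) - 1, coarse_nodes)
        refit = procrustes_map(m1, m2)
        assert refit.residual <= shared_u_residual + 1e-9

    def test_alignment_invariance_under_common_orthogonal_transform(self):
        g1 = make_planted_graph(24, 3, 0.6, 0.05, directed=False, seed=0)
        g2 = make_planted_graph(24, 3, 0.6, 0.05, directed=False, seed=1)
        cfg = RunConfig(mode="gcn", d=8, seed=0)
        base = compare_networks(g1, g2, cfg)
        q = ortho_group.rvs(8, random_state=11)
        pair = base.pair
        e1q = base.e1.transformed(q)
        # e2 must be rotated before its own alignment: rebuild from scratch
        h2 = base.h2
        e2 = embed_hierarchy(h2, d=8, seed=0)
        e2q = e2.transformed(q)
        amap_q, e2a_q = align_pair(e1q, e2q, pair)
        df_q = node_distances(e1q, e2a_q, base.h1, h2, pair.shared_nodes)
        merged = base.distances.merge(df_q, on=["gene", "level"], suffixes=("", "_q"))
        assert np.abs(merged["dl2norm"] - merged["dl2norm_q"]).max() <= 1e-6


class TestNodeDistances:
    def _embedding_sets(self):
        from netrewire.embed import EmbeddingSet
        genes = [f"g{i}" for i in range(6)]
        rng = np.random.default_rng(3)
        lv0_a = {g: rng.normal(size=4) for g in genes}
        lv0_b = {g: rng.normal(size=4) for g in genes}
        e1 = EmbeddingSet([lv0_a], 4)
        e2 = EmbeddingSet([lv0_b], 4)
        from netrewire.coarsen import CoarsenHierarchy
        g = AttributedGraph(genes, [(genes[0], genes[1], 1.0)], False)
        h = CoarsenHierarchy([g], [])
        return genes, e1, e2, h

    def test_raw_distances_match_vector_arithmetic(self):
        genes, e1, e2, h = self._embedding_sets()
        df = node_distances(e1, e2, h, h, genes)
        for gene in genes:
            expected = np.linalg.norm(e1.per_level[0][gene] - e2.per_level[0][gene])
            got = df.loc[(df.gene == gene) & (df.level == 0), "raw"].item()
            assert got == pytest.approx(expected, abs=1e-12)

    def test_max_gene_has_dl2norm_one(self):
        genes, e1, e2, h = self._embedding_sets()
        df = node_distances(e1, e2, h, h, genes)
        assert df["dl2norm"].max() == pytest.approx(1.0)
        top = df.loc[df["dl2norm"].idxmax()]
        assert top["raw"] == df["raw"].max()

    def test_missing_gene_excluded_with_warning(self):
        genes, e1, e2, h = self._embedding_sets()
        del e2.per_level[0][genes[0]]
        with pytest.warns(UserWarning, match=genes[0]):
            df = node_distances(e1, e2, h, h, genes)
        assert genes[0] not in set(df["gene"])


class TestClassifyDivergent:
    def _frame(self, profiles: dict[str, tuple]) -> pd.DataFrame:
        rows = []
        for gene, vals in profiles.items():
            # vals ordered coarsest -> finest; level index 0 is finest
            n = len(vals)
            for lv, val in enumerate(reversed(vals)):
                rows.append((gene, lv, val, val))
        return pd.DataFrame(rows, columns=["gene", "level", "raw", "dl2norm"])

    def test_flat_high_profile_is_edg(self):
        df = self._frame({
            "hot": (0.9, 0.9, 0.9),
            **{f"bg{i}": (0.1, 0.1, 0.1) for i in range(9)},
        })
        out = classify_divergent(df, high_quantile=0.1)
        assert out.loc["hot", "class"] == "EDG"
        assert out.loc["hot", "rank"] == 1

    def test_rising_profile_is_ldg(self):
        df = self._frame({
            "late": (0.1, 0.4, 0.9),
            **{f"bg{i}": (0.2, 0.1, 0.1) for i in range(9)},
        })
        out = classify_divergent(df, high_quantile=0.1)
        assert out.loc["late", "class"] == "LDG"

    def test_all_zero_profile_is_conserved(self):
        df = self._frame({
            "flat": (0.0, 0.0, 0.0),
            "a": (0.5, 0.6, 0.9),
            **{f"bg{i}": (0.3, 0.2, 0.2) for i in range(8)},
        })
        out = classify_divergent(df, high_quantile=0.1)
        assert out.loc["flat", "class"] == "conserved"

    def test_every_gene_gets_exactly_one_class(self):
        rng = np.random.default_rng(9)
        df = self._frame({f"g{i}": tuple(rng.uniform(size=3)) for i in range(40)})
        out = classify_divergent(df)
        assert set(out["class"]) <= {"EDG", "LDG", "conserved"}
        assert len(out) == 40
        assert sorted(out["rank"]) == list(range(1, 41))

    def test_single_level_rejected(self):
        df = pd.DataFrame({"gene": ["a"], "level": [0], "raw": [1.0], "dl2norm": [1.0]})
        with pytest.raises(ValueError, match="2 hierarchy levels"):
            classify_divergent(df)

    def test_level_labels(self):
        assert level_labels(3) == ["late", "middle", "early"]
        assert level_labels(2) == ["late", "early"]


class TestHierarchyRoles:
    def test_pure_out_hub_is_commander(self):
        nodes = ["hub"] + [f"t{i}" for i in range(5)]
        edges = [("hub", t, 1.0) for t in nodes[1:]]
        g = AttributedGraph(nodes, edges, directed=True)
        emb = {n: np.array([float(i), 0.0]) for i, n in enumerate(nodes)}
        emb["hub"] = np.array([-10.0, 0.0])
        roles = hierarchy_roles(g, emb, k=2, seed=0)
        t = roles.table.set_index("node")
        assert t.loc["hub", "ratio"] == 0.0
        hub_cluster = t.loc["hub", "cluster"]
        ordered = sorted(roles.cluster_ratios, key=roles.cluster_ratios.get)
        assert ordered[0] == hub_cluster

    def test_star_hub_isolated_by_structural_embedding(self):
        from netrewire.embed import embed_base
        nodes = ["hub"] + [f"leaf{i}" for i in range(6)]
        g = AttributedGraph(nodes, [("hub", l, 1.0) for l in nodes[1:]], directed=True)
        emb = embed_base(g, d=4, mode="structural")
        roles = hierarchy_roles(g, emb, k=2, seed=0)
        t = roles.table.set_index("node")
        hub_cluster = t.loc["hub", "cluster"]
        assert (t["cluster"] == hub_cluster).sum() == 1

    def test_three_way_roles_ordered_by_ratio(self):
        rng = np.random.default_rng(0)
        nodes = [f"n{i}" for i in range(9)]
        edges = []
        for i in range(3):           # commanders: out only
            edges += [(f"n{i}", f"n{j}", 1.0) for j in range(3, 9)]
        for i in range(3, 6):        # messengers: some in, some out
            edges += [(f"n{i}", f"n{j}", 1.0) for j in range(6, 9)]
        g = AttributedGraph(nodes, edges, directed=True)
        emb = {n: np.array([i // 3 * 5.0 + rng.normal(0, 0.1), 0.0])
               for i, n in enumerate(nodes)}
        roles = hierarchy_roles(g, emb, k=3, seed=0)
        t = roles.table.set_index("node")
        assert t.loc["n0", "role"] == "commander"
        assert t.loc["n8", "role"] == "soldier"

    def test_undirected_input_rejected(self):
        g = AttributedGraph(["a", "b"], [("a", "b", 1.0)], directed=False)
        with pytest.raises(ValueError, match="directed"):
            hierarchy_roles(g, {"a": np.zeros(2), "b": np.zeros(2)}, k=2)

    def test_k_larger_than_n_rejected(self, toy_digraph):
        emb = {n: np.zeros(2) for n in toy_digraph.node_ids}
        with pytest.raises(ValueError, match="exceeds node count"):
            hierarchy_roles(toy_digraph, emb, k=10)

    def test_identical_conditions_no_switches(self, toy_digraph):
        emb = {n: np.array([float(i), 0.0]) for i, n in enumerate(toy_digraph.node_ids)}
        r = hierarchy_roles(toy_digraph, emb, k=2, seed=0)
        switches = role_switches(r, r)
        assert not switches["switched"].any()
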