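"""Biological distances, subnetworks and UPGMA trees."""

import itertools
import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from chdpath.connectome import (
    PpiGraph, biological_distance, closest_known, connectome_rank,
    distance_matrix, mean_distance_to_set, minimum_subnetwork, top1_connectome,
    upgma_tree)


def all_pairs_oracle(graph: PpiGraph):
    """Shortest distances by exhaustive simple-path enumeration."""
    G = graph.graph
    out = {}
    for a, b in itertools.combinations(sorted(G.nodes), 2):
        best = math.inf
        for path in nx.all_simple_paths(G, a, b):
            w = sum(G[u][v]["length"] for u, v in zip(path, path[1:]))
            best = min(best, w)
        out[(a, b)] = best
    return out


class TestBiologicalDistance:
    def test_single_edge_reciprocal_confidence(self):
        g = PpiGraph.from_edges([("A", "B", 0.8)])
        res = biological_distance("A", "B", g)
        assert res.distance == pytest.approx(1.25)
        assert res.degrees_of_separation == 1
        assert res.route_str == "A[1.25]B"

    def test_identity(self, triangle_graph):
        res = biological_distance("A", "A", triangle_graph)
        assert res.distance == 0 and res.degrees_of_separation == 0

    def test_triangle_prefers_two_hop_route(self, triangle_graph):
        res = biological_distance("A", "C", triangle_graph)
        assert res.distance == pytest.approx(2.0)
        assert res.route == ["A", "B", "C"]
        assert res.degrees_of_separation == 2

    def test_disconnected_pair_sentinel(self):
        g = PpiGraph.from_edges([("A", "B", 1.0), ("C", "D", 1.0)])
        res = biological_distance("A", "C", g)
        assert math.isinf(res.distance) and res.route == []

    def test_matches_simple_path_enumeration_on_random_graphs(self):
        rng = np.random.default_rng(5)
        for _ in range(12):
            n = int(rng.integers(3, 9))
            base = nx.gnp_random_graph(n, 0.5, seed=int(rng.integers(2**31)))
            edges = [(f"N{u}", f"N{v}", float(rng.uniform(0.2, 1.0)))
                     for u, v in base.edges]
            if not edges:
                continue
            g = PpiGraph.from_edges(edges)
            oracle = all_pairs_oracle(g)
            for (a, b), want in oracle.items():
                got = biological_distance(a, b, g).distance
                assert got == pytest.approx(want), (a, b)

    def test_symmetry_and_triangle_inequality(self, triangle_graph):
        nodes = ["A", "B", "C"]
        d = {(a, b): biological_distance(a, b, triangle_graph).distance
             for a in nodes for b in nodes}
        for a in nodes:
            for b in nodes:
                assert d[a, b] == pytest.approx(d[b, a])
                for c in nodes:
                    assert d[a, b] <= d[a, c] + d[c, b] + 1e-12

    def test_neglog_mode(self):
        g = PpiGraph.from_edges([("A", "B", 0.5)], length_mode="neglog")
        assert biological_distance("A", "B", g).distance == pytest.approx(
            math.log(2))


class TestConnectomeRank:
    def make_line(self, n):
        # chain of unit-confidence edges: distances 1, 2, ..., n-1 from N0
        return PpiGraph.from_edges(
            [(f"N{i:03d}", f"N{i + 1:03d}", 1.0) for i in range(n - 1)])

    def test_rank_arithmetic(self):
        g = self.make_line(101)  # 100 reachable from N000
        df = connectome_rank("N000", [], g)
        assert len(df) == 100
        row5 = df[df["gene"] == "N005"].iloc[0]
        assert row5["percentile_p"] == pytest.approx(0.05)
        one = df[df["gene"] == "N001"].iloc[0]
        assert one["percentile_p"] == pytest.approx(0.01) and one["top"]

    def test_ties_share_maximal_rank(self):
        # 200 reachable: Z at rank 1, then T1 == T2 straddling the 1% cut
        edges = [("HUB", "Z", 1.0)]
        edges += [("HUB", x, 0.8) for x in ("T1", "T2")]
        edges += [("HUB", f"F{i:03d}", 0.4) for i in range(197)]
        g = PpiGraph.from_edges(edges)
        df = connectome_rank("HUB", ["T1", "T2"], g)
        assert len(df) == 200
        tied = df[df["gene"].isin(["T1", "T2"])]
        assert tied["percentile_p"].nunique() == 1
        assert tied["percentile_p"].iloc[0] == pytest.approx(3 / 200)
        assert not tied["top"].any()  # shared max rank pushes both past 1%
        assert df[df["gene"] == "Z"].iloc[0]["top"]

    def test_top_fraction_count_bound(self):
        g = self.make_line(60)
        top = top1_connectome("N000", g, top_fraction=0.05)
        assert len(top) <= math.ceil(0.05 * 59)


class TestClosestKnown:
    def test_star_graph_picks_nearer_leaf(self):
        g = PpiGraph.from_edges([("C", "K1", 1 / 1.2), ("C", "K2", 0.5)])
        res = closest_known("C", ["K1", "K2"], g)
        assert res.gene_b == "K1"
        assert res.distance == pytest.approx(1.2)
        assert res.route_str == "K1[1.20]C"  # known-to-candidate orientation

    def test_candidate_in_known_resolves_to_itself(self, triangle_graph):
        res = closest_known("A", ["A", "B"], triangle_graph)
        assert res.gene_b == "A" and res.distance == 0

    def test_unreachable_known_gives_sentinel(self):
        g = PpiGraph.from_edges([("A", "B", 1.0), ("K", "L", 1.0)])
        res = closest_known("A", ["K"], g)
        assert math.isinf(res.distance) and res.route == []

    def test_tie_broken_lexicographically(self):
        g = PpiGraph.from_edges([("C", "KB", 1.0), ("C", "KA", 1.0)])
        assert closest_known("C", ["KB", "KA"], g).gene_b == "KA"


def steiner_brute_force(graph: PpiGraph, seeds):
    """Minimum total edge length of a connected subgraph spanning seeds."""
    G = graph.graph
    others = [n for n in G.nodes if n not in seeds]
    best = math.inf
    for r in range(len(others) + 1):
        for extra in itertools.combinations(others, r):
            nodes = set(seeds) | set(extra)
            H = G.subgraph(nodes)
            if len(H) and nx.is_connected(H):
                T = nx.minimum_spanning_tree(H, weight="length")
                w = sum(d["length"] for _, _, d in T.edges(data=True))
                best = min(best, w)
    return best


class TestMinimumSubnetwork:
    def test_path_graph_unique_connector(self):
        g = PpiGraph.from_edges([("A", "B", 1.0), ("B", "C", 1.0)])
        sub = minimum_subnetwork(["A", "C"], g, confidence_floor=0.5)
        assert sub.nodes == ["A", "B", "C"]

    def test_single_seed(self):
        g = PpiGraph.from_edges([("A", "B", 1.0)])
        sub = minimum_subnetwork(["A"], g, confidence_floor=0.5)
        assert sub.nodes == ["A"] and sub.edges == []

    def test_seed_in_other_component_dropped(self):
        g = PpiGraph.from_edges(
            [("A", "B", 1.0), ("B", "C", 1.0), ("X", "Y", 1.0)])
        sub = minimum_subnetwork(["A", "C", "X"], g, confidence_floor=0.5)
        assert sub.dropped_seeds == ["X"]
        assert set(sub.focus_genes) == {"A", "C"}

    def test_confidence_floor_strict(self):
        g = PpiGraph.from_edges([("A", "B", 0.9), ("A", "C", 0.95)])
        sub = minimum_subnetwork(["A", "C"], g, confidence_floor=0.9)
        assert ("A", "B", 0.9) not in sub.edges
        # a seed isolated by the floor still yields itself alone
        alone = minimum_subnetwork(["B"], g, confidence_floor=0.99)
        assert alone.nodes == ["B"]
        with pytest.raises(ValueError):
            minimum_subnetwork(["Q"], g, confidence_floor=0.99)

    def test_within_factor_two_of_brute_force(self):
        rng = np.random.default_rng(17)
        for _ in range(8):
            n = int(rng.integers(5, 11))
            base = nx.gnp_random_graph(n, 0.45,
                                       seed=int(rng.integers(2**31)))
            if base.number_of_edges() == 0:
                continue
            g = PpiGraph.from_edges(
                [(f"N{u}", f"N{v}", float(rng.uniform(0.3, 1.0)))
                 for u, v in base.edges])
            comp = max(nx.connected_components(g.graph), key=len)
            if len(comp) < 3:
                continue
            seeds = sorted(comp)[:3]
            sub = minimum_subnetwork(seeds, g, confidence_floor=0.0)
            H = nx.Graph()
            H.add_nodes_from(sub.nodes)
            H.add_edges_from((a, b) for a, b, _ in sub.edges)
            assert nx.is_connected(H)
            assert set(seeds) <= set(sub.nodes)
            w = sum(1.0 / c for _, _, c in sub.edges)
            assert w <= 2 * steiner_brute_force(g, seeds) + 1e-9


class TestUpgma:
    def test_hand_executed_three_leaves(self):
        nwk = upgma_tree(["A", "B", "C"],
                         [[0, 2, 8], [2, 0, 8], [8, 8, 0]])
        assert nwk == "((A:1,B:1):3,C:4);"

    def test_two_leaves(self):
        assert upgma_tree(["A", "B"], [[0, 4], [4, 0]]) == "(A:2,B:2);"

    def test_closest_pair_merges_first(self):
        nwk = upgma_tree(["A", "B", "C"],
                         [[0, 6, 6], [6, 0, 2], [6, 2, 0]])
        assert "(B:1,C:1)" in nwk

    def test_lexicographic_tie_break(self):
        nwk = upgma_tree(["C", "A", "B"],
                         [[0, 4, 4], [4, 0, 4], [4, 4, 0]])
        assert nwk == "((A:2,B:2):0,C:2);"

    def test_non_symmetric_raises(self):
        with pytest.raises(ValueError):
            upgma_tree(["A", "B"], [[0, 1], [2, 0]])

    def test_ultrametric_heights(self):
        rng = np.random.default_rng(3)
        n = 8
        pts = rng.uniform(0, 10, size=(n, 2))
        D = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        labels = [f"L{i}" for i in range(n)]
        nwk = upgma_tree(labels, D)
        # parse with dendropy-free check: leaf root-path sums must be equal
        import io as _io

        from Bio import Phylo

        tree = Phylo.read(_io.StringIO(nwk), "newick")
        depths = tree.depths()
        leaf_depths = {t.name: d for t, d in depths.items() if t.name}
        vals = list(leaf_depths.values())
        assert all(abs(v - vals[0]) < 1e-9 for v in vals)


class TestMeanDistance:
    def test_simple_mean(self):
        g = PpiGraph.from_edges([("C", "K1", 1.0), ("C", "K2", 0.5)])
        df = mean_distance_to_set(["C"], ["K1", "K2"], g)
        assert df.iloc[0]["mean_distance"] == pytest.approx(1.5)

    def test_self_excluded_by_default(self, triangle_graph):
        df = mean_distance_to_set(["A"], ["A", "B"], triangle_graph)
        assert df.iloc[0]["mean_distance"] == pytest.approx(1.0)
        df2 = mean_distance_to_set(["A"], ["A", "B"], triangle_graph,
                                   include_self=True)
        assert df2.iloc[0]["mean_distance"] == pytest.approx(0.5)

    def test_star_fixture_hand_computation(self):
        g = PpiGraph.from_edges(
            [("HUB", "C", 1.0), ("HUB", "K1", 0.8), ("HUB", "K2", 0.4)])
        df = mean_distance_to_set(["C"], ["K1", "K2"], g)
        assert df.iloc[0]["mean_distance"] == pytest.approx(
            ((1 + 1.25) + (1 + 2.5)) / 2)


class TestGraphIO:
    def test_tsv_round_trip(self, tmp_path, triangle_graph):
        path = tmp_path / "edges.tsv"
        triangle_graph.to_tsv(path)
        back = PpiGraph.from_tsv(path)
        want = {(min(a, b), max(a, b)): pytest.approx(d["confidence"])
                for a, b, d in triangle_graph.graph.edges(data=True)}
        got = {(min(a, b), max(a, b)): d["confidence"]
               for a, b, d in back.graph.edges(data=True)}
        assert got == want

    def test_string_scale_autodetect(self, tmp_path):
        path = tmp_path / "string.tsv"
        pd.DataFrame({"gene_a": ["A"], "gene_b": ["B"], "score": [900]}
                     ).to_csv(path, sep="\t", index=False)
        g = PpiGraph.from_tsv(path)
        assert g.graph["A"]["B"]["confidence"] == pytest.approx(0.9)

    def test_confidence_validation(self):
        with pytest.raises(ValueError):
            PpiGraph.from_edges([("A", "B", 1.5)])

    def test_distance_matrix_symmetric_zero_diag(self, triangle_graph):
        dm = distance_matrix(["A", "B", "C"], triangle_graph)
        assert np.allclose(dm.values, dm.values.T)
        assert np.allclose(np.diag(dm.values), 0)
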