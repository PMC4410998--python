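"""Co-occurrence networks, statistics, layout and export."""

import itertools
import math

import networkx as nx
import numpy as np
import pytest

from coword import network
from tests.conftest import make_record


def weighted_graph(edges):
    g = nx.Graph()
    for u, v, w in edges:
        g.add_edge(u, v, weight=w)
    return g


class TestBuildGraph:
    def test_one_paper_yields_all_pairs(self):
        g = network.build_graph([make_record(1, 1995, keywords=["a", "b", "c"])])
        assert set(map(frozenset, g.edges)) == {
            frozenset(p) for p in itertools.combinations("abc", 2)
        }
        assert all(d["weight"] == 1 for _, _, d in g.edges(data=True))

    def test_repeated_pair_accumulates_weight(self):
        records = [make_record(i, 1995, keywords=["a", "b"]) for i in range(2)]
        g = network.build_graph(records)
        assert g["a"]["b"]["weight"] == 2

    def test_single_keyword_paper_has_no_edges(self):
        g = network.build_graph([make_record(1, 1995, keywords=["a"])])
        assert g.number_of_edges() == 0 and "a" in g

    def test_min_frequency_excludes_before_pairing(self):
        records = [make_record(1, 1995, keywords=["a", "b"]),
                   make_record(2, 1995, keywords=["a", "c"])]
        g = network.build_graph(records, min_keyword_frequency=2)
        assert set(g.nodes) == {"a"} and g.number_of_edges() == 0

    def test_bin_restricts_papers(self):
        records = [make_record(1, 1995, keywords=["a", "b"]),
                   make_record(2, 2005, keywords=["a", "b"])]
        g = network.build_graph(records, bin_=(1993, 1997))
        assert g["a"]["b"]["weight"] == 1

    def test_edge_weights_match_brute_force_recount(self):
        rng = np.random.default_rng(5)
        vocab = [f"k{i}" for i in range(12)]
        records = []
        for i in range(150):
            kws = list(rng.choice(vocab, size=rng.integers(1, 6), replace=False))
            records.append(make_record(i, 1995, keywords=kws))
        g = network.build_graph(records)
        for u, v in itertools.combinations(vocab, 2):
            expected = sum(1 for r in records
                           if u in r.keywords and v in r.keywords)
            got = g[u][v]["weight"] if g.has_edge(u, v) else 0
            assert got == expected


class TestStatistics:
    def test_avg_weighted_degree_is_mean_edge_weight(self):
        # pairs A-B=10, B-C=20, A-C absent -> 15
        g = weighted_graph([("A", "B", 10), ("B", "C", 20)])
        assert network.avg_weighted_degree(g) == 15.0

    def test_node_mean_reading_differs(self):
        g = weighted_graph([("A", "B", 10), ("B", "C", 20)])
        assert network.avg_weighted_degree(g, mode="node_mean") == pytest.approx(20.0)

    def test_single_edge_and_unit_weights(self):
        assert network.avg_weighted_degree(weighted_graph([("a", "b", 7)])) == 7.0
        tri = weighted_graph([("a", "b", 1), ("b", "c", 1), ("a", "c", 1)])
        assert network.avg_weighted_degree(tri) == 1.0

    def test_edgeless_graph_flagged(self):
        g = nx.Graph(); g.add_node("a")
        assert math.isnan(network.avg_weighted_degree(g))

    def test_density_examples(self):
        complete = weighted_graph([(a, b, 1) for a, b in itertools.combinations("abcd", 2)])
        assert network.density(complete) == 1.0
        path2 = weighted_graph([("a", "b", 1), ("b", "c", 1)])
        assert network.density(path2) == pytest.approx(2 / 3)
        edgeless = nx.Graph(); edgeless.add_nodes_from("ab")
        assert network.density(edgeless) == 0.0

    def test_clustering_examples(self):
        tri = weighted_graph([("a", "b", 1), ("b", "c", 1), ("a", "c", 1)])
        assert network.avg_clustering(tri) == 1.0
        path = weighted_graph([("a", "b", 1), ("b", "c", 1)])
        assert network.avg_clustering(path) == 0.0
        k4_minus = weighted_graph(
            [("a", "b", 1), ("a", "c", 1), ("a", "d", 1), ("b", "c", 1), ("c", "d", 1)]
        )  # local coefficients (1, 1, 2/3, 2/3)
        assert network.avg_clustering(k4_minus) == pytest.approx(5 / 6, abs=1e-9)

    def test_modularity_single_community_is_zero(self):
        g = weighted_graph([("a", "b", 3), ("b", "c", 1)])
        assert network.modularity(g, [set(g.nodes)]) == pytest.approx(0.0)

    def test_two_triangles_split_by_triangle(self):
        edges = [("a", "b", 1), ("b", "c", 1), ("a", "c", 1),
                 ("x", "y", 1), ("y", "z", 1), ("x", "z", 1)]
        g = weighted_graph(edges)
        q = network.modularity(g, [{"a", "b", "c"}, {"x", "y", "z"}])
        assert q == pytest.approx(0.5)

    def test_detected_partition_beats_singletons(self):
        g = weighted_graph([("a", "b", 5), ("b", "c", 5), ("c", "a", 5),
                            ("c", "d", 1), ("d", "e", 5), ("e", "f", 5), ("f", "d", 5)])
        detected_q = network.modularity(g, network.detect_communities(g, seed=0))
        singleton_q = network.modularity(g, [{n} for n in g.nodes])
        assert detected_q >= singleton_q

    def test_detection_deterministic_given_seed(self):
        rng = np.random.default_rng(2)
        g = nx.gnm_random_graph(30, 120, seed=3)
        nx.set_edge_attributes(g, {e: int(rng.integers(1, 5)) for e in g.edges}, "weight")
        a = network.detect_communities(g, seed=11)
        b = network.detect_communities(g, seed=11)
        assert sorted(map(sorted, a)) == sorted(map(sorted, b))


class TestLayout:
    def test_single_node_at_origin_with_zero_score(self):
        g = nx.Graph(); g.add_node("solo")
        layout = network.layout_map(g, seed=1)
        assert layout.positions["solo"] == (0.0, 0.0)
        assert layout.density_score["solo"] == 0.0

    def test_symmetric_triangle_is_equilateral(self):
        tri = weighted_graph([("a", "b", 3), ("b", "c", 3), ("a", "c", 3)])
        layout = network.layout_map(tri, seed=0)
        d = [math.dist(layout.positions[u], layout.positions[v])
             for u, v in itertools.combinations("abc", 2)]
        assert max(d) - min(d) < 1e-6

    def test_scores_bounded_and_colors_valid(self):
        g = nx.complete_graph(6)
        nx.set_edge_attributes(g, 1, "weight")
        layout = network.layout_map(g, seed=4)
        for node in g.nodes:
            assert 0.0 <= layout.density_score[node] <= 2.0
            assert all(0.0 <= c <= 1.0 for c in layout.color[node])

    def test_two_block_structure_separates_blocks(self):
        # dense within blocks, one weak bridge; intra distances < inter
        g = nx.Graph()
        blocks = [[f"a{i}" for i in range(5)], [f"b{i}" for i in range(5)]]
        for block in blocks:
            for u, v in itertools.combinations(block, 2):
                g.add_edge(u, v, weight=10)
        g.add_edge("a0", "b0", weight=1)
        layout = network.layout_map(g, seed=0)

        def mean_dist(pairs):
            return np.mean([math.dist(layout.positions[u], layout.positions[v])
                            for u, v in pairs])

        intra = list(itertools.combinations(blocks[0], 2)) + \
            list(itertools.combinations(blocks[1], 2))
        inter = [(u, v) for u in blocks[0] for v in blocks[1]]
        assert mean_dist(intra) < mean_dist(inter)

    def test_deterministic_given_seed(self):
        g = weighted_graph([("a", "b", 2), ("b", "c", 1), ("c", "d", 4)])
        p1 = network.layout_map(g, seed=9).positions
        p2 = network.layout_map(g, seed=9).positions
        assert p1 == p2


class TestExport:
    @pytest.fixture
    def graph10(self):
        rng = np.random.default_rng(0)
        g = nx.gnm_random_graph(10, 20, seed=1)
        g = nx.relabel_nodes(g, {i: f"kw{i}" for i in g.nodes})
        nx.set_edge_attributes(g, {e: int(rng.integers(1, 9)) for e in g.edges}, "weight")
        return g

    def test_graphml_round_trip(self, graph10, tmp_path):
        (path,) = network.export_graph(graph10, None, ["graphml"], tmp_path / "g")
        back = nx.read_graphml(path)
        assert set(back.nodes) == set(graph10.nodes)
        for u, v, d in graph10.edges(data=True):
            assert int(back[u][v]["weight"]) == d["weight"]

    def test_pajek_line_counts(self, tmp_path):
        g = weighted_graph([("a", "b", 1), ("b", "c", 2)])
        (path,) = network.export_graph(g, None, ["pajek"], tmp_path / "g")
        lines = path.read_text().splitlines()
        assert lines[0] == "*Vertices 3"
        assert lines[4] == "*Edges"
        assert len(lines) == 1 + 3 + 1 + 2

    def test_vosviewer_map_columns(self, graph10, tmp_path):
        layout = network.layout_map(graph10, seed=0)
        map_path, net_path = network.export_graph(graph10, layout, ["vos"], tmp_path / "g")
        header = map_path.read_text().splitlines()[0].split("\t")
        assert header == ["id", "label", "x", "y", "score"]
        assert len(net_path.read_text().splitlines()) == graph10.number_of_edges()

    def test_unknown_format_rejected(self, graph10, tmp_path):
        with pytest.raises(ValueError):
            network.export_graph(graph10, None, ["gexf"], tmp_path / "g")
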