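"""Interactome merging, ortholog conversion and topology metrics."""

from itertools import combinations

import networkx as nx
import pandas as pd
import pytest

from ecmprofiler.network import induce_and_measure, map_orthologs, merge_interactomes


def edges_df(pairs, source="db"):
    return pd.DataFrame([{"a": a, "b": b, "source": source} for a, b in pairs])


def metrics_oracle(G):
    """Degree, clustering coefficient and density by brute-force enumeration."""
    degree = {v: len(list(G.neighbors(v))) for v in G}
    clustering = {}
    for v in G:
        nbrs = list(G.neighbors(v))
        k = len(nbrs)
        if k < 2:
            clustering[v] = 0.0
            continue
        e = sum(1 for a, b in combinations(nbrs, 2) if G.has_edge(a, b))
        clustering[v] = 2.0 * e / (k * (k - 1))
    connected = [v for v in G if degree[v] > 0]
    N, E = len(connected), G.number_of_edges()
    density = 2.0 * E / (N * (N - 1)) if N >= 2 else 0.0
    return degree, clustering, density


class TestMerge:
    def test_reversed_rows_collapse_with_both_sources(self):
        G = merge_interactomes([edges_df([("A", "B")], "db1"), edges_df([("B", "A")], "db2")])
        assert G.number_of_edges() == 1
        assert G.edges["A", "B"]["sources"] == {"db1", "db2"}

    def test_self_loop_dropped_and_counted(self, caplog):
        with caplog.at_level("WARNING"):
            G = merge_interactomes([edges_df([("A", "A"), ("A", "B")])])
        assert G.number_of_edges() == 1
        assert G.graph["self_loops_dropped"] == 1

    def test_disjoint_lists_union(self):
        lists = [edges_df([("A", "B")], "x"), edges_df([("C", "D")], "y"),
                 edges_df([("E", "F")], "z")]
        assert merge_interactomes(lists).number_of_edges() == 3

    def test_empty_input(self):
        with pytest.raises(ValueError):
            merge_interactomes([])


class TestOrthologs:
    def test_basic_mapping(self):
        mapped, unmapped = map_orthologs({"Fn1"}, {"Fn1": "FN1"})
        assert mapped == {"FN1"} and unmapped == []

    def test_unmapped_excluded_and_logged(self, caplog):
        with caplog.at_level("WARNING"):
            mapped, unmapped = map_orthologs(["Fn1", "Xyz1"], {"Fn1": "FN1"})
        assert mapped == {"FN1"} and unmapped == ["Xyz1"]
        assert any("without ortholog" in r.message for r in caplog.records)

    def test_collagen_pair(self):
        omap = {"Col1a1": "COL1A1", "Col1a2": "COL1A2"}
        mapped, _ = map_orthologs({"Col1a1", "Col1a2"}, omap)
        assert mapped == {"COL1A1", "COL1A2"}

    def test_many_to_one_deduplicated(self):
        mapped, _ = map_orthologs(["A1", "A2"], {"A1": "H", "A2": "H"})
        assert mapped == {"H"}


class TestTopology:
    def test_triangle(self):
        G = merge_interactomes([edges_df([("A", "B"), ("B", "C"), ("A", "C")])])
        rep = induce_and_measure(G, ["A", "B", "C"])
        assert all(rep.clustering[v] == 1.0 for v in "ABC")
        assert rep.density == 1.0

    def test_star(self):
        G = merge_interactomes([edges_df([("c", "l1"), ("c", "l2"), ("c", "l3")])])
        rep = induce_and_measure(G, ["c", "l1", "l2", "l3"])
        assert rep.clustering["c"] == 0.0
        assert rep.density == pytest.approx(3 / 6)
        assert rep.hubs[0] == "c" and rep.degree["c"] == 3

    def test_path(self):
        G = merge_interactomes([edges_df([("A", "B"), ("B", "C")])])
        rep = induce_and_measure(G, ["A", "B", "C"])
        assert rep.clustering["B"] == 0.0 and rep.degree["B"] == 2
        assert rep.density == pytest.approx(2 / 3)

    def test_isolated_node_excluded_by_default(self):
        G = merge_interactomes([edges_df([("A", "B")])])
        G.add_node("Z")
        rep = induce_and_measure(G, ["A", "B", "Z"])
        assert rep.n_nodes == 2 and rep.density == 1.0
        rep_all = induce_and_measure(G, ["A", "B", "Z"], include_isolates=True)
        assert rep_all.n_nodes == 3 and rep_all.density == pytest.approx(1 / 3)

    def test_empty_hits(self):
        G = merge_interactomes([edges_df([("A", "B")])])
        with pytest.raises(ValueError, match="empty"):
            induce_and_measure(G, [])

    def test_matches_brute_force_on_random_graphs(self, rng):
        for _ in range(12):
            n = int(rng.integers(5, 51))
            G = nx.gnp_random_graph(n, 0.15, seed=int(rng.integers(0, 2**31)))
            G = nx.relabel_nodes(G, {i: f"v{i}" for i in range(n)})
            full = nx.Graph(self_loops_dropped=0)
            full.add_nodes_from(G.nodes)
            full.add_edges_from(G.edges)
            rep = induce_and_measure(full, list(G.nodes)) if G.nodes else None
            deg, clus, dens = metrics_oracle(G)
            assert rep.degree == deg
            for v in G:
                assert rep.clustering[v] == pytest.approx(clus[v])
            assert rep.density == pytest.approx(dens)

    def test_adding_edge_never_decreases_degree(self, rng):
        G = nx.gnp_random_graph(20, 0.2, seed=7)
        G = nx.relabel_nodes(G, {i: f"v{i}" for i in range(20)})
        base = induce_and_measure(G, list(G.nodes))
        non_edges = list(nx.non_edges(G))
        a, b = non_edges[0]
        G.add_edge(a, b)
        grown = induce_and_measure(G, list(G.nodes))
        assert all(grown.degree[v] >= base.degree[v] for v in base.degree)

    def test_removing_isolated_node_leaves_density_unchanged(self):
        G = nx.Graph([("A", "B"), ("B", "C")])
        G.add_node("iso")
        with_iso = induce_and_measure(G, list(G.nodes))
        without = induce_and_measure(G, ["A", "B", "C"])
        assert with_iso.density == without.density
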