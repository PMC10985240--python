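from itertools import combinations

import networkx as nx
import numpy as np
import pytest

from netpharm.io_formats import EdgeList
from netpharm.network_topology import (
    BipartiteNetwork,
    PPINetwork,
    TopologyRecord,
    betweenness,
    build_bipartite,
    build_ppi,
    degree,
    rank_hubs,
    realize_bipartite_degree_sequence,
    screen_compounds,
)
from netpharm.target_sets import merge_compound_targets, merge_disease_targets, intersect

import pandas as pd


# --- independent oracle: exhaustive BFS shortest-path enumeration ----------

def _all_shortest_paths(graph: nx.Graph, s, t):
    """Every shortest s-t path, by BFS distances + recursive DAG descent."""
    dist = {s: 0}
    frontier = [s]
    while frontier:
        nxt = []
        for u in frontier:
            for w in graph[u]:
                if w not in dist:
                    dist[w] = dist[u] + 1
                    nxt.append(w)
        frontier = nxt
    if t not in dist:
        return []
    paths = []

    def descend(u, acc):
        if u == s:
            paths.append(list(reversed(acc + [s])))
            return
        for w in graph[u]:
            if dist.get(w, -1) == dist[u] - 1:
                descend(w, acc + [u])

    descend(t, [])
    return paths


def brute_force_betweenness(graph: nx.Graph, normalized=True):
    nodes = list(graph.nodes)
    bc = dict.fromkeys(nodes, 0.0)
    for s, t in combinations(nodes, 2):
        paths = _all_shortest_paths(graph, s, t)
        if not paths:
            continue
        for v in nodes:
            if v in (s, t):
                continue
            bc[v] += sum(v in p for p in paths) / len(paths)
    n = len(nodes)
    if normalized and n > 2:
        for v in bc:
            bc[v] /= (n - 1) * (n - 2) / 2
    return bc


def random_graphs(n_graphs, max_nodes=12, seed=0):
    rng = np.random.default_rng(seed)
    for _ in range(n_graphs):
        n = int(rng.integers(2, max_nodes + 1))
        p = float(rng.uniform(0.1, 0.9))
        yield nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))


class TestBetweenness:
    def test_path_center_is_one(self):
        g = nx.path_graph(["A", "B", "C"])
        assert betweenness(g)["B"] == pytest.approx(1.0)

    def test_complete_graph_all_zero(self):
        g = nx.complete_graph(4)
        assert all(v == 0 for v in betweenness(g).values())

    def test_tiny_graphs_zero_by_convention(self):
        g = nx.path_graph(2)
        assert set(betweenness(g).values()) == {0.0}

    def test_leaves_have_zero_betweenness(self):
        g = nx.star_graph(5)
        bc = betweenness(g)
        assert bc[0] == pytest.approx(1.0)
        assert all(bc[i] == 0 for i in range(1, 6))

    def test_matches_brute_force_on_random_graphs(self):
        for g in random_graphs(100, seed=7):
            expected = brute_force_betweenness(g)
            got = betweenness(g)
            for v in g.nodes:
                assert got[v] == pytest.approx(expected[v], abs=1e-12)

    def test_matches_networkx_on_random_graphs(self):
        # independent cross-check against a second implementation
        for g in random_graphs(50, max_nodes=20, seed=11):
            ref = nx.betweenness_centrality(g, normalized=True)
            got = betweenness(g)
            for v in g.nodes:
                assert got[v] == pytest.approx(ref[v], abs=1e-12)

    def test_disconnected_pairs_contribute_nothing(self):
        g = nx.Graph([("A", "B"), ("B", "C"), ("X", "Y")])
        assert betweenness(g)["B"] == pytest.approx(1.0 / 6)  # (5-1)(5-2)/2 pairs

    def test_values_in_unit_interval(self):
        for g in random_graphs(50, seed=3):
            assert all(0 <= v <= 1 for v in betweenness(g).values())


class TestBipartite:
    def _overlap(self, compound_genes, disease_genes):
        cmap = merge_compound_targets(
            [(c, g, 0.5) for c, genes in compound_genes.items() for g in genes]
            + [(c, "NOPE", 0.0) for c, genes in compound_genes.items() if not genes]
        )
        disease = merge_disease_targets([("s", pd.DataFrame({"gene": list(disease_genes)}))])
        return cmap, intersect(cmap, disease)

    def test_compound_without_overlap_edges_dropped(self):
        cmap, ov = self._overlap({"A": {"T1"}, "B": set()}, {"T1"})
        net = build_bipartite(ov, cmap)
        assert net.compound_nodes == {"A"} and net.target_nodes == {"T1"}
        assert net.n_edges == 1 and net.dropped_compounds == {"B"}

    def test_handshake_identity(self, study, study_overlap):
        net = build_bipartite(study_overlap, study.compound_map)
        deg = degree(net)
        comp_sum = sum(deg[c] for c in net.compound_nodes)
        targ_sum = sum(deg[t] for t in net.target_nodes)
        assert comp_sum == targ_sum == net.n_edges

    def test_node_sets_disjoint_enforced(self):
        with pytest.raises(ValueError):
            BipartiteNetwork({"A"}, {"A"}, set())

    def test_realized_published_degree_sequence(self, cbeo_topology):
        degrees = {r.node: r.degree for r in cbeo_topology}
        net = realize_bipartite_degree_sequence(degrees, n_targets=29)
        assert net.n_nodes == 45
        assert net.n_edges == 178
        got = degree(net)
        assert all(got[c] == d for c, d in degrees.items())


class TestScreening:
    def test_published_table_selects_exactly_five(self, cbeo_topology):
        result = screen_compounds(cbeo_topology)
        assert result.mean_degree == pytest.approx(11.125)
        assert set(result.selected) == {
            "Linalool", "p-Cymene", "α-Terpinene", "Terpinen-4-ol", "α-Terpineol",
        }

    def test_high_degree_low_betweenness_excluded(self, cbeo_topology):
        # the most abundant compound has degree 14 > mean but betweenness below mean
        result = screen_compounds(cbeo_topology)
        rec = next(r for r in cbeo_topology if r.node == "D-Limonene")
        assert rec.degree > result.mean_degree
        assert rec.betweenness < result.mean_betweenness
        assert "D-Limonene" not in result.selected

    def test_selected_sorted_by_degree_desc(self, cbeo_topology):
        result = screen_compounds(cbeo_topology)
        degrees = {r.node: r.degree for r in cbeo_topology}
        assert result.selected == sorted(
            result.selected, key=lambda c: (-degrees[c], c)
        )

    def test_identical_metrics_select_nothing(self):
        recs = [TopologyRecord(f"c{i}", 5, 0.1) for i in range(4)]
        assert screen_compounds(recs).selected == []

    def test_invariant_to_order_and_duplication(self, cbeo_topology):
        base = screen_compounds(cbeo_topology)
        doubled = screen_compounds(list(reversed(cbeo_topology)) + cbeo_topology)
        assert doubled.selected == base.selected
        assert doubled.mean_degree == base.mean_degree

    def test_ge_comparator_available(self):
        recs = [TopologyRecord("a", 5, 0.1), TopologyRecord("b", 5, 0.1)]
        assert screen_compounds(recs, comparator="ge").selected == ["a", "b"]


class TestPPI:
    def test_free_members_excluded(self):
        el = EdgeList.from_pairs([("A", "B"), ("B", "C")])
        net = build_ppi(el, {"A", "B", "C", "D"})
        assert net.nodes == {"A", "B", "C"} and net.excluded_free_nodes == {"D"}

    def test_mean_degree_at_published_scale(self):
        # 28 nodes and 82 edges give mean degree 5.857, reported rounded as 6
        members = [f"G{i}" for i in range(28)]
        pairs = list(combinations(members, 2))[:82]
        net = build_ppi(EdgeList.from_pairs(pairs), set(members))
        assert net.mean_degree == pytest.approx(2 * 82 / 28, abs=1e-9)
        assert round(net.mean_degree) == 6

    def test_edges_outside_member_set_dropped(self):
        el = EdgeList.from_pairs([("A", "B"), ("A", "Z")])
        net = build_ppi(el, {"A", "B"})
        assert net.n_edges == 1

    def test_empty_edge_list_all_free(self):
        net = build_ppi(EdgeList.from_pairs([]), {"A", "B"})
        assert net.n_nodes == 0 and net.excluded_free_nodes == {"A", "B"}


class _FixedDegreePPI(PPINetwork):
    """PPI stand-in exposing an explicit degree map (for ranking tests)."""

    def __init__(self, degs):
        super().__init__(set(degs), set(), set())
        self._degs = dict(degs)

    def degrees(self):
        return self._degs


class TestHubs:
    def test_named_hub_ranking(self):
        degs = {"OPRM1": 13, "PTGS2": 13, "ESR1": 12, "SLC6A4": 12,
                "DRD2": 11, "NR3C1": 11, "X": 9}
        top = rank_hubs(_FixedDegreePPI(degs), k=6)
        assert [g for g, _ in top] == ["OPRM1", "PTGS2", "ESR1", "SLC6A4", "DRD2", "NR3C1"]
        assert "X" not in dict(top)

    def test_tie_expansion_beyond_k(self):
        top = rank_hubs(_FixedDegreePPI({"A": 5, "B": 5, "C": 5, "D": 5}), k=2)
        assert len(top) == 4  # full tie expansion

    def test_k_larger_than_network_returns_all(self):
        el = EdgeList.from_pairs([("A", "B")])
        net = build_ppi(el, {"A", "B"})
        assert len(rank_hubs(net, k=10)) == 2

    def test_planted_hubs_recovered_at_study_scale(self, study, study_overlap):
        ppi = build_ppi(study.ppi_edges, study_overlap.intersection)
        assert ppi.n_nodes == 28  # one overlap gene left free
        top = {g for g, _ in rank_hubs(ppi, k=6)}
        assert study.truth.planted_hubs <= top
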