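"""Degree/betweenness centrality and hub-bottleneck selection."""

import itertools
import random
from collections import deque

import networkx as nx
import pytest

from conftest import build_network
from ppinet.centrality import (
    CentralityRecord,
    betweenness_map,
    centrality_records,
    degree_map,
    select_hub_bottlenecks,
)


def brute_force_betweenness(g: nx.Graph, normalized: bool = True) -> dict:
    """Independent oracle: enumerate every shortest path of every pair by BFS.

    For each ordered pair (s, t) we count, per intermediate node v, the
    number of shortest s-t paths through v over the total number of
    shortest s-t paths, summing over unordered pairs.
    """

    def all_shortest_paths(s, t):
        # BFS layering, then backward path enumeration.
        dist = {s: 0}
        preds = {s: []}
        q = deque([s])
        while q:
            u = q.popleft()
            for w in g.neighbors(u):
                if w not in dist:
                    dist[w] = dist[u] + 1
                    preds[w] = [u]
                    q.append(w)
                elif dist[w] == dist[u] + 1:
                    preds[w].append(u)
        if t not in dist:
            return []
        paths = []

        def walk(node, acc):
            if node == s:
                paths.append(list(reversed(acc + [s])))
                return
            for p in preds[node]:
                walk(p, acc + [node])

        walk(t, [])
        return paths

    bc = {v: 0.0 for v in g.nodes}
    for s, t in itertools.combinations(g.nodes, 2):
        paths = all_shortest_paths(s, t)
        if not paths:
            continue
        for v in g.nodes:
            if v in (s, t):
                continue
            through = sum(1 for p in paths if v in p)
            bc[v] += through / len(paths)
    n = g.number_of_nodes()
    if normalized and n > 2:
        scale = (n - 1) * (n - 2) / 2
        bc = {v: x / scale for v, x in bc.items()}
    return bc


class TestDegree:
    def test_path(self, path_abc):
        assert degree_map(path_abc) == {"A": 1, "B": 2, "C": 1}

    def test_complete_graph(self, clique):
        assert set(degree_map(clique(4)).values()) == {3}

    def test_handshake_identity_on_random_graph(self):
        rng = random.Random(42)
        net = build_network(
            [(f"N{i}", f"N{j}") for i in range(20) for j in range(i + 1, 20)
             if rng.random() < 0.3]
        )
        assert sum(degree_map(net).values()) == 2 * net.n_edges


class TestBetweenness:
    def test_path_middleman(self, path_abc):
        bc = betweenness_map(path_abc)
        assert bc == {"A": 0.0, "B": 1.0, "C": 0.0}

    def test_star_center(self):
        net = build_network([("HUB", leaf) for leaf in ["A", "B", "C"]])
        bc = betweenness_map(net)
        assert bc["HUB"] == 1.0
        assert bc["A"] == bc["B"] == bc["C"] == 0.0

    def test_four_cycle_split_credit(self):
        net = build_network([("A", "B"), ("B", "C"), ("C", "D"), ("D", "A")])
        bc = betweenness_map(net)
        # each node carries half of one pair's credit over (n-1)(n-2)/2 = 3 pairs
        for v in "ABCD":
            assert bc[v] == pytest.approx(0.5 / 3)

    def test_matches_brute_force_on_small_random_graphs(self):
        rng = random.Random(7)
        for _ in range(30):
            n = rng.randint(3, 7)
            g = nx.gnp_random_graph(n, rng.uniform(0.2, 0.9), seed=rng.randint(0, 10**6))
            g = nx.relabel_nodes(g, {i: f"N{i}" for i in range(n)})
            net = build_network(list(g.edges), nodes=list(g.nodes))
            expected = brute_force_betweenness(net.graph)
            got = betweenness_map(net)
            for v in net.nodes:
                assert got[v] == pytest.approx(expected[v], abs=1e-9)

    def test_normalized_range_and_leaf_zero(self, clique):
        net = clique(5)
        net.add_edge("N0", "LEAF")
        bc = betweenness_map(net)
        assert all(0.0 <= x <= 1.0 for x in bc.values())
        assert bc["LEAF"] == 0.0


class TestHubBottlenecks:
    def make_records(self, rows):
        return [CentralityRecord(n, k, b) for n, k, b in rows]

    def test_top_fraction_counts(self):
        records = self.make_records(
            [(f"N{i:03d}", 200 - i, (200 - i) / 200.0) for i in range(100)]
        )
        hb = select_hub_bottlenecks(records, 0.10)
        assert len(hb.hubs) == 10
        assert len(hb.bottlenecks) == 10
        assert len(hb.hub_bottlenecks) == 10

    def test_single_common_top_node(self):
        rows = [(f"N{i}", 10 - i, (10 - i) / 10) for i in range(10)]
        hb = select_hub_bottlenecks(self.make_records(rows), 0.1)
        assert hb.hub_bottlenecks == ("N0",)

    def test_intersection_ordered_by_degree(self):
        # 12 nodes; degree and betweenness rankings agree only on A and C.
        rows = [
            ("A", 50, 0.90), ("B", 45, 0.01), ("C", 40, 0.80), ("D", 35, 0.02),
            ("E", 30, 0.03), ("F", 25, 0.04), ("G", 20, 0.30), ("H", 15, 0.28),
            ("I", 10, 0.26), ("J", 8, 0.24), ("K", 6, 0.22), ("L", 4, 0.20),
        ]
        hb = select_hub_bottlenecks(self.make_records(rows), 4 / 12)
        assert set(hb.hubs) == {"A", "B", "C", "D"}
        assert set(hb.bottlenecks) == {"A", "C", "G", "H"}
        assert hb.hub_bottlenecks == ("A", "C")

    def test_boundary_ties_are_included(self):
        rows = [("A", 9, 0.9), ("B", 5, 0.5), ("C", 5, 0.4), ("D", 1, 0.1),
                ("E", 1, 0.05)]
        hb = select_hub_bottlenecks(self.make_records(rows), 0.4)
        # B and C tie at the degree boundary: both kept.
        assert hb.hubs == {"A", "B", "C"}

    def test_invariant_to_record_order(self):
        rows = [(f"N{i}", i, i / 20) for i in range(20)]
        records = self.make_records(rows)
        shuffled = records[::-1]
        assert (
            select_hub_bottlenecks(records, 0.2).hub_bottlenecks
            == select_hub_bottlenecks(shuffled, 0.2).hub_bottlenecks
        )

    @pytest.mark.parametrize("fraction", [0.0, -0.1, 1.5])
    def test_invalid_fraction_rejected(self, fraction):
        with pytest.raises(ValueError):
            select_hub_bottlenecks(self.make_records([("A", 1, 0.1)]), fraction)

    def test_empty_records_rejected(self):
        with pytest.raises(ValueError):
            select_hub_bottlenecks([], 0.1)


def test_records_computed_on_main_component_by_default():
    net = build_network([("A", "B"), ("B", "C"), ("A", "C"), ("X", "Y")])
    recs = centrality_records(net)
    assert {r.node for r in recs} == {"A", "B", "C"}
    recs_all = centrality_records(net, main_component_only=False)
    assert {r.node for r in recs_all} == {"A", "B", "C", "X", "Y"}
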