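"""Minimum shortest path, bipartite betweenness and group statistics."""

import itertools

import networkx as nx
import numpy as np
import pytest

from dcnet.topology import (
    bipartite_betweenness,
    min_shortest_path_to_set,
    msp_table,
    permutation_test_mean_diff,
    rank_sum_test,
)


def bbc_by_enumeration(graph, sources, targets):
    """Exhaustive oracle: enumerate every shortest path of every ordered
    (source, target) pair and credit interior vertices fractionally."""
    out = {v: 0.0 for v in graph.nodes}
    for s in sources:
        for t in targets:
            if s == t or not nx.has_path(graph, s, t):
                continue
            paths = list(nx.all_shortest_paths(graph, s, t))
            for path in paths:
                for v in path[1:-1]:
                    out[v] += 1.0 / len(paths)
    return out


def random_graph(rng, n_max=8):
    n = int(rng.integers(3, n_max + 1))
    p = float(rng.uniform(0.25, 0.7))
    g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
    return g


class TestMsp:
    def path_graph(self):
        g = nx.path_graph(["g", "a", "b", "d"])
        return g

    def test_driver_itself_zero(self):
        assert min_shortest_path_to_set(self.path_graph(), "d", {"d"}) == 0

    def test_adjacent_one(self):
        assert min_shortest_path_to_set(self.path_graph(), "b", {"d"}) == 1

    def test_path_distance_three(self):
        assert min_shortest_path_to_set(self.path_graph(), "g", {"d"}) == 3

    def test_unreachable_is_none(self):
        g = self.path_graph()
        g.add_node("island")
        assert min_shortest_path_to_set(g, "island", {"d"}) is None

    def test_missing_gene_errors(self):
        with pytest.raises(ValueError):
            min_shortest_path_to_set(self.path_graph(), "nope", {"d"})

    def test_bulk_matches_per_gene_bfs(self, rng):
        for _ in range(25):
            g = random_graph(rng)
            drivers = set(
                rng.choice(list(g.nodes), size=max(1, len(g) // 3), replace=False)
            )
            bulk = msp_table(g, drivers)
            for v in g.nodes:
                assert bulk[v] == min_shortest_path_to_set(g, v, drivers)

    def test_msp_is_lipschitz_along_edges(self, rng):
        for _ in range(20):
            g = random_graph(rng)
            drivers = {list(g.nodes)[0]}
            msp = msp_table(g, drivers)
            for u, v in g.edges:
                if msp[u] is not None and msp[v] is not None:
                    assert abs(msp[u] - msp[v]) <= 1


class TestBipartiteBetweenness:
    def test_single_interior_vertex(self):
        g = nx.path_graph(["s", "v", "t"])
        bbc = bipartite_betweenness(g, {"s"}, {"t"})
        assert bbc == {"s": 0.0, "v": 1.0, "t": 0.0}

    def test_vertex_off_all_paths_zero(self):
        g = nx.path_graph(["s", "v", "t"])
        g.add_edge("v", "offside")
        bbc = bipartite_betweenness(g, {"s"}, {"t"})
        assert bbc["offside"] == 0.0

    def test_split_flow_fractional(self):
        g = nx.cycle_graph(["s", "u", "t", "w"])  # two equal shortest paths
        bbc = bipartite_betweenness(g, {"s"}, {"t"})
        assert bbc["u"] == pytest.approx(0.5)
        assert bbc["w"] == pytest.approx(0.5)

    def test_cut_vertex_between_groups_is_strict_max(self):
        """Two branches feed a single articulation point separating the
        source group from the target group; it dominates every other node."""
        g = nx.Graph()
        sources = {"a1", "a2", "a3"}
        targets = {"b1", "b2", "b3"}
        g.add_edges_from([("a1", "x"), ("a2", "x"), ("x", "D"), ("a3", "D")])
        g.add_edges_from([("D", t) for t in targets])
        bbc = bipartite_betweenness(g, sources, targets)
        assert bbc["D"] == pytest.approx(9.0)  # all 3x3 pairs pass through D
        top = max(v for k, v in bbc.items() if k != "D")
        assert bbc["D"] > top

    def test_matches_enumeration_on_random_graphs(self, rng):
        for _ in range(60):
            g = random_graph(rng)
            nodes = list(g.nodes)
            sources = set(rng.choice(nodes, size=max(1, len(nodes) // 3), replace=False))
            targets = set(rng.choice(nodes, size=max(1, len(nodes) // 3), replace=False))
            got = bipartite_betweenness(g, sources, targets)
            want = bbc_by_enumeration(g, sources, targets)
            for v in g.nodes:
                assert got[v] == pytest.approx(want[v], abs=1e-9)

    def test_all_pairs_recovers_standard_betweenness(self, rng):
        """sources = targets = V over ordered pairs equals 2x the undirected
        betweenness centrality (independent networkx implementation)."""
        for _ in range(15):
            g = random_graph(rng, n_max=12)
            nodes = set(g.nodes)
            got = bipartite_betweenness(g, nodes, nodes)
            want = nx.betweenness_centrality(g, normalized=False)
            for v in nodes:
                assert got[v] == pytest.approx(2.0 * want[v], abs=1e-9)

    def test_flow_conservation_identity(self, rng):
        """Sum of bbc over vertices equals the summed average interior path
        length over reachable ordered pairs."""
        for _ in range(10):
            g = random_graph(rng)
            nodes = list(g.nodes)
            sources, targets = set(nodes[:2]), set(nodes[-2:])
            got = bipartite_betweenness(g, sources, targets)
            total = 0.0
            for s in sources:
                for t in targets:
                    if s != t and nx.has_path(g, s, t):
                        paths = list(nx.all_shortest_paths(g, s, t))
                        total += float(np.mean([len(p) - 2 for p in paths]))
            assert sum(got.values()) == pytest.approx(total, abs=1e-9)

    def test_empty_sets_all_zero(self):
        g = nx.path_graph(3)
        assert set(bipartite_betweenness(g, set(), {0}).values()) == {0.0}


class TestRankSum:
    def test_identical_samples_p_one(self):
        x = [1.0, 2.0, 3.0]
        u, p = rank_sum_test(x, x)
        assert u == pytest.approx(4.5)  # |x||y|/2
        assert p == pytest.approx(1.0)

    def test_complete_separation(self):
        u, p = rank_sum_test([1, 2, 3], [4, 5, 6])
        assert u == 0.0

    def test_shift_invariance(self):
        u1, p1 = rank_sum_test([1, 5, 3], [2, 8, 9])
        u2, p2 = rank_sum_test([101, 105, 103], [102, 108, 109])
        assert (u1, p1) == (u2, p2)

    def test_all_tied_p_one(self):
        assert rank_sum_test([2, 2], [2, 2, 2])[1] == 1.0


class TestPermutationTest:
    def test_identical_groups_p_one(self):
        values = {f"g{i}": 1.0 for i in range(8)}
        labels = {f"g{i}": ("dc" if i < 4 else "other") for i in range(8)}
        assert permutation_test_mean_diff(values, labels, n_perm=200, seed=1) == 1.0

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(5)
        values = {f"g{i}": float(v) for i, v in enumerate(rng.normal(size=10))}
        labels = {f"g{i}": ("dc" if i < 3 else "other") for i in range(10)}
        p1 = permutation_test_mean_diff(values, labels, n_perm=500, seed=7)
        p2 = permutation_test_mean_diff(values, labels, n_perm=500, seed=7)
        assert p1 == p2

    def test_matches_exact_enumeration_4v4(self):
        vals = [0.1, 0.4, 0.2, 0.3, 1.1, 0.9, 1.3, 0.8]
        genes = [f"g{i}" for i in range(8)]
        values = dict(zip(genes, vals))
        labels = {g: ("dc" if i < 4 else "other") for i, g in enumerate(genes)}
        observed = np.mean(vals[:4]) - np.mean(vals[4:])
        arr = np.array(vals)
        hits = total = 0
        for combo in itertools.combinations(range(8), 4):
            mask = np.zeros(8, dtype=bool)
            mask[list(combo)] = True
            stat = arr[mask].mean() - arr[~mask].mean()
            hits += abs(stat) >= abs(observed) - 1e-12
            total += 1
        exact = hits / total
        sampled = permutation_test_mean_diff(values, labels, n_perm=20_000, seed=3)
        se = np.sqrt(exact * (1 - exact) / 20_000)
        assert abs(sampled - exact) <= 3 * se + 1e-4
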