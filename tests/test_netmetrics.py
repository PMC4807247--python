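"""Topological metrics: hand examples, brute-force oracles, power-law MLE."""

import itertools

import networkx as nx
import numpy as np
import pytest

import forumnet as fn
from forumnet.netmetrics import (
    largest_fraction,
    per_node_shortest_path,
    powerlaw_mle_continuous,
    reciprocity_corrected,
    sample_discrete_power_law,
    simple_digraph,
)


def random_digraph(rng, n_max=6):
    n = int(rng.integers(2, n_max + 1))
    g = nx.DiGraph()
    g.add_nodes_from(range(n))
    for u in range(n):
        for v in range(n):
            if u != v and rng.random() < 0.35:
                g.add_edge(u, v)
    return g


class TestDegreeRecords:
    def test_single_edge(self):
        g = nx.MultiDiGraph([("A", "B")])
        recs = {r.node: r for r in fn.degree_records(g)}
        assert (recs["A"].in_degree, recs["A"].out_degree) == (0, 1)
        assert (recs["B"].in_degree, recs["B"].out_degree) == (1, 0)

    def test_toy_graph_hand_counts(self):
        g = nx.MultiDiGraph()
        g.add_edge("A", "A", kind="opening")
        g.add_edge("B", "A", kind="to_initiator")
        g.add_edge("C", "B", kind="to_message")
        g.add_edge("C", "B", kind="to_message")
        recs = {r.node: r for r in fn.degree_records(g)}
        assert recs["A"].n_threads_created == 1
        assert recs["A"].in_degree == 1
        assert recs["B"].in_degree == 2 and recs["B"].out_degree == 1
        assert recs["C"].out_degree == 2

    def test_handshake_identity(self, small_corpus):
        g = fn.build_conversation_graph(small_corpus)
        recs = fn.degree_records(g)
        m = sum(1 for u, v in g.edges() if u != v)
        assert sum(r.in_degree for r in recs) == m
        assert sum(r.out_degree for r in recs) == m


class TestDensity:
    def test_published_arithmetic_directed(self):
        g = nx.MultiDiGraph()
        g.add_nodes_from(range(5050))
        # density depends only on n and the non-loop edge count
        rng = np.random.default_rng(0)
        for _ in range(36657):
            u = int(rng.integers(5050))
            v = (u + 1 + int(rng.integers(5049))) % 5050
            g.add_edge(u, v)
        assert round(1e5 * fn.density(g), 1) == 143.8

    def test_complete_digraph(self):
        assert fn.density(nx.complete_graph(5, nx.DiGraph)) == 1.0

    def test_too_small(self):
        g = nx.DiGraph()
        g.add_node(0)
        with pytest.raises(ValueError):
            fn.density(g)

    def test_multiedges_counted_self_loops_excluded(self):
        g = nx.MultiDiGraph([("A", "B"), ("A", "B"), ("A", "A"), ("B", "C")])
        assert fn.density(g) == pytest.approx(3 / 6)

    def test_adding_edge_never_decreases_density(self):
        rng = np.random.default_rng(3)
        g = random_digraph(rng)
        nodes = list(g.nodes)
        before = fn.density(g)
        for u, v in itertools.product(nodes, nodes):
            if u != v and not g.has_edge(u, v):
                g.add_edge(u, v)
                break
        assert fn.density(g) >= before


class TestReciprocity:
    def test_fully_mutual_pair(self):
        assert fn.reciprocity(nx.DiGraph([("A", "B"), ("B", "A")])) == 1.0

    def test_hand_counted(self):
        g = nx.DiGraph([("A", "B"), ("B", "C"), ("C", "B")])
        assert fn.reciprocity(g) == pytest.approx(2 / 3)

    def test_edgeless_rejected(self):
        g = nx.DiGraph()
        g.add_nodes_from("AB")
        with pytest.raises(ValueError):
            fn.reciprocity(g)

    def test_corrected_variant_below_raw_for_sparse(self):
        g = nx.DiGraph([("A", "B"), ("B", "A"), ("B", "C")])
        assert reciprocity_corrected(g) < fn.reciprocity(g)


class TestClustering:
    def test_triangle(self):
        assert fn.clustering(nx.complete_graph(3, nx.DiGraph)) == 1.0

    def test_path_has_zero(self):
        assert fn.clustering(nx.path_graph(4, nx.DiGraph)) == 0.0

    def test_runs_on_undirected_projection(self):
        # A->B, B->C, C->A is a directed 3-cycle: undirected triangle
        g = nx.DiGraph([("A", "B"), ("B", "C"), ("C", "A")])
        assert fn.clustering(g) == 1.0


class TestShortestPaths:
    def test_directed_three_cycle(self):
        g = nx.DiGraph([(0, 1), (1, 2), (2, 0)])
        asp, diam = fn.shortest_path_stats(g)
        assert asp == pytest.approx(1.5)
        assert diam == 2

    def test_isolated_nodes_rejected(self):
        g = nx.DiGraph()
        g.add_nodes_from([0, 1])
        with pytest.raises(ValueError):
            fn.shortest_path_stats(g)

    def test_unreachable_pairs_not_imputed(self):
        g = nx.DiGraph([(0, 1), (2, 3)])
        asp, diam = fn.shortest_path_stats(g)
        assert asp == 1.0 and diam == 1

    def test_adding_edge_never_increases_asp_on_strongly_connected(self):
        g = nx.cycle_graph(6, nx.DiGraph)
        before, _ = fn.shortest_path_stats(g)
        g.add_edge(0, 3)
        after, _ = fn.shortest_path_stats(g)
        assert after <= before

    def test_per_node_mean_distance(self):
        g = nx.DiGraph([(0, 1), (1, 2)])
        d = per_node_shortest_path(g)
        assert d[0] == pytest.approx(1.5)  # distances 1, 2
        assert d[1] == 1.0
        assert np.isnan(d[2])  # reaches nothing: flagged, not zero


class TestBetweenness:
    def test_star_center_maximal(self):
        g = nx.DiGraph()
        for i in range(1, 6):
            g.add_edge(i, 0)
            g.add_edge(0, i)
        b = fn.betweenness(g)
        assert b[0] == max(b.values()) and b[0] > 0
        assert all(v == 0 for n, v in b.items() if n != 0)

    def test_path_middle_hand_value(self):
        # directed path 0->1->2->3; node 1 lies on paths 0->2, 0->3 (2 of
        # the (n-1)(n-2)=6 ordered non-endpoint pairs)
        g = nx.path_graph(4, nx.DiGraph)
        b = fn.betweenness(g)
        assert b[1] == pytest.approx(2 / 6)

    def test_matches_bruteforce_enumeration(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            g = random_digraph(rng, n_max=8)
            got = fn.betweenness(g)
            n = g.number_of_nodes()
            brute = {v: 0.0 for v in g.nodes}
            for s in g.nodes:
                for t in g.nodes:
                    if s == t or not nx.has_path(g, s, t):
                        continue
                    paths = list(nx.all_shortest_paths(g, s, t))
                    for v in g.nodes:
                        if v in (s, t):
                            continue
                        frac = sum(1 for p in paths if v in p) / len(paths)
                        brute[v] += frac
            scale = 1.0 / ((n - 1) * (n - 2)) if n > 2 else 1.0
            for v in g.nodes:
                assert got[v] == pytest.approx(brute[v] * scale, abs=1e-12)


class TestComponents:
    def test_two_disjoint_edges(self):
        g = nx.DiGraph([(0, 1), (2, 3)])
        assert fn.weak_components(g) == [2, 2]

    def test_toy_partition(self):
        g = nx.DiGraph([(0, 1), (1, 2), (3, 4)])
        g.add_node(5)
        assert fn.weak_components(g) == [3, 2, 1]

    def test_largest_fraction_published_arithmetic(self):
        sizes = [4883] + [1] * 167
        assert round(largest_fraction(sizes), 2) == 96.69


class TestBruteForceOracleAllMetrics:
    """Every metric vs a naive implementation on small random digraphs."""

    @pytest.mark.parametrize("seed", range(30))
    def test_oracle_equivalence(self, seed):
        rng = np.random.default_rng(seed)
        g = random_digraph(rng, n_max=6)
        n = g.number_of_nodes()
        edges = set(g.edges())
        if edges:
            m = len(edges)
            assert fn.density(g) == pytest.approx(m / (n * (n - 1)))
            mutual = sum(1 for (u, v) in edges if (v, u) in edges)
            assert fn.reciprocity(g) == pytest.approx(mutual / m)
        und = nx.Graph(g.to_undirected())
        und.remove_edges_from(nx.selfloop_edges(und))
        local = []
        for v in und.nodes:
            nbrs = list(und[v])
            k = len(nbrs)
            if k < 2:
                local.append(0.0)
                continue
            links = sum(
                1 for a, b in itertools.combinations(nbrs, 2) if und.has_edge(a, b)
            )
            local.append(2 * links / (k * (k - 1)))
        assert fn.clustering(g) == pytest.approx(float(np.mean(local)))
        # shortest paths via explicit BFS enumeration
        dists = [
            d
            for s in g.nodes
            for t, d in nx.single_source_shortest_path_length(g, s).items()
            if t != s
        ]
        if dists:
            asp, diam = fn.shortest_path_stats(g)
            assert asp == pytest.approx(float(np.mean(dists)))
            assert diam == max(dists)


class TestPowerLaw:
    def test_recovers_known_exponent(self):
        rng = np.random.default_rng(1234)
        x = sample_discrete_power_law(2.5, 10_000, rng)
        fit = fn.fit_power_law(x)
        assert fit.alpha == pytest.approx(2.5, abs=0.05)
        assert fit.x_min >= 1

    def test_bias_shrinks_with_sample_size(self):
        rng = np.random.default_rng(99)
        errs = []
        for n in (10**3, 10**4, 10**5):
            x = sample_discrete_power_law(2.3, n, rng)
            errs.append(abs(fn.fit_power_law(x).alpha - 2.3))
        assert errs[-1] < 0.05
        assert errs[-1] <= errs[0]

    def test_constant_sample_rejected(self):
        with pytest.raises(ValueError):
            fn.fit_power_law([1] * 50)

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            fn.fit_power_law([1, 2, 3])

    def test_continuous_mle_closed_form_hand_sample(self):
        # alpha_hat = 1 + n / sum(ln(x/xmin)) with x={1,2,4,8}, xmin=1:
        # sum ln = ln 64 = 6 ln 2 -> 1 + 4/(6 ln 2)
        got = powerlaw_mle_continuous([1, 2, 4, 8], x_min=1)
        assert got == pytest.approx(1 + 4 / (6 * np.log(2)))

    def test_deterministic_for_fixed_input(self):
        rng = np.random.default_rng(5)
        x = sample_discrete_power_law(2.1, 2000, rng)
        assert fn.fit_power_law(x) == fn.fit_power_law(x)


class TestNetworkSummary:
    def test_row_assembles_scaled_fields(self, small_corpus):
        g = fn.strip_self_loops(fn.build_conversation_graph(small_corpus))
        row = fn.network_summary(g, "toy", fit_degrees=False)
        assert row.n_edges == g.number_of_edges()
        assert row.density_1e5 == pytest.approx(1e5 * fn.density(g))
        assert row.reciprocity_1e2 == pytest.approx(100 * fn.reciprocity(g))
        assert row.clustering_1e2 == pytest.approx(100 * fn.clustering(g))
        assert row.notes["clustering_projection"] == "undirected simple"
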