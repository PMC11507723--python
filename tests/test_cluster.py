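"""Two-stage clustering: threshold, cohesiveness growth, MCL, sweep, tiers."""

import itertools

import networkx as nx
import numpy as np
import pytest

import complexkit as ck
from complexkit.goldstd import Complex, ComplexSet


def weighted_graph(edges):
    g = nx.Graph()
    for a, b, w in edges:
        g.add_edge(a, b, weight=w)
    return g


def two_triangles(bridge=0.1, w=0.9):
    edges = [("a1", "a2", w), ("a1", "a3", w), ("a2", "a3", w),
             ("b1", "b2", w), ("b1", "b3", w), ("b2", "b3", w),
             ("a1", "b1", bridge)]
    return weighted_graph(edges)


class TestThreshold:
    def test_at_or_above_cutoff_retained(self):
        scored = {("a", "b"): 0.96, ("b", "c"): 0.95, ("c", "d"): 0.94}
        g = ck.threshold_network(scored, 0.95)
        assert g.number_of_edges() == 2

    def test_cutoff_zero_keeps_all(self):
        scored = {("a", "b"): 0.3, ("c", "d"): 0.01}
        assert ck.threshold_network(scored, 0.0).number_of_edges() == 2

    def test_cutoff_one_empties(self):
        scored = {("a", "b"): 0.99}
        g = ck.threshold_network(scored, 1.0)
        assert g.number_of_nodes() == 0


def oracle_cohesiveness(graph, cluster, penalty):
    """Independent recomputation of w_in / (w_in + w_bound + penalty |C|)."""
    w_in = sum(
        d["weight"]
        for u, v, d in graph.edges(data=True)
        if u in cluster and v in cluster
    )
    w_bound = sum(
        d["weight"]
        for u, v, d in graph.edges(data=True)
        if (u in cluster) != (v in cluster)
    )
    denom = w_in + w_bound + penalty * len(cluster)
    return w_in / denom if denom else 0.0


class TestClusterOne:
    def test_two_triangles_split(self):
        clusters = ck.cluster_one(two_triangles(), density=0.1, max_overlap=0.7)
        assert sorted(sorted(c) for c in clusters) == [
            ["a1", "a2", "a3"],
            ["b1", "b2", "b3"],
        ]

    def test_triangles_are_cohesiveness_optima_by_enumeration(self):
        # brute force over all single-node add/remove neighbours of each
        # triangle confirms it is a local optimum of the cohesiveness
        g = two_triangles()
        nodes = set(g.nodes)
        for tri in ({"a1", "a2", "a3"}, {"b1", "b2", "b3"}):
            f_tri = oracle_cohesiveness(g, tri, penalty=2.0)
            for v in nodes - tri:
                assert oracle_cohesiveness(g, tri | {v}, 2.0) <= f_tri + 1e-12
            for v in tri:
                assert oracle_cohesiveness(g, tri - {v}, 2.0) <= f_tri + 1e-12

    def test_single_clique_returned_whole(self):
        g = nx.complete_graph(5)
        nx.set_edge_attributes(g, 0.8, "weight")
        clusters = ck.cluster_one(g, density=0.1, max_overlap=0.8)
        assert clusters == [set(range(5))]

    def test_overlapping_clusters_merge(self):
        a = {1, 2, 3, 4}
        b = {2, 3, 4, 5}
        # match coefficient 9/16 = 0.5625
        from complexkit.cluster import _merge_overlapping

        merged = _merge_overlapping([a, b], max_overlap=0.5)
        assert merged == [{1, 2, 3, 4, 5}]
        kept = _merge_overlapping([a, b], max_overlap=0.6)
        assert len(kept) == 2

    def test_match_coefficient(self):
        assert ck.match_coefficient({1, 2}, {1, 2}) == 1.0
        assert ck.match_coefficient({1, 2, 3}, {3, 4, 5}) == pytest.approx(1 / 9)

    def test_grown_clusters_locally_optimal_random_graphs(self):
        rng = np.random.default_rng(123)
        for _ in range(20):
            n = int(rng.integers(4, 13))
            g = nx.gnp_random_graph(n, 0.45, seed=int(rng.integers(2**31)))
            for u, v in g.edges:
                g[u][v]["weight"] = float(rng.uniform(0.1, 1.0))
            for cluster in ck.grow_clusters(g, penalty=2.0):
                f = oracle_cohesiveness(g, cluster, 2.0)
                neighbors = {v for u in cluster for v in g[u]} - cluster
                for v in neighbors:
                    assert oracle_cohesiveness(g, cluster | {v}, 2.0) <= f + 1e-9
                if len(cluster) > 1:
                    for v in cluster:
                        assert oracle_cohesiveness(g, cluster - {v}, 2.0) <= f + 1e-9


class TestMCL:
    def test_disconnected_components_never_merge(self):
        g = weighted_graph([("x", "y", 1.0), ("u", "v", 1.0)])
        clusters = ck.mcl(g, inflation=2)
        assert {frozenset(c) for c in clusters} == {frozenset("xy"), frozenset("uv")}

    def test_two_triangles_split_at_inflation_two(self):
        clusters = ck.mcl(two_triangles(), inflation=2)
        assert sorted(sorted(c) for c in clusters) == [
            ["a1", "a2", "a3"],
            ["b1", "b2", "b3"],
        ]

    def test_high_inflation_fragments_path_graph(self):
        p = nx.path_graph(10)
        nx.set_edge_attributes(p, 1.0, "weight")
        low = ck.mcl(p, inflation=2)
        high = ck.mcl(p, inflation=15)
        assert len(high) >= len(low)

    def test_random_graphs_respect_components(self):
        rng = np.random.default_rng(77)
        for _ in range(30):
            n = int(rng.integers(5, 25))
            g = nx.gnp_random_graph(n, 0.15, seed=int(rng.integers(2**31)))
            for u, v in g.edges:
                g[u][v]["weight"] = float(rng.uniform(0.2, 1.0))
            comp_of = {}
            for i, comp in enumerate(nx.connected_components(g)):
                for v in comp:
                    comp_of[v] = i
            for cluster in ck.mcl(g, inflation=2):
                assert len({comp_of[v] for v in cluster}) == 1


class TestTwoStage:
    def test_member_without_strong_edge_removed(self):
        # c attaches to a 0.96-triangle only through 0.9 edges: dropped at 0.95
        scored = {
            ("a", "b"): 0.96, ("a", "d"): 0.96, ("b", "d"): 0.96,
            ("b", "c"): 0.95, ("a", "c"): 0.95,
        }
        params = ck.ClusteringParams(score_threshold=0.95, clusterone_density=0.1,
                                     clusterone_overlap=0.8, mcl_inflation=2.0)
        out = ck.two_stage_cluster(scored, params)
        members = set().union(*out.member_sets()) if len(out) else set()
        assert "c" not in members
        assert {"a", "b", "d"} <= members

    def test_oversized_cluster_dropped(self):
        scored = {}
        nodes = [f"n{i:03d}" for i in range(101)]
        for a, b in itertools.combinations(nodes, 2):
            scored[(a, b)] = 0.99
        params = ck.ClusteringParams(score_threshold=0.5, clusterone_density=0.1,
                                     clusterone_overlap=0.8, mcl_inflation=2.0,
                                     max_cluster_size=100)
        out = ck.two_stage_cluster(scored, params)
        assert len(out) == 0

    def test_planted_complexes_recovered(self, scored_network):
        params = ck.ClusteringParams(score_threshold=0.9, clusterone_density=0.2,
                                     clusterone_overlap=0.7, mcl_inflation=2.0)
        out = ck.two_stage_cluster(scored_network["scored"], params)
        planted_sets = set(scored_network["planted"].member_sets())
        recovered = set(out.member_sets())
        exact_hits = len(planted_sets & recovered)
        assert exact_hits >= 0.7 * len(planted_sets)

    def test_every_output_complex_connected_at_threshold(self, scored_network):
        params = ck.ClusteringParams(score_threshold=0.9, clusterone_density=0.2,
                                     clusterone_overlap=0.7, mcl_inflation=2.0)
        out = ck.two_stage_cluster(scored_network["scored"], params)
        g = ck.threshold_network(scored_network["scored"], 0.9)
        for c in out:
            sub = g.subgraph(c.members)
            assert nx.is_connected(sub)


class TestSweepAndTiers:
    def test_grid_size_is_cartesian_product(self):
        grid = ck.parameter_grid([0.9, 0.5], [0.6, 0.7], [0.1, 0.2], [2, 4])
        assert len(grid) == 2 * 2 * 2 * 2

    def test_sweep_rows_and_determinism(self, scored_network):
        grid = ck.parameter_grid([0.9], [0.7], [0.2], [2, 4])
        a = ck.parameter_sweep(scored_network["scored"], grid, scored_network["train"], seed=0)
        b = ck.parameter_sweep(scored_network["scored"], grid, scored_network["train"], seed=0)
        assert len(a) == 2
        assert a.equals(b)

    def test_empty_grid_errors(self, scored_network):
        with pytest.raises(ValueError):
            ck.parameter_sweep(scored_network["scored"], [], scored_network["train"])

    def test_tier_assignment_keeps_best(self):
        s1 = ComplexSet([Complex("x", frozenset("AB"))])
        s3 = ComplexSet([Complex("y", frozenset("AB")), Complex("z", frozenset("CD"))])
        union = ck.assemble_tiers([s1, ComplexSet([]), s3])
        tiers = {c.members: c.tier for c in union}
        assert tiers[frozenset("AB")] == 1
        assert tiers[frozenset("CD")] == 3
        assert len(union) == 2  # no duplicates

    def test_tier_labels_cover_six_levels(self):
        assert ck.TIER_LABELS[1] == "Extremely High"
        assert ck.TIER_LABELS[6] == "Medium"

    def test_pareto_frontier_nondominated(self, scored_network):
        grid = ck.parameter_grid([0.9, 0.5], [0.7], [0.2, 0.4], [2, 4])
        sweep = ck.parameter_sweep(scored_network["scored"], grid, scored_network["train"], seed=0)
        front = ck.pareto_frontier(sweep)
        assert 1 <= len(front) <= 6
        pts = front[["precision_weighted", "recall_weighted"]].to_numpy()
        for p, r in pts:
            assert not np.any((pts[:, 0] > p) & (pts[:, 1] > r))

    def test_union_recall_at_least_each_tier(self, scored_network):
        grid = ck.parameter_grid([0.95, 0.9, 0.5], [0.7], [0.2, 0.4], [2, 4])
        sweep = ck.parameter_sweep(scored_network["scored"], grid, scored_network["train"], seed=0)
        front = ck.pareto_frontier(sweep)
        sets = [
            ck.two_stage_cluster(
                scored_network["scored"],
                ck.ClusteringParams(
                    score_threshold=row.score_threshold,
                    clusterone_density=row.clusterone_density,
                    clusterone_overlap=row.clusterone_overlap,
                    mcl_inflation=row.mcl_inflation,
                ),
            )
            for row in front.itertuples()
        ]
        union = ck.assemble_tiers(sets)
        gold = scored_network["test"]
        union_recall = ck.clique_pr(union, gold, seed=0).recall_weighted
        for s in sets:
            if len(s):
                assert union_recall >= ck.clique_pr(s, gold, seed=0).recall_weighted - 1e-12
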