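import math

import networkx as nx
import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from netregmir import topology
from netregmir.topology import (ConnectivityCurve, compare_to_null,
                                connectivity_curve, characteristic_path_length,
                                degree_distribution, detect_communities,
                                extract_backbone, identify_hubs, rank_by_degree,
                                sample_degree_matched_null, small_worldness,
                                transitivity, z_score, z_scores_for_network)

from conftest import modularity_oracle, random_graph, transitivity_oracle


class TestDegreeRanking:
    def test_star_center_ranks_first(self):
        star = nx.star_graph(4)
        rk = rank_by_degree(nx.relabel_nodes(star, {0: "X", 1: "a", 2: "b",
                                                    3: "c", 4: "d"}))
        assert rk.nodes[0] == "X" and rk.degrees[0] == 4

    def test_ties_break_lexicographically(self):
        rk = rank_by_degree(nx.cycle_graph(["d", "b", "a", "c"]))
        assert rk.nodes == ["a", "b", "c", "d"]
        assert rk.tie_rule == "lexicographic"

    def test_degrees_match_adjacency_count_oracle(self):
        net = random_graph(60, 0.1, seed=2)
        rk = rank_by_degree(net)
        oracle = {v: sum(1 for e in net.edges if v in e) for v in net}
        assert {(v, d) for v, d in zip(rk.nodes, rk.degrees)} == set(oracle.items())
        assert all(d1 >= d2 for d1, d2 in zip(rk.degrees, rk.degrees[1:]))


class TestConnectivityCurve:
    def test_two_private_leaf_hubs_give_half_at_k2(self):
        net = nx.Graph()
        for hub, leaves in [("h1", "abc"), ("h2", "xyz")]:
            net.add_edges_from((hub, hub + leaf) for leaf in leaves)
        curve = connectivity_curve(net, rank_by_degree(net))
        assert curve.r[1] == 0.5

    def test_star_prefixes_always_connected(self):
        net = nx.star_graph(4)
        curve = connectivity_curve(net, rank_by_degree(net))
        assert np.all(curve.r == 1.0)

    def test_boundary_values(self, small_background):
        curve = connectivity_curve(small_background,
                                   rank_by_degree(small_background))
        assert curve.r[0] == 1.0
        assert curve.r[-1] == curve.r_full

    def test_matches_per_k_recomputation_from_scratch(self, small_background):
        net = small_background
        rk = rank_by_degree(net)
        curve = connectivity_curve(net, rk)
        for k in (10, 50, 100):
            sub = net.subgraph(rk.nodes[:k])
            largest = max(len(c) for c in nx.connected_components(sub))
            assert curve.r[k - 1] == pytest.approx(largest / k)


class TestIdentifyHubs:
    def test_constant_curve_cuts_immediately(self):
        curve = ConnectivityCurve(k=np.arange(1, 6), r=np.ones(5), r_full=1.0,
                                  nodes=list("abcde"))
        assert identify_hubs(curve, 0.05).cutoff_k == 1

    def test_direct_scan_of_suffix_rule(self):
        r = np.array([1, .5, .34, .5, .75, 1.0])
        curve = ConnectivityCurve(k=np.arange(1, 7), r=r, r_full=1.0,
                                  nodes=list("abcdef"))
        rep = identify_hubs(curve, 0.05)
        assert rep.cutoff_k == 6
        assert rep.hubs == list("abcdef")

    def test_monotone_in_tolerance(self, small_background):
        curve = connectivity_curve(small_background,
                                   rank_by_degree(small_background))
        cutoffs = [identify_hubs(curve, t).cutoff_k
                   for t in (0.01, 0.05, 0.1, 0.2)]
        assert all(a >= b for a, b in zip(cutoffs, cutoffs[1:]))

    def test_recovers_planted_hubs(self, small_background):
        truth = small_background.graph["truth"]
        curve = connectivity_curve(small_background,
                                   rank_by_degree(small_background))
        rep = identify_hubs(curve, 0.05)
        assert truth.planted_hubs <= set(rep.hubs)


class TestTransitivity:
    def test_complete_graph_fully_clustered(self):
        assert transitivity(nx.complete_graph(4)) == 1.0

    def test_path_has_no_triangles(self, path_p4):
        assert transitivity(path_p4) == 0.0

    def test_no_length_2_path_is_nan(self):
        net = nx.Graph([("A", "B")])
        assert math.isnan(transitivity(net))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_triple_scan(self, seed):
        net = random_graph(30, 0.15, seed=seed)
        expected = transitivity_oracle(net)
        got = transitivity(net)
        if math.isnan(expected):
            assert math.isnan(got)
        else:
            assert got == pytest.approx(expected, abs=1e-12)

    def test_matches_igraph_on_random_graphs(self):
        igraph = pytest.importorskip("igraph")
        net = random_graph(80, 0.08, seed=9)
        nodes = sorted(net)
        idx = {v: i for i, v in enumerate(nodes)}
        g = igraph.Graph(n=len(nodes),
                         edges=[(idx[u], idx[v]) for u, v in net.edges])
        assert transitivity(net) == pytest.approx(
            g.transitivity_undirected(mode="zero"), abs=1e-12)


class TestPathLength:
    def test_p4_component_average_is_ten_sixths(self, path_p4):
        # pairwise distances 1,1,1,2,2,3 over six pairs
        assert characteristic_path_length(path_p4) == pytest.approx(10 / 6)

    def test_uses_largest_component_only(self, path_p4):
        net = path_p4.copy()
        net.add_edge("X", "Y")
        assert characteristic_path_length(net) == pytest.approx(10 / 6)


class TestNullSampling:
    def test_template_equal_background_reproduces_it(self, small_background):
        net = small_background
        samples = sample_degree_matched_null(net, net, 3, rng_seed=0)
        for s in samples:
            assert set(s.nodes) == set(net.nodes)
            assert (set(map(frozenset, s.edges))
                    == set(map(frozenset, net.edges)))

    def test_zero_samples_gives_empty_list(self, small_background):
        assert sample_degree_matched_null(small_background, small_background,
                                          0, 0) == []

    def test_degree_multisets_match_template(self, small_background):
        net = small_background
        template = net.subgraph(sorted(net)[:60])
        want = sorted(net.degree[v] for v in template)
        for s in sample_degree_matched_null(net, template, 20, rng_seed=5):
            got = sorted(net.degree[v] for v in s)
            assert got == want

    def test_background_smaller_than_template_is_hard_error(self):
        big, small = nx.complete_graph(5), nx.complete_graph(3)
        with pytest.raises(ValueError):
            sample_degree_matched_null(small, big, 1, 0)

    def test_size_mode_matches_size_only(self, small_background):
        net = small_background
        template = net.subgraph(sorted(net)[:40])
        s = sample_degree_matched_null(net, template, 2, 1, mode="size")
        assert all(g.number_of_nodes() == 40 for g in s)

    def test_deterministic_under_seed(self, small_background):
        net = small_background
        template = net.subgraph(sorted(net)[:30])
        a = sample_degree_matched_null(net, template, 2, 9)
        b = sample_degree_matched_null(net, template, 2, 9)
        assert [set(g.nodes) for g in a] == [set(g.nodes) for g in b]


class TestCompareToNull:
    def test_observed_above_all_nulls(self):
        pct, _ = compare_to_null(10.0, [1.0, 2.0, 3.0])
        assert pct == 1.0

    def test_median_observed_sits_midway(self):
        rng = np.random.default_rng(0)
        nulls = rng.normal(size=10_000)
        pct, _ = compare_to_null(float(np.median(nulls)), nulls)
        assert 0.49 <= pct <= 0.51

    def test_all_nulls_equal_observed_is_zero_by_strict_convention(self):
        pct, _ = compare_to_null(5.0, [5.0] * 100)
        assert pct == 0.0

    def test_empty_null_list_is_hard_error(self):
        with pytest.raises(ValueError):
            compare_to_null(1.0, [])

    def test_far_observed_gives_tiny_ks_p(self):
        rng = np.random.default_rng(1)
        _, ks_p = compare_to_null(50.0, rng.normal(size=1000))
        assert ks_p < 1e-10


class TestZScore:
    def test_equal_proportions_give_zero(self):
        assert z_score(1, 2, 2, 4) == 0.0

    def test_hand_evaluated_value(self):
        # (0.5 - 0.25) / sqrt(0.25 * 0.75 / 4)
        assert z_score(2, 4, 1, 4) == pytest.approx(1.1547, abs=1e-4)

    def test_strictly_increasing_in_focal_links(self):
        values = [z_score(a, 10, 3, 20) for a in range(11)]
        assert all(x < y for x, y in zip(values, values[1:]))

    @pytest.mark.parametrize("b,d", [(0, 4), (4, 4)])
    def test_degenerate_reference_proportion_is_nan(self, b, d):
        assert math.isnan(z_score(1, 2, b, d))

    @given(st.integers(1, 50), st.integers(1, 50), st.integers(2, 50))
    def test_zero_whenever_cross_products_match(self, a, b, scale):
        # a/c = b/d whenever a·d = b·c (scale ≥ 2 keeps 0 < b < d defined)
        c, d = a * scale, b * scale
        assert z_score(a, c, b, d) == pytest.approx(0.0, abs=1e-12)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            z_score(5, 4, 1, 4)
        with pytest.raises(ValueError):
            z_score(1, 0, 1, 4)


class TestZScoresForNetwork:
    def test_identical_networks_give_all_zero(self, small_background):
        for rec in z_scores_for_network(small_background, small_background):
            assert rec.z == pytest.approx(0.0, abs=1e-12)

    def test_records_match_scalar_recomputation(self, small_background):
        net = small_background
        focal = net.subgraph(sorted(net)[:80])
        for rec in z_scores_for_network(focal, net):
            again = z_score(rec.a, rec.c, rec.b, rec.d)
            assert rec.z == again or (math.isnan(rec.z) and math.isnan(again))
            assert rec.a == focal.degree[rec.node]
            assert rec.b == net.degree[rec.node]

    def test_node_missing_from_reference_is_hard_error(self, path_p4):
        focal = nx.Graph([("A", "Z")])
        with pytest.raises(ValueError):
            z_scores_for_network(focal, path_p4)


class TestSmallWorldness:
    def test_network_against_itself_is_exactly_one(self):
        k5 = nx.complete_graph(5)
        rep = small_worldness(k5, [k5])
        assert rep.s_delta == 1.0

    def test_watts_strogatz_beats_rewired_nulls(self):
        net = nx.watts_strogatz_graph(500, 10, 0.05, seed=3)
        nulls = []
        for i in range(3):
            g = net.copy()
            nx.double_edge_swap(g, nswap=4 * g.number_of_edges(),
                                max_tries=10**6, seed=100 + i)
            nulls.append(g)
        assert small_worldness(net, nulls).s_delta > 1

    def test_empty_null_list_is_hard_error(self):
        with pytest.raises(ValueError):
            small_worldness(nx.complete_graph(5), [])


class TestCommunities:
    def test_two_cliques_joined_by_bridge_split_apart(self):
        net = nx.Graph()
        left = [f"a{i}" for i in range(5)]
        right = [f"b{i}" for i in range(5)]
        net.add_edges_from((u, v) for g in (left, right)
                           for i, u in enumerate(g) for v in g[i + 1:])
        net.add_edge(left[0], right[0])
        part = detect_communities(net)
        comms = part.communities()
        assert sorted(map(sorted, comms)) == [sorted(left), sorted(right)]
        # exhaustive check: no 2-partition has higher modularity
        best = max(modularity_oracle(net, {v: int(v in set(split)) for v in net})
                   for split in _bipartitions(left + right))
        assert part.modularity_q == pytest.approx(best, abs=1e-12)

    def test_edgeless_network_gives_singletons_with_zero_q(self):
        net = nx.empty_graph(["x", "y", "z"])
        part = detect_communities(net)
        assert len(part.communities()) == 3
        assert part.modularity_q == 0.0

    @pytest.mark.parametrize("seed", range(3))
    def test_reported_q_matches_independent_modularity_sum(self, seed):
        net = random_graph(50, 0.08, seed=seed)
        part = detect_communities(net)
        assert part.modularity_q == pytest.approx(
            modularity_oracle(net, part.labels), abs=1e-10)

    def test_every_node_labeled_once_and_deterministic(self, small_background):
        p1 = detect_communities(small_background)
        p2 = detect_communities(small_background)
        assert set(p1.labels) == set(small_background.nodes)
        assert p1.labels == p2.labels


def _bipartitions(nodes):
    from itertools import combinations
    for k in range(1, len(nodes) // 2 + 1):
        yield from combinations(nodes, k)


class TestBackbone:
    def test_star_center_covers_every_leaf(self):
        net = nx.star_graph(9)
        net = nx.relabel_nodes(net, {i: f"n{i}" for i in net})
        part = detect_communities(net)
        rep = extract_backbone(net, part, degree_percentile=99.0)
        assert rep.backbone == ["n0"]
        assert len(rep.covered) == 9 and not rep.uncovered

    def test_disjoint_triangles_keep_separate_hubs(self):
        net = nx.Graph()
        net.add_edges_from([("a", "b"), ("b", "c"), ("a", "c"),
                            ("x", "y"), ("y", "z"), ("x", "z")])
        part = detect_communities(net)
        rep = extract_backbone(net, part, top_k=1)
        assert len(rep.backbone) == 2
        assert rep.backbone_network.number_of_edges() == 0
        assert len(rep.covered) == 4

    def test_covered_matches_adjacency_scan_oracle(self, small_background):
        net = small_background
        part = detect_communities(net)
        rep = extract_backbone(net, part)
        bb = set(rep.backbone)
        oracle = {v for v in net if v not in bb
                  and any(u in bb for u in net.neighbors(v))}
        assert rep.covered == oracle
        assert rep.uncovered == set(net) - bb - oracle


class TestDegreeDistribution:
    def test_complete_graph_histogram(self):
        assert degree_distribution(nx.complete_graph(4)).histogram == {3: 4}

    def test_star_histogram(self):
        assert degree_distribution(nx.star_graph(9)).histogram == {9: 1, 1: 9}

    def test_all_isolates_slope_undefined(self):
        d = degree_distribution(nx.empty_graph(5))
        assert d.histogram == {0: 5}
        assert math.isnan(d.loglog_slope)
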