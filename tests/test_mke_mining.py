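import logging

import networkx as nx
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mke.edge_weighting import to_directed_weighted
from mke.graph_core import MKEConfig
from mke.mke_mining import (
    Cluster,
    best_neighbours,
    cluster_neighbours,
    degree_threshold,
    extend_kernel,
    extend_one_stage,
    identify_first_level_kernels,
    local_average_weight,
    merge_overlapping,
    overlap_ratio,
    run_mke,
)


def brute_degree_threshold(g, pk):
    n = g.number_of_nodes()
    degrees = [d for _, d in g.degree()]
    d_max = max(degrees)
    for k in range(min(degrees), d_max + 1):
        if sum(1 for d in degrees if d >= k) / n <= pk:
            return k
    return d_max


class TestDegreeThreshold:
    def test_single_hub_among_hundred(self):
        g = nx.Graph()
        g.add_edges_from(("hub", f"leaf{i}") for i in range(10))
        g.add_edges_from(nx.complete_graph([f"m{i}" for i in range(4)]).edges())
        g.add_nodes_from(f"pad{i}" for i in range(100 - g.number_of_nodes()))
        assert g.number_of_nodes() == 100
        assert degree_threshold(g, 0.01) == 4

    def test_pk_one_gives_minimum_degree(self, path3):
        assert degree_threshold(path3, 1.0) == 1

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            degree_threshold(nx.Graph(), 0.01)

    def test_massive_ties_fall_back_to_max_degree(self, k4):
        # all degrees equal: no k reaches fraction <= 0.01, so d_max returned
        assert degree_threshold(k4, 0.01) == 3

    @pytest.mark.parametrize("seed", range(10))
    @pytest.mark.parametrize("pk", [0.01, 0.05, 0.2, 1.0])
    def test_matches_exhaustive_scan(self, seed, pk):
        g = nx.barabasi_albert_graph(500 if pk == 0.01 else 60, 2, seed=seed)
        k = degree_threshold(g, pk)
        assert k == brute_degree_threshold(g, pk)
        seeds = {v for v, d in g.degree() if d >= k}
        assert seeds  # never empty thanks to the fallback


class TestFirstLevelKernels:
    def test_high_threshold_gives_singletons(self, two_k5):
        dwg = to_directed_weighted(two_k5)
        kernels = identify_first_level_kernels(dwg, 4, 0.8)
        assert len(kernels) == 10
        assert all(len(k.members) == 1 for k in kernels)
        assert all(k.delta_history == (1,) for k in kernels)

    def test_lower_threshold_groups_each_clique(self, two_k5):
        dwg = to_directed_weighted(two_k5)
        kernels = identify_first_level_kernels(dwg, 4, 0.5)
        assert sorted(sorted(k.members) for k in kernels) == [
            ["a0", "a1", "a2", "a3", "a4"],
            ["b0", "b1", "b2", "b3", "b4"],
        ]

    def test_single_seed_gives_singleton_kernel(self, star4):
        dwg = to_directed_weighted(star4)
        kernels = identify_first_level_kernels(dwg, 3, 0.8)
        assert len(kernels) == 1
        assert kernels[0].members == frozenset({"c"})
        assert kernels[0].delta_history == (1,)

    def test_no_seeds_gives_empty_list(self, triangle):
        dwg = to_directed_weighted(triangle)
        assert identify_first_level_kernels(dwg, 99, 0.8) == []


class TestClusterNeighbours:
    def test_triangle(self, triangle):
        assert cluster_neighbours(triangle, {"a", "b"}) == {"c"}

    def test_isolated_clique_has_none(self, k4):
        assert cluster_neighbours(k4, set(k4.nodes())) == set()

    def test_matches_brute_force(self):
        g = nx.gnp_random_graph(20, 0.2, seed=11)
        members = {0, 1, 2}
        expected = {
            v for v in g if v not in members and any(g.has_edge(v, u) for u in members)
        }
        assert cluster_neighbours(g, members) == expected


class TestLocalAverageWeight:
    def test_triangle_uniform(self, triangle):
        dwg = to_directed_weighted(triangle)
        assert local_average_weight(dwg, {"a", "b"}) == pytest.approx(0.5)

    def test_four_cycle_zero(self, c4):
        dwg = to_directed_weighted(c4)
        assert local_average_weight(dwg, {"a", "b"}) == 0.0

    def test_k4_two_thirds(self, k4):
        dwg = to_directed_weighted(k4)
        # V = K4: 12 ordered adjacent pairs of weight 2/3 over 4*3 pairs
        assert local_average_weight(dwg, {"a", "b"}) == pytest.approx(2 / 3)

    def test_isolated_cluster_returns_zero_with_warning(self, caplog):
        g = nx.Graph()
        g.add_node("solo")
        dwg = to_directed_weighted(g)
        with caplog.at_level(logging.WARNING, logger="mke.mke_mining"):
            assert local_average_weight(dwg, {"solo"}) == 0.0
        assert any("|V| < 2" in r.message for r in caplog.records)

    def test_matches_brute_force_summation(self, two_k5):
        dwg = to_directed_weighted(two_k5)
        members = {"a0", "a1"}
        nodes = set(members) | cluster_neighbours(two_k5, members)
        total = sum(
            dwg.weight(s, t) for s in nodes for t in nodes if s != t
        )
        expected = total / (len(nodes) * (len(nodes) - 1))
        assert local_average_weight(dwg, members) == pytest.approx(expected)


class TestBestNeighbours:
    def test_k4_equality_admitted(self, k4):
        dwg = to_directed_weighted(k4)
        assert best_neighbours(dwg, {"a", "b"}, 2 / 3) == {"c", "d"}

    def test_threshold_one_excludes_everything(self, k4):
        assert best_neighbours(to_directed_weighted(k4), {"a", "b"}, 1.0) == set()

    def test_zero_threshold_admits_all_neighbours(self, c4):
        dwg = to_directed_weighted(c4)
        assert best_neighbours(dwg, {"a", "b"}, 0.0) == {"c", "d"}


class TestExtendOneStage:
    def test_no_qualifiers_appends_zero(self, k4):
        dwg = to_directed_weighted(k4)
        c = Cluster(frozenset({"a"}), (1,))
        out = extend_one_stage(dwg, c, w_ave=0.8)
        assert out.members == c.members
        assert out.delta_history == (1, 0)
        assert out.alpha == 2

    def test_k4_singleton_grows_fully_at_half(self, k4):
        dwg = to_directed_weighted(k4)
        c = Cluster(frozenset({"a"}), (1,))
        out = extend_one_stage(dwg, c, w_ave=0.5)
        assert out.members == frozenset("abcd")
        assert out.delta_history == (1, 3)


class TestRunMke:
    def test_two_cliques_recovered_exactly(self, two_k5):
        cfg = MKEConfig(w_init=0.5, t_alpha=4)
        result = run_mke(two_k5, cfg)
        assert sorted(sorted(c) for c in result) == [
            ["a0", "a1", "a2", "a3", "a4"],
            ["b0", "b1", "b2", "b3", "b4"],
        ]

    def test_edgeless_graph_gives_empty_set(self):
        g = nx.Graph()
        g.add_nodes_from("abc")
        assert run_mke(g, MKEConfig()) == []

    def test_deterministic_repeat(self, two_k5):
        cfg = MKEConfig(w_init=0.5, t_alpha=4)
        assert run_mke(two_k5, cfg) == run_mke(two_k5, cfg)

    @pytest.mark.parametrize("seed", range(5))
    def test_extension_invariants_on_random_graphs(self, seed):
        g = nx.gnp_random_graph(40, 0.15, seed=seed)
        cfg = MKEConfig(pk=0.1, w_init=0.5, t_alpha=4)
        dwg = to_directed_weighted(g)
        k = degree_threshold(g, cfg.pk)
        for kernel in identify_first_level_kernels(dwg, k, cfg.w_init):
            final = extend_kernel(dwg, kernel, cfg)
            # members only grow, alpha within cap + 1
            assert kernel.members <= final.members
            assert final.alpha <= cfg.t_alpha + 1
            hist = final.delta_history
            assert sum(hist) == len(final.members)
            # stopping rule: shrank, hit the cap, or stalled
            assert (
                (len(hist) >= 2 and hist[-1] < hist[-2])
                or len(hist) == cfg.t_alpha + 1
                or hist[-1] == 0
                or len(hist) == 1
            )


class TestOverlapAndMerge:
    def test_overlap_ratio_values(self):
        assert overlap_ratio({"a"}, {"a"}) == 1.0
        assert overlap_ratio({"a"}, {"b"}) == 0.0
        assert overlap_ratio({"a", "b", "c"}, {"b", "c", "d"}) == 0.5

    def test_overlap_ratio_empty_rejected(self):
        with pytest.raises(ValueError):
            overlap_ratio(set(), set())

    def test_duplicates_always_merge(self):
        out = merge_overlapping([{"a", "b", "c"}, {"a", "b", "c"}], 1.0)
        assert out == [frozenset({"a", "b", "c"})]

    def test_half_overlap_merges_to_union(self):
        out = merge_overlapping([{"a", "b", "c"}, {"b", "c", "d"}], 0.5)
        assert out == [frozenset("abcd")]

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(
        st.lists(
            st.frozensets(st.sampled_from("abcdefghij"), min_size=1, max_size=5),
            min_size=1,
            max_size=7,
        ),
        st.sampled_from([0.2, 0.5, 0.9]),
    )
    def test_fixed_point_and_order_invariance(self, complexes, threshold):
        merged = merge_overlapping(complexes, threshold)
        for i in range(len(merged)):
            for j in range(i + 1, len(merged)):
                assert overlap_ratio(merged[i], merged[j]) < threshold
        assert merge_overlapping(list(reversed(complexes)), threshold) == merged
        # membership is conserved
        assert frozenset().union(*merged) == frozenset().union(*complexes)


class TestCluster:
    def test_history_must_sum_to_size(self):
        with pytest.raises(ValueError):
            Cluster(frozenset({"a", "b"}), (1,))

    def test_empty_members_rejected(self):
        with pytest.raises(ValueError):
            Cluster(frozenset(), (0,))
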