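"""The four-phase prediction algorithm: ordering, filters, peeling, pruning."""

import pytest

from corepeel import CorePeelParams, Graph, core_and_peel, density
from corepeel.algorithm import (
    Cluster,
    candidate_set,
    order_vertices,
    passes_filter,
    peel,
    prune_clusters,
)
from corepeel.graph import compute_core_info

from .conftest import clique_edges
from .test_graph import random_graph


def cluster(members, seed=None):
    members = frozenset(members)
    return Cluster(members=members, seed=seed if seed is not None else min(members), density=1.0)


class TestOrderVertices:
    def test_high_core_first(self, k4_pendant):
        order = order_vertices(k4_pendant, compute_core_info(k4_pendant))
        assert order[-1] == 4  # pendant last
        assert set(order[:4]) == {0, 1, 2, 3}

    def test_larger_clique_first(self):
        g = Graph(clique_edges([f"b{i}" for i in range(5)]) + clique_edges("xyz"))
        order = order_vertices(g, compute_core_info(g))
        assert order[:5] == [0, 1, 2, 3, 4]

    def test_ties_by_index(self, k4):
        assert order_vertices(k4, compute_core_info(k4)) == [0, 1, 2, 3]


class TestCandidateSet:
    def test_clique(self, k4):
        info = compute_core_info(k4)
        assert candidate_set(k4, info, 0) == {0, 1, 2, 3}

    def test_pendant_sees_clique_neighbour(self, k4_pendant):
        info = compute_core_info(k4_pendant)
        assert candidate_set(k4_pendant, info, 4) == {4, 0}

    def test_isolated(self):
        g = Graph(nodes="a")
        assert candidate_set(g, compute_core_info(g), 0) == {0}


class TestPassesFilter:
    @pytest.mark.parametrize("policy", [0, 1, 2])
    def test_too_small_always_fails(self, k4, policy):
        params = CorePeelParams(q=5, policy=policy)
        assert not passes_filter(k4, {0, 1, 2, 3}, params)

    def test_clique_passes_policy0(self, k4):
        params = CorePeelParams(q=4, delta=0.9, delta_low=0.5, policy=0)
        assert passes_filter(k4, {0, 1, 2, 3}, params)

    def test_star_fails_policy1(self):
        g = Graph([("hub", f"x{i}") for i in range(6)])
        params = CorePeelParams(q=4, delta=0.9, policy=1)
        assert not passes_filter(g, set(range(7)), params)

    def test_policy0_strict_at_delta_low(self):
        # 4-path induced density is exactly 1/2: rejected by policy 0
        g = Graph([("a", "b"), ("b", "c"), ("c", "d")])
        params = CorePeelParams(q=4, delta=0.9, delta_low=0.5, policy=0)
        assert not passes_filter(g, set(range(4)), params)

    def test_policy2_is_union(self):
        # sparse overall (density <= 1/2) but contains >= q high-degree nodes
        g = Graph(clique_edges("abcd") + [(x, f"t{i}") for i, x in
                                          enumerate("abcd") for _ in [0]])
        s = set(range(g.n))
        params = CorePeelParams(q=4, delta=1.0, delta_low=0.5, policy=2)
        assert density(g, s) <= 0.5
        assert passes_filter(g, s, params)


class TestPeel:
    def test_dense_set_returned_unchanged(self, k4):
        params = CorePeelParams(q=4, delta=1.0)
        result = peel(k4, {0, 1, 2, 3}, params, seed=0)
        assert result.members == frozenset(range(4))
        assert result.density == 1.0

    def test_pendant_peeled_from_clique(self):
        g = Graph(clique_edges([f"c{i}" for i in range(6)]) + [("c0", "p")])
        params = CorePeelParams(q=4, delta=1.0)
        result = peel(g, set(range(7)), params, seed=0)
        assert result.members == frozenset(range(6))

    def test_sparse_path_fails(self):
        g = Graph([(str(i), str(i + 1)) for i in range(5)])
        params = CorePeelParams(q=4, delta=0.9)
        assert peel(g, set(range(6)), params, seed=0) is None

    def test_lost_seed_discarded(self):
        # seed p is the unique minimum-degree node: peeled first, so the
        # dense remainder no longer contains it and must be rejected
        g = Graph(clique_edges([f"c{i}" for i in range(6)]) + [("c0", "p")])
        params = CorePeelParams(q=4, delta=1.0)
        assert peel(g, set(range(7)), params, seed=6) is None

    def test_tie_break_by_neighbour_degree_sum(self):
        # K5 {a..e} with pendants u, z on a and w on b: all three pendants
        # have degree 1, but S(w) = deg(b) = 5 < S(u) = S(z) = deg(a) = 6,
        # so w is peeled first even though u has the smaller index; delta is
        # chosen so peeling stops right after that first removal
        g = Graph(
            clique_edges("abcde") + [("a", "u"), ("b", "w"), ("a", "z")]
        )
        params = CorePeelParams(q=7, delta=0.55)
        result = peel(g, set(range(g.n)), params, seed=0)
        assert result.members == frozenset(range(g.n)) - {g.index_of("w")}


class TestPruneClusters:
    params = CorePeelParams(q=2, delta=0.1, jaccard_max=0.8)

    def test_duplicates_collapse(self):
        out = prune_clusters([cluster({1, 2, 3}), cluster({1, 2, 3})], self.params)
        assert len(out) == 1

    def test_subset_removed(self):
        out = prune_clusters(
            [cluster({1, 2, 3, 4}), cluster({2, 3, 4})], self.params
        )
        assert [set(c.members) for c in out] == [{1, 2, 3, 4}]

    def test_jaccard_near_duplicate_removed(self):
        a = cluster(set(range(1, 11)), seed=1)
        b = cluster(set(range(1, 10)) | {11}, seed=2)
        # Jaccard = 9/11 > 0.8; equal sizes: the later-seeded one goes
        out = prune_clusters([a, b], self.params)
        assert out == [a]

    def test_jaccard_below_threshold_kept(self):
        a = cluster(set(range(8)))
        b = cluster(set(range(5, 13)))
        out = prune_clusters([a, b], self.params)
        assert len(out) == 2

    def test_smaller_of_similar_pair_removed(self):
        big = cluster(set(range(10)) | {99})
        # not a subset: shares 9 of big's nodes, J = 9/12 -> keep both at 0.8
        small = cluster(set(range(9)) | {98})
        out = prune_clusters([small, big], CorePeelParams(q=2, delta=0.1, jaccard_max=0.7))
        assert out == [big]


class TestCoreAndPeel:
    def test_single_clique(self):
        g = Graph(clique_edges([f"k{i}" for i in range(8)]))
        out = core_and_peel(g, CorePeelParams(q=4, delta=0.9))
        assert len(out) == 1
        assert out[0].members == frozenset(range(8))

    def test_two_disjoint_cliques(self, two_k6):
        out = core_and_peel(two_k6, CorePeelParams(q=4, delta=0.9))
        assert sorted((set(c.members) for c in out), key=min) == [
            set(range(6)),
            set(range(6, 12)),
        ]

    def test_sparse_graph_empty_output(self):
        g = Graph([(str(i), str(i + 1)) for i in range(10)])
        out = core_and_peel(g, CorePeelParams(q=4, delta=0.9))
        assert out == []

    @pytest.mark.parametrize("seed", range(10))
    def test_soundness_on_random_graphs(self, seed):
        g = random_graph(60, 0.1, seed)
        params = CorePeelParams(q=3 + seed % 3, delta=0.6 + 0.1 * (seed % 4))
        for c in core_and_peel(g, params):
            assert len(c.members) >= params.q
            assert density(g, c.members) >= params.delta
            assert c.seed in c.members
            assert c.members <= g.adj[c.seed] | {c.seed}

    def test_deterministic(self):
        g = random_graph(80, 0.12, 5)
        params = CorePeelParams(q=4, delta=0.7)
        assert core_and_peel(g, params) == core_and_peel(g, params)
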