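"""Local fitness maximization: fitness, gains, expansion, cover, merging."""

import itertools

import networkx as nx
import numpy as np
import pytest

from conftest import graph_from_edges, random_weighted_graph
from lfm_oracle import brute_fitness, is_local_max
from mccnet import (
    community_fitness,
    cover_similarity,
    detect_communities,
    expand_from_seed,
    fitness_gain,
    lfm_cover,
    merge_similar,
    similarity,
)
from mccnet.community import Community, CommunityCover, make_community


class TestFitness:
    def test_isolated_clique_alpha_one(self, two_triangles):
        assert community_fitness(two_triangles, {"a", "b", "c"}, 1.0) == pytest.approx(1.0)

    def test_single_node_with_one_edge(self):
        g = graph_from_edges([("a", "b", 1.0)])
        assert community_fitness(g, {"a"}, 1.0) == 0.0

    def test_triangle_with_one_boundary_edge(self):
        # k_in = 2*3 = 6, k_out = 1 -> 6/7 at alpha = 1
        g = graph_from_edges([("a", "b", 1.0), ("b", "c", 1.0), ("a", "c", 1.0), ("c", "d", 1.0)])
        assert community_fitness(g, {"a", "b", "c"}, 1.0) == pytest.approx(6 / 7)

    def test_isolated_node_fitness_zero(self):
        g = nx.Graph()
        g.add_node("solo")
        assert community_fitness(g, {"solo"}, 1.0) == 0.0

    def test_empty_set_rejected(self, two_triangles):
        with pytest.raises(ValueError):
            community_fitness(two_triangles, set(), 1.0)

    def test_matches_brute_force_on_random_graphs(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            g = random_weighted_graph(rng, max_nodes=7)
            alpha = float(rng.uniform(0.5, 1.6))
            nodes = list(g.nodes)
            size = int(rng.integers(1, len(nodes) + 1))
            subset = set(rng.choice(nodes, size=size, replace=False))
            assert community_fitness(g, subset, alpha) == pytest.approx(
                brute_fitness(g, subset, alpha), abs=1e-12)


class TestGain:
    def test_completing_a_clique_is_positive(self):
        g = graph_from_edges([(a, b, 1.0) for a, b in itertools.combinations("abcd", 2)])
        assert fitness_gain(g, {"a", "b", "c"}, "d", 1.0) > 0

    def test_absorbing_isolated_pendant_is_positive(self):
        # counterintuitive but exact: swallowing a pendant removes the only
        # boundary edge, so f goes 6/7 -> 8/8 = 1
        g = graph_from_edges([(a, b, 1.0) for a, b in itertools.combinations("abc", 2)]
                             + [("c", "z", 1.0)])
        assert fitness_gain(g, {"a", "b", "c"}, "z", 1.0) == pytest.approx(1 - 6 / 7, abs=1e-12)

    def test_weakly_tied_stranger_with_outside_edges_is_negative(self):
        # f({abc}) = 6/6.1; f({abcz}) = 6.2/7.2 -- the stranger drags in more
        # boundary weight than it internalizes
        g = graph_from_edges([(a, b, 1.0) for a, b in itertools.combinations("abc", 2)]
                             + [("c", "z", 0.1), ("z", "w", 1.0)])
        gain = fitness_gain(g, {"a", "b", "c"}, "z", 1.0)
        expect = brute_fitness(g, {"a", "b", "c", "z"}, 1.0) - brute_fitness(g, {"a", "b", "c"}, 1.0)
        assert gain == pytest.approx(expect, abs=1e-12)
        assert gain < 0

    def test_gain_equals_fitness_difference(self, two_triangles):
        g = two_triangles
        gain = fitness_gain(g, {"a", "b"}, "c", 1.0)
        diff = community_fitness(g, {"a", "b", "c"}, 1.0) - community_fitness(g, {"a", "b"}, 1.0)
        assert gain == pytest.approx(diff, abs=1e-12)

    def test_unknown_node_rejected(self, two_triangles):
        with pytest.raises(ValueError):
            fitness_gain(two_triangles, {"a"}, "nope", 1.0)


class TestExpansion:
    def test_recovers_own_triangle(self, two_triangles):
        for seed in ("a", "b", "c"):
            comm = expand_from_seed(two_triangles, seed, 1.0)
            assert comm.nodes == frozenset({"a", "b", "c"})
        assert expand_from_seed(two_triangles, "x", 1.0).nodes == frozenset({"x", "y", "z"})

    def test_singleton_component(self):
        g = nx.Graph()
        g.add_node("solo")
        comm = expand_from_seed(g, "solo", 1.0)
        assert comm.nodes == frozenset({"solo"}) and comm.fitness == 0.0

    def test_barbell_stops_at_weak_bridge(self):
        edges = [(a, b, 1.0) for a, b in itertools.combinations(["l1", "l2", "l3", "l4"], 2)]
        edges += [(a, b, 1.0) for a, b in itertools.combinations(["r1", "r2", "r3", "r4"], 2)]
        edges += [("l1", "r1", 0.1)]
        g = graph_from_edges(edges)
        comm = expand_from_seed(g, "l3", 1.0)
        assert comm.nodes == frozenset({"l1", "l2", "l3", "l4"})


class TestCover:
    def test_two_triangles_any_seed_order(self, two_triangles):
        for seed in range(5):
            cover = lfm_cover(two_triangles, 1.0, rng_seed=seed)
            assert sorted(sorted(c.nodes) for c in cover.communities) == \
                [["a", "b", "c"], ["x", "y", "z"]]

    def test_complete_graph_single_community(self):
        g = graph_from_edges([(a, b, 1.0) for a, b in itertools.combinations("abcde", 2)])
        cover = lfm_cover(g, 1.0, rng_seed=0)
        assert len(cover) == 1
        assert cover.communities[0].nodes == frozenset("abcde")

    def test_every_node_covered(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            g = random_weighted_graph(rng)
            cover = lfm_cover(g, 1.0, rng_seed=int(rng.integers(100)))
            assert set(cover.assignment()) == set(g.nodes)

    def test_strength_seed_strategy_deterministic_without_rng(self):
        rng = np.random.default_rng(2)
        g = random_weighted_graph(rng)
        covers = [lfm_cover(g, 1.0, rng_seed=s, seed_strategy="strength") for s in (0, 99)]
        assert [c.nodes for c in covers[0].communities] == [c.nodes for c in covers[1].communities]

    def test_resolution_monotonicity_on_planted_blocks(self):
        # three 4-cliques (weight 0.9 inside) sparsely tied by 0.1 edges:
        # higher alpha must not yield fewer communities on average
        edges = []
        for b in range(3):
            names = [f"b{b}n{i}" for i in range(4)]
            edges += [(u, v, 0.9) for u, v in itertools.combinations(names, 2)]
        edges += [("b0n0", "b1n0", 0.1), ("b1n1", "b2n0", 0.1), ("b0n1", "b2n1", 0.1)]
        g = graph_from_edges(edges)
        counts = {a: np.mean([len(lfm_cover(g, a, rng_seed=s)) for s in range(20)])
                  for a in (0.5, 1.5)}
        assert counts[1.5] >= counts[0.5]


class TestSimilarity:
    def test_identical_disjoint_partial(self):
        assert similarity({"a", "b"}, {"a", "b"}) == 1.0
        assert similarity({"a", "b"}, {"c", "d"}) == 0.0
        assert similarity({"a", "b", "c"}, {"b", "c", "d", "e"}) == pytest.approx(2 / 3)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            similarity(set(), {"a"})


class TestMerge:
    def _cover(self, graph, sets):
        return CommunityCover([make_community(graph, s, 1.0) for s in sets], alpha=1.0)

    def test_identical_communities_merge(self, two_triangles):
        cover = self._cover(two_triangles, [{"a", "b", "c"}, {"a", "b", "c"}])
        assert len(merge_similar(two_triangles, cover, beta=0.99)) == 1

    def test_disjoint_cover_unchanged(self, two_triangles):
        cover = self._cover(two_triangles, [{"a", "b", "c"}, {"x", "y", "z"}])
        merged = merge_similar(two_triangles, cover, beta=0.5)
        assert sorted(sorted(c.nodes) for c in merged.communities) == \
            [["a", "b", "c"], ["x", "y", "z"]]

    def test_chained_greedy_merge(self):
        g = graph_from_edges([(u, v, 1.0) for u, v in
                              itertools.combinations("abcde", 2)])
        # S(A,B) = 2/3 > beta merges first; then S(AuB, C) = 2/3 > beta again
        cover = self._cover(g, [{"a", "b", "c"}, {"b", "c", "d"}, {"c", "d", "e"}])
        merged = merge_similar(g, cover, beta=0.5)
        assert len(merged) == 1
        assert merged.communities[0].nodes == frozenset("abcde")

    def test_post_merge_similarity_bounded(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            g = random_weighted_graph(rng, max_nodes=8)
            beta = float(rng.uniform(0.2, 0.8))
            nodes = list(g.nodes)
            sets = []
            for _ in range(int(rng.integers(2, 6))):
                size = int(rng.integers(1, len(nodes) + 1))
                sets.append(set(rng.choice(nodes, size=size, replace=False)))
            merged = merge_similar(g, self._cover(g, sets), beta=beta)
            for c1, c2 in itertools.combinations(merged.communities, 2):
                assert similarity(c1.nodes, c2.nodes) <= beta

    def test_fitness_recomputed_after_merge(self, two_triangles):
        cover = self._cover(two_triangles, [{"a", "b"}, {"b", "c"}])
        merged = merge_similar(two_triangles, cover, beta=0.4)
        assert len(merged) == 1
        assert merged.communities[0].fitness == pytest.approx(1.0)


class TestLocalMaximality:
    def test_expansion_returns_single_move_local_maximum(self):
        rng = np.random.default_rng(11)
        for _ in range(60):
            g = random_weighted_graph(rng, max_nodes=8)
            alpha = float(rng.uniform(0.6, 1.4))
            seed = sorted(g.nodes)[int(rng.integers(len(g)))]
            comm = expand_from_seed(g, seed, alpha)
            assert is_local_max(g, comm.nodes, alpha, anchor=seed), (
                sorted(comm.nodes), seed, alpha)


def test_cover_similarity_restriction():
    detected = [{"a", "b", "q"}, {"c"}]
    planted = [{"a", "b"}, {"c"}]
    full = cover_similarity(detected, planted)
    restricted = cover_similarity(detected, planted, restrict={"a", "b", "c"})
    assert restricted == pytest.approx(1.0)
    assert full <= restricted


def test_detect_communities_pipeline(two_triangles):
    cover = detect_communities(two_triangles, alpha=1.0, beta=0.5, rng_seed=0)
    assert len(cover) == 2 and cover.beta == 0.5
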