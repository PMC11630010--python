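"""Overlapping community detection by Local Fitness Maximization (LFM).

A community G in a weighted graph has fitness

    f_G = k_in^G / (k_in^G + k_out^G)^alpha

where k_in is twice the total weight of internal edges, k_out the total
weight of boundary edges, and alpha a resolution exponent (smaller alpha
yields larger communities). Starting from a random uncovered seed, the
community greedily absorbs the adjacent node with the largest positive
fitness gain f' = f_{G+i} - f_{G-i}; after each insertion, members whose
removal would raise fitness are ejected (the seed itself is anchored, so the
result is the seed's natural community). Seeding repeats until every node is
covered, which yields possibly-overlapping communities; near-duplicates are
then merged whenever their overlap similarity

    S(G1, G2) = |G1 n G2| / min(|G1|, |G2|)

exceeds a preset threshold beta.

On unit-weight graphs the weighted k_in/k_out reduce to the classic
degree-based LFM quantities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np


@dataclass(frozen=True)
class Community:
    nodes: frozenset
    k_in: float
    k_out: float
    fitness: float
    #: expansion seed when the community came from expand_from_seed
    seed: object = None

    def sorted_nodes(self) -> list:
        return sorted(self.nodes)

    def __len__(self) -> int:
        return len(self.nodes)


@dataclass
class CommunityCover:
    communities: list[Community]
    alpha: float
    beta: float | None = None
    rng_seed: int | None = None

    def assignment(self) -> dict:
        """node -> set of community indices (total over all covered nodes)."""
        out: dict = {}
        for idx, c in enumerate(self.communities):
            for node in c.nodes:
                out.setdefault(node, set()).add(idx)
        return out

    def membership_counts(self) -> dict:
        return {node: len(ids) for node, ids in self.assignment().items()}

    def __len__(self) -> int:
        return len(self.communities)


def _degrees(graph: nx.Graph, node_set: frozenset) -> tuple[float, float]:
    k_in = 0.0
    k_out = 0.0
    for u in node_set:
        for v, d in graph[u].items():
            w = d.get("weight", 1.0)
            if v in node_set:
                k_in += w  # each internal edge hit from both ends -> twice its weight
            else:
                k_out += w
    return k_in, k_out


def community_fitness(graph: nx.Graph, node_set, alpha: float) -> float:
    """Eq.-style fitness k_in / (k_in + k_out)**alpha; 0 for an isolated set."""
    node_set = frozenset(node_set)
    if not node_set:
        raise ValueError("community must be nonempty")
    missing = node_set - set(graph)
    if missing:
        raise ValueError(f"nodes not in graph: {sorted(missing)}")
    k_in, k_out = _degrees(graph, node_set)
    total = k_in + k_out
    if total == 0:
        return 0.0
    return k_in / total**alpha


def make_community(graph: nx.Graph, node_set, alpha: float, seed=None) -> Community:
    node_set = frozenset(node_set)
    k_in, k_out = _degrees(graph, node_set)
    total = k_in + k_out
    fitness = 0.0 if total == 0 else k_in / total**alpha
    return Community(node_set, k_in, k_out, fitness, seed=seed)


def fitness_gain(graph: nx.Graph, community, node, alpha: float) -> float:
    """f' = f_{G u {i}} - f_{G \\ {i}}: the node's fitness contribution.

    Positive for a candidate worth adding; negative for a member whose
    removal would raise fitness.
    """
    if node not in graph:
        raise ValueError(f"node {node!r} not in graph")
    members = frozenset(community)
    with_node = members | {node}
    without_node = members - {node}
    f_with = community_fitness(graph, with_node, alpha)
    f_without = community_fitness(graph, without_node, alpha) if without_node else 0.0
    return f_with - f_without


def expand_from_seed(graph: nx.Graph, seed, alpha: float, removal: bool = True) -> Community:
    """Grow the natural community of ``seed`` by greedy fitness maximization.

    Repeatedly adds the neighboring node with the largest strictly positive
    gain (lexicographically smallest label on ties); after each insertion,
    non-seed members with negative fitness contribution are removed, provided
    removal keeps the community connected. Stops when no neighbor improves
    fitness. Deterministic given (graph, seed, alpha).
    """
    if seed not in graph:
        raise ValueError(f"seed {seed!r} not in graph")
    members = {seed}
    while True:
        neighbors = sorted({v for u in members for v in graph[u]} - members)
        best_node, best_gain = None, 0.0
        for cand in neighbors:
            gain = fitness_gain(graph, members, cand, alpha)
            if gain > best_gain:
                best_node, best_gain = cand, gain
        if best_node is None:
            break
        members.add(best_node)
        if removal:
            _prune(graph, members, seed, alpha)
    return make_community(graph, members, alpha, seed=seed)


def _prune(graph: nx.Graph, members: set, seed, alpha: float) -> None:
    """Eject members (never the seed) whose removal strictly raises fitness."""
    changed = True
    while changed and len(members) > 1:
        changed = False
        f_now = community_fitness(graph, members, alpha)
        for m in sorted(members):
            if m == seed or len(members) == 1:
                continue
            rest = members - {m}
            if not nx.is_connected(graph.subgraph(rest)):
                continue
            if community_fitness(graph, rest, alpha) > f_now:
                members.discard(m)
                changed = True
                break


def lfm_cover(
    graph: nx.Graph,
    alpha: float,
    rng_seed: int | None = 0,
    removal: bool = True,
    seed_strategy: str = "random",
) -> CommunityCover:
    """Cover the whole graph with (possibly overlapping) LFM communities.

    Randomness enters only through the choice of the next uncovered seed;
    "strength" strategy instead picks the highest-strength uncovered node
    (ties by label) and is fully deterministic.
    """
    if len(graph) == 0:
        raise ValueError("graph is empty")
    rng = np.random.default_rng(rng_seed)
    uncovered = set(graph.nodes)
    communities: list[Community] = []
    while uncovered:
        pool = sorted(uncovered)
        if seed_strategy == "strength":
            seed = max(pool, key=lambda n: (graph.degree(n, weight="weight"), n))
        else:
            seed = pool[int(rng.integers(len(pool)))]
        comm = expand_from_seed(graph, seed, alpha, removal=removal)
        communities.append(comm)
        uncovered -= comm.nodes
    return CommunityCover(communities, alpha=alpha, rng_seed=rng_seed)


def similarity(c1, c2) -> float:
    """Overlap similarity S = |intersection| / min size, in [0, 1]."""
    s1, s2 = set(c1), set(c2)
    if not s1 or not s2:
        raise ValueError("similarity of an empty community is undefined")
    return len(s1 & s2) / min(len(s1), len(s2))


def merge_similar(graph: nx.Graph, cover: CommunityCover, beta: float) -> CommunityCover:
    """Greedily union the most-similar pair while any S exceeds beta.

    Fitness is recomputed after every merge; the surviving communities are
    returned sorted by node labels so identical inputs give identical output.
    """
    if not 0.0 <= beta <= 1.0:
        raise ValueError("beta must lie in [0, 1]")
    sets = [set(c.nodes) for c in cover.communities]
    # exact duplicates collapse first (S = 1 regardless of beta < 1)
    while len(sets) > 1:
        best = None
        best_s = beta
        for i in range(len(sets)):
            for j in range(i + 1, len(sets)):
                s = similarity(sets[i], sets[j])
                if s > best_s:
                    best, best_s = (i, j), s
        if best is None:
            break
        i, j = best
        merged = sets[i] | sets[j]
        sets = [s for k, s in enumerate(sets) if k not in (i, j)] + [merged]
    sets.sort(key=lambda s: sorted(s))
    communities = [make_community(graph, s, cover.alpha) for s in sets]
    return CommunityCover(communities, alpha=cover.alpha, beta=beta, rng_seed=cover.rng_seed)


def detect_communities(
    graph: nx.Graph,
    alpha: float = 1.0,
    beta: float = 0.5,
    rng_seed: int | None = 0,
    removal: bool = True,
    seed_strategy: str = "random",
) -> CommunityCover:
    """lfm_cover followed by merge_similar: the full detection pipeline."""
    cover = lfm_cover(graph, alpha, rng_seed=rng_seed, removal=removal, seed_strategy=seed_strategy)
    return merge_similar(graph, cover, beta)


def cover_similarity(cover_a, cover_b, restrict=None) -> float:
    """Symmetric best-match overlap similarity between two covers.

    For each community in one cover take its best S against the other cover;
    average within each direction, then average the two directions. Accepts
    CommunityCover objects or plain iterables of node sets. ``restrict``
    limits the comparison to a node subset (communities emptied by the
    restriction are dropped): when scoring recovery of a planted cover, nodes
    the ground truth never assigns carry no information.
    """
    def _sets(cov):
        sets = [set(c.nodes) for c in cov.communities] if isinstance(cov, CommunityCover) else [set(c) for c in cov]
        if restrict is not None:
            keep = set(restrict)
            sets = [s & keep for s in sets]
            sets = [s for s in sets if s]
        return sets

    a, b = _sets(cover_a), _sets(cover_b)
    if not a or not b:
        raise ValueError("cannot compare an empty cover")
    ab = float(np.mean([max(similarity(x, y) for y in b) for x in a]))
    ba = float(np.mean([max(similarity(y, x) for x in a) for y in b]))
    return 0.5 * (ab + ba)
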