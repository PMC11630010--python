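"""Independent brute-force oracle for the community fitness function.

Computes k_in / k_out by direct enumeration of the graph's edge list, with
no shared code with the implementation, and checks single-move local
maximality (add an adjacent node, or remove a non-anchor member whose
removal keeps the community connected) by exhaustive search.
"""

import networkx as nx


def brute_fitness(graph, nodes, alpha):
    nodes = set(nodes)
    k_in = 0.0
    k_out = 0.0
    for u, v, data in graph.edges(data=True):
        w = data.get("weight", 1.0)
        inside = (u in nodes) + (v in nodes)
        if inside == 2:
            k_in += 2 * w
        elif inside == 1:
            k_out += w
    total = k_in + k_out
    return 0.0 if total == 0 else k_in / total**alpha


def single_move_neighbors(graph, nodes, anchor=None):
    """All covers reachable by one addition or one connectivity-preserving
    removal (the anchor node, when given, is never removed)."""
    nodes = set(nodes)
    for cand in {v for u in nodes for v in graph[u]} - nodes:
        yield nodes | {cand}
    for member in nodes:
        if member == anchor or len(nodes) == 1:
            continue
        rest = nodes - {member}
        if nx.is_connected(graph.subgraph(rest)):
            yield rest


def is_local_max(graph, nodes, alpha, anchor=None, tol=1e-12):
    f = brute_fitness(graph, nodes, alpha)
    return all(
        brute_fitness(graph, other, alpha) <= f + tol
        for other in single_move_neighbors(graph, nodes, anchor)
    )
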