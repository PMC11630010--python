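"""Integrated multimorbidity (MCC) network.

The monomodal disease graph and the bipartite disease-factor graph are merged
by plain node/edge union. Correlation weights (|r|) and standardized-beta
weights (|beta|) are mixed without rescaling: both are unitless effect sizes
on a comparable [0, ~1] scale. An optional per-kind min-max rescaling is
available as a sensitivity switch.
"""

from __future__ import annotations

import networkx as nx


def integrate(g: nx.Graph, f: nx.Graph, rescale: bool = False) -> nx.Graph:
    """Union of the disease-disease and disease-factor networks.

    Both inputs must be built over the same disease label set; weights and
    edge attributes are carried over unchanged (bitwise) unless ``rescale``.
    """
    g_diseases = {n for n, c in g.nodes(data="node_class") if c == "disease"}
    f_diseases = {n for n, c in f.nodes(data="node_class") if c == "disease"}
    if g_diseases != f_diseases:
        raise ValueError(
            "disease sets differ between networks: "
            f"only in monomodal {sorted(g_diseases - f_diseases)}, "
            f"only in bipartite {sorted(f_diseases - g_diseases)}"
        )
    net = nx.Graph()
    for src in (g, f):
        for node, data in src.nodes(data=True):
            net.add_node(node, **data)
        for u, v, data in src.edges(data=True):
            net.add_edge(u, v, **data)
    if rescale:
        _minmax_rescale(net)
    _check(net)
    return net


def _minmax_rescale(net: nx.Graph) -> None:
    for kind in ("disease_disease", "disease_factor"):
        ws = [d["weight"] for _, _, d in net.edges(data=True) if d["edge_kind"] == kind]
        if not ws:
            continue
        lo, hi = min(ws), max(ws)
        span = hi - lo
        for _, _, d in net.edges(data=True):
            if d["edge_kind"] == kind:
                # map into (0, 1]; degenerate span keeps weight 1
                d["weight"] = 1.0 if span == 0 else 0.5 + 0.5 * (d["weight"] - lo) / span


def _check(net: nx.Graph) -> None:
    for u, v, d in net.edges(data=True):
        cu, cv = net.nodes[u]["node_class"], net.nodes[v]["node_class"]
        if cu == cv == "factor":
            raise ValueError(f"factor-factor edge ({u}, {v}) violates integration contract")
        if d["weight"] <= 0:
            raise ValueError(f"non-positive weight on edge ({u}, {v})")


def subnetwork(net: nx.Graph, node_class: str) -> nx.Graph:
    """Induced subgraph on one node class ('disease' or 'factor')."""
    if node_class not in ("disease", "factor"):
        raise ValueError("node_class must be 'disease' or 'factor'")
    keep = [n for n, c in net.nodes(data="node_class") if c == node_class]
    return nx.Graph(net.subgraph(keep))
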