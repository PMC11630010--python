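import networkx as nx
import numpy as np
import pandas as pd
import pytest

from mccnet.tables import PrevalenceTable, RiskFactorTable


def graph_from_edges(edges):
    """Build a weighted graph from (u, v, w) triples."""
    g = nx.Graph()
    for u, v, w in edges:
        g.add_edge(u, v, weight=w)
    return g


def random_weighted_graph(rng, max_nodes=8):
    """A random connected weighted graph with 2..max_nodes nodes."""
    n = int(rng.integers(2, max_nodes + 1))
    while True:
        g = nx.gnp_random_graph(n, p=float(rng.uniform(0.3, 0.9)), seed=int(rng.integers(2**31)))
        if nx.is_connected(g) and g.number_of_edges() > 0:
            break
    for u, v in g.edges:
        g[u][v]["weight"] = float(rng.uniform(0.05, 1.0))
    return nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes})


@pytest.fixture
def toy_tables():
    """5 matched counties, 3 diseases, 3 factors, all complete."""
    rng = np.random.default_rng(7)
    ids = ["01001", "01003", "01005", "01007", "01009"]
    prev = PrevalenceTable(pd.DataFrame(
        rng.uniform(5, 40, size=(5, 3)), index=ids, columns=["d_a", "d_b", "d_c"]))
    fact = RiskFactorTable(pd.DataFrame(
        rng.uniform(5, 40, size=(5, 3)), index=ids, columns=["f_x", "f_y", "f_z"]))
    return prev, fact


@pytest.fixture
def two_triangles():
    """Two disjoint unit-weight triangles."""
    return graph_from_edges([
        ("a", "b", 1.0), ("b", "c", 1.0), ("a", "c", 1.0),
        ("x", "y", 1.0), ("y", "z", 1.0), ("x", "z", 1.0),
    ])
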