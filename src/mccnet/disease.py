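"""Monomodal disease-disease network.

Every unordered pair of disease prevalence columns is tested with a Pearson
correlation (two-sided t test, n-2 df). Pairs significant at the configured
level become edges of an undirected weighted graph G = (D, E_DD): the edge
weight is |r| (so downstream degree-style sums are nonnegative) and the
signed coefficient is kept as an attribute.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class CorrelationResult:
    disease_i: str
    disease_j: str
    r: float
    p_value: float
    n: int


def pearson_all_pairs(prev) -> list[CorrelationResult]:
    """Pearson r and two-sided p for every unordered disease pair.

    ``prev`` is a PrevalenceTable or a counties x diseases DataFrame. Columns
    with zero variance are rejected by name — a constant prevalence column is
    a data error, not a zero correlation.
    """
    df = prev.data if hasattr(prev, "data") else pd.DataFrame(prev)
    if len(df) < 3:
        raise ValueError("need at least 3 counties for a correlation p-value")
    sd = df.std(ddof=1)
    flat = sd[sd == 0].index.tolist()
    if flat:
        raise ValueError(f"zero-variance disease column(s): {flat}")
    names = list(df.columns)
    n = len(df)
    out: list[CorrelationResult] = []
    for a in range(len(names)):
        for b in range(a + 1, len(names)):
            res = stats.pearsonr(df[names[a]], df[names[b]])
            out.append(
                CorrelationResult(names[a], names[b], float(res.statistic), float(res.pvalue), n)
            )
    return out


def build_disease_network(results: list[CorrelationResult], p_threshold: float) -> nx.Graph:
    """Eq.-style adjacency: a_ij = r_ij when the pair is significantly
    correlated (p < threshold), 0 (no edge) otherwise.

    Nodes carry node_class="disease"; edges carry weight=|r|, signed_value=r,
    p_value, edge_kind="disease_disease".
    """
    g = nx.Graph()
    for res in results:
        for name in (res.disease_i, res.disease_j):
            g.add_node(name, node_class="disease")
        if res.p_value < p_threshold:
            g.add_edge(
                res.disease_i,
                res.disease_j,
                weight=abs(res.r),
                signed_value=res.r,
                p_value=res.p_value,
                edge_kind="disease_disease",
            )
    return g


def adjacency_matrix(g: nx.Graph, signed: bool = True) -> pd.DataFrame:
    """Dense symmetric adjacency (zero diagonal) over sorted disease names."""
    nodes = sorted(g.nodes)
    attr = "signed_value" if signed else "weight"
    mat = pd.DataFrame(0.0, index=nodes, columns=nodes)
    for u, v, d in g.edges(data=True):
        mat.loc[u, v] = mat.loc[v, u] = d[attr]
    return mat


def correlation_extremes(results: list[CorrelationResult]) -> tuple[CorrelationResult, CorrelationResult]:
    """(most negative, most positive) correlation across all pairs."""
    lo = min(results, key=lambda r: r.r)
    hi = max(results, key=lambda r: r.r)
    return lo, hi
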