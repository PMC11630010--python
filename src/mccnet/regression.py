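"""Bipartite disease-risk-factor network from per-disease OLS fits.

Each disease prevalence column is regressed on all risk factors at once.
Response and predictors are z-scored first, so the coefficients are
standardized betas: unitless effect sizes comparable across factors and
diseases, and commensurate with the |r| weights of the disease network.
Significant coefficients become edges of the bipartite graph F = (D, U, E_DU).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
import statsmodels.api as sm

#: design condition number above which a collinearity warning is emitted
CONDITION_WARN = 1e8


@dataclass
class RegressionResult:
    disease: str
    factor_names: list[str]
    beta: np.ndarray          # standardized coefficients, one per factor
    stderr: np.ndarray
    p_values: np.ndarray
    r_squared: float
    n: int

    def coef(self, factor: str) -> float:
        return float(self.beta[self.factor_names.index(factor)])


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("zero-variance column cannot be standardized")
    return (x - x.mean(axis=0)) / sd


def fit_disease_ols(disease_column, factor_matrix, disease_name: str | None = None) -> RegressionResult:
    """OLS of one disease's prevalence on all risk factors (standardized).

    Classical (homoskedastic) standard errors and two-sided t-test p-values.
    Rank-deficient designs are rejected naming the collinear columns.
    """
    y = np.asarray(disease_column, dtype=float)
    if isinstance(factor_matrix, pd.DataFrame):
        factor_names = list(factor_matrix.columns)
        x = factor_matrix.to_numpy(dtype=float)
    else:
        x = np.asarray(factor_matrix, dtype=float)
        factor_names = [f"f{i}" for i in range(x.shape[1])]
    n, k = x.shape
    if n <= k + 1:
        raise ValueError(f"n={n} too small for {k} factors")
    xz = _zscore(x)
    yz = _zscore(y.reshape(-1, 1)).ravel()
    rank = np.linalg.matrix_rank(xz)
    if rank < k:
        # identify columns whose removal restores full rank
        collinear = [
            factor_names[j]
            for j in range(k)
            if np.linalg.matrix_rank(np.delete(xz, j, axis=1)) == rank
        ]
        raise ValueError(f"rank-deficient factor design; collinear columns: {collinear}")
    cond = np.linalg.cond(xz)
    if cond > CONDITION_WARN:
        warnings.warn(f"ill-conditioned factor design (cond={cond:.3g})", stacklevel=2)
    model = sm.OLS(yz, sm.add_constant(xz)).fit()
    if disease_name is None and hasattr(disease_column, "name"):
        disease_name = str(disease_column.name)
    return RegressionResult(
        disease=disease_name or "disease",
        factor_names=factor_names,
        beta=np.asarray(model.params[1:]),
        stderr=np.asarray(model.bse[1:]),
        p_values=np.asarray(model.pvalues[1:]),
        r_squared=float(model.rsquared),
        n=n,
    )


def fit_all_diseases(analysis) -> list[RegressionResult]:
    """One OLS fit per disease column of an AnalysisTable."""
    factors = analysis.factors
    return [
        fit_disease_ols(analysis.data[d], factors, disease_name=d)
        for d in analysis.disease_names
    ]


def build_bipartite_network(results: list[RegressionResult], p_threshold: float) -> nx.Graph:
    """Edges (disease, factor) for every coefficient with p < threshold.

    Strictly bipartite: disease nodes connect only to factor nodes. Weight is
    |standardized beta|; the sign is kept as signed_value.
    """
    g = nx.Graph()
    for res in results:
        g.add_node(res.disease, node_class="disease")
        for j, factor in enumerate(res.factor_names):
            g.add_node(factor, node_class="factor")
            if res.p_values[j] < p_threshold:
                g.add_edge(
                    res.disease,
                    factor,
                    weight=abs(float(res.beta[j])),
                    signed_value=float(res.beta[j]),
                    p_value=float(res.p_values[j]),
                    edge_kind="disease_factor",
                )
    return g
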