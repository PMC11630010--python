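"""Readers, writers, and the end-to-end pipeline driver.

Input tables are UTF-8 delimited text with a header row; the county
identifier column is read as a string so FIPS codes keep leading zeros.
Outputs are plain-text edge lists (TSV, full float precision for lossless
round-trips), a GraphML export of the integrated network, a JSON community
listing, metric/role TSVs, and a JSON run manifest recording every
threshold, seed, and input hash that produced them.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

from . import __version__
from .community import CommunityCover, detect_communities
from .config import PipelineConfig
from .disease import build_disease_network, pearson_all_pairs
from .importance import NodeImportance, RoleAssignment, classify_roles, compute_metrics
from .integrate import integrate, subnetwork
from .regression import build_bipartite_network, fit_all_diseases
from .tables import (
    AnalysisTable,
    PrevalenceTable,
    RiskFactorTable,
    SchemaError,
    ValidationError,
    _validate_frame,
    align_tables,
)

logger = logging.getLogger(__name__)

OUTPUT_FILES = (
    "disease_edges.tsv",
    "bipartite_edges.tsv",
    "mcc_network.graphml",
    "communities.json",
    "metrics.tsv",
    "roles.tsv",
    "manifest.json",
)


@dataclass
class TableSchema:
    """Column-name map for a delimited county table.

    ``value_columns`` maps canonical variable names to file column names
    (or lists file columns to take verbatim); None means "every column
    except the county column".
    """

    county_column: str = "county_id"
    value_columns: dict | list | None = None
    delimiter: str | None = None  # None: sniff by extension (.tsv -> tab)


def _read_table(path, schema: TableSchema, kind: str, missing_policy: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = schema.delimiter or ("\t" if path.suffix.lower() in (".tsv", ".tab") else ",")
    df = pd.read_csv(path, sep=sep, dtype={schema.county_column: str}, encoding="utf-8")
    if schema.county_column not in df.columns:
        raise SchemaError(f"{kind} file {path.name} lacks county column {schema.county_column!r}")
    df = df.set_index(schema.county_column)
    if schema.value_columns is None:
        pass
    elif isinstance(schema.value_columns, dict):
        missing = [c for c in schema.value_columns.values() if c not in df.columns]
        if missing:
            raise SchemaError(f"{kind} file {path.name} lacks column(s) {missing}")
        df = df[list(schema.value_columns.values())]
        df.columns = list(schema.value_columns.keys())
    else:
        missing = [c for c in schema.value_columns if c not in df.columns]
        if missing:
            raise SchemaError(f"{kind} file {path.name} lacks column(s) {missing}")
        df = df[list(schema.value_columns)]
    if df.shape[1] < 2:
        raise SchemaError(f"{kind} file {path.name} must provide at least 2 value columns")
    return _validate_frame(df, kind=kind, missing_policy=missing_policy)


def load_prevalence_table(
    path, schema: TableSchema | None = None, missing_policy: str = "drop_row"
) -> PrevalenceTable:
    """Read a counties x diseases prevalence table (percent scale)."""
    return PrevalenceTable(_read_table(path, schema or TableSchema(), "prevalence", missing_policy))


def load_factor_table(
    path,
    schema: TableSchema | None = None,
    missing_policy: str = "drop_row",
    disease_names: list | None = None,
) -> RiskFactorTable:
    """Read a counties x risk-factors table; factor names must not collide
    with the disease names when those are supplied."""
    table = RiskFactorTable(_read_table(path, schema or TableSchema(), "risk-factor", missing_policy))
    if disease_names:
        overlap = set(table.factor_names) & set(disease_names)
        if overlap:
            raise ValidationError(f"factor column(s) named like diseases: {sorted(overlap)}")
    return table


# -- writers ----------------------------------------------------------------


def write_edge_list(graph: nx.Graph, path, extra_cols: tuple = ("p_value",)) -> None:
    """4+ column TSV (node_u, node_v, weight, signed_value, ...) at full
    float precision, rows sorted for byte-stable output."""
    rows = []
    for u, v, d in graph.edges(data=True):
        a, b = sorted((str(u), str(v)))
        row = {"node_u": a, "node_v": b, "weight": d["weight"], "signed_value": d["signed_value"]}
        for c in extra_cols:
            row[c] = d.get(c)
        rows.append(row)
    rows.sort(key=lambda r: (r["node_u"], r["node_v"]))
    df = pd.DataFrame(rows, columns=["node_u", "node_v", "weight", "signed_value", *extra_cols])
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_edge_list(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"node_u": str, "node_v": str})


def communities_to_json(cover: CommunityCover, net: nx.Graph) -> list[dict]:
    out = []
    for idx, comm in enumerate(cover.communities):
        nodes = comm.sorted_nodes()
        classes = [net.nodes[n].get("node_class", "disease") for n in nodes]
        out.append(
            {
                "id": idx,
                "nodes": nodes,
                "n_disease": classes.count("disease"),
                "n_factor": classes.count("factor"),
                "fitness": comm.fitness,
                "alpha": cover.alpha,
                "beta": cover.beta,
            }
        )
    return out


def write_communities(cover: CommunityCover, net: nx.Graph, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(communities_to_json(cover, net), fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_metrics(metrics: list[NodeImportance], path) -> None:
    df = pd.DataFrame(
        [(m.node, m.node_class, m.strength, m.influence, m.degree, m.variant) for m in metrics],
        columns=["node", "node_class", "strength", "influence", "degree", "variant"],
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def write_roles(roles: list[RoleAssignment], path) -> None:
    df = pd.DataFrame(
        [(r.node, r.role, r.n_communities, r.rule_trace) for r in roles],
        columns=["disease", "role", "n_communities", "rule_trace"],
    )
    df.to_csv(path, sep="\t", index=False)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


# -- pipeline ---------------------------------------------------------------


@dataclass
class ReportBundle:
    config: PipelineConfig
    analysis: AnalysisTable
    correlations: list
    disease_net: nx.Graph
    regressions: list
    bipartite_net: nx.Graph
    mcc_net: nx.Graph
    cover: CommunityCover
    metrics: list[NodeImportance]
    roles: list[RoleAssignment]
    manifest: dict


def analyze_tables(prev: PrevalenceTable, fact: RiskFactorTable, config: PipelineConfig) -> ReportBundle:
    """The full in-memory analysis on already-loaded tables."""
    analysis = align_tables(prev, fact, missing_policy=config.missing_policy)
    prev_aligned = PrevalenceTable(analysis.diseases)
    correlations = pearson_all_pairs(prev_aligned)
    disease_net = build_disease_network(correlations, config.p_threshold)
    regressions = fit_all_diseases(analysis)
    bipartite_net = build_bipartite_network(regressions, config.p_threshold)
    mcc_net = integrate(disease_net, bipartite_net, rescale=config.rescale_weights)
    cover = detect_communities(
        mcc_net,
        alpha=config.alpha,
        beta=config.beta,
        rng_seed=config.rng_seed,
        removal=config.lfm_removal,
        seed_strategy=config.seed_strategy,
    )
    metric_net = mcc_net if config.metrics_scope == "full" else subnetwork(mcc_net, "disease")
    metrics = compute_metrics(metric_net, variant=config.influence_variant)
    roles = classify_roles(cover, metrics, core_k=config.core_k, core_threshold=config.core_threshold)
    manifest = {
        "package_version": __version__,
        "config": config.to_dict(),
        "rng_seed": config.rng_seed,
        "row_counts": {
            "prevalence": prev.row_count,
            "factors": fact.row_count,
            "analysis": analysis.row_count,
            "dropped_join": analysis.n_dropped_join,
            "dropped_missing": analysis.n_dropped_missing,
        },
        "n_disease_edges": disease_net.number_of_edges(),
        "n_bipartite_edges": bipartite_net.number_of_edges(),
        "n_communities": len(cover),
    }
    return ReportBundle(
        config, analysis, correlations, disease_net, regressions, bipartite_net,
        mcc_net, cover, metrics, roles, manifest,
    )


def run_pipeline(
    config: PipelineConfig,
    prev_path,
    fact_path,
    out_dir,
    prev_schema: TableSchema | None = None,
    fact_schema: TableSchema | None = None,
) -> ReportBundle:
    """Load, analyze, and write every output file (atomically: partial
    outputs are removed if any stage fails)."""
    prev = load_prevalence_table(prev_path, prev_schema, missing_policy=config.missing_policy)
    fact = load_factor_table(
        fact_path, fact_schema, missing_policy=config.missing_policy,
        disease_names=prev.disease_names,
    )
    bundle = analyze_tables(prev, fact, config)
    bundle.manifest["inputs"] = {
        "prevalence": {"path": str(prev_path), "sha256": _sha256(prev_path)},
        "factors": {"path": str(fact_path), "sha256": _sha256(fact_path)},
    }

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        def _target(name: str) -> Path:
            p = out_dir / name
            written.append(p)
            return p

        write_edge_list(bundle.disease_net, _target("disease_edges.tsv"))
        write_edge_list(bundle.bipartite_net, _target("bipartite_edges.tsv"))
        nx.write_graphml(bundle.mcc_net, _target("mcc_network.graphml"))
        write_communities(bundle.cover, bundle.mcc_net, _target("communities.json"))
        write_metrics(bundle.metrics, _target("metrics.tsv"))
        write_roles(bundle.roles, _target("roles.tsv"))
        with open(_target("manifest.json"), "w", encoding="utf-8") as fh:
            json.dump(bundle.manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise
    return bundle
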