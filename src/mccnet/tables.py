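"""County-indexed prevalence and risk-factor tables.

Both tables hold percentages in [0, 100] keyed by an opaque county
identifier (FIPS codes are strings: numeric parsing drops leading zeros).
``AnalysisTable`` is the inner join of one of each, the complete-case
matrix every downstream stage consumes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING_POLICIES = ("drop_row", "error")


class SchemaError(ValueError):
    """A required column is absent or misnamed in an input file."""


class ValidationError(ValueError):
    """Parsed data violate a table invariant (range, uniqueness, disjointness)."""


def _validate_frame(df: pd.DataFrame, *, kind: str, missing_policy: str) -> pd.DataFrame:
    """Apply the missing-data policy and enforce the [0, 100] percent range.

    Missing / non-numeric cells are handled per policy; numeric cells outside
    [0, 100] are always an error, naming the offending row and column.
    """
    if missing_policy not in MISSING_POLICIES:
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate county_id values in {kind} table: {dupes}")
    if len(set(df.columns)) != len(df.columns):
        raise ValidationError(f"duplicate column names in {kind} table")

    values = df.apply(pd.to_numeric, errors="coerce")
    bad = values.notna() & ((values < 0) | (values > 100))
    if bad.to_numpy().any():
        row = bad.any(axis=1).idxmax()
        col = bad.loc[row].idxmax()
        raise ValidationError(
            f"{kind} table cell out of percent range [0, 100]: "
            f"county {row!r}, column {col!r} = {values.loc[row, col]}"
        )
    missing = values.isna()
    if missing.to_numpy().any():
        n_bad = int(missing.any(axis=1).sum())
        if missing_policy == "error":
            row = missing.any(axis=1).idxmax()
            col = missing.loc[row].idxmax()
            raise ValidationError(
                f"{kind} table has a missing/non-numeric cell at county {row!r}, "
                f"column {col!r} (missing_policy='error')"
            )
        values = values.dropna(axis=0, how="any")
        logger.info("%s table: dropped %d incomplete rows (missing_policy=drop_row)", kind, n_bad)
    return values


@dataclass
class CountyTable:
    """A counties x variables percentage matrix with validated invariants."""

    data: pd.DataFrame  # index: county_id (str), columns: variable names
    kind: str = "county"

    def __post_init__(self) -> None:
        self.data.index = self.data.index.astype(str)
        if not np.isfinite(self.data.to_numpy(dtype=float)).all():
            raise ValidationError(f"{self.kind} table contains non-finite cells")

    @property
    def county_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def names(self) -> list[str]:
        return list(self.data.columns)

    @property
    def row_count(self) -> int:
        return len(self.data)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)


@dataclass
class PrevalenceTable(CountyTable):
    kind: str = "prevalence"

    @property
    def disease_names(self) -> list[str]:
        return self.names


@dataclass
class RiskFactorTable(CountyTable):
    kind: str = "risk-factor"

    @property
    def factor_names(self) -> list[str]:
        return self.names


@dataclass
class AnalysisTable:
    """Inner join of a prevalence and a risk-factor table on county_id."""

    data: pd.DataFrame
    disease_names: list[str]
    factor_names: list[str]
    n_dropped_join: int = 0
    n_dropped_missing: int = 0

    @property
    def row_count(self) -> int:
        return len(self.data)

    @property
    def diseases(self) -> pd.DataFrame:
        return self.data[self.disease_names]

    @property
    def factors(self) -> pd.DataFrame:
        return self.data[self.factor_names]


def align_tables(
    prev: PrevalenceTable,
    fact: RiskFactorTable,
    missing_policy: str = "drop_row",
) -> AnalysisTable:
    """Inner-join the two tables on county_id.

    Counties present in only one table are dropped (and counted); the
    variable sets must be disjoint so every column name stays unambiguous.
    """
    overlap = set(prev.disease_names) & set(fact.factor_names)
    if overlap:
        raise ValidationError(f"disease and factor names overlap: {sorted(overlap)}")
    common = prev.data.index.intersection(fact.data.index)
    if len(common) == 0:
        raise ValidationError("no counties in common between prevalence and factor tables")
    n_dropped = (prev.row_count - len(common)) + (fact.row_count - len(common))
    if n_dropped:
        logger.info("align_tables: dropped %d county rows absent from one table", n_dropped)
    joined = prev.data.loc[common].join(fact.data.loc[common], how="inner")
    missing = joined.isna().any(axis=1)
    n_missing = int(missing.sum())
    if n_missing:
        if missing_policy == "error":
            raise ValidationError(f"{n_missing} joined rows have missing cells")
        joined = joined.loc[~missing]
    return AnalysisTable(
        data=joined,
        disease_names=prev.disease_names,
        factor_names=fact.factor_names,
        n_dropped_join=n_dropped,
        n_dropped_missing=n_missing,
    )
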