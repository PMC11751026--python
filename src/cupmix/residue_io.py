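"""Data model and CSV readers/writers for residue, compound and endpoint tables.

The pipeline's universal input is a long-format residue table: one row per
(site, management system, matrix, distance class, month, compound) with a
concentration in ug/kg dry weight (equivalently ng/g) and a censoring status.
Censoring semantics follow standard monitoring practice for left-censored
residue data: a detection between the limit of detection (LOD) and the limit
of quantification (LOQ) is *counted* as a detection but carries concentration
0 in all concentration arithmetic; a quantified value is one at or above the
LOQ.

Canonical units are fixed at read time: concentrations in ug/kg dry weight,
soil toxicological endpoints (NOEC, LC50) in mg/kg soil, and honey-bee acute
contact LD50 in ng active ingredient per bee. Declared-unit columns in input
files are converted on ingestion so downstream arithmetic never carries
hidden unit factors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

SYSTEMS = ("arable", "vegetable", "viticulture")
MATRICES = ("soil", "vegetation")
DISTANCE_CLASSES = ("in_field", "m1", "m5", "m20")
DETECT_STATUSES = ("not_detected", "below_loq", "quantified")
PCLASSES = ("fungicide", "herbicide", "insecticide")

#: columns identifying one composite sample
SAMPLE_KEY = ["site_id", "matrix", "distance_class", "month_index"]

RECORD_COLUMNS = [
    "site_id",
    "system",
    "matrix",
    "distance_class",
    "month_index",
    "compound_id",
    "concentration_ug_kg",
    "detect_status",
    "loq_ug_kg",
    "lod_ug_kg",
]

COMPOUND_COLUMNS = ["compound_id", "name", "pclass"]

ENDPOINT_COLUMNS = [
    "compound_id",
    "noec_collembola_mg_kg",
    "noec_earthworm_mg_kg",
    "lc50_earthworm_mg_kg",
    "ld50_bee_contact_ng_bee",
    "source",
]


class SchemaError(ValueError):
    """A required column is missing from an input file."""


class ValidationError(ValueError):
    """One or more rows violate the table invariants.

    The message lists row-level diagnostics (row index and the broken rule).
    """

    def __init__(self, problems: Sequence[str]):
        self.problems = list(problems)
        super().__init__(
            f"{len(self.problems)} validation problem(s):\n"
            + "\n".join(self.problems[:20])
            + ("\n..." if len(self.problems) > 20 else "")
        )


@dataclass(frozen=True)
class ResidueTable:
    """A validated residue campaign: measurement records plus compound roster.

    ``records`` holds one row per measurement in :data:`RECORD_COLUMNS` order;
    ``compounds`` maps every ``compound_id`` to a pesticide class
    (fungicide / herbicide / insecticide).
    """

    records: pd.DataFrame
    compounds: pd.DataFrame

    def __post_init__(self) -> None:
        validate_compounds(self.compounds)
        validate_records(self.records, set(self.compounds["compound_id"]))

    @property
    def n_samples(self) -> int:
        return len(self.records[SAMPLE_KEY].drop_duplicates())

    def subset(self, **conditions) -> "ResidueTable":
        """Restrict records by equality on any record column, e.g. matrix='soil'."""
        mask = pd.Series(True, index=self.records.index)
        for col, val in conditions.items():
            if col not in self.records.columns:
                raise KeyError(f"unknown record column {col!r}")
            mask &= self.records[col] == val
        return ResidueTable(self.records[mask].reset_index(drop=True), self.compounds)

    def pclass_of(self) -> Mapping[str, str]:
        return dict(zip(self.compounds["compound_id"], self.compounds["pclass"]))


@dataclass(frozen=True)
class EndpointTable:
    """Per-compound toxicological endpoints in canonical units.

    Soil endpoints (collembola NOEC, earthworm NOEC/LC50) in mg/kg soil;
    honey-bee acute contact LD50 in ng a.i. per bee. An absent endpoint is
    NaN, never 0 — a compound without an endpoint is excluded from mixture
    sums (reducing coverage), not treated as harmless.
    """

    data: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=ENDPOINT_COLUMNS))

    def __post_init__(self) -> None:
        problems = []
        df = self.data
        missing = [c for c in ENDPOINT_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"endpoint table missing columns: {missing}")
        if df["compound_id"].duplicated().any():
            dups = df.loc[df["compound_id"].duplicated(), "compound_id"].tolist()
            problems.append(f"duplicate compound_id entries: {dups}")
        for col in ENDPOINT_COLUMNS[1:-1]:
            bad = df.index[df[col].notna() & (df[col] <= 0)]
            problems.extend(f"row {i}: non-positive {col}" for i in bad)
        if problems:
            raise ValidationError(problems)

    def __len__(self) -> int:
        return len(self.data)

    def get(self, compound_id: str) -> pd.Series | None:
        hit = self.data[self.data["compound_id"] == compound_id]
        return None if hit.empty else hit.iloc[0]


def validate_compounds(compounds: pd.DataFrame) -> None:
    missing = [c for c in COMPOUND_COLUMNS if c not in compounds.columns]
    if missing:
        raise SchemaError(f"compound table missing columns: {missing}")
    problems = []
    if compounds["compound_id"].duplicated().any():
        dups = compounds.loc[compounds["compound_id"].duplicated(), "compound_id"]
        problems.append(f"duplicate compound_id: {sorted(set(dups))}")
    bad = compounds.index[~compounds["pclass"].isin(PCLASSES)]
    problems.extend(
        f"row {i}: pclass {compounds.at[i, 'pclass']!r} not in {PCLASSES}" for i in bad
    )
    if problems:
        raise ValidationError(problems)


def validate_records(records: pd.DataFrame, known_compounds: set[str]) -> None:
    """Enforce the residue-record invariants, reporting row-level diagnostics."""
    missing = [c for c in RECORD_COLUMNS if c not in records.columns]
    if missing:
        raise SchemaError(f"residue table missing columns: {missing}")
    problems: list[str] = []

    def flag(mask: pd.Series, rule: str) -> None:
        problems.extend(f"row {i}: {rule}" for i in records.index[mask])

    flag(~records["system"].isin(SYSTEMS), "unknown system")
    flag(~records["matrix"].isin(MATRICES), "unknown matrix")
    flag(~records["distance_class"].isin(DISTANCE_CLASSES), "unknown distance_class")
    flag(~records["detect_status"].isin(DETECT_STATUSES), "unknown detect_status")
    flag(~records["compound_id"].isin(known_compounds), "compound_id not in compound table")
    flag(records["concentration_ug_kg"] < 0, "negative concentration")
    flag(records["loq_ug_kg"] <= 0, "non-positive LOQ")
    flag(records["lod_ug_kg"] <= 0, "non-positive LOD")
    flag(records["lod_ug_kg"] > records["loq_ug_kg"], "LOD exceeds LOQ")

    quant = records["detect_status"] == "quantified"
    flag(quant & (records["concentration_ug_kg"] < records["loq_ug_kg"]),
         "quantified but concentration < LOQ")
    flag(~quant & (records["concentration_ug_kg"] != 0),
         "non-quantified record carries a non-zero concentration")

    key = RECORD_COLUMNS[:6]
    dup = records.duplicated(subset=key, keep=False) & records.duplicated(subset=key)
    flag(dup, "duplicate (site, matrix, distance, month, compound) key")

    if problems:
        raise ValidationError(problems)


def _apply_schema(df: pd.DataFrame, schema: Mapping[str, str] | None) -> pd.DataFrame:
    """Rename external column names to the canonical ones.

    ``schema`` maps canonical name -> column name in the file, so a foreign
    deposit can be ingested without editing the file itself.
    """
    if schema:
        df = df.rename(columns={v: k for k, v in schema.items()})
    return df


def read_compound_table(path: str | Path, schema: Mapping[str, str] | None = None) -> pd.DataFrame:
    df = _apply_schema(pd.read_csv(path, dtype={"compound_id": str}), schema)
    if "name" not in df.columns and "compound_id" in df.columns:
        df = df.assign(name=df["compound_id"])
    validate_compounds(df)
    return df[COMPOUND_COLUMNS].reset_index(drop=True)


def read_residue_table(
    path: str | Path,
    compounds: pd.DataFrame | str | Path,
    schema: Mapping[str, str] | None = None,
) -> ResidueTable:
    """Read and validate a long-format residue CSV.

    Parameters
    ----------
    path
        CSV with the columns of :data:`RECORD_COLUMNS` (after ``schema``
        renaming).
    compounds
        Compound roster DataFrame, or path to its CSV.
    schema
        Optional mapping canonical column -> file column, for ingesting
        deposits with different headers.
    """
    if isinstance(compounds, (str, Path)):
        compounds = read_compound_table(compounds)
    df = _apply_schema(pd.read_csv(path, dtype={"compound_id": str, "site_id": str}), schema)
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"residue file {path} missing columns: {missing}")
    df = df[RECORD_COLUMNS].copy()
    df["month_index"] = df["month_index"].astype(int)
    for col in ("concentration_ug_kg", "loq_ug_kg", "lod_ug_kg"):
        df[col] = df[col].astype(float)
    return ResidueTable(df.reset_index(drop=True), compounds)


def write_residue_table(table: ResidueTable, records_path: str | Path,
                        compounds_path: str | Path | None = None) -> None:
    """Write the canonical CSV dialect (UTF-8, comma-separated, header row)."""
    table.records[RECORD_COLUMNS].to_csv(records_path, index=False)
    if compounds_path is not None:
        table.compounds[COMPOUND_COLUMNS].to_csv(compounds_path, index=False)


_LD50_UNIT_FACTORS = {
    "ng/bee": 1.0,
    "ng_per_bee": 1.0,
    "ug/bee": 1000.0,
    "ug_per_bee": 1000.0,
    "µg/bee": 1000.0,
}


def read_endpoint_table(path: str | Path, schema: Mapping[str, str] | None = None) -> EndpointTable:
    """Read per-compound endpoints, converting declared units to canonical ones.

    A ``ld50_unit`` column (values like ``ng/bee`` or ``ug/bee``) is honoured:
    LD50 values declared in ug/bee are stored as value x 1000 ng/bee. An empty
    file yields an empty table (downstream coverage 0).
    """
    try:
        df = pd.read_csv(path, dtype={"compound_id": str})
    except pd.errors.EmptyDataError:
        return EndpointTable()
    df = _apply_schema(df, schema)
    if df.empty:
        return EndpointTable()
    if "ld50_unit" in df.columns and "ld50_bee_contact_ng_bee" in df.columns:
        unit = df["ld50_unit"].fillna("ng/bee").str.strip().str.lower()
        unknown = sorted(set(unit) - set(_LD50_UNIT_FACTORS))
        if unknown:
            raise ValidationError([f"unknown LD50 unit(s): {unknown}"])
        df["ld50_bee_contact_ng_bee"] = df["ld50_bee_contact_ng_bee"] * unit.map(
            _LD50_UNIT_FACTORS
        )
        df = df.drop(columns=["ld50_unit"])
    if "source" not in df.columns:
        df["source"] = ""
    for col in ENDPOINT_COLUMNS[1:-1]:
        if col not in df.columns:
            df[col] = np.nan
        df[col] = df[col].astype(float)
    return EndpointTable(df[ENDPOINT_COLUMNS].reset_index(drop=True))


def write_endpoint_table(table: EndpointTable, path: str | Path) -> None:
    table.data[ENDPOINT_COLUMNS].to_csv(path, index=False)
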