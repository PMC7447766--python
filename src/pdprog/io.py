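"""Cohort CSV round-tripping with schema validation.

One header row, columns in canonical order, missing cells written as
empty fields.  Violations are reported with the offending row/column.
"""

from __future__ import annotations

import os

import pandas as pd

from .cohort import COLUMNS, TEST_COLUMNS

_INT_COLUMNS = ["site", "sex", "apoe4", "gba", "mapt_h1", "status"]
_FLOAT_COLUMNS = [
    "education_years",
    "onset_age_years",
    "visit_time_years",
    "age_years",
    "disease_duration_years",
    "ledd_mg",
    "gds15",
] + TEST_COLUMNS


class SchemaError(ValueError):
    pass


def validate_cohort(table: pd.DataFrame) -> pd.DataFrame:
    unknown = [c for c in table.columns if c not in COLUMNS]
    if unknown:
        raise SchemaError(f"unknown columns: {unknown}")
    missing = [c for c in COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"missing columns: {missing}")
    table = table[COLUMNS]
    status = table["status"]
    if status.isna().any():
        row = int(status.index[status.isna()][0])
        raise SchemaError(f"missing status at row {row}")
    bad = ~status.isin([0, 1, 2])
    if bad.any():
        row = int(status.index[bad][0])
        raise SchemaError(f"status value {status[bad].iloc[0]!r} at row {row} is not in {{0,1,2}}")
    dup = table.duplicated(subset=["subject_id", "visit_time_years"])
    if dup.any():
        row = int(table.index[dup][0])
        raise SchemaError(f"duplicate (subject_id, visit_time_years) at row {row}")
    return table


def read_cohort(path) -> pd.DataFrame:
    """Read a cohort CSV, validating the schema; empty fields become NaN."""
    if os.path.getsize(path) == 0:
        raise SchemaError(f"{path} is empty")
    table = pd.read_csv(path, dtype={"subject_id": str})
    if table.empty:
        raise SchemaError(f"{path} has a header but no rows")
    table = validate_cohort(table)
    for c in _INT_COLUMNS:
        table[c] = table[c].astype(int)
    for c in _FLOAT_COLUMNS:
        table[c] = table[c].astype(float)
    return table


def write_cohort(table: pd.DataFrame, path) -> None:
    validate_cohort(table).to_csv(path, index=False, na_rep="")
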