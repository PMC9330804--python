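"""Dataset I/O: long-format CSV tables with schema checks and lossless round trips."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

__all__ = ["read_dataset", "write_dataset", "read_nonmem_dataset", "SchemaError"]

#: columns of the long-format (NONMEM-flavored) observation table
OBSERVATION_SCHEMA = ["ID", "OCC", "TAD", "TIME", "DOSE", "DV_TRUE", "DV",
                      "WT", "FFM", "HT", "AGE", "SEX", "HIV", "RACE", "BMI"]
RICH_SCHEMA = ["ID", "OCC", "TAD", "TIME", "DOSE", "DV_TRUE", "DV"]
SUBJECT_SCHEMA = ["ID", "WT", "FFM", "HT", "AGE", "SEX", "HIV", "RACE",
                  "BMI", "DOSEGRP", "DOSE"]
AUC_SCHEMA = ["ID", "OCC", "AUC0_24"]

#: minimal columns an externally supplied realization must map onto
EXTERNAL_MINIMAL = ["ID", "OCC", "TAD", "DOSE", "DV"]


class SchemaError(ValueError):
    pass


def write_dataset(table: pd.DataFrame, path) -> Path:
    """Write a table as CSV at full float precision (shortest round-trip repr)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False)
    return path


def read_dataset(path, schema: list[str] | None = None) -> pd.DataFrame:
    """Read a CSV table, optionally enforcing an exact column schema.

    Malformed numeric cells are reported with row/column coordinates.
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"dataset not found: {path}")
    table = pd.read_csv(path)
    if schema is not None:
        missing = [c for c in schema if c not in table.columns]
        extra = [c for c in table.columns if c not in schema]
        if missing or extra:
            raise SchemaError(
                f"{path.name}: column mismatch (missing={missing}, extra={extra})")
        table = table[list(schema)]
    for col in table.columns:
        if table[col].dtype == object:
            coerced = pd.to_numeric(table[col], errors="coerce")
            bad = table.index[coerced.isna() & table[col].notna()]
            n_values = int(table[col].notna().sum())
            if len(bad) == n_values:
                continue  # genuinely non-numeric column (labels etc.)
            if len(bad):
                raise SchemaError(
                    f"{path.name}: malformed numeric cell at row {bad[0] + 2} "
                    f"(1-based incl. header), column {col!r}: "
                    f"{table.loc[bad[0], col]!r}")
            table[col] = coerced
    return table


def read_nonmem_dataset(path, column_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Ingest an externally supplied long-format realization.

    ``column_map`` maps external column names onto the internal ones; after
    mapping, at least ID, OCC, TAD, DOSE and DV must be present. Extra
    covariate columns are kept as-is.
    """
    table = pd.read_csv(Path(path))
    if column_map:
        table = table.rename(columns=dict(column_map))
    missing = [c for c in EXTERNAL_MINIMAL if c not in table.columns]
    if missing:
        raise SchemaError(
            f"external dataset lacks required columns after mapping: {missing}")
    return table
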