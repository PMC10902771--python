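"""Measurement-table I/O and validation.

A measurement table is a long-format pandas DataFrame with columns
``subject_id, rater_id, method, repeat, hc_cm`` — one row per measurement of
one subject by one rater with one method. All agreement statistics consume
this schema; CSVs written by the simulator and by hand must round-trip
through it unchanged.
"""
from __future__ import annotations

from pathlib import Path

import pandas as pd

from .errors import TableSchemaError

REQUIRED_COLUMNS = ["subject_id", "rater_id", "method", "repeat", "hc_cm"]
KEY_COLUMNS = ["subject_id", "rater_id", "method", "repeat"]


def validate_measurement_table(df: pd.DataFrame) -> pd.DataFrame:
    """Check schema, key uniqueness and positivity; return the frame.

    Error messages carry 1-based data row numbers (header excluded) so a
    malformed CSV line can be found by eye.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise TableSchemaError(f"missing required columns: {missing}")
    if len(df) == 0:
        raise TableSchemaError("measurement table is empty")
    hc = pd.to_numeric(df["hc_cm"], errors="coerce")
    bad = df.index[hc.isna() | (hc <= 0)].tolist()
    if bad:
        rows = [i + 1 for i in bad[:10]]
        raise TableSchemaError(
            f"hc_cm must be a positive number; offending data rows: {rows}")
    rep = pd.to_numeric(df["repeat"], errors="coerce")
    bad = df.index[rep.isna() | (rep != rep.round())].tolist()
    if bad:
        rows = [i + 1 for i in bad[:10]]
        raise TableSchemaError(f"repeat must be an integer; offending data rows: {rows}")
    dup = df.duplicated(subset=KEY_COLUMNS, keep=False)
    if dup.any():
        keys = df.loc[dup, KEY_COLUMNS].drop_duplicates().head(5)
        raise TableSchemaError(
            "duplicated (subject_id, rater_id, method, repeat) keys: "
            + "; ".join(str(tuple(r)) for r in keys.itertuples(index=False)))
    out = df.copy()
    out["hc_cm"] = hc.astype(float)
    out["repeat"] = rep.astype(int)
    return out


def read_measurement_table(path) -> pd.DataFrame:
    """Read and validate a measurement CSV (UTF-8, comma-separated)."""
    df = pd.read_csv(Path(path), dtype={"subject_id": str, "rater_id": str,
                                        "method": str})
    return validate_measurement_table(df)


def write_measurement_table(df: pd.DataFrame, path) -> Path:
    """Validate and write a measurement table CSV."""
    validate_measurement_table(df)
    path = Path(path)
    df.to_csv(path, index=False)
    return path
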