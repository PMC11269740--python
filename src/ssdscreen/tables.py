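"""Readers and writers for the pipeline's tab-separated tables.

Schemas
-------
counts      wide matrix: first column ``family``, one integer column per species
traits      columns ``species``, ``male_mass``, ``female_mass``; optional ``brain_mass``
go_map      columns ``gene``, ``term``
membership  columns ``gene``, ``family``
expression  columns ``gene``, ``tissue``, ``stage``, ``sex``, ``value``; optional
            ``stage_index``, ``phase``

All readers validate and refuse to coerce: a negative count or a non-numeric
mass is an error that names the offending row, not a silent NaN.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SchemaError, ValidationError
from .trees import normalize_species_name

logger = logging.getLogger(__name__)

SCHEMAS = ("counts", "traits", "go_map", "membership", "expression")

_REQUIRED = {
    "traits": ["species", "male_mass", "female_mass"],
    "go_map": ["gene", "term"],
    "membership": ["gene", "family"],
    "expression": ["gene", "tissue", "stage", "sex", "value"],
}


def _require_columns(df: pd.DataFrame, required: list[str], path: Path, schema: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path}: schema '{schema}' requires columns {required}; "
            f"found {list(df.columns)}; missing {missing}"
        )


def _read_counts(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2 or df.columns[0] != "family":
        raise SchemaError(
            f"{path}: counts schema requires a leading 'family' column followed by "
            f"one column per species; found columns {list(df.columns)}"
        )
    df = df.set_index("family")
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValidationError(f"{path}: duplicate family identifiers {dupes[:5]}")
    out = {}
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals != np.floor(vals))
        if bad.any():
            row = int(np.argmax(bad.to_numpy())) + 2  # +1 header, +1 one-based
        else:
            row = None
        if row is not None:
            raise ValidationError(
                f"{path}: non-integer count in column '{col}' at line {row}"
            )
        if (vals < 0).any():
            row = int(np.argmax((vals < 0).to_numpy())) + 2
            raise ValidationError(
                f"{path}: negative count in column '{col}' at line {row}"
            )
        out[normalize_species_name(col)] = vals.astype(np.int64)
    res = pd.DataFrame(out, index=df.index)
    logger.info("read counts %s: %d families x %d species", path, *res.shape)
    return res


def _read_traits(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, _REQUIRED["traits"], path, "traits")
    df["species"] = df["species"].map(normalize_species_name)
    if df["species"].duplicated().any():
        raise ValidationError(f"{path}: duplicate species rows")
    numeric_cols = [c for c in df.columns if c != "species"]
    for col in numeric_cols:
        vals = pd.to_numeric(df[col], errors="coerce")
        missing_ok = col not in ("male_mass", "female_mass")
        bad = vals.isna() & df[col].notna() if missing_ok else vals.isna()
        if bad.any():
            row = int(np.argmax(bad.to_numpy())) + 2
            raise ValidationError(f"{path}: non-numeric value in '{col}' at line {row}")
        df[col] = vals
    for col in ("male_mass", "female_mass"):
        if (df[col] <= 0).any():
            row = int(np.argmax((df[col] <= 0).to_numpy())) + 2
            raise ValidationError(f"{path}: nonpositive mass in '{col}' at line {row}")
    logger.info("read traits %s: %d species", path, len(df))
    return df


def _read_pair(path: Path, schema: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, _REQUIRED[schema], path, schema)
    if df[_REQUIRED[schema]].isna().any().any():
        raise ValidationError(f"{path}: empty cells in required columns")
    logger.info("read %s %s: %d rows", schema, path, len(df))
    return df


def _read_expression(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, _REQUIRED["expression"], path, "expression")
    vals = pd.to_numeric(df["value"], errors="coerce")
    if vals.isna().any():
        row = int(np.argmax(vals.isna().to_numpy())) + 2
        raise ValidationError(f"{path}: non-numeric expression value at line {row}")
    if (vals < 0).any():
        row = int(np.argmax((vals < 0).to_numpy())) + 2
        raise ValidationError(f"{path}: negative expression value at line {row}")
    df["value"] = vals
    if "stage_index" in df.columns:
        df["stage_index"] = pd.to_numeric(df["stage_index"], errors="raise")
    logger.info("read expression %s: %d rows, %d genes, %d tissues",
                path, len(df), df["gene"].nunique(), df["tissue"].nunique())
    return df


def read_table(path: str | Path, schema: str) -> pd.DataFrame:
    """Read a TSV into a validated, typed DataFrame.

    Parameters
    ----------
    path : path
        Tab-separated file with a header row.
    schema : {"counts", "traits", "go_map", "membership", "expression"}
        Which layout to expect and validate against.
    """
    if schema not in SCHEMAS:
        raise SchemaError(f"unknown schema {schema!r}; expected one of {SCHEMAS}")
    path = Path(path)
    if schema == "counts":
        return _read_counts(path)
    if schema == "traits":
        return _read_traits(path)
    if schema == "expression":
        return _read_expression(path)
    return _read_pair(path, schema)


def write_results(table: pd.DataFrame, path: str | Path) -> None:
    """Write a result table as TSV: stable column order, floats at 6 significant digits.

    Refuses to write an empty table (an empty result upstream should be handled
    there, not discovered later as a headerless file).
    """
    if table is None or len(table) == 0:
        raise ValidationError(f"refusing to write empty result table to {path}")
    df = table.reset_index() if table.index.name is not None else table
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    logger.info("wrote %s: %d rows x %d columns", path, *df.shape)
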