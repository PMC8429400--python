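"""Typed table IO with schema validation and provenance sidecars."""

from __future__ import annotations

import csv
import json
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from . import __version__

__all__ = ["SCHEMAS", "SchemaError", "read_table", "write_table"]


class SchemaError(ValueError):
    """Input table does not match its declared schema."""


#: column -> required dtype kind ('f' numeric, 's' string) per schema
SCHEMAS: dict[str, dict[str, str]] = {
    "calibration": {"ph": "f", "ratio": "f"},
    "cells": {"cell_id": "s", "ratio": "f", "expression_au": "f", "group": "s"},
    "timecourse": {"time_min": "f"},  # plus 'ratio' or 'ph', checked below
    "lectin": {
        "condition": "s",
        "replicate_id": "s",
        "lectin": "s",
        "spot_index": "f",
        "intensity": "f",
    },
    "trajectory": {
        "time_min": "f",
        "ph": "f",
        "cl_mm": "f",
        "hco3_mm": "f",
        "co2_mm": "f",
    },
}


def _sniff_delimiter(sample: str) -> str:
    try:
        return csv.Sniffer().sniff(sample, delimiters=",\t").delimiter
    except csv.Error:
        return "\t" if "\t" in sample.splitlines()[0] else ","


def read_table(path, schema: str) -> pd.DataFrame:
    """Read a CSV/TSV into a schema-validated frame.

    Header matching is case-insensitive; the delimiter is auto-detected
    among comma and tab; CRLF and LF parse identically.  Missing columns
    raise :class:`SchemaError` naming them; malformed numerics raise with
    the 1-based data line number.
    """
    if schema not in SCHEMAS:
        raise KeyError(f"unknown schema {schema!r}; known: {sorted(SCHEMAS)}")
    path = Path(path)
    text = path.read_text()
    delim = _sniff_delimiter(text[:4096])
    df = pd.read_csv(path, sep=delim, dtype=str, skipinitialspace=True)
    df.columns = [c.strip().lower() for c in df.columns]

    spec = dict(SCHEMAS[schema])
    if schema == "timecourse":
        if "ph" in df.columns:
            spec["ph"] = "f"
        elif "ratio" in df.columns:
            spec["ratio"] = "f"
        else:
            raise SchemaError("timecourse table needs a 'ratio' or 'ph' column")

    missing = [c for c in spec if c not in df.columns]
    if missing:
        raise SchemaError(f"missing column(s) {missing} in {path.name}")

    for col, kind in spec.items():
        if kind == "f":
            converted = pd.to_numeric(df[col], errors="coerce")
            bad = converted.isna() & df[col].notna()
            if bad.any():
                line = int(bad.idxmax()) + 2  # +1 header, +1 one-based
                raise SchemaError(
                    f"malformed numeric in column {col!r} at line {line} of {path.name}: "
                    f"{df.loc[bad.idxmax(), col]!r}"
                )
            df[col] = converted
        else:
            df[col] = df[col].astype(str)
    return df[[c for c in spec] + [c for c in df.columns if c not in spec]]


def write_table(df: pd.DataFrame, path, schema: str | None = None, metadata: dict | None = None) -> Path:
    """Write a frame as CSV/TSV (by extension) plus a JSON metadata sidecar.

    Column order is deterministic: schema columns first when a schema is
    given.  The sidecar ``<path>.meta.json`` records version, timestamp and
    any caller-supplied metadata (seed, parameters, ...).
    """
    path = Path(path)
    if schema is not None:
        if schema not in SCHEMAS:
            raise KeyError(f"unknown schema {schema!r}")
        by_lower = {c.lower(): c for c in df.columns}
        cols = [by_lower[c] for c in SCHEMAS[schema] if c in by_lower]
        cols += [c for c in df.columns if c not in cols]
        df = df[cols]
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep=sep, index=False)
    sidecar = path.with_name(path.name + ".meta.json")
    meta = {
        "version": __version__,
        "written": datetime.now(timezone.utc).isoformat(timespec="seconds"),
        "schema": schema,
        "rows": int(len(df)),
    }
    meta.update(metadata or {})
    sidecar.write_text(json.dumps(meta, indent=2, sort_keys=True, default=str) + "\n")
    return path
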