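"""CSV / JSON table input-output.

CSV dialect is fixed: comma separator, UTF-8, ``.`` decimal, header row
required.  Floats are written with pandas' shortest round-trip repr, so a
write/read cycle reproduces the in-memory values exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .datatypes import (REQUIRED_COLUMNS, Cohort, PhantomScan, feature_columns,
                        phantom_frame, phantom_records)
from .errors import SchemaError


def read_cohort(path: str | Path, stage: str = "original") -> Cohort:
    """Read and validate a participant table.

    Categorical labels are normalized case-insensitively (``hc``/``Pd`` ->
    ``HC``/``PD``; ``m``/``f`` -> ``M``/``F``).  Row order is preserved.
    Raises :class:`SchemaError` for missing columns and
    :class:`ValidationError` for invariant violations (duplicate ids,
    non-positive original SBRs, under-age participants...).
    """
    df = pd.read_csv(path, dtype={"id": str, "site": str, "scanner": str},
                     float_precision="round_trip")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"cohort CSV {path} is missing required column(s) {missing}")
    df["diagnosis"] = df["diagnosis"].astype(str).str.strip().str.upper()
    df["sex"] = df["sex"].astype(str).str.strip().str.upper()
    df["age"] = pd.to_numeric(df["age"], errors="raise")
    for c in feature_columns(df):
        df[c] = pd.to_numeric(df[c], errors="raise")
    return Cohort(df, stage=stage)


def _roundtrip_repr(x: float) -> str:
    # shortest decimal repr that parses back to the same float64
    return repr(float(x))


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort as CSV with the canonical column order.

    Floats use the shortest exact round-trip representation.
    """
    feats = feature_columns(cohort.data)
    cols = list(REQUIRED_COLUMNS) + feats
    cohort.data[cols].to_csv(path, index=False, float_format=_roundtrip_repr)


def read_phantom(path: str | Path) -> list[PhantomScan]:
    """Read phantom scans from CSV (columns scanner,true_ratio,measured_sbr)."""
    return phantom_records(pd.read_csv(path, dtype={"scanner": str},
                                       float_precision="round_trip"))


def write_phantom(scans: list[PhantomScan], path: str | Path) -> None:
    phantom_frame(scans).to_csv(path, index=False, float_format=_roundtrip_repr)


def write_report(report, path: str | Path) -> None:
    """Serialize an evaluation report (or any mapping) as JSON.

    Key order is the report's own construction order (stable across runs);
    floats use Python's repr, which round-trips float64 exactly.
    """
    payload = report.to_dict() if hasattr(report, "to_dict") else report
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")


def read_report(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
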