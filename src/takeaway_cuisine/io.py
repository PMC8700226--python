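"""Readers and writers for outlet data.

Two input formats: the standard outlet CSV
(``name,label1,label2,label3[,area_code]``) and locally saved FHRS-style
JSON (food-hygiene register records with ``BusinessName`` and
``LocalAuthorityCode`` fields, no cuisine labels).  Classified output is
CSV with ``name,area_code,cuisine,confidence``; the confidence column is
blank for rule-derived labels and round-trips through the reader.
"""

from __future__ import annotations

import json
from typing import Optional, Sequence, Union

import pandas as pd

from .charlm import Prediction
from .records import OutletRecord

__all__ = ["read_outlets", "write_classified", "read_classified", "read_population_csv"]


def read_outlets(path, format: str = "csv") -> list[OutletRecord]:
    """Read outlet records from ``path``.

    ``format="csv"`` expects a header with a ``name`` column and optional
    ``label1..label3`` / ``area_code`` columns; ``format="fhrs_json"``
    expects a JSON array of records (or an object with an
    ``establishments`` array) carrying ``BusinessName`` and optionally
    ``LocalAuthorityCode``.
    """
    if format == "csv":
        return _read_csv(path)
    if format == "fhrs_json":
        return _read_fhrs(path)
    raise ValueError(f"unknown outlet format {format!r}")


def _read_csv(path) -> list[OutletRecord]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if df.empty and df.columns.empty:
        raise ValueError(f"{path}: empty file")
    if "name" not in df.columns:
        raise ValueError(f"{path}: missing required 'name' column")
    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        name = getattr(row, "name", "")
        if not str(name).strip():
            raise ValueError(f"{path}: row {i + 2} has an empty name")
        labels = tuple(
            str(getattr(row, col)).strip()
            for col in ("label1", "label2", "label3")
            if col in df.columns and str(getattr(row, col)).strip()
        )
        area = str(getattr(row, "area_code")).strip() if "area_code" in df.columns else ""
        records.append(
            OutletRecord(name=str(name), labels=labels,
                         area_code=area or None, record_id=f"r{i:06d}")
        )
    return records


def _read_fhrs(path) -> list[OutletRecord]:
    with open(path, encoding="utf-8") as fh:
        data = json.load(fh)
    if isinstance(data, dict):
        data = data.get("establishments", data.get("Establishments"))
        if data is None:
            raise ValueError(f"{path}: no 'establishments' array in FHRS JSON")
    records = []
    for i, entry in enumerate(data):
        name = entry.get("BusinessName")
        if not name or not str(name).strip():
            raise ValueError(f"{path}: record {i} has no BusinessName")
        area = entry.get("LocalAuthorityCode")
        records.append(
            OutletRecord(name=str(name), labels=(),
                         area_code=str(area) if area is not None else None,
                         record_id=f"r{i:06d}")
        )
    if not records:
        raise ValueError(f"{path}: no records")
    return records


def write_classified(
    results: Sequence[tuple[OutletRecord, Union[Prediction, str]]], path
) -> None:
    """Write classified outlets as CSV.

    Model predictions carry their confidence; rule-derived class strings
    leave the confidence column blank.
    """
    rows = []
    for record, outcome in results:
        if isinstance(outcome, Prediction):
            cuisine, confidence = outcome.cuisine, f"{outcome.confidence:.6f}"
        else:
            cuisine, confidence = str(outcome), ""
        rows.append(
            {
                "name": record.name,
                "area_code": record.area_code or "",
                "cuisine": cuisine,
                "confidence": confidence,
            }
        )
    pd.DataFrame(rows, columns=["name", "area_code", "cuisine", "confidence"]).to_csv(
        path, index=False
    )


def read_classified(path) -> list[tuple[OutletRecord, str, Optional[float]]]:
    """Read a classified CSV back: (record, cuisine, confidence|None)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in ("name", "cuisine"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required {col!r} column")
    out = []
    for i, row in df.iterrows():
        area = str(row.get("area_code", "")).strip()
        conf = str(row.get("confidence", "")).strip()
        out.append(
            (
                OutletRecord(name=row["name"], area_code=area or None,
                             record_id=f"r{i:06d}"),
                row["cuisine"],
                float(conf) if conf else None,
            )
        )
    return out


def read_population_csv(path) -> dict[str, int]:
    """Read an area population table: columns ``area_code,population``."""
    df = pd.read_csv(path, dtype={"area_code": str})
    for col in ("area_code", "population"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required {col!r} column")
    return {str(r.area_code): int(r.population) for r in df.itertuples(index=False)}
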