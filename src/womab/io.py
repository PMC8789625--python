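"""Cohort CSV input/output with schema validation, and model serialization.

The cohort schema is the one emitted by the trial scorer: one row per
participant with ``participant_id, age, education, sex`` and the ten raw
outcome columns.  Reading validates rows individually — violations are
collected into a reject report while valid rows are retained.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .battery import OUTCOME_COLUMNS
from .pipeline import NormativeModel, NormativeReport
from .published import _RAW_MAX, normalize_sex

__all__ = ["CohortTable", "read_cohort", "write_cohort",
           "serialize_report", "deserialize_report"]

_META_COLUMNS = ("participant_id", "age", "education", "sex")
_ALL_COLUMNS = (*_META_COLUMNS, *OUTCOME_COLUMNS)


@dataclass
class CohortTable:
    """Validated cohort rows plus the rows rejected at ingest."""

    data: pd.DataFrame
    rejects: pd.DataFrame = field(default_factory=pd.DataFrame)
    provenance: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.data)


def _validate_row(row: pd.Series) -> str | None:
    """Reason the row is invalid, or None."""
    try:
        age = float(row["age"])
        edu = float(row["education"])
    except (TypeError, ValueError):
        return "non-numeric age or education"
    if not (age > 0 and age == int(age)):
        return "age must be a positive integer"
    if age >= 100:
        return "transform domain: age must be below 100 (ln(100 - age))"
    if not (edu >= 1 and edu == int(edu)):
        return "transform domain: education must be an integer >= 1 (uses 1/education)"
    try:
        normalize_sex(row["sex"])
    except ValueError:
        return f"sex must be m/f, got {row['sex']!r}"
    for oid, hi in _RAW_MAX.items():
        v = row.get(oid)
        if v is None or pd.isna(v):
            continue
        try:
            v = float(v)
        except (TypeError, ValueError):
            return f"{oid}: non-numeric value {row[oid]!r}"
        if not 0 <= v <= hi:
            return f"{oid}: value {v:g} outside theoretical range 0-{hi}"
    for oid in ("DSR_T", "DSR_WMS"):
        v = row.get(oid)
        if v is not None and not pd.isna(v) and float(v) < 0:
            return f"{oid}: ratio cannot be negative"
    return None


def read_cohort(path, decimal: str = ".") -> CohortTable:
    """Read and validate a cohort CSV.

    Headers are matched case-insensitively; mandatory columns are
    ``participant_id, age, education, sex``.  Invalid rows are moved to the
    reject report with a reason; ages outside the study's stated inclusion
    range 20-90 draw a warning but are retained.
    """
    df = pd.read_csv(path, decimal=decimal)
    if df.empty and df.columns.empty:
        raise ValueError(f"{path}: empty file")
    canon = {c.lower(): c for c in _ALL_COLUMNS}
    df = df.rename(columns=lambda c: canon.get(str(c).strip().lower(), c))
    missing = set(_META_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing mandatory columns {sorted(missing)}")
    if df["participant_id"].duplicated().any():
        dups = df.loc[df["participant_id"].duplicated(), "participant_id"].tolist()
        raise ValueError(f"{path}: duplicate participant ids {dups}")

    reasons = df.apply(_validate_row, axis=1)
    bad = reasons.notna()
    rejects = df[bad].copy()
    if bad.any():
        rejects["reject_reason"] = reasons[bad]
    data = df[~bad].reset_index(drop=True)
    if not data.empty:
        outside = (data["age"].astype(float) < 20) | (data["age"].astype(float) > 90)
        if outside.any():
            warnings.warn(
                f"{int(outside.sum())} participant(s) outside the stated inclusion "
                "age range 20-90 (retained)", stacklevel=2)
    data = data.reindex(columns=[c for c in _ALL_COLUMNS if c in df.columns]
                        + [c for c in df.columns if c not in _ALL_COLUMNS])
    return CohortTable(data=data, rejects=rejects,
                       provenance={"source": str(path), "package_version": __version__})


def write_cohort(table: CohortTable | pd.DataFrame, path) -> None:
    """Write a cohort CSV: deterministic column order, UTF-8, '.' decimals,
    missing values as empty fields."""
    df = table.data if isinstance(table, CohortTable) else table
    ordered = [c for c in _ALL_COLUMNS if c in df.columns] \
        + [c for c in df.columns if c not in _ALL_COLUMNS]
    df[ordered].to_csv(path, index=False, encoding="utf-8", na_rep="")


def serialize_report(report: NormativeReport) -> str:
    """Lossless JSON of a fitted normative report (full-precision floats)."""
    return json.dumps(report.to_dict(), indent=1, allow_nan=True)


def deserialize_report(text: str) -> NormativeReport:
    """Inverse of :func:`serialize_report`; rejects unknown or broken schemas."""
    payload = json.loads(text)
    version = payload.get("schema_version")
    if version != 1:
        raise ValueError(f"unknown normative-report schema version: {version!r}")
    try:
        models = {k: NormativeModel.from_dict(m) for k, m in payload["models"].items()}
    except KeyError as exc:
        raise ValueError(f"malformed normative report: missing field {exc}") from exc
    return NormativeReport(models=models,
                           aes_limits=payload.get("aes_limits", {}),
                           errors=payload.get("errors", {}))
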