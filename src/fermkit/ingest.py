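"""Raw tabular readers and the canonical tidy writer.

Three dialects are supported, each as CSV or XLSX (first sheet, UTF-8,
decimal point):

* **tidy long** — the package's canonical interchange format, header
  ``trial_identifier,analyte_name,time_h,value,unit``, one row per
  observation; missing values as empty cells or ``nan``.
* **HPLC wide** — one row per injection: a ``sample`` column holding a flat
  identifier that embeds ``time:`` (and usually ``rep:``), then one column
  per analyte with the quantified concentration.
* **plate matrix** — first column is time, remaining columns are well labels
  (A1..P24); a separate layout CSV (``well,identifier``) maps wells to trial
  identifiers. The analyte defaults to OD600 unless the layout identifier
  carries an ``analyte:`` key.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError
from .identifiers import (
    IdentifierParseError,
    TrialIdentifier,
    parse_identifier,
    serialize_identifier,
)
from .schema import Experiment, TimePoint

logger = logging.getLogger(__name__)

_WELL_RE = re.compile(r"^[A-P][0-9]{1,2}$")
_TIDY_COLUMNS = ["trial_identifier", "analyte_name", "time_h", "value", "unit"]
_TIME_FACTORS = {"h": 1.0, "min": 1.0 / 60.0, "s": 1.0 / 3600.0}


@dataclass
class ParseSummary:
    """Bookkeeping from one read: rows seen, points produced, cells skipped."""

    rows_read: int = 0
    points: int = 0
    skipped_cells: int = 0
    warnings: list[str] = field(default_factory=list)


@dataclass
class PlateLayout:
    """Well label -> flat identifier string for a plate-reader run."""

    wells: dict[str, str]

    def __post_init__(self):
        for well, ident in self.wells.items():
            if not _WELL_RE.match(well):
                raise FormatError(f"invalid well label {well!r} (expected A1..P24)")
            try:
                parse_identifier(ident)
            except IdentifierParseError as exc:
                raise FormatError(f"layout identifier for well {well}: {exc}") from exc

    @classmethod
    def from_csv(cls, path: str | Path) -> "PlateLayout":
        df = _read_table(path)
        cols = [c.strip().lower() for c in df.columns]
        if cols[:2] != ["well", "identifier"]:
            raise FormatError(f"plate layout {path} must have header 'well,identifier'")
        df.columns = cols + list(df.columns[2:])
        return cls({str(r.well).strip(): str(r.identifier).strip() for r in df.itertuples()})


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix.lower() in {".xlsx", ".xlsm"}:
        return pd.read_excel(path, sheet_name=0)
    # round_trip parser: written floats must re-read bit-identically
    return pd.read_csv(path, float_precision="round_trip")


def _to_value(cell) -> float:
    """Missing-value convention: empty cell or literal 'nan' -> NaN."""
    if cell is None or (isinstance(cell, float) and np.isnan(cell)):
        return float("nan")
    s = str(cell).strip()
    if s == "" or s.lower() == "nan":
        return float("nan")
    return float(s)


def read_tidy_long(path: str | Path, summary: ParseSummary | None = None) -> list[TimePoint]:
    """Read the canonical tidy long format into time points."""
    df = _read_table(path)
    df.columns = [str(c).strip().lower() for c in df.columns]
    for col in _TIDY_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"tidy file {path} is missing required column {col!r}")
    points: list[TimePoint] = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            time_h = float(getattr(row, "time_h"))
        except (TypeError, ValueError) as exc:
            raise FormatError(f"{path}: row {i + 2}: unparseable time {getattr(row, 'time_h')!r}") from exc
        try:
            ident = parse_identifier(str(getattr(row, "trial_identifier")))
        except IdentifierParseError as exc:
            raise FormatError(f"{path}: row {i + 2}: {exc}") from exc
        ident = replace(ident, analyte_name=str(getattr(row, "analyte_name")), sample_time=time_h)
        unit = getattr(row, "unit")
        unit = "" if unit is None or (isinstance(unit, float) and np.isnan(unit)) else str(unit)
        points.append(TimePoint(ident, _to_value(getattr(row, "value")), unit))
    if summary is not None:
        summary.rows_read += len(df)
        summary.points += len(points)
    return points


def read_hplc_wide(path: str | Path, summary: ParseSummary | None = None) -> list[TimePoint]:
    """Read an HPLC-style wide table (one row per injection).

    Each finite (row, analyte column) cell becomes a time point at the
    injection's ``time:`` key; empty cells are skipped. Repeated injections of
    the same sample produce duplicate triples that assembly averages.
    """
    df = _read_table(path)
    df.columns = [str(c).strip() for c in df.columns]
    lower = [c.lower() for c in df.columns]
    if "sample" not in lower:
        raise FormatError(f"HPLC file {path} has no 'sample' column")
    sample_col = df.columns[lower.index("sample")]
    analyte_cols = [c for c in df.columns if c != sample_col]
    if not analyte_cols:
        raise FormatError(f"HPLC file {path} has no analyte columns")

    points: list[TimePoint] = []
    skipped = 0
    for i, row in df.iterrows():
        try:
            ident = parse_identifier(str(row[sample_col]))
        except IdentifierParseError as exc:
            raise FormatError(f"{path}: row {i + 2}: {exc}") from exc
        if ident.sample_time is None:
            raise FormatError(
                f"{path}: row {i + 2}: sample identifier lacks a 'time:' key"
            )
        for col in analyte_cols:
            value = _to_value(row[col])
            if np.isnan(value):
                skipped += 1
                continue
            pid = replace(ident, analyte_name=col)
            points.append(TimePoint(pid, value, ""))
    if summary is not None:
        summary.rows_read += len(df)
        summary.points += len(points)
        summary.skipped_cells += skipped
    return points


def read_plate_matrix(
    path: str | Path,
    layout: PlateLayout,
    time_unit: str = "h",
    summary: ParseSummary | None = None,
) -> list[TimePoint]:
    """Read a plate-reader matrix (time x wells) against a plate layout."""
    if time_unit not in _TIME_FACTORS:
        raise FormatError(f"unknown time unit {time_unit!r}; expected h, min or s")
    factor = _TIME_FACTORS[time_unit]
    df = _read_table(path)
    df.columns = [str(c).strip() for c in df.columns]
    well_cols = list(df.columns[1:])
    points: list[TimePoint] = []
    skipped = 0
    warned: set[str] = set()
    for i, row in df.iterrows():
        try:
            t = float(row.iloc[0]) * factor
        except (TypeError, ValueError) as exc:
            raise FormatError(f"{path}: row {i + 2}: non-numeric time {row.iloc[0]!r}") from exc
        for well in well_cols:
            if well not in layout.wells:
                if well not in warned:
                    logger.warning("well %s present in data but absent from layout; skipped", well)
                    warned.add(well)
                skipped += 1
                continue
            value = _to_value(row[well])
            if np.isnan(value):
                skipped += 1
                continue
            ident = parse_identifier(layout.wells[well])
            analyte = ident.analyte_name or "OD600"
            points.append(TimePoint(replace(ident, analyte_name=analyte, sample_time=t), value, ""))
    if summary is not None:
        summary.rows_read += len(df)
        summary.points += len(points)
        summary.skipped_cells += skipped
        summary.warnings += [f"well {w} absent from layout" for w in sorted(warned)]
    return points


def write_tidy_long(e: Experiment, path: str | Path) -> int:
    """Write every stored time point in canonical tidy long form.

    Rows are ordered lexicographically by (trial identifier, analyte, time);
    missing values are written as ``nan``. Returns the row count.
    """
    rows = []
    for rep in e.replicates:
        for single in rep.singles:
            tkey = serialize_identifier(single.identifier)
            for name in sorted(single.courses):
                course = single.courses[name]
                for t, v in zip(course.times, course.values):
                    rows.append((tkey, name, float(t), float(v), course.unit))
    rows.sort(key=lambda r: (r[0], r[1], r[2]))
    df = pd.DataFrame(rows, columns=_TIDY_COLUMNS)
    path = Path(path)
    if path.suffix.lower() in {".xlsx", ".xlsm"}:
        df.to_excel(path, index=False)
    else:
        df.to_csv(path, index=False, na_rep="nan")
    return len(rows)
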