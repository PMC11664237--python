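"""CSV reading/writing of patient cohorts.

The on-disk format is a flat UTF-8 CSV/TSV with a mandatory header row and
one column per patient field (snake_case; lab and biomarker analytes appear
as top-level columns).  Empty cells mean "unknown".  Booleans accept
{0, 1, yes, no, true, false}, case-insensitively; anything else in a boolean
column is a hard parse error — outcome-bearing columns must never be
guessed.  A config flag lets a D-dimer column declared in ng/mL be ingested
as numerically identical to the native ug/dL scale (the two labels are used
interchangeably for this assay at this numeric scale in the source
literature; see docs/methods.md).
"""

from __future__ import annotations

import csv
import dataclasses
from typing import Iterable, Optional, Sequence

from .cohort import (
    BiomarkerPanel,
    LabPanel,
    PatientRecord,
    validate_record,
    _BIOMARKER_FIELDS,
    _LAB_FIELDS,
)

_BOOL_TOKENS = {
    "0": False, "1": True, "no": False, "yes": True, "false": False, "true": True,
}

_BOOL_COLUMNS = (
    "b_symptoms", "picc", "mediastinal_involvement", "prior_vte", "infection",
    "reduced_mobility", "extranodal", "esa_use", "vte", "event_death",
)
_FLOAT_COLUMNS = ("age_years", "bmi", "vte_time_months", "followup_months")
_STR_COLUMNS = ("id", "sex", "stage")

LAB_COLUMNS = tuple(sorted(_LAB_FIELDS))
BIOMARKER_COLUMNS = tuple(sorted(_BIOMARKER_FIELDS))

#: Canonical column order of the cohort CSV dialect.
COLUMNS: tuple[str, ...] = (
    "id", "age_years", "sex", "bmi", "stage", "ecog",
    *_BOOL_COLUMNS[:-2],
    *LAB_COLUMNS,
    *BIOMARKER_COLUMNS,
    "vte", "vte_time_months", "followup_months", "event_death",
)


class CohortParseError(ValueError):
    """Raised on malformed headers, cells, or invariant-violating rows."""


def _parse_bool(token: str, column: str, line: int) -> bool:
    key = token.strip().lower()
    if key not in _BOOL_TOKENS:
        raise CohortParseError(
            f"line {line}: column {column!r}: {token!r} is not a recognised "
            "boolean (use 0/1/yes/no/true/false)"
        )
    return _BOOL_TOKENS[key]


def _parse_float(token: str, column: str, line: int) -> float:
    try:
        return float(token)
    except ValueError:
        raise CohortParseError(
            f"line {line}: column {column!r}: {token!r} is not a number"
        ) from None


def read_cohort(
    path,
    delimiter: str = ",",
    d_dimer_ng_ml: bool = False,
    strict: bool = True,
) -> list[PatientRecord]:
    """Read and validate a cohort CSV/TSV.

    With ``strict`` (default) any invariant violation aborts with the row
    number; with ``strict=False`` offending rows are dropped.  Setting
    ``d_dimer_ng_ml`` declares the d_dimer column to be labelled ng/mL,
    which is ingested unchanged (numerically identical scale).
    """
    records: list[PatientRecord] = []
    problems: list[str] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        if reader.fieldnames is None:
            raise CohortParseError("empty file: header row is mandatory")
        unknown = set(reader.fieldnames) - set(COLUMNS)
        if unknown:
            raise CohortParseError(f"unknown columns in header: {sorted(unknown)}")
        for line_no, row in enumerate(reader, start=2):
            rec = _record_from_row(row, line_no)
            violations = validate_record(rec)
            if violations:
                msg = f"line {line_no}: " + "; ".join(violations)
                if strict:
                    raise CohortParseError(msg)
                problems.append(msg)
                continue
            records.append(rec)
    return records


def _record_from_row(row: dict, line_no: int) -> PatientRecord:
    def cell(col: str) -> Optional[str]:
        v = row.get(col)
        if v is None or v.strip() == "":
            return None
        return v.strip()

    kwargs: dict = {}
    for col in _STR_COLUMNS:
        v = cell(col)
        if v is not None:
            kwargs[col] = v
    for col in _FLOAT_COLUMNS:
        v = cell(col)
        if v is not None:
            kwargs[col] = _parse_float(v, col, line_no)
    v = cell("ecog")
    if v is not None:
        f = _parse_float(v, "ecog", line_no)
        if f != int(f):
            raise CohortParseError(f"line {line_no}: ecog must be an integer")
        kwargs["ecog"] = int(f)
    for col in _BOOL_COLUMNS:
        v = cell(col)
        if v is not None:
            kwargs[col] = _parse_bool(v, col, line_no)

    labs = {
        col: _parse_float(cell(col), col, line_no)
        for col in LAB_COLUMNS
        if cell(col) is not None
    }
    kwargs["labs"] = LabPanel(**labs)
    markers = {
        col: _parse_float(cell(col), col, line_no)
        for col in BIOMARKER_COLUMNS
        if cell(col) is not None
    }
    if markers:
        kwargs["biomarkers"] = BiomarkerPanel(**markers)
    return PatientRecord(**kwargs)


def write_cohort(
    cohort: Iterable[PatientRecord], path, delimiter: str = ","
) -> None:
    """Write a cohort in the canonical CSV dialect (missing values empty)."""

    def fmt(value) -> str:
        if value is None:
            return ""
        if isinstance(value, bool):
            return "1" if value else "0"
        if isinstance(value, float):
            return repr(value)
        return str(value)

    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(COLUMNS)
        for rec in cohort:
            flat = dataclasses.asdict(rec)
            labs = flat.pop("labs") or {}
            markers = flat.pop("biomarkers") or {}
            flat.update(labs)
            flat.update(markers)
            writer.writerow([fmt(flat.get(col)) for col in COLUMNS])
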