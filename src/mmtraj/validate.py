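"""Schema validation for the persons / events input tables.

Externally prepared tables must match the documented schemas before the
pipeline will consume them; every violation is reported with its (1-based,
header-exclusive) row number so claims-extraction errors can be traced.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .conditions import CONDITION_INDEX

PERSON_REQUIRED = ["person_id", "gender", "age_band", "censor_time"]
EVENT_REQUIRED = ["person_id", "condition", "onset_time"]


@dataclass
class Violation:
    table: str
    row: int | None  # 1-based data row; None for table-level problems
    message: str

    def __str__(self) -> str:
        loc = f"row {self.row}" if self.row is not None else "table"
        return f"{self.table} [{loc}]: {self.message}"


@dataclass
class ValidationReport:
    violations: list[Violation] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def add(self, table: str, row: int | None, message: str) -> None:
        self.violations.append(Violation(table, row, message))

    def __str__(self) -> str:
        if self.ok:
            return "validation passed: no violations"
        lines = [f"validation failed: {len(self.violations)} violation(s)"]
        lines += [f"  - {v}" for v in self.violations]
        return "\n".join(lines)


def _rows_where(mask: pd.Series) -> list[int]:
    return (np.flatnonzero(mask.to_numpy()) + 1).tolist()


def validate_tables(
    persons_path: str | Path, events_path: str | Path
) -> ValidationReport:
    """Validate a persons/events table pair against the published schemas.

    Checks column presence, numeric types, person_id uniqueness, foreign-key
    integrity of events, known condition codes, onset-time finiteness, and
    per-(person, condition) uniqueness.  Missing files and malformed headers
    raise; content problems are collected in the report.
    """
    report = ValidationReport()
    persons = pd.read_csv(persons_path)
    events = pd.read_csv(events_path)

    for name, df, required in [
        ("persons", persons, PERSON_REQUIRED),
        ("events", events, EVENT_REQUIRED),
    ]:
        missing = [c for c in required if c not in df.columns]
        for col in missing:
            report.add(name, None, f"missing required column {col!r}")
    if report.violations:
        return report  # column checks below would only cascade

    pid = pd.to_numeric(persons["person_id"], errors="coerce")
    for r in _rows_where(pid.isna()):
        report.add("persons", r, "person_id is not numeric")
    dup = persons["person_id"].duplicated(keep=False) & pid.notna()
    for r in _rows_where(dup):
        report.add("persons", r, f"duplicate person_id {persons['person_id'].iloc[r-1]}")
    ct = pd.to_numeric(persons["censor_time"], errors="coerce")
    for r in _rows_where(ct.isna() | (ct <= 0)):
        report.add("persons", r, "censor_time must be a positive number")

    known_ids = set(persons.loc[pid.notna(), "person_id"].tolist())
    epid = pd.to_numeric(events["person_id"], errors="coerce")
    for r in _rows_where(epid.isna()):
        report.add("events", r, "person_id is not numeric")
    fk = ~events["person_id"].isin(known_ids) & epid.notna()
    for r in _rows_where(fk):
        report.add(
            "events", r,
            f"person_id {events['person_id'].iloc[r-1]} not present in persons",
        )
    bad_code = ~events["condition"].isin(CONDITION_INDEX)
    for r in _rows_where(bad_code):
        report.add("events", r, f"unknown condition code {events['condition'].iloc[r-1]!r}")
    ot = pd.to_numeric(events["onset_time"], errors="coerce")
    for r in _rows_where(ot.isna() | ~np.isfinite(ot.fillna(np.inf))):
        report.add("events", r, "onset_time must be a finite number")
    dup_ev = events.duplicated(subset=["person_id", "condition"], keep=False)
    # report each duplicated pair once, at its second occurrence
    second = events.duplicated(subset=["person_id", "condition"], keep="first")
    for r in _rows_where(second & dup_ev):
        report.add(
            "events", r,
            f"duplicate (person_id, condition) = "
            f"({events['person_id'].iloc[r-1]}, {events['condition'].iloc[r-1]})",
        )
    return report
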