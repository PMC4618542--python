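"""Admission-level data model and delimited-text I/O.

One :class:`AdmissionRecord` is one hospitalization: the analysis is
admission-level throughout — there is no patient identifier and no linkage
of readmissions.  A :class:`Cohort` is the ordered collection of records
that every downstream statistic operates on.

The on-disk format is plain CSV (UTF-8, comma, header required) with
columns ``institution_id, year, age_years, los_days, billed_charges,
discharge_status``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd

__all__ = [
    "AdmissionRecord",
    "Cohort",
    "ReadReport",
    "validate_record",
    "read_admissions",
    "write_admissions",
    "CSV_COLUMNS",
]

CSV_COLUMNS = (
    "institution_id",
    "year",
    "age_years",
    "los_days",
    "billed_charges",
    "discharge_status",
)

#: discharge-status vocabulary accepted on input (case-insensitive)
_DIED_TOKENS = frozenset({"died", "dead", "inpatient_death", "1", "true"})
_ALIVE_TOKENS = frozenset({"alive", "discharged", "0", "false"})

MIN_AGE, MAX_AGE = 0, 21
DEFAULT_YEAR_RANGE = (2004, 2013)


@dataclass(frozen=True)
class AdmissionRecord:
    """One hospitalization for the primary diagnosis.

    Parameters
    ----------
    institution_id : str
        Opaque hospital label.
    year : int
        Calendar year of admission.
    age_years : int
        Completed years of age at admission (0-21).
    los_days : int
        Length of stay in inpatient-days, at least 1.
    billed_charges : float
        Total billed charges in US dollars (not cost), non-negative.
    died : bool
        True if discharge status was inpatient death.
    """

    institution_id: str
    year: int
    age_years: int
    los_days: int
    billed_charges: float
    died: bool


@dataclass(frozen=True)
class Cohort:
    """An ordered collection of admission records.

    The cohort is the unit every statistic in this package operates on.
    It may be empty.  ``provenance`` is a free-text label recording where
    the records came from (a file path, a generator seed, ...).
    """

    records: tuple[AdmissionRecord, ...]
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[AdmissionRecord]:
        return iter(self.records)

    def __getitem__(self, i):
        return self.records[i]

    @classmethod
    def from_records(
        cls, records: Iterable[AdmissionRecord], provenance: str = ""
    ) -> "Cohort":
        return cls(records=tuple(records), provenance=provenance)

    def to_frame(self) -> pd.DataFrame:
        """Return the cohort as a DataFrame with the CSV columns
        (``discharge_status`` rendered as ``died``/``alive``)."""
        return pd.DataFrame(
            {
                "institution_id": [r.institution_id for r in self.records],
                "year": [r.year for r in self.records],
                "age_years": [r.age_years for r in self.records],
                "los_days": [r.los_days for r in self.records],
                "billed_charges": [r.billed_charges for r in self.records],
                "discharge_status": [
                    "died" if r.died else "alive" for r in self.records
                ],
            }
        )

    @property
    def n_deaths(self) -> int:
        return sum(r.died for r in self.records)


@dataclass
class ReadReport:
    """Tally returned by :func:`read_admissions` in lenient mode."""

    n_read: int = 0
    n_dropped: int = 0
    dropped_rows: list[tuple[int, str]] = field(default_factory=list)


def validate_record(
    record: AdmissionRecord,
    year_range: tuple[int, int] = DEFAULT_YEAR_RANGE,
) -> list[str]:
    """Return a list of invariant violations for *record* (empty if valid).

    Total function: never raises.  Each violation names the offending
    field and the rule it breaks.
    """
    violations: list[str] = []
    if not (MIN_AGE <= record.age_years <= MAX_AGE):
        violations.append(
            f"age_years={record.age_years} outside [{MIN_AGE}, {MAX_AGE}]"
        )
    lo, hi = year_range
    if not (lo <= record.year <= hi):
        violations.append(f"year={record.year} outside [{lo}, {hi}]")
    if record.los_days < 1:
        violations.append(f"los_days={record.los_days} must be >= 1")
    if record.billed_charges < 0:
        violations.append(
            f"billed_charges={record.billed_charges} must be >= 0"
        )
    return violations


def _parse_died(token: str) -> bool:
    t = token.strip().lower()
    if t in _DIED_TOKENS:
        return True
    if t in _ALIVE_TOKENS:
        return False
    raise ValueError(f"unrecognized discharge_status {token!r}")


def _parse_row(row: dict) -> AdmissionRecord:
    return AdmissionRecord(
        institution_id=str(row["institution_id"]).strip(),
        year=int(row["year"]),
        age_years=int(row["age_years"]),
        los_days=int(row["los_days"]),
        billed_charges=float(row["billed_charges"]),
        died=_parse_died(str(row["discharge_status"])),
    )


def read_admissions(
    path: str | Path,
    strict: bool = True,
    year_range: tuple[int, int] = DEFAULT_YEAR_RANGE,
) -> tuple[Cohort, ReadReport]:
    """Read an admission cohort from a CSV file.

    In strict mode (default) any unparseable or invariant-violating row
    raises :class:`ValueError` naming the row.  In lenient mode such rows
    are dropped and counted in the returned :class:`ReadReport`, so that
    ``n_read + n_dropped`` equals the number of data rows in the file.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"admission file not found: {path}")
    report = ReadReport()
    records: list[AdmissionRecord] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise ValueError(f"{path}: empty file, header required")
        missing = set(CSV_COLUMNS) - set(reader.fieldnames)
        if missing:
            raise ValueError(
                f"{path}: missing required columns {sorted(missing)}"
            )
        for i, row in enumerate(reader, start=2):  # header is line 1
            try:
                rec = _parse_row(row)
                violations = validate_record(rec, year_range=year_range)
                if violations:
                    raise ValueError("; ".join(violations))
            except (ValueError, KeyError, TypeError) as exc:
                if strict:
                    raise ValueError(f"{path}, line {i}: {exc}") from exc
                report.n_dropped += 1
                report.dropped_rows.append((i, str(exc)))
                continue
            records.append(rec)
            report.n_read += 1
    return Cohort.from_records(records, provenance=str(path)), report


def write_admissions(cohort: Cohort, path: str | Path) -> Path:
    """Write *cohort* as CSV; round-trips field-for-field through
    :func:`read_admissions`.

    Charges are written with two decimal places (cents); all other fields
    are exact integers or strings.
    """
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_COLUMNS)
        for r in cohort:
            writer.writerow(
                [
                    r.institution_id,
                    r.year,
                    r.age_years,
                    r.los_days,
                    f"{r.billed_charges:.2f}",
                    "died" if r.died else "alive",
                ]
            )
    return path
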