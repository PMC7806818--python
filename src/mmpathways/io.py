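"""CSV readers/writers for the five-table claims bundle.

Schemas (UTF-8, header row mandatory, ISO-8601 dates):

* ``patients.csv``:    patient_id,birth_date,sex,enroll_start,enroll_end
* ``diagnoses.csv``:   patient_id,claim_date,icd9,position,setting
* ``dispensings.csv``: patient_id,dispense_date,drug,days_supply,setting
* ``procedures.csv``:  patient_id,procedure_date,procedure
* ``deaths.csv``:      patient_id,death_date

A missing file or a wrong header is fatal.  A malformed *row* (bad date,
``days_supply < 1``, unknown drug, …) is never silently dropped: it lands
in the :class:`RejectReport` with the file, row number and reason, so an
auditor can reconcile input and output row counts exactly.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from datetime import date, datetime
from pathlib import Path
from typing import Optional, Sequence

from .dictionary import DrugDictionary, UnknownDrugError
from .records import (
    ClaimsBundle,
    DeathRecord,
    DiagnosisClaim,
    DrugDispensing,
    PatientRecord,
    ProcedureClaim,
    RecordError,
)

TABLE_FILES = {
    "patients": "patients.csv",
    "diagnoses": "diagnoses.csv",
    "dispensings": "dispensings.csv",
    "procedures": "procedures.csv",
    "deaths": "deaths.csv",
}

TABLE_COLUMNS = {
    "patients": ["patient_id", "birth_date", "sex", "enroll_start", "enroll_end"],
    "diagnoses": ["patient_id", "claim_date", "icd9", "position", "setting"],
    "dispensings": ["patient_id", "dispense_date", "drug", "days_supply", "setting"],
    "procedures": ["patient_id", "procedure_date", "procedure"],
    "deaths": ["patient_id", "death_date"],
}


class BundleReadError(ValueError):
    """Fatal bundle problem: missing file or header mismatch."""


@dataclass(frozen=True, slots=True)
class RejectedRow:
    table: str
    row: int  # 1-based data-row number (header excluded)
    reason: str
    raw: dict


@dataclass(slots=True)
class RejectReport:
    rejects: list[RejectedRow] = field(default_factory=list)

    def add(self, table: str, row: int, reason: str, raw: dict) -> None:
        self.rejects.append(RejectedRow(table, row, reason, raw))

    def __len__(self) -> int:
        return len(self.rejects)

    def by_table(self, table: str) -> list[RejectedRow]:
        return [r for r in self.rejects if r.table == table]

    def to_csv(self, path: Path | str) -> None:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(["table", "row", "reason"])
            for r in self.rejects:
                w.writerow([r.table, r.row, r.reason])


def _parse_date(value: str, field_name: str) -> date:
    try:
        return datetime.strptime(value.strip(), "%Y-%m-%d").date()
    except ValueError:
        raise RecordError(f"unparseable date in {field_name}: {value!r}") from None


def _parse_optional_date(value: str, field_name: str) -> Optional[date]:
    if value is None or value.strip() == "":
        return None
    return _parse_date(value, field_name)


def _read_table(path: Path, table: str) -> list[dict]:
    if not path.exists():
        raise BundleReadError(f"missing bundle file: {path}")
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        if list(header) != TABLE_COLUMNS[table]:
            raise BundleReadError(
                f"{path.name}: header {header} does not match schema {TABLE_COLUMNS[table]}"
            )
        return list(reader)


def read_claims_bundle(
    directory: Path | str,
    dictionary: DrugDictionary | None = None,
) -> tuple[ClaimsBundle, RejectReport]:
    """Read the five CSVs under ``directory`` into typed records.

    Returns the bundle plus the reject report; accepted + rejected row
    counts equal the input row counts table by table.
    """
    directory = Path(directory)
    dictionary = dictionary or DrugDictionary.default()
    report = RejectReport()
    bundle = ClaimsBundle()

    rows = {t: _read_table(directory / f, t) for t, f in TABLE_FILES.items()}

    for i, row in enumerate(rows["patients"], start=1):
        try:
            bundle.patients.append(
                PatientRecord(
                    patient_id=row["patient_id"].strip(),
                    birth_date=_parse_date(row["birth_date"], "birth_date"),
                    sex=row["sex"].strip().lower(),
                    enroll_start=_parse_date(row["enroll_start"], "enroll_start"),
                    enroll_end=_parse_optional_date(row["enroll_end"], "enroll_end"),
                )
            )
        except RecordError as exc:
            report.add("patients", i, str(exc), row)

    for i, row in enumerate(rows["diagnoses"], start=1):
        try:
            bundle.diagnoses.append(
                DiagnosisClaim(
                    patient_id=row["patient_id"].strip(),
                    claim_date=_parse_date(row["claim_date"], "claim_date"),
                    icd9=row["icd9"].strip(),
                    position=row["position"].strip().lower(),
                    setting=row["setting"].strip().lower(),
                )
            )
        except RecordError as exc:
            report.add("diagnoses", i, str(exc), row)

    for i, row in enumerate(rows["dispensings"], start=1):
        try:
            try:
                days = int(row["days_supply"])
            except ValueError:
                raise RecordError(f"days_supply not an integer: {row['days_supply']!r}")
            if days < 1:
                raise RecordError("days_supply < 1")
            try:
                drug = dictionary.resolve(row["drug"])
            except UnknownDrugError:
                raise RecordError(f"unknown drug: {row['drug']!r}")
            bundle.dispensings.append(
                DrugDispensing(
                    patient_id=row["patient_id"].strip(),
                    dispense_date=_parse_date(row["dispense_date"], "dispense_date"),
                    drug=drug,
                    days_supply=days,
                    setting=row["setting"].strip().lower(),
                )
            )
        except RecordError as exc:
            report.add("dispensings", i, str(exc), row)

    for i, row in enumerate(rows["procedures"], start=1):
        try:
            bundle.procedures.append(
                ProcedureClaim(
                    patient_id=row["patient_id"].strip(),
                    procedure_date=_parse_date(row["procedure_date"], "procedure_date"),
                    procedure=row["procedure"].strip(),
                )
            )
        except RecordError as exc:
            report.add("procedures", i, str(exc), row)

    for i, row in enumerate(rows["deaths"], start=1):
        try:
            bundle.deaths.append(
                DeathRecord(
                    patient_id=row["patient_id"].strip(),
                    death_date=_parse_date(row["death_date"], "death_date"),
                )
            )
        except RecordError as exc:
            report.add("deaths", i, str(exc), row)

    return bundle, report


def _iso(d: Optional[date]) -> str:
    return d.isoformat() if d is not None else ""


def write_claims_bundle(bundle: ClaimsBundle, directory: Path | str) -> None:
    """Write the bundle back to the five-CSV layout (lossless round trip)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    def dump(table: str, rows: Sequence[Sequence]) -> None:
        with open(directory / TABLE_FILES[table], "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(TABLE_COLUMNS[table])
            w.writerows(rows)

    dump(
        "patients",
        [
            (p.patient_id, _iso(p.birth_date), p.sex, _iso(p.enroll_start), _iso(p.enroll_end))
            for p in bundle.patients
        ],
    )
    dump(
        "diagnoses",
        [
            (d.patient_id, _iso(d.claim_date), d.icd9, d.position, d.setting)
            for d in bundle.diagnoses
        ],
    )
    dump(
        "dispensings",
        [
            (r.patient_id, _iso(r.dispense_date), r.drug, r.days_supply, r.setting)
            for r in bundle.dispensings
        ],
    )
    dump(
        "procedures",
        [(p.patient_id, _iso(p.procedure_date), p.procedure) for p in bundle.procedures],
    )
    dump("deaths", [(d.patient_id, _iso(d.death_date)) for d in bundle.deaths])
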