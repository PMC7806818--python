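"""Typed claims records shared by every pipeline stage.

Administrative claims arrive as five flat tables: patients, diagnosis
claims (ICD-9-CM coded), drug dispensings with days-supply, procedure
claims (ASCT), and death-registry records.  Each row becomes a frozen
dataclass whose ``__post_init__`` enforces the row-level invariants;
rows that violate them are collected in a reject report by the readers
in :mod:`mmpathways.io` rather than silently dropped.

Dates are day-granular :class:`datetime.date` everywhere — the finest
granularity claims data supports.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date
from typing import Optional

SEXES = ("male", "female")
SETTINGS = ("outpatient", "inpatient")
POSITIONS = ("primary", "secondary")
PROCEDURES = ("ASCT", "other")


class RecordError(ValueError):
    """A claims row violates a schema invariant."""


@dataclass(frozen=True, slots=True)
class PatientRecord:
    """Demographics and enrollment span for one insured person.

    ``enroll_end`` is ``None`` for open enrollment (still enrolled at the
    data cut).
    """

    patient_id: str
    birth_date: date
    sex: str
    enroll_start: date
    enroll_end: Optional[date] = None

    def __post_init__(self) -> None:
        if not self.patient_id:
            raise RecordError("patient_id is empty")
        if self.sex not in SEXES:
            raise RecordError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if self.enroll_end is not None and self.enroll_start > self.enroll_end:
            raise RecordError("enroll_start > enroll_end")
        if self.birth_date > self.enroll_start:
            raise RecordError("birth_date > enroll_start")


@dataclass(frozen=True, slots=True)
class DiagnosisClaim:
    """One dated ICD-9-CM diagnosis, primary or secondary, by care setting."""

    patient_id: str
    claim_date: date
    icd9: str
    position: str = "primary"
    setting: str = "outpatient"

    def __post_init__(self) -> None:
        if self.position not in POSITIONS:
            raise RecordError(f"position must be one of {POSITIONS}")
        if self.setting not in SETTINGS:
            raise RecordError(f"setting must be one of {SETTINGS}")
        if not _valid_icd9(self.icd9):
            raise RecordError(f"malformed ICD-9 code {self.icd9!r}")


@dataclass(frozen=True, slots=True)
class DrugDispensing:
    """One dated dispensing of a myeloma drug — the atom of line-of-therapy
    construction.  Coverage runs ``[dispense_date, dispense_date + days_supply - 1]``.
    """

    patient_id: str
    dispense_date: date
    drug: str
    days_supply: int
    setting: str = "outpatient"

    def __post_init__(self) -> None:
        if self.days_supply < 1:
            raise RecordError("days_supply < 1")
        if self.setting not in SETTINGS:
            raise RecordError(f"setting must be one of {SETTINGS}")
        if not self.drug:
            raise RecordError("drug is empty")


@dataclass(frozen=True, slots=True)
class ProcedureClaim:
    patient_id: str
    procedure_date: date
    procedure: str = "ASCT"

    def __post_init__(self) -> None:
        if self.procedure not in PROCEDURES:
            raise RecordError(f"procedure must be one of {PROCEDURES}")


@dataclass(frozen=True, slots=True)
class DeathRecord:
    patient_id: str
    death_date: date


def _valid_icd9(code: str) -> bool:
    """3-character root (digits, or V/E prefix) with optional decimals."""
    code = code.strip()
    if not code:
        return False
    root, _, frac = code.partition(".")
    if frac and not frac.isdigit():
        return False
    if len(frac) > 2:
        return False
    if root.isdigit():
        return len(root) == 3
    if root[:1].upper() == "V":
        return len(root) == 3 and root[1:].isdigit()
    if root[:1].upper() == "E":
        return len(root) == 4 and root[1:].isdigit()
    return False


def normalize_icd9(code: str) -> str:
    """Canonical dot-free upper-case form used for all prefix matching."""
    return code.strip().upper().replace(".", "")


@dataclass(slots=True)
class PatientClaims:
    """All claims for one patient, grouped once and shared by the stages."""

    patient: PatientRecord
    diagnoses: list[DiagnosisClaim] = field(default_factory=list)
    dispensings: list[DrugDispensing] = field(default_factory=list)
    procedures: list[ProcedureClaim] = field(default_factory=list)
    death: Optional[DeathRecord] = None


@dataclass(slots=True)
class ClaimsBundle:
    """The five typed record collections of one claims extract."""

    patients: list[PatientRecord] = field(default_factory=list)
    diagnoses: list[DiagnosisClaim] = field(default_factory=list)
    dispensings: list[DrugDispensing] = field(default_factory=list)
    procedures: list[ProcedureClaim] = field(default_factory=list)
    deaths: list[DeathRecord] = field(default_factory=list)

    def grouped(self) -> dict[str, PatientClaims]:
        """Group every table by patient, preserving input order within patient.

        Raises :class:`RecordError` if a patient has more than one death
        record (the registry carries at most one).
        """
        out: dict[str, PatientClaims] = {}
        for p in self.patients:
            if p.patient_id in out:
                raise RecordError(f"duplicate patient record {p.patient_id}")
            out[p.patient_id] = PatientClaims(patient=p)
        for dx in self.diagnoses:
            if dx.patient_id in out:
                out[dx.patient_id].diagnoses.append(dx)
        for rx in self.dispensings:
            if rx.patient_id in out:
                out[rx.patient_id].dispensings.append(rx)
        for pr in self.procedures:
            if pr.patient_id in out:
                out[pr.patient_id].procedures.append(pr)
        for de in self.deaths:
            pc = out.get(de.patient_id)
            if pc is None:
                continue
            if pc.death is not None:
                raise RecordError(f"multiple death records for {de.patient_id}")
            pc.death = de
        return out

    def counts(self) -> dict[str, int]:
        return {
            "patients": len(self.patients),
            "diagnoses": len(self.diagnoses),
            "dispensings": len(self.dispensings),
            "procedures": len(self.procedures),
            "deaths": len(self.deaths),
        }
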