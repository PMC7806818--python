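"""Charlson/Deyo comorbidity index and the four MM-associated comorbidities.

The CCI is the sum of weights over distinct Deyo condition groups matched
by any ICD-9-CM diagnosis claim in the 12 months before the index date.
Each group counts once; hierarchy rules keep a severe condition from being
double-counted with its mild form (complicated vs uncomplicated diabetes,
moderate/severe vs mild liver disease, metastatic vs any malignancy).

Because every patient in this cohort has myeloma, the malignancy and
metastatic groups are *excluded from the score by default* — including
them would add a constant 2 to everyone.  Set ``include_malignancy=True``
to restore the textbook score.

The MM-associated comorbidities — anemia (281, 283, 284, 285, 776), renal
injury/failure (586), pneumonia (486) and bone fracture (800-829) — are
flagged when the patient has >= 3 outpatient visit claims (distinct dates)
or >= 1 hospitalization claim with the diagnosis in the assessment window,
which runs from 12 months before index through the index date itself.

The Deyo code table ships as ``data/deyo_icd9.csv`` (condition,
weight, pipe-delimited ICD-9 prefixes) so auditors can amend codes
without touching code.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from datetime import date, timedelta
from importlib import resources
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .records import DiagnosisClaim, normalize_icd9

#: severe group -> mild group it supersedes
HIERARCHY = {
    "diabetes_with_complication": "diabetes_without_complication",
    "moderate_severe_liver_disease": "mild_liver_disease",
    "metastatic_solid_tumor": "any_malignancy",
}

MALIGNANCY_GROUPS = ("any_malignancy", "metastatic_solid_tumor")

MM_COMORBIDITY_CODES: dict[str, tuple[str, ...]] = {
    "anemia": ("281", "283", "284", "285", "776"),
    "renal": ("586",),
    "pneumonia": ("486",),
    "fracture": tuple(str(c) for c in range(800, 830)),
}

CCI_BANDS = ("0", "1", "2", "3+")


@dataclass(frozen=True)
class DeyoMap:
    """Condition group -> (normalized ICD-9 prefixes, weight)."""

    groups: Mapping[str, tuple[tuple[str, ...], int]]

    @classmethod
    def default(cls) -> "DeyoMap":
        with resources.files("mmpathways.data").joinpath("deyo_icd9.csv").open(
            encoding="utf-8"
        ) as fh:
            reader = csv.DictReader(fh)
            groups = {}
            for row in reader:
                prefixes = tuple(
                    normalize_icd9(p) for p in row["icd9_prefixes"].split("|")
                )
                groups[row["condition"]] = (prefixes, int(row["weight"]))
        m = cls(groups=groups)
        m._check()
        return m

    def _check(self) -> None:
        for cond, (_, w) in self.groups.items():
            if w not in (1, 2, 3, 6):
                raise ValueError(f"{cond}: weight {w} not in {{1,2,3,6}}")

    def matching_groups(self, icd9: str) -> set[str]:
        code = normalize_icd9(icd9)
        hit = set()
        for cond, (prefixes, _) in self.groups.items():
            if any(code.startswith(p) for p in prefixes):
                hit.add(cond)
        return hit

    def weight(self, condition: str) -> int:
        return self.groups[condition][1]


@dataclass(frozen=True, slots=True)
class ComorbidityProfile:
    patient_id: str
    cci: int
    cci_band: str
    anemia: bool
    renal: bool
    pneumonia: bool
    fracture: bool


def cci_band(cci: int) -> str:
    """Band the score as reported: 0, 1, 2, >=3."""
    if cci < 0:
        raise ValueError("CCI cannot be negative")
    return str(cci) if cci < 3 else "3+"


def compute_cci(
    diagnoses: Iterable[DiagnosisClaim],
    index_date: date,
    window_days: int = 365,
    deyo: DeyoMap | None = None,
    include_malignancy: bool = False,
) -> int:
    """Deyo-weighted Charlson score from the pre-index window.

    Claims with ``index - window_days <= date < index`` contribute; each
    matched group counts once and hierarchy rules drop the mild member of
    each severe/mild pair.
    """
    deyo = deyo or DeyoMap.default()
    start = index_date - timedelta(days=window_days)
    present: set[str] = set()
    for dx in diagnoses:
        if start <= dx.claim_date < index_date:
            present |= deyo.matching_groups(dx.icd9)
    for severe, mild in HIERARCHY.items():
        if severe in present:
            present.discard(mild)
    if not include_malignancy:
        present -= set(MALIGNANCY_GROUPS)
    return sum(deyo.weight(c) for c in present)


def flag_mm_comorbidities(
    diagnoses: Iterable[DiagnosisClaim],
    index_date: date,
    window_days: int = 365,
) -> dict[str, bool]:
    """The four condition flags from the claim-frequency rule.

    A condition is present iff the window holds >= 3 outpatient claims on
    distinct dates, or >= 1 inpatient claim, with a matching primary or
    secondary diagnosis.
    """
    start = index_date - timedelta(days=window_days)
    flags: dict[str, bool] = {}
    for cond, prefixes in MM_COMORBIDITY_CODES.items():
        outpatient_dates: set[date] = set()
        inpatient = 0
        for dx in diagnoses:
            if not (start <= dx.claim_date <= index_date):
                continue
            code = normalize_icd9(dx.icd9)
            if not any(code.startswith(p) for p in prefixes):
                continue
            if dx.setting == "inpatient":
                inpatient += 1
            else:
                outpatient_dates.add(dx.claim_date)
        flags[cond] = inpatient >= 1 or len(outpatient_dates) >= 3
    return flags


def comorbidity_profile(
    patient_id: str,
    diagnoses: Iterable[DiagnosisClaim],
    index_date: date,
    window_days: int = 365,
    deyo: DeyoMap | None = None,
    include_malignancy: bool = False,
) -> ComorbidityProfile:
    dxs = list(diagnoses)
    score = compute_cci(dxs, index_date, window_days, deyo, include_malignancy)
    flags = flag_mm_comorbidities(dxs, index_date, window_days)
    return ComorbidityProfile(
        patient_id=patient_id,
        cci=score,
        cci_band=cci_band(score),
        anemia=flags["anemia"],
        renal=flags["renal"],
        pneumonia=flags["pneumonia"],
        fracture=flags["fracture"],
    )


def comorbidity_frame(profiles: Sequence[ComorbidityProfile]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "patient_id": p.patient_id,
                "cci": p.cci,
                "cci_band": p.cci_band,
                "anemia": p.anemia,
                "renal": p.renal,
                "pneumonia": p.pneumonia,
                "fracture": p.fracture,
            }
            for p in profiles
        ]
    )
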