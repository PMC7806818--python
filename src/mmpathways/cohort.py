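"""Cohort selection for newly diagnosed, treated multiple myeloma.

The study cohort is every patient first diagnosed with MM (ICD-9 203,
203.0, 203.0x) between 2007-01-01 and 2015-12-31 who was an adult at
diagnosis, had at least 12 months of enrollment before the index date,
had a further MM visit after diagnosis, and received MM drug treatment.
Patients with any other primary cancer before index, or with plasma cell
leukaemia / other immunoproliferative neoplasm codes (203.1x / 203.8x)
within two months of the first MM claim, are excluded.

Exclusions are logged per triggered rule with the first-triggered rule
as primary, so the selection flow-chart can be reconstructed and
``members + excluded patients == input patients`` always holds.

The diagnosis era splits at the first-line bortezomib reimbursement
boundary: index dates up to 2012-05-31 are *pre-bortezomib*, from
2012-06-01 *post-bortezomib*.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, timedelta
from typing import Iterable, Optional, Sequence

import pandas as pd

from .dictionary import DrugDictionary
from .records import (
    ClaimsBundle,
    DeathRecord,
    DiagnosisClaim,
    DrugDispensing,
    PatientClaims,
    ProcedureClaim,
    normalize_icd9,
)

PRE_BORTEZOMIB = "pre_bortezomib"
POST_BORTEZOMIB = "post_bortezomib"

#: Exclusion rules, in the order they are evaluated.  The first triggered
#: rule is recorded as the patient's primary exclusion reason.
EXCLUSION_RULES = (
    "no_mm_diagnosis",
    "index_out_of_window",
    "underage",
    "insufficient_lookback",
    "prior_cancer",
    "plasma_cell_leukemia_within_2mo",
    "no_mm_visit_after_index",
    "untreated",
)


@dataclass(frozen=True)
class CohortConfig:
    """Tunable selection rules (defaults reproduce the study design)."""

    study_start: date = date(2007, 1, 1)
    study_end: date = date(2015, 12, 31)
    censor_date: date = date(2017, 12, 31)
    period_boundary: date = date(2012, 6, 1)  # first post-bortezomib index date
    lookback_days: int = 365  # "12 months prior" as a fixed-day window
    pcl_window_days: int = 61  # "within 2 months" of the first MM claim
    prior_cancer_min_claims: int = 1

    def __post_init__(self) -> None:
        if self.censor_date < self.study_start:
            raise ValueError("censor date before study start")


@dataclass(frozen=True, slots=True)
class CohortMember:
    patient_id: str
    index_date: date
    age_at_dx: int
    sex: str
    period: str
    treated: bool
    asct: bool
    asct_date: Optional[date]
    followup_end: date
    followup_years: float
    died: bool


@dataclass(frozen=True, slots=True)
class ExclusionEntry:
    patient_id: str
    rule: str
    detail: str
    primary: bool


def is_mm_code(icd9: str) -> bool:
    """203, 203.0 or 203.0x — the index-defining myeloma codes."""
    n = normalize_icd9(icd9)
    return n == "203" or n.startswith("2030")


def is_pcl_or_ipn_code(icd9: str) -> bool:
    """203.1x (plasma cell leukaemia) or 203.8x (other immunoproliferative)."""
    n = normalize_icd9(icd9)
    return n.startswith("2031") or n.startswith("2038")


def is_other_primary_cancer_code(icd9: str) -> bool:
    """Any ICD-9 malignancy (140-208) that is not an MM index code."""
    n = normalize_icd9(icd9)
    if not n[:3].isdigit():
        return False
    root = int(n[:3])
    return 140 <= root <= 208 and not is_mm_code(icd9)


def find_index_date(diagnoses: Iterable[DiagnosisClaim]) -> Optional[date]:
    """Earliest claim date with an MM index code, any position/setting."""
    dates = [d.claim_date for d in diagnoses if is_mm_code(d.icd9)]
    return min(dates) if dates else None


def assign_period(index_date: date, config: CohortConfig | None = None) -> str:
    config = config or CohortConfig()
    if not (config.study_start <= index_date <= config.study_end):
        raise ValueError(f"index date {index_date} outside study window")
    return POST_BORTEZOMIB if index_date >= config.period_boundary else PRE_BORTEZOMIB


def age_at(birth_date: date, on: date) -> int:
    """Completed years (floor) at ``on``."""
    years = on.year - birth_date.year
    if (on.month, on.day) < (birth_date.month, birth_date.day):
        years -= 1
    return years


def compute_followup(
    index_date: date,
    death: Optional[DeathRecord],
    enroll_end: Optional[date],
    config: CohortConfig | None = None,
) -> tuple[date, float, bool]:
    """Follow-up to the first of death, dis-enrolment or the censor date.

    Returns ``(followup_end, followup_years, died)``; ``died`` is True only
    when the death is observed inside follow-up.
    """
    config = config or CohortConfig()
    candidates = [config.censor_date]
    if enroll_end is not None:
        candidates.append(enroll_end)
    if death is not None:
        if death.death_date < index_date:
            raise ValueError(
                f"death {death.death_date} before index {index_date} (corrupt data)"
            )
        candidates.append(death.death_date)
    end = min(candidates)
    died = death is not None and death.death_date <= end
    return end, (end - index_date).days / 365.25, died


def flag_asct(
    index_date: date, procedures: Iterable[ProcedureClaim]
) -> tuple[bool, Optional[date]]:
    """First ASCT on/after the index date; pre-index procedures are ignored."""
    dates = [
        p.procedure_date
        for p in procedures
        if p.procedure == "ASCT" and p.procedure_date >= index_date
    ]
    if not dates:
        return False, None
    return True, min(dates)


def _evaluate_rules(
    pc: PatientClaims,
    dictionary: DrugDictionary,
    config: CohortConfig,
) -> list[tuple[str, str]]:
    """All triggered exclusion rules for one patient, in rule order."""
    triggered: list[tuple[str, str]] = []
    index = find_index_date(pc.diagnoses)

    if index is None:
        return [("no_mm_diagnosis", "no 203/203.0x claim")]
    if not (config.study_start <= index <= config.study_end):
        # later rules are index-relative; an out-of-window index stands alone
        return [("index_out_of_window", f"index {index}")]

    age = age_at(pc.patient.birth_date, index)
    if age < 18:
        triggered.append(("underage", f"age {age} at index"))

    lookback_start = index - timedelta(days=config.lookback_days)
    if pc.patient.enroll_start > lookback_start:
        triggered.append(
            (
                "insufficient_lookback",
                f"enrolled {pc.patient.enroll_start}, needed by {lookback_start}",
            )
        )

    prior = [
        d
        for d in pc.diagnoses
        if d.claim_date < index and is_other_primary_cancer_code(d.icd9)
    ]
    if len(prior) >= config.prior_cancer_min_claims:
        triggered.append(("prior_cancer", f"e.g. {prior[0].icd9} on {prior[0].claim_date}"))

    pcl_limit = index + timedelta(days=config.pcl_window_days)
    pcl = [
        d
        for d in pc.diagnoses
        if is_pcl_or_ipn_code(d.icd9) and index <= d.claim_date <= pcl_limit
    ]
    if pcl:
        triggered.append(
            ("plasma_cell_leukemia_within_2mo", f"{pcl[0].icd9} on {pcl[0].claim_date}")
        )

    if not any(d.claim_date > index and is_mm_code(d.icd9) for d in pc.diagnoses):
        triggered.append(("no_mm_visit_after_index", "no MM claim after index"))

    if not any(
        r.dispense_date >= index and r.drug in dictionary for r in pc.dispensings
    ):
        triggered.append(("untreated", "no MM drug dispensing on/after index"))

    return triggered


def apply_selection(
    bundle: ClaimsBundle,
    config: CohortConfig | None = None,
    dictionary: DrugDictionary | None = None,
) -> tuple[list[CohortMember], list[ExclusionEntry]]:
    """Apply every inclusion/exclusion rule and build the cohort.

    Every input patient ends up either as a :class:`CohortMember` or in the
    exclusion log (possibly with several entries; exactly one primary).
    Patients are processed in sorted-id order so the result is independent
    of input row order.
    """
    config = config or CohortConfig()
    dictionary = dictionary or DrugDictionary.default()
    members: list[CohortMember] = []
    log: list[ExclusionEntry] = []

    grouped = bundle.grouped()
    for pid in sorted(grouped):
        pc = grouped[pid]
        triggered = _evaluate_rules(pc, dictionary, config)
        if triggered:
            for j, (rule, detail) in enumerate(triggered):
                log.append(ExclusionEntry(pid, rule, detail, primary=(j == 0)))
            continue

        index = find_index_date(pc.diagnoses)
        assert index is not None
        asct, asct_date = flag_asct(index, pc.procedures)
        end, years, died = compute_followup(index, pc.death, pc.patient.enroll_end, config)
        members.append(
            CohortMember(
                patient_id=pid,
                index_date=index,
                age_at_dx=age_at(pc.patient.birth_date, index),
                sex=pc.patient.sex,
                period=assign_period(index, config),
                treated=True,
                asct=asct,
                asct_date=asct_date,
                followup_end=end,
                followup_years=years,
                died=died,
            )
        )
    return members, log


def cohort_frame(members: Sequence[CohortMember]) -> pd.DataFrame:
    """Cohort as a DataFrame (one row per member, ``cohort.csv`` layout)."""
    return pd.DataFrame(
        [
            {
                "patient_id": m.patient_id,
                "index_date": m.index_date,
                "age_at_dx": m.age_at_dx,
                "sex": m.sex,
                "period": m.period,
                "treated": m.treated,
                "asct": m.asct,
                "asct_date": m.asct_date,
                "followup_end": m.followup_end,
                "followup_years": m.followup_years,
                "died": m.died,
            }
            for m in members
        ]
    )


def exclusion_frame(log: Sequence[ExclusionEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"patient_id": e.patient_id, "rule": e.rule, "detail": e.detail, "primary": e.primary}
            for e in log
        ]
    )
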