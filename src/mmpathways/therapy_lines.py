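"""Line-of-therapy (LOT) construction and regimen classification.

A line of therapy is a contiguous treatment episode inferred from
dispensing claims.  Each dispensing covers ``[dispense_date,
dispense_date + days_supply - 1]``; a line accumulates drugs and ends at
the earliest of

(a) **gap** — at least ``gap_days`` (default 60) consecutive days with no
    coverage from any drug of the line; the line's end is its last covered
    day and the next dispensing (of any drug) opens the next line;
(b) **late addition** — a dispensing of a drug outside the line's set more
    than ``addition_window_days`` (default 90) after line start; the line
    ends the day before and that dispensing opens the next line.  New
    drugs dispensed *within* the window (day 90 inclusive) simply join the
    line's drug set;
(c) **death**;
(d) **data end** (end of follow-up).

A drug already in the line never opens a new line by re-dispensing, and
drugs carried over a late-addition switch join the new line only through
their own dispensings on/after the switch date.

Classification: a line is **NA** (novel agents, no chemotherapy), **CCNA**
(chemotherapy combined with novel agents), **CA** (chemotherapy alone) or
**SA** (steroids alone).  Steroids never demote NA/CCNA/CA.  The named
regimen labels mirror the published first-line taxonomy (bortezomib +
thalidomide, melphalan-based, two-chemo combination, ...).
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, timedelta
from itertools import groupby
from typing import Iterable, Optional, Sequence

import pandas as pd

from .dictionary import DrugCategory, DrugDictionary
from .records import DrugDispensing

GAP = "gap"
NEW_DRUG = "new_drug_after_90d"
DEATH = "death"
DATA_END = "data_end"

REGIMEN_CLASSES = ("NA", "CCNA", "CA", "SA")


@dataclass(frozen=True)
class LotParams:
    """Tunables of the LOT algorithm.

    ``gap_basis="coverage"`` measures gaps in days without drug coverage
    (dispense date + days supply), the standard claims convention;
    ``"dispense_date"`` ignores days-supply and measures gaps between
    dispense dates, for sensitivity analysis.
    """

    gap_days: int = 60
    addition_window_days: int = 90
    gap_basis: str = "coverage"

    def __post_init__(self) -> None:
        if self.gap_days < 1 or self.addition_window_days < 1:
            raise ValueError("gap_days and addition_window_days must be positive")
        if self.gap_basis not in ("coverage", "dispense_date"):
            raise ValueError("gap_basis must be 'coverage' or 'dispense_date'")


@dataclass(frozen=True, slots=True)
class TherapyLine:
    patient_id: str
    line_number: int
    start_date: date
    end_date: date
    drugs: frozenset[str]
    end_reason: str
    regimen_class: str = ""
    named_regimen: str = ""

    def __post_init__(self) -> None:
        if self.start_date > self.end_date:
            raise ValueError("line start after end")
        if not self.drugs:
            raise ValueError("line has empty drug set")


def coverage_intervals(
    dispensings: Iterable[DrugDispensing],
) -> dict[str, list[tuple[date, date]]]:
    """Per-drug coverage intervals with overlapping/adjacent spans merged."""
    by_drug: dict[str, list[tuple[date, date]]] = {}
    for d in sorted(dispensings, key=lambda r: (r.drug, r.dispense_date)):
        end = d.dispense_date + timedelta(days=d.days_supply - 1)
        spans = by_drug.setdefault(d.drug, [])
        if spans and d.dispense_date <= spans[-1][1] + timedelta(days=1):
            spans[-1] = (spans[-1][0], max(spans[-1][1], end))
        else:
            spans.append((d.dispense_date, end))
    return by_drug


def _supply(d: DrugDispensing, params: LotParams) -> int:
    return 1 if params.gap_basis == "dispense_date" else d.days_supply


def build_lines(
    dispensings: Sequence[DrugDispensing],
    index_date: date,
    death_date: Optional[date],
    data_end: date,
    params: LotParams | None = None,
) -> list[TherapyLine]:
    """Partition one patient's dispensings into ordered therapy lines.

    Every dispensing on/after the index date is attributed to exactly one
    line.  Dispensings are processed in calendar-day groups so that a day
    carrying both an in-line drug and a late new drug is handled
    atomically: the whole day belongs to the new line.
    """
    params = params or LotParams()
    if not dispensings:
        return []
    disp = sorted(dispensings, key=lambda d: (d.dispense_date, d.drug, d.days_supply))
    if disp[0].dispense_date < index_date:
        raise ValueError(
            f"dispensing on {disp[0].dispense_date} precedes index {index_date}"
        )
    observed_death = death_date if (death_date is not None and death_date <= data_end) else None
    if observed_death is not None and disp[-1].dispense_date > observed_death:
        raise ValueError("dispensing after death (corrupt data)")

    day_groups = [
        (day, list(g)) for day, g in groupby(disp, key=lambda d: d.dispense_date)
    ]

    lines: list[TherapyLine] = []
    pid = disp[0].patient_id
    i = 0  # index into day_groups: first day of the current line
    while i < len(day_groups):
        line_start = day_groups[i][0]
        drugs: set[str] = set()
        last_covered = line_start - timedelta(days=1)
        end: Optional[tuple[date, str]] = None
        j = i
        next_i = None
        while j < len(day_groups):
            day, group = day_groups[j]
            if j > i:
                uncovered = (day - last_covered).days - 1
                if uncovered >= params.gap_days:
                    end = (last_covered, GAP)
                    next_i = j
                    break
            new_late = any(
                g.drug not in drugs
                and (day - line_start).days > params.addition_window_days
                for g in group
            ) and j > i
            if new_late:
                end = (day - timedelta(days=1), NEW_DRUG)
                next_i = j
                break
            for g in group:
                drugs.add(g.drug)
                cov_end = day + timedelta(days=_supply(g, params) - 1)
                if cov_end > last_covered:
                    last_covered = cov_end
            j += 1

        if end is None:
            # terminal line: death, an observed trailing gap, or data end
            if observed_death is not None:
                end = (min(last_covered, observed_death), DEATH)
            elif (data_end - last_covered).days >= params.gap_days:
                end = (last_covered, GAP)
            else:
                end = (min(last_covered, data_end), DATA_END)
            next_i = len(day_groups)

        lines.append(
            TherapyLine(
                patient_id=pid,
                line_number=len(lines) + 1,
                start_date=line_start,
                end_date=end[0],
                drugs=frozenset(drugs),
                end_reason=end[1],
            )
        )
        assert next_i is not None and next_i > i
        i = next_i
    return lines


def classify_line(
    drugs: Iterable[str], dictionary: DrugDictionary | None = None
) -> str:
    """NA / CCNA / CA / SA from the drug categories present.

    Steroid presence never changes an NA/CCNA/CA call; SA means steroids
    only.
    """
    dictionary = dictionary or DrugDictionary.default()
    cats = {dictionary.categorize(d) for d in drugs}
    if not cats:
        raise ValueError("empty drug set")
    has_novel = DrugCategory.NOVEL_AGENT in cats
    has_chemo = DrugCategory.CHEMOTHERAPY in cats
    if has_novel and has_chemo:
        return "CCNA"
    if has_novel:
        return "NA"
    if has_chemo:
        return "CA"
    return "SA"


def name_regimen(
    drugs: Iterable[str], dictionary: DrugDictionary | None = None
) -> str:
    """First matching label of the published first-line regimen taxonomy.

    Melphalan triples/pairs are matched before the generic bortezomib +
    thalidomide rules so each printed row label is reachable; chemo-only
    regimens are split by how many distinct cytotoxics they contain.
    """
    dictionary = dictionary or DrugDictionary.default()
    ds = {d.strip().lower() for d in drugs}
    chemo = {d for d in ds if dictionary.categorize(d) is DrugCategory.CHEMOTHERAPY}
    novel = {d for d in ds if dictionary.categorize(d) is DrugCategory.NOVEL_AGENT}
    steroid = {d for d in ds if dictionary.categorize(d) is DrugCategory.STEROID}

    bor = "bortezomib" in ds
    thal = "thalidomide" in ds
    len_ = "lenalidomide" in ds
    mel = "melphalan" in ds
    other_chemo = chemo - {"melphalan"}

    if mel and bor and thal:
        return "Melphalan + bortezomib + thalidomide"
    if bor and thal:
        return "Bortezomib + Thalidomide + chemo" if chemo else "Bortezomib + Thalidomide"
    if mel and thal:
        return "Melphalan + thalidomide"
    if mel and bor:
        return "Melphalan + bortezomib"
    if thal:
        return "Thalidomide-based + chemo" if chemo else "Thalidomide-based"
    if bor:
        return "Bortezomib-based + chemo" if chemo else "Bortezomib-based"
    if len_:
        return "Lenalidomide-based"
    if chemo:
        if len(chemo) == 1:
            if mel:
                return "Melphalan-based"
            if "cyclophosphamide" in chemo:
                return "Cyclophosphamide-based"
            return "Other mono chemo"
        if len(chemo) == 2:
            return "Two-chemo combination"
        return "Three-chemo combination"
    if steroid:
        return "Steroid"
    return "other"


def classify_lines(
    lines: Sequence[TherapyLine], dictionary: DrugDictionary | None = None
) -> list[TherapyLine]:
    """Return lines with regimen_class and named_regimen filled in."""
    dictionary = dictionary or DrugDictionary.default()
    out = []
    for ln in lines:
        out.append(
            TherapyLine(
                patient_id=ln.patient_id,
                line_number=ln.line_number,
                start_date=ln.start_date,
                end_date=ln.end_date,
                drugs=ln.drugs,
                end_reason=ln.end_reason,
                regimen_class=classify_line(ln.drugs, dictionary),
                named_regimen=name_regimen(ln.drugs, dictionary),
            )
        )
    return out


def lines_frame(lines: Sequence[TherapyLine]) -> pd.DataFrame:
    """``lines.csv`` layout; drug sets rendered pipe-delimited and sorted."""
    return pd.DataFrame(
        [
            {
                "patient_id": ln.patient_id,
                "line_number": ln.line_number,
                "start_date": ln.start_date,
                "end_date": ln.end_date,
                "drugs": "|".join(sorted(ln.drugs)),
                "end_reason": ln.end_reason,
                "regimen_class": ln.regimen_class,
                "named_regimen": ln.named_regimen,
            }
            for ln in lines
        ]
    )
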