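"""Independent brute-force oracles used to validate the fast implementations.

These deliberately re-derive the rules in the most literal way possible:
the LOT oracle walks every calendar day tracking which days are covered,
and the CCI oracle enumerates the weight table group by group.  They share
no code with the implementations they check.
"""

from __future__ import annotations

from collections import defaultdict
from datetime import date, timedelta

from mmpathways.comorbidity import HIERARCHY, MALIGNANCY_GROUPS, DeyoMap
from mmpathways.records import normalize_icd9


def lot_day_scan(
    dispensings,
    index_date: date,
    death_date,
    data_end: date,
    gap_days: int = 60,
    addition_window_days: int = 90,
):
    """Day-by-day line-of-therapy simulation.

    Returns a list of (start, end, frozenset(drugs), reason) tuples.
    """
    disp = sorted(dispensings, key=lambda d: (d.dispense_date, d.drug, d.days_supply))
    if not disp:
        return []
    observed_death = (
        death_date if (death_date is not None and death_date <= data_end) else None
    )
    by_date = defaultdict(list)
    for d in disp:
        by_date[d.dispense_date].append(d)
    dates = sorted(by_date)

    lines = []
    di = 0  # next unconsumed dispensing day
    while di < len(dates):
        start = dates[di]
        drugs: set[str] = set()
        covered: set[date] = set()
        last_covered = start - timedelta(days=1)
        uncovered_run = 0
        day = start
        end = reason = None
        while end is None:
            if di < len(dates) and dates[di] == day:
                if uncovered_run >= gap_days:
                    end, reason = last_covered, "gap"
                    break
                group = by_date[day]
                if day != start and any(
                    g.drug not in drugs
                    and (day - start).days > addition_window_days
                    for g in group
                ):
                    end, reason = day - timedelta(days=1), "new_drug_after_90d"
                    break
                for g in group:
                    drugs.add(g.drug)
                    for k in range(g.days_supply):
                        covered.add(day + timedelta(days=k))
                di += 1
            if day in covered:
                last_covered = day
                uncovered_run = 0
            else:
                uncovered_run += 1
            if di >= len(dates):
                # endgame: no further dispensing anywhere
                max_cov = max(covered)
                if observed_death is not None:
                    end, reason = min(max_cov, observed_death), "death"
                elif uncovered_run >= gap_days:
                    end, reason = last_covered, "gap"
                elif day >= data_end:
                    end, reason = min(max_cov, data_end), "data_end"
            day += timedelta(days=1)
        lines.append((start, end, frozenset(drugs), reason))
    return lines


def cci_brute_force(
    diagnoses,
    index_date: date,
    window_days: int = 365,
    include_malignancy: bool = False,
) -> int:
    """Enumerate the Deyo weight table group by group over the window."""
    deyo = DeyoMap.default()
    start = index_date - timedelta(days=window_days)
    window_codes = [
        normalize_icd9(d.icd9)
        for d in diagnoses
        if start <= d.claim_date < index_date
    ]
    present = set()
    for cond, (prefixes, _) in deyo.groups.items():
        for code in window_codes:
            if any(code.startswith(p) for p in prefixes):
                present.add(cond)
                break
    for severe, mild in HIERARCHY.items():
        if severe in present and mild in present:
            present.remove(mild)
    if not include_malignancy:
        present -= set(MALIGNANCY_GROUPS)
    return sum(deyo.groups[c][1] for c in present)
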