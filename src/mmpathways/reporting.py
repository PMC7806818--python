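"""Paper-shaped summary tables with small-cell privacy suppression.

Two table builders mirror the published presentation: a demographics /
clinical-characteristics table (sex, age bands, follow-up, comorbidity,
CCI bands — columns per stratum x first-line class) and a first-line
named-regimen table.  Counts render as ``n (pct)`` with the column N as
denominator.

Privacy suppression follows the small-cell rule used for the published
tables: every non-zero count below the threshold (default 3) is masked,
together with its percentage.  Zeros render explicitly as ``0 (0.0)``.
The mask token is the self-describing ``"<3"`` rather than an asterisk.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Optional, Sequence

import pandas as pd

DEFAULT_MASK = "<3"

AGE_BANDS = (
    ("18-29", 18, 29),
    ("30-39", 30, 39),
    ("40-49", 40, 49),
    ("50-59", 50, 59),
    ("60-69", 60, 69),
    ("70-79", 70, 79),
    (">=80", 80, 200),
)

CLASS_ORDER = ("NA", "CCNA", "CA", "SA")

REGIMEN_ORDER = (
    "Melphalan + bortezomib + thalidomide",
    "Bortezomib + Thalidomide",
    "Bortezomib + Thalidomide + chemo",
    "Thalidomide-based",
    "Thalidomide-based + chemo",
    "Bortezomib-based",
    "Bortezomib-based + chemo",
    "Melphalan + thalidomide",
    "Melphalan + bortezomib",
    "Melphalan-based",
    "Cyclophosphamide-based",
    "Other mono chemo",
    "Two-chemo combination",
    "Three-chemo combination",
    "Lenalidomide-based",
    "Steroid",
    "other",
)


def age_band(age: int) -> str:
    for label, lo, hi in AGE_BANDS:
        if lo <= age <= hi:
            return label
    raise ValueError(f"age {age} outside all bands (cohort requires >= 18)")


@dataclass(frozen=True)
class Cell:
    """One table cell: a count (with percentage), a statistic, or text."""

    kind: str  # "count" | "stat" | "empty"
    count: Optional[int] = None
    pct: Optional[float] = None
    text: Optional[str] = None
    masked: bool = False

    def render(self, mask_token: str = DEFAULT_MASK) -> str:
        if self.masked:
            return mask_token
        if self.kind == "count":
            if self.pct is None:
                return str(self.count)
            return f"{self.count} ({self.pct:.1f})"
        if self.kind == "stat":
            return self.text or ""
        return ""


@dataclass(frozen=True)
class SummaryTable:
    """Row-label x column-label grid of :class:`Cell`."""

    rows: tuple[str, ...]
    columns: tuple[str, ...]
    cells: Mapping[tuple[str, str], Cell]
    mask_token: str = DEFAULT_MASK

    def cell(self, row: str, col: str) -> Cell:
        return self.cells.get((row, col), Cell("empty"))

    def to_frame(self) -> pd.DataFrame:
        data = {
            c: [self.cell(r, c).render(self.mask_token) for r in self.rows]
            for c in self.columns
        }
        return pd.DataFrame(data, index=list(self.rows))

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index_label="variable")


def suppress_small_counts(table: SummaryTable, threshold: int = 3) -> SummaryTable:
    """Mask every count cell with ``1 <= count < threshold``.

    Zeros and counts at/above the threshold are untouched; the masked
    cell's percentage is masked with it (one token replaces both).
    """
    new_cells = {}
    for key, cell in table.cells.items():
        if cell.kind == "count" and cell.count is not None and 1 <= cell.count < threshold:
            new_cells[key] = replace(cell, masked=True)
        else:
            new_cells[key] = cell
    return SummaryTable(table.rows, table.columns, new_cells, table.mask_token)


# ---------------------------------------------------------------------------
# Demographics table
# ---------------------------------------------------------------------------

_CANONICAL_VALUES = {
    "asct": (True, False),
    "first_line_class": CLASS_ORDER,
    "period": ("pre_bortezomib", "post_bortezomib"),
}


def _stratum_columns(df: pd.DataFrame, strata: Sequence[str]) -> list[tuple]:
    axes = []
    for key in strata:
        if key in _CANONICAL_VALUES:
            axes.append(list(_CANONICAL_VALUES[key]))
        else:
            axes.append(sorted(df[key].dropna().unique().tolist()))
    combos: list[tuple] = [()]
    for axis in axes:
        combos = [c + (v,) for c in combos for v in axis]
    return combos


def _column_label(strata: Sequence[str], combo: tuple) -> str:
    parts = []
    for key, val in zip(strata, combo):
        if key == "asct":
            parts.append("ASCT" if val else "no ASCT")
        else:
            parts.append(str(val))
    return " / ".join(parts)


def _count_cell(n: int, denom: int) -> Cell:
    pct = 100.0 * n / denom if denom else 0.0
    return Cell("count", count=n, pct=pct)


def demographics_table(
    cohort: pd.DataFrame,
    comorbidity: pd.DataFrame,
    lines: pd.DataFrame,
    strata: Sequence[str] = ("asct", "first_line_class"),
    period: Optional[str] = None,
) -> SummaryTable:
    """Demographics, follow-up and comorbidity by stratum x first-line class.

    ``cohort``/``comorbidity``/``lines`` are the stage output frames.  An
    empty stratum yields a column with N = 0 and explicit zero counts.
    """
    first = lines[lines["line_number"] == 1][["patient_id", "regimen_class"]].rename(
        columns={"regimen_class": "first_line_class"}
    )
    df = cohort.merge(first, on="patient_id", how="left").merge(
        comorbidity, on="patient_id", how="left"
    )
    if period is not None:
        df = df[df["period"] == period]

    combos = _stratum_columns(df, strata)
    columns = tuple(_column_label(strata, c) for c in combos)

    row_labels: list[str] = ["N", "Male", "Female"]
    row_labels += [f"Age {b[0]}" for b in AGE_BANDS]
    row_labels += [
        "Age mean (SD)",
        "Follow-up mean (SD)",
        "Follow-up median (min-max)",
        "Follow-up Q1, Q3",
        "Renal impairment",
        "Anemia",
        "Bone fracture",
        "Pneumonia",
        "Mean CCI (SD)",
        "CCI = 0",
        "CCI = 1",
        "CCI = 2",
        "CCI >= 3",
    ]

    cells: dict[tuple[str, str], Cell] = {}
    for combo, col in zip(combos, columns):
        sub = df
        for key, val in zip(strata, combo):
            sub = sub[sub[key] == val]
        n = len(sub)
        cells[("N", col)] = Cell("count", count=n, pct=None)
        for sex_label, sex in (("Male", "male"), ("Female", "female")):
            cells[(sex_label, col)] = _count_cell(int((sub["sex"] == sex).sum()), n)
        for label, lo, hi in AGE_BANDS:
            k = int(sub["age_at_dx"].between(lo, hi).sum())
            cells[(f"Age {label}", col)] = _count_cell(k, n)

        def stat(text: str) -> Cell:
            return Cell("stat", text=text)

        if n:
            age = sub["age_at_dx"].astype(float)
            fu = sub["followup_years"].astype(float)
            cells[("Age mean (SD)", col)] = stat(f"{age.mean():.1f} ({age.std(ddof=1):.1f})" if n > 1 else f"{age.mean():.1f} (0.0)")
            cells[("Follow-up mean (SD)", col)] = stat(
                f"{fu.mean():.2f} ({fu.std(ddof=1):.2f})" if n > 1 else f"{fu.mean():.2f} (0.00)"
            )
            cells[("Follow-up median (min-max)", col)] = stat(
                f"{fu.median():.2f} ({fu.min():.2f}-{fu.max():.2f})"
            )
            cells[("Follow-up Q1, Q3", col)] = stat(
                f"{fu.quantile(0.25):.2f}, {fu.quantile(0.75):.2f}"
            )
        for row, flag in (
            ("Renal impairment", "renal"),
            ("Anemia", "anemia"),
            ("Bone fracture", "fracture"),
            ("Pneumonia", "pneumonia"),
        ):
            k = int(sub[flag].fillna(False).astype(bool).sum()) if n else 0
            cells[(row, col)] = _count_cell(k, n)
        if n and sub["cci"].notna().any():
            cci = sub["cci"].astype(float)
            cells[("Mean CCI (SD)", col)] = stat(
                f"{cci.mean():.1f} ({cci.std(ddof=1):.1f})" if n > 1 else f"{cci.mean():.1f} (0.0)"
            )
        for band in ("0", "1", "2", "3+"):
            row = f"CCI >= 3" if band == "3+" else f"CCI = {band}"
            k = int((sub["cci_band"].astype(str) == band).sum()) if n else 0
            cells[(row, col)] = _count_cell(k, n)

    return SummaryTable(tuple(row_labels), columns, cells)


# ---------------------------------------------------------------------------
# First-line regimen table
# ---------------------------------------------------------------------------


def regimen_table(
    lines: pd.DataFrame,
    cohort: pd.DataFrame,
    strata: Sequence[str] = ("period", "asct"),
    line_number: int = 1,
) -> SummaryTable:
    """Named-regimen counts for one line number, by stratum."""
    sel = lines[lines["line_number"] == line_number][
        ["patient_id", "named_regimen"]
    ].merge(cohort, on="patient_id", how="inner")

    combos = _stratum_columns(sel, strata)
    columns = tuple(_column_label(strata, c) for c in combos)
    observed = set(sel["named_regimen"].unique())
    regimens = [r for r in REGIMEN_ORDER if r in observed]

    rows = ("N", *regimens)
    cells: dict[tuple[str, str], Cell] = {}
    for combo, col in zip(combos, columns):
        sub = sel
        for key, val in zip(strata, combo):
            sub = sub[sub[key] == val]
        n = len(sub)
        cells[("N", col)] = Cell("count", count=n, pct=None)
        for reg in regimens:
            k = int((sub["named_regimen"] == reg).sum())
            cells[(reg, col)] = _count_cell(k, n)
    return SummaryTable(rows, columns, cells)
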