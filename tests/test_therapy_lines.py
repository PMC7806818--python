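"""Line-of-therapy construction against hand-traces and the day-scan oracle."""

from __future__ import annotations

from datetime import date, timedelta

import numpy as np
import pytest

from mmpathways.therapy_lines import (
    DATA_END,
    DEATH,
    GAP,
    NEW_DRUG,
    LotParams,
    build_lines,
    classify_line,
    coverage_intervals,
    name_regimen,
)
from _oracles import lot_day_scan
from conftest import ORIGIN, disp

FAR_END = ORIGIN + timedelta(days=4000)


def day(n: int) -> date:
    return ORIGIN + timedelta(days=n)


class TestCoverageIntervals:
    def test_single_dispensing_arithmetic(self):
        iv = coverage_intervals([disp(0, "thalidomide", 30)])
        assert iv == {"thalidomide": [(day(0), day(29))]}

    def test_adjacent_intervals_merge(self):
        iv = coverage_intervals([disp(0, "thalidomide", 30), disp(30, "thalidomide", 30)])
        assert iv["thalidomide"] == [(day(0), day(59))]

    def test_disjoint_intervals_stay_split(self):
        iv = coverage_intervals([disp(0, "thalidomide", 30), disp(60, "thalidomide", 30)])
        assert iv["thalidomide"] == [(day(0), day(29)), (day(60), day(89))]


class TestBuildLines:
    def test_gap_then_new_agent(self):
        """Six monthly thalidomide fills, 90 days silence, then bortezomib."""
        d = [disp(30 * k, "thalidomide", 28) for k in range(6)]
        # last coverage ends day 177; bortezomib at day 270 after a 92-day gap
        d.append(disp(270, "bortezomib", 28))
        lines = build_lines(d, ORIGIN, None, FAR_END)
        assert len(lines) == 2
        assert lines[0].drugs == {"thalidomide"}
        assert lines[0].end_reason == GAP
        assert lines[0].end_date == day(177)
        assert lines[1].drugs == {"bortezomib"}
        assert lines[1].start_date == day(270)

    def test_early_addition_extends_line(self):
        """A drug added on day 45 joins the line."""
        d = [disp(0, "bortezomib", 60), disp(45, "thalidomide", 60), disp(60, "bortezomib", 60)]
        lines = build_lines(d, ORIGIN, None, FAR_END)
        assert len(lines) == 1
        assert lines[0].drugs == {"bortezomib", "thalidomide"}

    def test_late_new_drug_opens_line(self):
        """Continuous bortezomib; lenalidomide first dispensed on day 120."""
        d = [disp(k, "bortezomib", 30) for k in (0, 30, 60, 90, 120, 150)]
        d.append(disp(120, "lenalidomide", 30))
        lines = build_lines(d, ORIGIN, None, FAR_END)
        assert len(lines) == 2
        assert lines[0].drugs == {"bortezomib"}
        assert lines[0].end_date == day(119)
        assert lines[0].end_reason == NEW_DRUG
        assert lines[1].start_date == day(120)
        # bortezomib is still being dispensed on/after the switch day
        assert lines[1].drugs == {"bortezomib", "lenalidomide"}

    def test_death_ends_line(self):
        d = [disp(0, "melphalan", 30)]
        lines = build_lines(d, ORIGIN, day(20), FAR_END)
        assert lines[0].end_reason == DEATH and lines[0].end_date == day(20)

    def test_death_in_trailing_gap_attributed_to_line(self):
        d = [disp(0, "melphalan", 30)]
        lines = build_lines(d, ORIGIN, day(200), FAR_END)
        assert lines[0].end_reason == DEATH and lines[0].end_date == day(29)

    def test_data_end_without_observable_gap(self):
        d = [disp(0, "melphalan", 30)]
        lines = build_lines(d, ORIGIN, None, day(50))
        assert lines[0].end_reason == DATA_END and lines[0].end_date == day(29)

    def test_dispensing_before_index_is_error(self):
        with pytest.raises(ValueError, match="index"):
            build_lines([disp(0, "melphalan", 30)], day(10), None, FAR_END)

    def test_redispensing_never_opens_line(self):
        d = [disp(k, "thalidomide", 28) for k in (0, 28, 56, 84, 112, 140, 168, 196)]
        lines = build_lines(d, ORIGIN, None, FAR_END)
        assert len(lines) == 1

    def test_infinite_params_give_single_line(self):
        rng = np.random.default_rng(1)
        days = np.cumsum(rng.integers(1, 200, size=8))
        drugs = ["bortezomib", "melphalan", "dexamethasone"]
        d = [
            disp(int(t), drugs[int(rng.integers(0, 3))], int(rng.integers(1, 60)))
            for t in days
        ]
        params = LotParams(gap_days=10**6, addition_window_days=10**6)
        lines = build_lines(d, ORIGIN, None, FAR_END, params)
        assert len(lines) == 1

    def test_duplicated_rows_change_nothing(self):
        d = [disp(0, "bortezomib", 30), disp(75, "bortezomib", 30), disp(200, "melphalan", 30)]
        base = build_lines(d, ORIGIN, None, FAR_END)
        doubled = build_lines(d + [d[1]], ORIGIN, None, FAR_END)
        assert [(l.start_date, l.end_date, l.drugs, l.end_reason) for l in base] == [
            (l.start_date, l.end_date, l.drugs, l.end_reason) for l in doubled
        ]

    def test_every_dispensing_attributed_to_one_line(self):
        rng = np.random.default_rng(7)
        drugs = ["bortezomib", "melphalan", "dexamethasone"]
        for _ in range(100):
            t = 0
            d = []
            for k in range(int(rng.integers(1, 11))):
                t += int(rng.integers(1, 201)) if k else 0
                d.append(disp(t, drugs[int(rng.integers(0, 3))], int(rng.integers(1, 61))))
            lines = build_lines(d, ORIGIN, None, FAR_END)
            starts = [l.start_date for l in lines]
            assert starts == sorted(set(starts))
            covered = 0
            for rec in d:
                owners = [
                    l
                    for l in lines
                    if l.start_date <= rec.dispense_date
                    and (l is lines[-1] or rec.dispense_date < lines[lines.index(l) + 1].start_date)
                ]
                assert len(owners) == 1
                covered += 1
            assert covered == len(d)

    def test_matches_day_scan_oracle_randomized(self):
        rng = np.random.default_rng(99)
        drugs = ["bortezomib", "melphalan", "dexamethasone"]
        for _ in range(200):
            t = 0
            d = []
            for k in range(int(rng.integers(1, 11))):
                t += int(rng.integers(1, 201)) if k else 0
                d.append(disp(t, drugs[int(rng.integers(0, 3))], int(rng.integers(1, 61))))
            death = day(t + int(rng.integers(0, 300))) if rng.random() < 0.3 else None
            data_end = day(t + 400)
            got = build_lines(d, ORIGIN, death, data_end)
            expected = lot_day_scan(d, ORIGIN, death, data_end)
            assert [(l.start_date, l.end_date, l.drugs, l.end_reason) for l in got] == expected


class TestClassification:
    @pytest.mark.parametrize(
        "drugs,cls",
        [
            ({"bortezomib", "thalidomide", "dexamethasone"}, "NA"),
            ({"melphalan", "thalidomide"}, "CCNA"),
            ({"dexamethasone"}, "SA"),
            ({"melphalan", "prednisolone"}, "CA"),
            ({"lenalidomide"}, "NA"),
            ({"cyclophosphamide", "vincristine"}, "CA"),
        ],
    )
    def test_classes(self, drugs, cls):
        assert classify_line(drugs) == cls

    def test_empty_set_errors(self):
        with pytest.raises(ValueError):
            classify_line(set())

    @pytest.mark.parametrize(
        "drugs,label",
        [
            ({"bortezomib", "thalidomide"}, "Bortezomib + Thalidomide"),
            ({"bortezomib", "thalidomide", "cyclophosphamide"}, "Bortezomib + Thalidomide + chemo"),
            ({"melphalan", "bortezomib", "thalidomide"}, "Melphalan + bortezomib + thalidomide"),
            ({"melphalan", "thalidomide"}, "Melphalan + thalidomide"),
            ({"melphalan", "bortezomib"}, "Melphalan + bortezomib"),
            ({"thalidomide", "dexamethasone"}, "Thalidomide-based"),
            ({"thalidomide", "cisplatin"}, "Thalidomide-based + chemo"),
            ({"bortezomib"}, "Bortezomib-based"),
            ({"melphalan", "prednisolone"}, "Melphalan-based"),
            ({"cyclophosphamide"}, "Cyclophosphamide-based"),
            ({"etoposide"}, "Other mono chemo"),
            ({"cyclophosphamide", "vincristine"}, "Two-chemo combination"),
            ({"cyclophosphamide", "vincristine", "etoposide"}, "Three-chemo combination"),
            ({"dexamethasone"}, "Steroid"),
            ({"lenalidomide", "dexamethasone"}, "Lenalidomide-based"),
        ],
    )
    def test_named_regimens(self, drugs, label):
        assert name_regimen(drugs) == label
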