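"""Cohort selection: index dates, eras, follow-up, ASCT and exclusions."""

from __future__ import annotations

import random
from datetime import date, timedelta

import pytest

from mmpathways.cohort import (
    CohortConfig,
    POST_BORTEZOMIB,
    PRE_BORTEZOMIB,
    apply_selection,
    assign_period,
    compute_followup,
    find_index_date,
    flag_asct,
)
from mmpathways.records import ClaimsBundle, DeathRecord, ProcedureClaim
from mmpathways.simulate import default_config, simulate_bundle
from conftest import dx


class TestIndexDate:
    def test_earliest_mm_claim_wins(self):
        claims = [dx(0, "203.00", origin=date(2013, 4, 2)), dx(0, "203.01", origin=date(2013, 1, 15))]
        assert find_index_date(claims) == date(2013, 1, 15)

    def test_no_mm_code_gives_none(self):
        assert find_index_date([dx(0, "250.00")]) is None

    def test_position_does_not_gate_index(self):
        claims = [
            dx(0, "203", "secondary", origin=date(2010, 6, 1)),
            dx(0, "203.0", "primary", origin=date(2010, 5, 20)),
        ]
        assert find_index_date(claims) == date(2010, 5, 20)

    @pytest.mark.parametrize("code", ["203.1", "203.10", "203.8", "204.0"])
    def test_non_index_plasma_codes_ignored(self, code):
        assert find_index_date([dx(0, code)]) is None


class TestPeriod:
    @pytest.mark.parametrize(
        "d,expected",
        [
            (date(2012, 5, 31), PRE_BORTEZOMIB),
            (date(2012, 6, 1), POST_BORTEZOMIB),
            (date(2007, 1, 1), PRE_BORTEZOMIB),
            (date(2015, 12, 31), POST_BORTEZOMIB),
        ],
    )
    def test_boundary(self, d, expected):
        assert assign_period(d) == expected

    def test_out_of_window_errors(self):
        with pytest.raises(ValueError):
            assign_period(date(2016, 1, 1))


class TestFollowup:
    def test_exact_year_death(self):
        end, years, died = compute_followup(
            date(2015, 1, 1), DeathRecord("P1", date(2016, 1, 1)), None
        )
        assert (end, died) == (date(2016, 1, 1), True)
        assert years == pytest.approx(1.0, abs=0.002)

    def test_censored_at_study_end(self):
        end, years, died = compute_followup(date(2015, 1, 1), None, None)
        assert end == date(2017, 12, 31) and not died

    def test_zero_length_followup(self):
        end, years, died = compute_followup(date(2017, 12, 31), None, None)
        assert years == 0.0

    def test_disenrolment_cuts_followup(self):
        end, _, died = compute_followup(date(2015, 1, 1), None, date(2016, 6, 30))
        assert end == date(2016, 6, 30) and not died

    def test_death_before_index_is_corrupt(self):
        with pytest.raises(ValueError, match="death"):
            compute_followup(date(2015, 1, 1), DeathRecord("P1", date(2014, 1, 1)), None)


class TestAsct:
    def test_no_claims(self):
        assert flag_asct(date(2013, 1, 1), []) == (False, None)

    def test_first_post_index_asct(self):
        idx = date(2013, 1, 1)
        procs = [ProcedureClaim("P1", idx + timedelta(days=300))]
        assert flag_asct(idx, procs) == (True, idx + timedelta(days=300))

    def test_pre_index_asct_ignored(self):
        idx = date(2013, 1, 1)
        procs = [ProcedureClaim("P1", idx - timedelta(days=10))]
        assert flag_asct(idx, procs) == (False, None)


class TestSelection:
    def test_insufficient_lookback_excluded(self):
        bundle, truth = simulate_bundle(
            default_config(n_patients=1, seed=2, exclusion_plants={"insufficient_lookback": 1})
        )
        members, log = apply_selection(bundle)
        assert members == []
        assert [e.rule for e in log if e.primary] == ["insufficient_lookback"]

    def test_pcl_within_two_months_excluded(self):
        bundle, _ = simulate_bundle(
            default_config(
                n_patients=1, seed=3, exclusion_plants={"plasma_cell_leukemia_within_2mo": 1}
            )
        )
        members, log = apply_selection(bundle)
        assert members == []
        assert log[0].rule == "plasma_cell_leukemia_within_2mo"

    def test_planted_violations_recovered_exactly(self):
        plants = {
            "underage": 2,
            "insufficient_lookback": 2,
            "prior_cancer": 2,
            "plasma_cell_leukemia_within_2mo": 2,
            "no_mm_visit_after_index": 1,
            "untreated": 1,
        }
        bundle, truth = simulate_bundle(
            default_config(n_patients=100, seed=4, exclusion_plants=plants)
        )
        members, log = apply_selection(bundle)
        assert len(members) == 90
        primary = {e.patient_id: e.rule for e in log if e.primary}
        planted = {p.patient_id: p.excluded_rule for p in truth.patients if p.excluded_rule}
        assert primary == planted

    def test_partition_and_order_independence(self):
        bundle, _ = simulate_bundle(
            default_config(n_patients=80, seed=6, exclusion_plants={"untreated": 4})
        )
        members, log = apply_selection(bundle)
        member_ids = {m.patient_id for m in members}
        excluded_ids = {e.patient_id for e in log}
        assert not member_ids & excluded_ids
        assert len(member_ids) + len(excluded_ids) == len(bundle.patients)

        rng = random.Random(0)
        shuffled = ClaimsBundle(
            patients=rng.sample(bundle.patients, len(bundle.patients)),
            diagnoses=rng.sample(bundle.diagnoses, len(bundle.diagnoses)),
            dispensings=rng.sample(bundle.dispensings, len(bundle.dispensings)),
            procedures=rng.sample(bundle.procedures, len(bundle.procedures)),
            deaths=rng.sample(bundle.deaths, len(bundle.deaths)),
        )
        members2, _ = apply_selection(shuffled)
        assert members2 == members

    def test_lookback_relaxation_is_monotone(self):
        bundle, _ = simulate_bundle(
            default_config(n_patients=60, seed=8, exclusion_plants={"insufficient_lookback": 5})
        )
        strict, _ = apply_selection(bundle, CohortConfig(lookback_days=365))
        relaxed, _ = apply_selection(bundle, CohortConfig(lookback_days=0))
        assert {m.patient_id for m in strict} <= {m.patient_id for m in relaxed}
        assert len(relaxed) == 60

    def test_member_fields_consistent(self):
        bundle, truth = simulate_bundle(default_config(n_patients=50, seed=10))
        members, _ = apply_selection(bundle)
        by_truth = {p.patient_id: p for p in truth.patients}
        for m in members:
            t = by_truth[m.patient_id]
            assert m.index_date == t.index_date
            assert m.period == t.period
            assert m.asct == t.asct
            assert m.age_at_dx == t.age
            assert m.age_at_dx >= 18
            assert m.followup_end == t.followup_end
            assert m.died == (t.death_date is not None)
            assert m.index_date <= m.followup_end <= date(2017, 12, 31)

    def test_censor_before_study_start_fatal(self):
        with pytest.raises(ValueError):
            CohortConfig(censor_date=date(2006, 1, 1))
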