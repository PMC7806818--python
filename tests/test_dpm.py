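"""Journeys, empirical Markov estimation, durations and Sankey structure."""

from __future__ import annotations

from datetime import date, timedelta

import pytest

from mmpathways.dpm import (
    DiseaseProgressionModel,
    JourneyState,
    PatientJourney,
    build_journey,
    check_flow_conservation,
    estimate_transitions,
    summarize_durations,
    to_sankey,
)
from mmpathways.therapy_lines import TherapyLine
from conftest import ORIGIN

D = lambda n: ORIGIN + timedelta(days=n)


def line(k: int, start: int, end: int, pid: str = "P1") -> TherapyLine:
    return TherapyLine(pid, k, D(start), D(end), frozenset({"bortezomib"}), "gap")


def journey(states, dates=None, pid="P", **strata) -> PatientJourney:
    states = tuple(JourneyState(s) for s in states)
    if dates is None:
        dates = tuple(D(30 * k) for k in range(len(states)))
    return PatientJourney(pid, states, tuple(dates), strata)


class TestBuildJourney:
    def test_single_line_alive(self):
        j = build_journey([line(1, 0, 100)], None, D(400))
        assert [s.value for s in j.states] == ["L1", "CONTINUE"]
        assert j.dates == (D(0), D(400))

    def test_two_lines_then_death(self):
        j = build_journey([line(1, 0, 100), line(2, 150, 300)], D(320), D(320))
        assert [s.value for s in j.states] == ["L1", "L2", "DEATH"]

    def test_four_lines_fold_into_l3(self):
        lines = [line(1, 0, 90), line(2, 100, 190), line(3, 200, 290), line(4, 300, 390)]
        j = build_journey(lines, None, D(500))
        assert [s.value for s in j.states] == ["L1", "L2", "L3", "CONTINUE"]

    def test_death_after_line_3_attributed_to_l3(self):
        lines = [line(1, 0, 90), line(2, 100, 190), line(3, 200, 290), line(4, 300, 390)]
        j = build_journey(lines, D(420), D(420))
        assert j.states[-1] is JourneyState.DEATH and j.dates[-1] == D(420)

    def test_death_before_first_line_is_error(self):
        with pytest.raises(ValueError, match="death"):
            build_journey([line(1, 10, 100)], D(5), D(100))


class TestEstimation:
    def test_degenerate_all_continue(self):
        js = [journey(["L1", "CONTINUE"], pid=f"P{i}") for i in range(10)]
        t = estimate_transitions(js)
        assert t.loc[0, "probability"] == 1.0 and t.loc[0, "n_at_risk"] == 10

    def test_simple_counting(self):
        js = (
            [journey(["L1", "L2", "CONTINUE"], pid=f"A{i}") for i in range(6)]
            + [journey(["L1", "DEATH"], pid=f"B{i}") for i in range(3)]
            + [journey(["L1", "CONTINUE"], pid=f"C{i}") for i in range(1)]
        )
        t = estimate_transitions(js)
        l1 = t[t["src"] == "L1"].set_index("dst")["probability"]
        assert l1["L2"] == pytest.approx(0.6)
        assert l1["DEATH"] == pytest.approx(0.3)
        assert l1["CONTINUE"] == pytest.approx(0.1)

    def test_rows_sum_to_one(self):
        js = [journey(["L1", "L2", "L3", "DEATH"], pid=f"P{i}") for i in range(4)] + [
            journey(["L1", "DEATH"], pid=f"Q{i}") for i in range(3)
        ]
        t = estimate_transitions(js)
        sums = t.groupby("src")["probability"].sum()
        assert (abs(sums - 1.0) < 1e-9).all()

    def test_pooled_equals_sum_over_strata(self):
        js = [
            journey(["L1", "L2", "CONTINUE"], pid=f"P{i}", arm="a" if i % 2 else "b")
            for i in range(8)
        ] + [journey(["L1", "DEATH"], pid=f"Q{i}", arm="a") for i in range(4)]
        pooled = estimate_transitions(js)
        strat = estimate_transitions(js, strata=("arm",))
        merged = strat.groupby(["src", "dst"])["count"].sum()
        for _, row in pooled.iterrows():
            assert merged[(row["src"], row["dst"])] == row["count"]

    def test_empty_journeys_empty_table(self):
        assert estimate_transitions([]).empty


class TestDurations:
    def test_unit_conversion(self):
        j = journey(["L1", "L2", "CONTINUE"], dates=(D(0), D(365), D(500)))
        d = summarize_durations([j])
        assert d.loc[0, "transition"] == "L1->L2"
        assert d.loc[0, "median"] == pytest.approx(365 / 30.4375, abs=1e-9)
        assert d.loc[0, "median"] == pytest.approx(12.0, abs=0.01)

    def test_odd_count_median(self):
        js = [
            journey(["L1", "L2", "CONTINUE"], dates=(D(0), D(t), D(900)), pid=f"P{t}")
            for t in (30, 61, 91)
        ]
        d = summarize_durations(js)
        assert d.loc[0, "n"] == 3
        assert d.loc[0, "median"] == pytest.approx(2.0, abs=0.01)
        assert d.loc[0, "min"] <= d.loc[0, "median"] <= d.loc[0, "max"]

    def test_absorbing_transitions_excluded(self):
        js = [journey(["L1", "DEATH"], pid="P1")]
        assert summarize_durations(js).empty


class TestSankey:
    def test_single_state_graph(self):
        js = [journey(["L1", "CONTINUE"], pid=f"P{i}") for i in range(5)]
        g = to_sankey(estimate_transitions(js))
        assert len(g.nodes) == 2 and len(g.links) == 1
        assert g.links[0]["count"] == 5 and g.links[0]["pct"] == 100.0

    def test_branch_percentages(self):
        js = (
            [journey(["L1", "L2", "CONTINUE"], pid=f"A{i}") for i in range(6)]
            + [journey(["L1", "DEATH"], pid=f"B{i}") for i in range(3)]
            + [journey(["L1", "CONTINUE"], pid=f"C{i}") for i in range(1)]
        )
        g = to_sankey(estimate_transitions(js))
        pct = {(l["source"], l["target"]): l["pct"] for l in g.links}
        assert pct[("L1@0", "L2@1")] == 60.0
        assert pct[("L1@0", "DEATH@1")] == 30.0
        assert pct[("L1@0", "CONTINUE@1")] == 10.0

    def test_flow_conservation_audited(self):
        js = [journey(["L1", "L2", "L3", "DEATH"], pid=f"P{i}") for i in range(4)] + [
            journey(["L1", "L2", "CONTINUE"], pid=f"Q{i}") for i in range(3)
        ] + [journey(["L1", "DEATH"], pid=f"R{i}") for i in range(2)]
        g = to_sankey(estimate_transitions(js))
        check_flow_conservation(g)  # must not raise
        assert g.inflow("L2@1") == g.outflow("L2@1") == 7

    def test_stratified_table_rejected(self):
        js = [journey(["L1", "CONTINUE"], pid="P1", arm="a")]
        with pytest.raises(ValueError, match="stratified"):
            to_sankey(estimate_transitions(js, strata=("arm",)))


class TestModelResults:
    def test_fit_and_summary(self):
        js = [
            journey(["L1", "L2", "CONTINUE"], pid=f"P{i}", arm="a") for i in range(5)
        ] + [journey(["L1", "DEATH"], pid=f"Q{i}", arm="b") for i in range(5)]
        res = DiseaseProgressionModel(js, strata=("arm",)).fit()
        assert res.probability("L1", "L2", arm="a") == 1.0
        assert res.probability("L1", "DEATH", arm="b") == 1.0
        text = res.summary()
        assert "arm=a" in text and "100.0%" in text
        sankeys = res.sankey_bundle()
        assert set(sankeys) == {"arm=a", "arm=b"}

    def test_plot_sankey_runs(self, tmp_path):
        import matplotlib

        matplotlib.use("Agg")
        js = [journey(["L1", "L2", "CONTINUE"], pid=f"P{i}") for i in range(4)]
        ax = DiseaseProgressionModel(js).fit().plot_sankey()
        ax.figure.savefig(tmp_path / "sankey.png")
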