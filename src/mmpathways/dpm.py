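"""Markov disease-progression model (DPM) over treatment lines.

Each patient's journey is an ordered walk over the states

    L1 -> L2 -> L3 -> {DEATH, CONTINUE}

where L1..L3 are the first three lines of therapy (lines beyond the third
are folded into L3 occupancy), DEATH is death before starting the next
line, and CONTINUE means the patient was still on the current line at the
end of follow-up.  DEATH and CONTINUE are absorbing.

The Markov model is estimated empirically: for every source state the
transition probabilities are the multinomial maximum-likelihood fractions
``count(src -> dst) / n_at_risk(src)``, with binomial standard errors.
No time-homogeneous rate matrix is fitted — the published presentation is
branch percentages plus median inter-line durations (sojourn times), so
that is what the results object carries.  Estimation can be stratified,
typically by diagnosis period x ASCT status x first-line class.

``DiseaseProgressionModel(journeys).fit()`` returns a :class:`DPMResults`
with the transition table, duration summaries, a ``summary()`` report and
Sankey export (JSON structure or a matplotlib rendering).
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .therapy_lines import TherapyLine

DAYS_PER_MONTH = 30.4375  # 365.25 / 12, used for every month conversion

MAX_LINE = 3


class JourneyState(str, enum.Enum):
    L1 = "L1"
    L2 = "L2"
    L3 = "L3"
    DEATH = "DEATH"
    CONTINUE = "CONTINUE"

    @property
    def absorbing(self) -> bool:
        return self in (JourneyState.DEATH, JourneyState.CONTINUE)


LINE_STATES = (JourneyState.L1, JourneyState.L2, JourneyState.L3)


@dataclass(frozen=True, slots=True)
class PatientJourney:
    """Ordered state path of one patient plus stratum annotations.

    ``dates[k]`` is the entry date into ``states[k]`` (line start dates;
    death date for DEATH; follow-up end for CONTINUE).
    """

    patient_id: str
    states: tuple[JourneyState, ...]
    dates: tuple[date, ...]
    strata: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.states or self.states[0] is not JourneyState.L1:
            raise ValueError("journey must start at L1")
        if not self.states[-1].absorbing:
            raise ValueError("journey must end in DEATH or CONTINUE")
        if len(self.states) != len(self.dates):
            raise ValueError("states and dates differ in length")


def build_journey(
    lines: Sequence[TherapyLine],
    death_date: Optional[date],
    followup_end: date,
    patient_id: str | None = None,
    strata: Mapping[str, object] | None = None,
) -> PatientJourney:
    """Journey from a patient's ordered therapy lines and vital status.

    Lines beyond the third are folded into L3 occupancy; death after line
    3 (or during any later line) is attributed to L3.
    """
    if not lines:
        raise ValueError("cannot build a journey without at least one line")
    pid = patient_id or lines[0].patient_id
    died = death_date is not None and death_date <= followup_end
    if died and death_date < lines[0].start_date:
        raise ValueError("death before first-line start (cohort requires treatment)")

    n_line_states = min(len(lines), MAX_LINE)
    states = list(LINE_STATES[:n_line_states])
    dates = [lines[k].start_date for k in range(n_line_states)]
    if died:
        states.append(JourneyState.DEATH)
        dates.append(death_date)
    else:
        states.append(JourneyState.CONTINUE)
        dates.append(followup_end)
    return PatientJourney(
        patient_id=pid,
        states=tuple(states),
        dates=tuple(dates),
        strata=dict(strata or {}),
    )


def _transition_records(
    journeys: Iterable[PatientJourney], strata: Sequence[str]
) -> pd.DataFrame:
    recs = []
    for j in journeys:
        keys = {k: j.strata.get(k) for k in strata}
        for src, dst, d_src, d_dst in zip(
            j.states[:-1], j.states[1:], j.dates[:-1], j.dates[1:]
        ):
            recs.append(
                {
                    **keys,
                    "patient_id": j.patient_id,
                    "src": src.value,
                    "dst": dst.value,
                    "months": (d_dst - d_src).days / DAYS_PER_MONTH,
                }
            )
    return pd.DataFrame(recs)


def estimate_transitions(
    journeys: Sequence[PatientJourney],
    strata: Sequence[str] = (),
) -> pd.DataFrame:
    """Multinomial MLE transition table, optionally stratified.

    Columns: stratum keys, src, dst, count, n_at_risk, probability, se.
    Per-source probabilities sum to 1 within each stratum.  An empty
    journey list yields an empty table.
    """
    recs = _transition_records(journeys, strata)
    if recs.empty:
        return pd.DataFrame(
            columns=[*strata, "src", "dst", "count", "n_at_risk", "probability", "se"]
        )
    keys = [*strata, "src"]
    counts = (
        recs.groupby([*keys, "dst"], dropna=False, observed=True)
        .size()
        .rename("count")
        .reset_index()
    )
    at_risk = (
        recs.groupby(keys, dropna=False, observed=True)
        .size()
        .rename("n_at_risk")
        .reset_index()
    )
    table = counts.merge(at_risk, on=keys)
    table["probability"] = table["count"] / table["n_at_risk"]
    table["se"] = np.sqrt(
        table["probability"] * (1 - table["probability"]) / table["n_at_risk"]
    )
    order = {s.value: i for i, s in enumerate(JourneyState)}
    table = table.sort_values(
        [*strata, "src", "dst"],
        key=lambda col: col.map(order) if col.name in ("src", "dst") else col,
    ).reset_index(drop=True)
    return table


def summarize_durations(
    journeys: Sequence[PatientJourney],
    strata: Sequence[str] = (),
) -> pd.DataFrame:
    """Months between consecutive line starts (L1->L2, L2->L3) per stratum.

    ``months = days / 30.4375``.  Transitions into DEATH/CONTINUE are not
    durations between lines and are excluded.
    """
    recs = _transition_records(journeys, strata)
    if recs.empty:
        return pd.DataFrame(
            columns=[*strata, "transition", "n", "mean", "median", "q1", "q3", "min", "max"]
        )
    line_moves = recs[
        recs["src"].isin([s.value for s in LINE_STATES])
        & recs["dst"].isin([s.value for s in LINE_STATES])
    ].copy()
    if line_moves.empty:
        return pd.DataFrame(
            columns=[*strata, "transition", "n", "mean", "median", "q1", "q3", "min", "max"]
        )
    line_moves["transition"] = line_moves["src"] + "->" + line_moves["dst"]
    g = line_moves.groupby([*strata, "transition"], dropna=False, observed=True)["months"]
    out = g.agg(
        n="size",
        mean="mean",
        median="median",
        q1=lambda s: s.quantile(0.25),
        q3=lambda s: s.quantile(0.75),
        min="min",
        max="max",
    ).reset_index()
    return out


# ---------------------------------------------------------------------------
# Sankey
# ---------------------------------------------------------------------------

NODE_LABELS = {
    "L1": "First-line",
    "L2": "Second-line",
    "L3": "Third-line",
    "DEATH": "Death",
    "CONTINUE": "Continue",
}


@dataclass(frozen=True)
class SankeyGraph:
    """Renderer-agnostic Sankey structure.

    ``nodes``: ``{"id", "label", "depth"}``; ``links``: ``{"source",
    "target", "count", "pct"}`` where pct is the branch percentage out of
    the source node.  Flow is conserved at every non-absorbing node.
    """

    nodes: tuple[dict, ...]
    links: tuple[dict, ...]

    def to_dict(self) -> dict:
        return {"nodes": list(self.nodes), "links": list(self.links)}

    def to_json(self, path: Path | str | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text

    def inflow(self, node_id: str) -> int:
        return sum(l["count"] for l in self.links if l["target"] == node_id)

    def outflow(self, node_id: str) -> int:
        return sum(l["count"] for l in self.links if l["source"] == node_id)


def to_sankey(transition_table: pd.DataFrame) -> SankeyGraph:
    """Sankey graph from a single-stratum transition table.

    States are laid out by depth: L1 at 0, L2 at 1, L3 at 2; each DEATH /
    CONTINUE outcome becomes its own node at ``source depth + 1`` so the
    branch structure of the published figures is preserved.
    """
    if transition_table.empty:
        return SankeyGraph(nodes=(), links=())
    extra = set(transition_table.columns) - {
        "src",
        "dst",
        "count",
        "n_at_risk",
        "probability",
        "se",
    }
    if extra:
        raise ValueError(
            f"transition table still stratified by {sorted(extra)}; "
            "select one stratum before building a Sankey"
        )
    line_depth = {"L1": 0, "L2": 1, "L3": 2}
    nodes: dict[str, dict] = {}
    links = []

    def node_id(state: str, depth: int) -> str:
        nid = f"{state}@{depth}"
        nodes.setdefault(
            nid, {"id": nid, "label": NODE_LABELS[state], "depth": depth}
        )
        return nid

    for _, row in transition_table.iterrows():
        src_depth = line_depth[row["src"]]
        dst_depth = (
            line_depth[row["dst"]] if row["dst"] in line_depth else src_depth + 1
        )
        links.append(
            {
                "source": node_id(row["src"], src_depth),
                "target": node_id(row["dst"], dst_depth),
                "count": int(row["count"]),
                "pct": round(100.0 * row["probability"], 1),
            }
        )
    graph = SankeyGraph(nodes=tuple(nodes.values()), links=tuple(links))
    check_flow_conservation(graph)
    return graph


def check_flow_conservation(graph: SankeyGraph) -> None:
    """Entrants = movers + deaths + continuers at every non-absorbing node."""
    for node in graph.nodes:
        state = node["id"].split("@")[0]
        if state in ("DEATH", "CONTINUE"):
            continue
        inflow, outflow = graph.inflow(node["id"]), graph.outflow(node["id"])
        if node["depth"] > 0 and inflow != outflow:
            raise ValueError(
                f"flow not conserved at {node['id']}: in={inflow} out={outflow}"
            )


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------


class DiseaseProgressionModel:
    """Empirical Markov model over per-patient treatment-line journeys.

    Parameters
    ----------
    journeys : sequence of PatientJourney
    strata : sequence of str
        Stratum keys to condition on (keys of ``journey.strata``), e.g.
        ``("period", "asct", "first_line_class")``.  Empty for a pooled
        model.
    """

    def __init__(
        self,
        journeys: Sequence[PatientJourney],
        strata: Sequence[str] = (),
    ) -> None:
        self.journeys = list(journeys)
        self.strata = tuple(strata)

    @classmethod
    def from_cohort(
        cls,
        members,
        lines_by_patient: Mapping[str, Sequence[TherapyLine]],
        strata: Sequence[str] = ("period", "asct", "first_line_class"),
    ) -> "DiseaseProgressionModel":
        """Build journeys from cohort members plus their therapy lines.

        Members without any line (never realised treatment inside
        follow-up) cannot enter the state space and are skipped.
        """
        journeys = []
        for m in members:
            lines = list(lines_by_patient.get(m.patient_id, ()))
            if not lines:
                continue
            journeys.append(
                build_journey(
                    lines,
                    death_date=m.followup_end if m.died else None,
                    followup_end=m.followup_end,
                    patient_id=m.patient_id,
                    strata={
                        "period": m.period,
                        "asct": m.asct,
                        "first_line_class": lines[0].regimen_class,
                    },
                )
            )
        return cls(journeys, strata=strata)

    def fit(self) -> "DPMResults":
        if not self.journeys:
            import warnings

            warnings.warn("empty journey set: transition table will be empty")
        transitions = estimate_transitions(self.journeys, self.strata)
        durations = summarize_durations(self.journeys, self.strata)
        return DPMResults(self, transitions, durations)


class DPMResults:
    """Fitted transition probabilities, their uncertainty and sojourns."""

    def __init__(
        self,
        model: DiseaseProgressionModel,
        transitions: pd.DataFrame,
        durations: pd.DataFrame,
    ) -> None:
        self.model = model
        self.transitions = transitions
        self.durations = durations

    @property
    def n_journeys(self) -> int:
        return len(self.model.journeys)

    def stratum_table(self, **stratum) -> pd.DataFrame:
        """Transition table restricted to one stratum, stratum keys dropped."""
        t = self.transitions
        for k, v in stratum.items():
            t = t[t[k] == v]
        return t.drop(columns=list(stratum)).reset_index(drop=True)

    def strata_values(self) -> list[dict]:
        if not self.model.strata:
            return [{}]
        cols = list(self.model.strata)
        uniq = self.transitions[cols].drop_duplicates().to_dict("records")
        return uniq

    def probability(self, src: str, dst: str, **stratum) -> float:
        t = self.stratum_table(**stratum)
        row = t[(t["src"] == src) & (t["dst"] == dst)]
        return float(row["probability"].iloc[0]) if len(row) else 0.0

    def to_sankey(self, **stratum) -> SankeyGraph:
        return to_sankey(self.stratum_table(**stratum))

    def sankey_bundle(self) -> dict:
        """One Sankey per stratum, keyed by a stable stratum label."""
        out = {}
        for s in self.strata_values():
            key = "|".join(f"{k}={s[k]}" for k in self.model.strata) or "pooled"
            out[key] = self.to_sankey(**s).to_dict()
        return out

    def plot_sankey(self, ax=None, **stratum):
        """Minimal matplotlib rendering (bands proportional to counts)."""
        import matplotlib.pyplot as plt

        graph = self.to_sankey(**stratum)
        if ax is None:
            _, ax = plt.subplots(figsize=(8, 5))
        ys: dict[str, float] = {}
        heights: dict[str, float] = {}
        total = max((l["count"] for l in graph.links), default=1)
        by_depth: dict[int, list[dict]] = {}
        for n in graph.nodes:
            by_depth.setdefault(n["depth"], []).append(n)
        for depth, ns in sorted(by_depth.items()):
            y = 0.0
            for n in ns:
                size = max(graph.inflow(n["id"]), graph.outflow(n["id"]), 1)
                h = size / total
                ax.add_patch(
                    plt.Rectangle((depth, y), 0.25, h, color="#4878d0", alpha=0.8)
                )
                ax.text(depth + 0.12, y + h / 2, n["label"], ha="center", va="center", fontsize=8)
                ys[n["id"]] = y
                heights[n["id"]] = h
                y += h + 0.15
        for l in graph.links:
            sx = graph.nodes[[n["id"] for n in graph.nodes].index(l["source"])]["depth"] + 0.25
            tx = graph.nodes[[n["id"] for n in graph.nodes].index(l["target"])]["depth"]
            sy = ys[l["source"]] + heights[l["source"]] / 2
            ty = ys[l["target"]] + heights[l["target"]] / 2
            ax.plot([sx, tx], [sy, ty], lw=1 + 6 * l["count"] / total, alpha=0.5, color="gray")
            ax.text((sx + tx) / 2, (sy + ty) / 2, f"{l['pct']}%", fontsize=7)
        ax.set_xlim(-0.3, max(n["depth"] for n in graph.nodes) + 0.6)
        ax.axis("off")
        return ax

    def summary(self) -> str:
        """Plain-text report: branch percentages +/- SE and median sojourns."""
        lines = [
            "Disease progression model (empirical Markov estimates)",
            f"journeys: {self.n_journeys}   strata: {self.model.strata or '(pooled)'}",
            "",
            "Transitions (probability [SE], count/n at risk):",
        ]
        for s in self.strata_values():
            label = ", ".join(f"{k}={v}" for k, v in s.items()) or "pooled"
            lines.append(f"  [{label}]")
            t = self.stratum_table(**s)
            for _, r in t.iterrows():
                lines.append(
                    f"    {r['src']:>4} -> {r['dst']:<8} "
                    f"{100 * r['probability']:5.1f}% [{100 * r['se']:.1f}] "
                    f"({int(r['count'])}/{int(r['n_at_risk'])})"
                )
        if not self.durations.empty:
            lines += ["", "Inter-line durations (months):"]
            for _, r in self.durations.iterrows():
                label = ", ".join(
                    f"{k}={r[k]}" for k in self.model.strata
                )
                lines.append(
                    f"    {r['transition']:<8} {label + ' ' if label else ''}"
                    f"median {r['median']:.1f} (IQR {r['q1']:.1f}-{r['q3']:.1f}, n={int(r['n'])})"
                )
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover
        return f"<DPMResults: {self.n_journeys} journeys, strata={self.model.strata}>"
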