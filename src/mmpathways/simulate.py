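"""Synthetic administrative-claims generator with known ground truth.

The generator emulates the structure of a national claims database linked
to a death registry: enrollment spans, ICD-9-coded diagnoses, dated MM
drug dispensings with days-supply, ASCT procedure claims and death dates.
Every patient is realised from an explicit treatment journey drawn from a
ground-truth Markov matrix (L1 -> L2 -> L3 -> death/continue), with
lognormal inter-line sojourn times, so the full pipeline can be tested by
round-trip recovery without access to restricted registry data.

Defaults are calibrated to the published post/pre-bortezomib cohorts:
period mix 0.545/0.455, ASCT probability 0.110 (pre) and 0.150 (post),
per-stratum first-line class mixes and age/sex distributions from the
printed demographics tables, post-period L1 branch fractions
(0.587/0.033/0.360 with ASCT; 0.519/0.330/0.151 without), and median L1
sojourns of 17.5 (pre) and 11.6 (post) months.

Realisation rules keep line boundaries unambiguous for recovery tests:
dispensings every 28 days with 28-day supply (continuous coverage),
inter-line gaps generated at 75 days (comfortably above the 60-day rule),
and regimen switches only beyond the 90-day addition window.  Exact
boundary cases (60/90 days) are exercised by dedicated unit fixtures, not
by the generator.

Determinism: each patient has a private random stream derived from
``(seed, patient index)``, so growing ``n_patients`` never perturbs
earlier patients, identical seeds give byte-identical bundles and
different seeds give different patient IDs.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, asdict
from datetime import date, timedelta
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from .cohort import PRE_BORTEZOMIB, POST_BORTEZOMIB
from .dictionary import DrugDictionary
from .records import (
    ClaimsBundle,
    DeathRecord,
    DiagnosisClaim,
    DrugDispensing,
    PatientRecord,
    ProcedureClaim,
)

DAYS_PER_MONTH = 30.4375

PLANT_RULES = (
    "underage",
    "insufficient_lookback",
    "prior_cancer",
    "plasma_cell_leukemia_within_2mo",
    "no_mm_visit_after_index",
    "untreated",
)

#: Regimen pools per first-line class (each a drug set a clinician might use).
FIRST_LINE_REGIMENS: dict[str, tuple[frozenset[str], ...]] = {
    "NA": (
        frozenset({"bortezomib", "thalidomide"}),
        frozenset({"thalidomide", "dexamethasone"}),
        frozenset({"bortezomib", "dexamethasone"}),
    ),
    "CCNA": (
        frozenset({"melphalan", "thalidomide"}),
        frozenset({"bortezomib", "thalidomide", "cyclophosphamide"}),
        frozenset({"melphalan", "bortezomib"}),
    ),
    "CA": (
        frozenset({"melphalan", "prednisolone"}),
        frozenset({"cyclophosphamide", "vincristine"}),
        frozenset({"melphalan"}),
    ),
    "SA": (
        frozenset({"dexamethasone"}),
        frozenset({"prednisolone"}),
    ),
}

LATER_LINE_REGIMENS: tuple[frozenset[str], ...] = (
    frozenset({"lenalidomide", "dexamethasone"}),
    frozenset({"bortezomib", "dexamethasone"}),
    frozenset({"cyclophosphamide", "etoposide"}),
    frozenset({"lenalidomide"}),
    frozenset({"melphalan", "prednisolone"}),
)

COMORBIDITY_CLAIM_CODES = {
    "anemia": "285.9",
    "renal": "586",
    "pneumonia": "486",
    "fracture": "820.8",
}

CCI_EXTRA_CODES = {
    "diabetes": "250.00",
    "heart_failure": "428.0",
    "copd": "496",
}


@dataclass(frozen=True)
class Lognormal:
    """Lognormal in months, parameterised by its median and log-scale sigma."""

    median_months: float
    sigma: float

    def draw_days(self, rng: np.random.Generator) -> int:
        days = self.median_months * DAYS_PER_MONTH * math.exp(rng.normal(0.0, self.sigma))
        return int(round(days))


@dataclass(frozen=True)
class StratumDynamics:
    """Ground truth for one period x ASCT stratum."""

    first_line_mix: Mapping[str, float]
    transitions: Mapping[str, Mapping[str, float]]
    sojourn: Mapping[str, Lognormal]  # keys "L1", "L2": inter-line gaps
    age_mean: float
    age_sd: float
    male_prob: float

    def validate(self) -> None:
        if abs(sum(self.first_line_mix.values()) - 1.0) > 1e-6:
            raise ValueError(f"first-line mix sums to {sum(self.first_line_mix.values())}")
        for src, row in self.transitions.items():
            if abs(sum(row.values()) - 1.0) > 1e-6:
                raise ValueError(f"transition row {src} sums to {sum(row.values())}")
            if any(not (0.0 <= p <= 1.0) for p in row.values()):
                raise ValueError(f"transition row {src} has probability outside [0,1]")


@dataclass(frozen=True)
class SimulationConfig:
    n_patients: int = 500
    seed: int = 0
    study_start: date = date(2007, 1, 1)
    study_end: date = date(2015, 12, 31)
    period_boundary: date = date(2012, 6, 1)
    censor_date: date = date(2017, 12, 31)
    period_mix: Mapping[str, float] = field(
        default_factory=lambda: {PRE_BORTEZOMIB: 0.545, POST_BORTEZOMIB: 0.455}
    )
    asct_prob: Mapping[str, float] = field(
        default_factory=lambda: {PRE_BORTEZOMIB: 0.110, POST_BORTEZOMIB: 0.150}
    )
    strata: Mapping[tuple[str, bool], StratumDynamics] = field(default_factory=dict)
    death_time: Lognormal = Lognormal(8.0, 0.8)  # line start -> in-line death
    asct_delay: Lognormal = Lognormal(9.6, 0.6)  # index -> transplant
    cadence_days: int = 28
    days_supply: int = 28
    interline_gap_days: int = 75
    switch_mechanism_prob: float = 0.5
    comorbidity_rates: Mapping[str, float] = field(
        default_factory=lambda: {
            "anemia": 0.39,
            "renal": 0.20,
            "pneumonia": 0.15,
            "fracture": 0.18,
        }
    )
    cci_extra_rates: Mapping[str, float] = field(
        default_factory=lambda: {"diabetes": 0.15, "heart_failure": 0.08, "copd": 0.10}
    )
    exclusion_plants: Mapping[str, int] = field(default_factory=dict)

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if abs(sum(self.period_mix.values()) - 1.0) > 1e-6:
            raise ValueError("period mix must sum to 1")
        for s in self.strata.values():
            s.validate()
        if self.cadence_days - self.days_supply >= 60:
            raise ValueError(
                "infeasible config: dispensing cadence leaves in-line coverage gaps "
                ">= the 60-day line-break threshold"
            )
        if self.interline_gap_days <= 60:
            raise ValueError("interline_gap_days must exceed the 60-day gap rule")
        for rule in self.exclusion_plants:
            if rule not in PLANT_RULES:
                raise ValueError(f"unknown plant rule {rule!r}")
        if sum(self.exclusion_plants.values()) > self.n_patients:
            raise ValueError("more planted violations than patients")


def default_config(n_patients: int = 500, seed: int = 0, **overrides) -> SimulationConfig:
    """Defaults calibrated from the published cohort tables (see module doc)."""
    strata = {
        (PRE_BORTEZOMIB, True): StratumDynamics(
            first_line_mix={"NA": 0.41, "CCNA": 0.19, "CA": 0.24, "SA": 0.16},
            transitions={
                "L1": {"L2": 0.65, "DEATH": 0.05, "CONTINUE": 0.30},
                "L2": {"L3": 0.50, "DEATH": 0.20, "CONTINUE": 0.30},
                "L3": {"DEATH": 0.45, "CONTINUE": 0.55},
            },
            sojourn={"L1": Lognormal(17.5, 0.6), "L2": Lognormal(14.9, 0.6)},
            age_mean=53.9,
            age_sd=7.2,
            male_prob=0.585,
        ),
        (PRE_BORTEZOMIB, False): StratumDynamics(
            first_line_mix={"NA": 0.18, "CCNA": 0.28, "CA": 0.30, "SA": 0.24},
            transitions={
                "L1": {"L2": 0.50, "DEATH": 0.40, "CONTINUE": 0.10},
                "L2": {"L3": 0.40, "DEATH": 0.40, "CONTINUE": 0.20},
                "L3": {"DEATH": 0.55, "CONTINUE": 0.45},
            },
            sojourn={"L1": Lognormal(17.5, 0.6), "L2": Lognormal(14.9, 0.6)},
            age_mean=69.4,
            age_sd=11.6,
            male_prob=0.573,
        ),
        (POST_BORTEZOMIB, True): StratumDynamics(
            first_line_mix={"NA": 0.761, "CCNA": 0.225, "CA": 0.007, "SA": 0.007},
            transitions={
                # printed branches sum to 98%; remainder goes to continuation
                "L1": {"L2": 0.587, "DEATH": 0.033, "CONTINUE": 0.380},
                "L2": {"L3": 0.424, "DEATH": 0.152, "CONTINUE": 0.424},
                "L3": {"DEATH": 0.35, "CONTINUE": 0.65},
            },
            sojourn={"L1": Lognormal(11.6, 0.6), "L2": Lognormal(6.8, 0.6)},
            age_mean=57.0,
            age_sd=7.7,
            male_prob=0.525,
        ),
        (POST_BORTEZOMIB, False): StratumDynamics(
            first_line_mix={"NA": 0.5455, "CCNA": 0.2946, "CA": 0.0278, "SA": 0.1321},
            transitions={
                "L1": {"L2": 0.519, "DEATH": 0.330, "CONTINUE": 0.151},
                "L2": {"L3": 0.40, "DEATH": 0.35, "CONTINUE": 0.25},
                "L3": {"DEATH": 0.50, "CONTINUE": 0.50},
            },
            sojourn={"L1": Lognormal(11.6, 0.6), "L2": Lognormal(6.8, 0.6)},
            age_mean=69.6,
            age_sd=11.6,
            male_prob=0.534,
        ),
    }
    cfg = SimulationConfig(
        n_patients=n_patients, seed=seed, strata=strata, **overrides
    )
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------------
# Truth
# ---------------------------------------------------------------------------


@dataclass
class PatientTruth:
    patient_id: str
    index: int
    period: str
    asct: bool
    asct_date: Optional[date]
    sex: str
    age: int
    first_line_class: Optional[str]
    excluded_rule: Optional[str]
    index_date: date
    death_date: Optional[date]
    followup_end: date
    journey_states: list[str]
    line_starts: list[date]
    line_ends: list[date]
    line_end_reasons: list[str]
    line_drugs: list[list[str]]
    mechanisms: list[str]  # inter-line mechanism: "gap" or "switch"


@dataclass
class SimulationTruth:
    """Serialized ground truth shipped alongside the generated bundle."""

    seed: int
    config_digest: str
    intended_transitions: dict
    intended_mixes: dict
    patients: list[PatientTruth]

    def journey_of(self, patient_id: str) -> PatientTruth:
        for p in self.patients:
            if p.patient_id == patient_id:
                return p
        raise KeyError(patient_id)

    def to_json(self, path: Path | str | None = None) -> str:
        def enc(o):
            if isinstance(o, date):
                return o.isoformat()
            raise TypeError(type(o))

        payload = {
            "seed": self.seed,
            "config_digest": self.config_digest,
            "intended_transitions": self.intended_transitions,
            "intended_mixes": self.intended_mixes,
            "patients": [asdict(p) for p in self.patients],
        }
        text = json.dumps(payload, default=enc, indent=1)
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text


def _config_digest(config: SimulationConfig) -> str:
    def conv(o):
        if isinstance(o, Mapping):
            return {str(k): conv(v) for k, v in sorted(o.items(), key=lambda kv: str(kv[0]))}
        if isinstance(o, (list, tuple)):
            return [conv(v) for v in o]
        if isinstance(o, date):
            return o.isoformat()
        return o

    blob = json.dumps(conv(asdict(config)), sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------


def _weighted_choice(rng: np.random.Generator, weights: Mapping[str, float]) -> str:
    keys = sorted(weights)
    p = np.array([weights[k] for k in keys], dtype=float)
    return keys[int(rng.choice(len(keys), p=p / p.sum()))]


def _birth_date_for_age(index_date: date, age: int, rng: np.random.Generator) -> date:
    try:
        anniversary = date(index_date.year - age, index_date.month, index_date.day)
    except ValueError:  # Feb 29
        anniversary = date(index_date.year - age, index_date.month, 28)
    # earlier by < 1 year keeps the completed-years age exact
    return anniversary - timedelta(days=int(rng.integers(0, 350)))


def _plant_assignment(config: SimulationConfig) -> dict[int, str]:
    plan: dict[int, str] = {}
    i = 0
    for rule in PLANT_RULES:
        for _ in range(config.exclusion_plants.get(rule, 0)):
            plan[i] = rule
            i += 1
    return plan


def _draw_journey(
    rng: np.random.Generator, dyn: StratumDynamics
) -> list[str]:
    states = ["L1"]
    while True:
        row = dyn.transitions[states[-1]]
        dst = _weighted_choice(rng, row)
        states.append(dst)
        if dst in ("DEATH", "CONTINUE"):
            return states


MIN_SOJOURN_DAYS = 92   # leaves room for both gap (75d) and switch (>90d) mechanisms
MIN_DEATH_DAYS = 14


def simulate_bundle(
    config: SimulationConfig | None = None,
) -> tuple[ClaimsBundle, SimulationTruth]:
    """Generate a claims bundle plus its ground truth.

    Journeys are drawn first; the index date is then placed inside the
    patient's diagnosis-period window, shifted earlier when needed so the
    whole journey completes before the censor date.  If even the earliest
    index cannot fit the journey, the realisation is truncated at the
    censor and the *truncated* journey is recorded as truth.
    """
    config = config or default_config()
    config.validate()
    dictionary = DrugDictionary.default()

    bundle = ClaimsBundle()
    truths: list[PatientTruth] = []
    plants = _plant_assignment(config)

    pre_window = (config.study_start, config.period_boundary - timedelta(days=1))
    post_window = (config.period_boundary, config.study_end)

    for i in range(config.n_patients):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=config.seed, spawn_key=(i,))
        )
        pid = f"S{config.seed}-{i:06d}"
        plant = plants.get(i)

        period = _weighted_choice(rng, config.period_mix)
        asct = bool(rng.random() < config.asct_prob[period])
        dyn = config.strata[(period, asct)]
        sex = "male" if rng.random() < dyn.male_prob else "female"
        age = int(np.clip(round(rng.normal(dyn.age_mean, dyn.age_sd)), 20, 90))
        if plant == "underage":
            age = 16
        fl_class = _weighted_choice(rng, dyn.first_line_mix)

        states = _draw_journey(rng, dyn)
        n_lines = sum(1 for s in states if s.startswith("L"))
        sojourns = [
            max(MIN_SOJOURN_DAYS, dyn.sojourn[f"L{k}"].draw_days(rng))
            for k in range(1, n_lines)
        ]
        died = states[-1] == "DEATH"
        death_dwell = (
            max(MIN_DEATH_DAYS, config.death_time.draw_days(rng)) if died else None
        )

        first_line_delay = int(rng.integers(0, 31))
        tail = death_dwell if died else config.cadence_days
        needed = first_line_delay + sum(sojourns) + tail

        p_start, p_end = pre_window if period == PRE_BORTEZOMIB else post_window
        latest = min(p_end, config.censor_date - timedelta(days=needed))
        if latest >= p_start:
            span = (latest - p_start).days
            index_date = p_start + timedelta(days=int(rng.integers(0, span + 1)))
        else:
            index_date = p_start  # journey will be truncated at the censor

        # --- realise lines, truncating at the censor -----------------------
        regimens: list[frozenset[str]] = [
            frozenset(FIRST_LINE_REGIMENS[fl_class][
                int(rng.integers(0, len(FIRST_LINE_REGIMENS[fl_class])))
            ])
        ]
        mechanisms: list[str] = []
        line_starts = [index_date + timedelta(days=first_line_delay)]
        for k, s_days in enumerate(sojourns):
            nxt = line_starts[-1] + timedelta(days=s_days)
            if nxt > config.censor_date:
                break
            line_starts.append(nxt)
            # pick the next regimen; a "switch" needs a genuinely new drug
            want_switch = (
                s_days > config.days_supply + 90
                and rng.random() < config.switch_mechanism_prob
            )
            options = [
                r for r in LATER_LINE_REGIMENS if not want_switch or (r - regimens[-1])
            ]
            nxt_reg = options[int(rng.integers(0, len(options)))]
            if want_switch and (nxt_reg - regimens[-1]):
                mechanisms.append("switch")
            else:
                mechanisms.append("gap")
            regimens.append(frozenset(nxt_reg))

        realized_n = len(line_starts)
        truncated = realized_n < n_lines
        death_date: Optional[date] = None
        if died and not truncated:
            death_date = line_starts[-1] + timedelta(days=death_dwell)
            if death_date > config.censor_date:
                death_date = None  # death beyond censor: observed as CONTINUE
        followup_end = min(death_date or config.censor_date, config.censor_date)

        # coverage duration of each realised line
        line_ends: list[date] = []
        reasons: list[str] = []
        disp_rows: list[DrugDispensing] = []
        skip_dispensing = plant == "untreated"
        for k in range(realized_n):
            t_k = line_starts[k]
            if k + 1 < realized_n:
                s_days = (line_starts[k + 1] - t_k).days
                if mechanisms[k] == "switch":
                    d_cov = s_days
                    line_ends.append(line_starts[k + 1] - timedelta(days=1))
                    reasons.append("new_drug_after_90d")
                else:
                    d_cov = s_days - config.interline_gap_days
                    line_ends.append(t_k + timedelta(days=d_cov - 1))
                    reasons.append("gap")
            elif death_date is not None:
                d_cov = (death_date - t_k).days + 1
                line_ends.append(death_date)
                reasons.append("death")
            else:
                d_cov = (followup_end - t_k).days + 1
                line_ends.append(followup_end)
                reasons.append("data_end")
            if skip_dispensing:
                continue
            offset = 0
            while offset < d_cov:
                supply = min(config.days_supply, d_cov - offset)
                for drug in sorted(regimens[k]):
                    disp_rows.append(
                        DrugDispensing(
                            patient_id=pid,
                            dispense_date=t_k + timedelta(days=offset),
                            drug=drug,
                            days_supply=supply,
                            setting="outpatient",
                        )
                    )
                offset += config.cadence_days

        journey_states = [f"L{k + 1}" for k in range(realized_n)]
        journey_states.append("DEATH" if death_date is not None else "CONTINUE")

        # --- claims -------------------------------------------------------
        if plant == "insufficient_lookback":
            enroll_start = index_date - timedelta(days=60)
        else:
            enroll_start = index_date - timedelta(days=365 + int(rng.integers(0, 1096)))
        bundle.patients.append(
            PatientRecord(
                patient_id=pid,
                birth_date=_birth_date_for_age(index_date, age, rng),
                sex=sex,
                enroll_start=enroll_start,
                enroll_end=None,
            )
        )

        bundle.diagnoses.append(
            DiagnosisClaim(pid, index_date, "203.00", "primary", "outpatient")
        )
        if plant != "no_mm_visit_after_index":
            bundle.diagnoses.append(
                DiagnosisClaim(
                    pid, index_date + timedelta(days=21), "203.01", "primary", "outpatient"
                )
            )
        if plant == "prior_cancer":
            bundle.diagnoses.append(
                DiagnosisClaim(
                    pid, index_date - timedelta(days=200), "162.9", "primary", "inpatient"
                )
            )
        if plant == "plasma_cell_leukemia_within_2mo":
            bundle.diagnoses.append(
                DiagnosisClaim(
                    pid, index_date + timedelta(days=30), "203.10", "secondary", "outpatient"
                )
            )
        for cond, rate in sorted(config.comorbidity_rates.items()):
            if rng.random() < rate:
                for back in (90, 180, 270):
                    bundle.diagnoses.append(
                        DiagnosisClaim(
                            pid,
                            index_date - timedelta(days=back),
                            COMORBIDITY_CLAIM_CODES[cond],
                            "secondary",
                            "outpatient",
                        )
                    )
        for cond, rate in sorted(config.cci_extra_rates.items()):
            if rng.random() < rate:
                bundle.diagnoses.append(
                    DiagnosisClaim(
                        pid,
                        index_date - timedelta(days=120),
                        CCI_EXTRA_CODES[cond],
                        "secondary",
                        "outpatient",
                    )
                )

        bundle.dispensings.extend(disp_rows)

        asct_date: Optional[date] = None
        if asct:
            delay = max(30, config.asct_delay.draw_days(rng))
            candidate = index_date + timedelta(days=delay)
            if candidate <= followup_end:
                asct_date = candidate
                bundle.procedures.append(ProcedureClaim(pid, asct_date, "ASCT"))
            else:
                asct = False

        if death_date is not None:
            bundle.deaths.append(DeathRecord(pid, death_date))

        truths.append(
            PatientTruth(
                patient_id=pid,
                index=i,
                period=period,
                asct=asct,
                asct_date=asct_date,
                sex=sex,
                age=age,
                first_line_class=None if skip_dispensing else fl_class,
                excluded_rule=plant,
                index_date=index_date,
                death_date=death_date,
                followup_end=followup_end,
                journey_states=journey_states,
                line_starts=line_starts,
                line_ends=line_ends,
                line_end_reasons=reasons,
                line_drugs=[sorted(r) for r in regimens[:realized_n]],
                mechanisms=mechanisms[: max(0, realized_n - 1)],
            )
        )

    truth = SimulationTruth(
        seed=config.seed,
        config_digest=_config_digest(config),
        intended_transitions={
            f"{period}|{'asct' if a else 'no_asct'}": {
                src: dict(row) for src, row in dyn.transitions.items()
            }
            for (period, a), dyn in config.strata.items()
        },
        intended_mixes={
            f"{period}|{'asct' if a else 'no_asct'}": dict(dyn.first_line_mix)
            for (period, a), dyn in config.strata.items()
        },
        patients=truths,
    )
    return bundle, truth
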