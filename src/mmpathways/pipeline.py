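"""End-to-end orchestration: claims -> cohort -> comorbidity -> lines -> DPM -> reports.

``run_pipeline`` executes every stage on a claims bundle (read from disk
or freshly simulated) and writes the artifact set:

* ``cohort.csv``, ``exclusions.csv``, ``rejects.csv``
* ``comorbidity.csv``
* ``lines.csv``
* ``transitions.csv``, ``durations.csv``, ``sankey.json``
* ``table1.csv`` (demographics), ``table2.csv`` (first-line regimens),
  both small-cell suppressed
* ``run.log`` with the config hash, seed and stage counts (no
  timestamps, so identical inputs give byte-identical artifacts).

Stage failures abort with the stage name attached.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from datetime import date, datetime
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from .cohort import (
    CohortConfig,
    CohortMember,
    apply_selection,
    cohort_frame,
    exclusion_frame,
)
from .comorbidity import DeyoMap, comorbidity_frame, comorbidity_profile
from .dictionary import DrugDictionary
from .dpm import DiseaseProgressionModel, DPMResults
from .io import RejectReport, read_claims_bundle, write_claims_bundle
from .records import ClaimsBundle
from .reporting import demographics_table, regimen_table, suppress_small_counts
from .simulate import SimulationConfig, default_config, simulate_bundle
from .therapy_lines import LotParams, build_lines, classify_lines, lines_frame


@dataclass(frozen=True)
class PipelineConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    lot: LotParams = field(default_factory=LotParams)
    comorbidity_window_days: int = 365
    include_malignancy: bool = False
    suppression_threshold: int = 3
    dpm_strata: tuple[str, ...] = ("period", "asct", "first_line_class")

    def digest(self) -> str:
        blob = json.dumps(asdict(self), default=str, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def load_config(path: Path | str) -> PipelineConfig:
    """PipelineConfig from a YAML file mirroring the stage defaults."""
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}

    def as_date(v):
        return v if isinstance(v, date) else datetime.strptime(v, "%Y-%m-%d").date()

    ck = dict(raw.get("cohort", {}))
    for k in ("study_start", "study_end", "censor_date", "period_boundary"):
        if k in ck:
            ck[k] = as_date(ck[k])
    rep = raw.get("reporting", {})
    com = raw.get("comorbidity", {})
    return PipelineConfig(
        cohort=CohortConfig(**ck),
        lot=LotParams(**raw.get("lot", {})),
        comorbidity_window_days=com.get("window_days", 365),
        include_malignancy=com.get("include_malignancy", False),
        suppression_threshold=rep.get("suppression_threshold", 3),
        dpm_strata=tuple(raw.get("dpm", {}).get("strata", ("period", "asct", "first_line_class"))),
    )


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception) -> None:
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage
        self.__cause__ = cause


@dataclass
class PipelineResult:
    bundle: ClaimsBundle
    rejects: RejectReport
    members: list[CohortMember]
    exclusions: list
    cohort: pd.DataFrame
    comorbidity: pd.DataFrame
    lines: pd.DataFrame
    dpm: DPMResults
    out_dir: Optional[Path] = None


def _build_all_lines(bundle, members, lot: LotParams, dictionary):
    grouped = bundle.grouped()
    all_lines = []
    lines_by_patient = {}
    for m in members:
        pc = grouped[m.patient_id]
        disp = [d for d in pc.dispensings if d.dispense_date >= m.index_date]
        death = pc.death.death_date if pc.death else None
        lines = classify_lines(
            build_lines(disp, m.index_date, death, m.followup_end, lot), dictionary
        )
        lines_by_patient[m.patient_id] = lines
        all_lines.extend(lines)
    return all_lines, lines_by_patient


def run_pipeline(
    out_dir: Path | str,
    input_dir: Path | str | None = None,
    bundle: ClaimsBundle | None = None,
    simulate: bool = False,
    sim_config: SimulationConfig | None = None,
    n: int | None = None,
    seed: int = 0,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Run every stage and write all artifacts under ``out_dir``.

    The bundle comes from exactly one of: ``bundle`` (in memory),
    ``input_dir`` (five CSVs), or ``simulate=True`` (generated with
    ``sim_config`` or the calibrated defaults at size ``n``/``seed``).
    """
    config = config or PipelineConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dictionary = DrugDictionary.default()
    log: list[str] = [f"config_digest {config.digest()}", f"seed {seed}"]

    try:
        rejects = RejectReport()
        if bundle is None and simulate:
            sim = sim_config or default_config(n_patients=n or 500, seed=seed)
            bundle, truth = simulate_bundle(sim)
            truth.to_json(out / "truth.json")
            write_claims_bundle(bundle, out / "bundle")
            log.append(f"simulated n={sim.n_patients} digest={truth.config_digest}")
        elif bundle is None:
            if input_dir is None:
                raise ValueError("provide bundle, input_dir or simulate=True")
            bundle, rejects = read_claims_bundle(input_dir, dictionary)
        rejects.to_csv(out / "rejects.csv")
        log.append(f"bundle {bundle.counts()} rejects={len(rejects)}")
    except Exception as exc:
        raise StageError("claims", exc) from exc

    try:
        members, exclusions = apply_selection(bundle, config.cohort, dictionary)
        cohort_df = cohort_frame(members)
        cohort_df.to_csv(out / "cohort.csv", index=False)
        exclusion_frame(exclusions).to_csv(out / "exclusions.csv", index=False)
        log.append(
            f"cohort members={len(members)} "
            f"excluded={len({e.patient_id for e in exclusions})}"
        )
    except Exception as exc:
        raise StageError("cohort", exc) from exc

    try:
        deyo = DeyoMap.default()
        grouped = bundle.grouped()
        profiles = [
            comorbidity_profile(
                m.patient_id,
                grouped[m.patient_id].diagnoses,
                m.index_date,
                config.comorbidity_window_days,
                deyo,
                config.include_malignancy,
            )
            for m in members
        ]
        comorbidity_df = comorbidity_frame(profiles)
        comorbidity_df.to_csv(out / "comorbidity.csv", index=False)
    except Exception as exc:
        raise StageError("comorbidity", exc) from exc

    try:
        all_lines, lines_by_patient = _build_all_lines(
            bundle, members, config.lot, dictionary
        )
        lines_df = lines_frame(all_lines)
        lines_df.to_csv(out / "lines.csv", index=False)
        log.append(f"lines n={len(all_lines)}")
    except Exception as exc:
        raise StageError("therapy_lines", exc) from exc

    try:
        model = DiseaseProgressionModel.from_cohort(
            members, lines_by_patient, strata=config.dpm_strata
        )
        results = model.fit()
        results.transitions.to_csv(out / "transitions.csv", index=False)
        results.durations.to_csv(out / "durations.csv", index=False)
        (out / "sankey.json").write_text(
            json.dumps(results.sankey_bundle(), indent=1), encoding="utf-8"
        )
        log.append(f"dpm journeys={results.n_journeys}")
    except Exception as exc:
        raise StageError("dpm", exc) from exc

    try:
        if len(cohort_df):
            t1 = demographics_table(cohort_df, comorbidity_df, lines_df)
            t2 = regimen_table(lines_df, cohort_df)
            suppress_small_counts(t1, config.suppression_threshold).to_csv(out / "table1.csv")
            suppress_small_counts(t2, config.suppression_threshold).to_csv(out / "table2.csv")
    except Exception as exc:
        raise StageError("reporting", exc) from exc

    (out / "run.log").write_text("\n".join(log) + "\n", encoding="utf-8")
    return PipelineResult(
        bundle=bundle,
        rejects=rejects,
        members=members,
        exclusions=exclusions,
        cohort=cohort_df,
        comorbidity=comorbidity_df,
        lines=lines_df,
        dpm=results,
        out_dir=out,
    )
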