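"""Shared fixtures and factories for the test suite."""

from __future__ import annotations

import dataclasses
from datetime import date, timedelta
from pathlib import Path

import numpy as np
import pytest

from mmpathways.cohort import POST_BORTEZOMIB, PRE_BORTEZOMIB
from mmpathways.records import DiagnosisClaim, DrugDispensing
from mmpathways.simulate import (
    Lognormal,
    SimulationConfig,
    StratumDynamics,
    default_config,
)

ORIGIN = date(2013, 1, 1)

FIXTURE_DIR = Path(__file__).parent / "data"


def disp(
    day: int,
    drug: str,
    supply: int = 28,
    pid: str = "P1",
    origin: date = ORIGIN,
) -> DrugDispensing:
    """Dispensing at ``origin + day`` — days keep hand-traces readable."""
    return DrugDispensing(pid, origin + timedelta(days=day), drug, supply)


def dx(
    day: int,
    icd9: str,
    position: str = "primary",
    setting: str = "outpatient",
    pid: str = "P1",
    origin: date = ORIGIN,
) -> DiagnosisClaim:
    return DiagnosisClaim(pid, origin + timedelta(days=day), icd9, position, setting)


def single_stratum_config(
    n_patients: int,
    seed: int,
    l1: dict | None = None,
    l2: dict | None = None,
    l3: dict | None = None,
    sojourn_l1_median: float = 11.6,
    sojourn_sigma: float = 0.6,
    **overrides,
) -> SimulationConfig:
    """Everyone post-period, non-ASCT, first-line NA: one stratum to study."""
    dyn = StratumDynamics(
        first_line_mix={"NA": 1.0, "CCNA": 0.0, "CA": 0.0, "SA": 0.0},
        transitions={
            "L1": l1 or {"L2": 0.52, "DEATH": 0.33, "CONTINUE": 0.15},
            "L2": l2 or {"L3": 0.40, "DEATH": 0.35, "CONTINUE": 0.25},
            "L3": l3 or {"DEATH": 0.50, "CONTINUE": 0.50},
        },
        sojourn={
            "L1": Lognormal(sojourn_l1_median, sojourn_sigma),
            "L2": Lognormal(6.8, sojourn_sigma),
        },
        age_mean=69.6,
        age_sd=11.6,
        male_prob=0.534,
    )
    base = default_config(n_patients=n_patients, seed=seed, **overrides)
    return dataclasses.replace(
        base,
        period_mix={PRE_BORTEZOMIB: 0.0, POST_BORTEZOMIB: 1.0},
        asct_prob={PRE_BORTEZOMIB: 0.0, POST_BORTEZOMIB: 0.0},
        strata={**base.strata, (POST_BORTEZOMIB, False): dyn},
    )


@pytest.fixture(scope="session")
def bundle3_dir() -> Path:
    return FIXTURE_DIR / "bundle3"


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20230917)
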