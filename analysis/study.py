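"""Shared study conditions for the numbered analysis scripts.

One scaled-down synthetic population standing in for the linked England
data: ten academic-year birth cohorts (2002/3-2011/12) of 4 000 children
each, default body-system hazards (any-CHC cumulative incidence ~26% by 16),
infant-heavy mortality, steady emigration at 0.5%/year with 30% of
departures leaving a final non-England contact, 50 in-migrating children per
cohort-year per age, 5% birth-to-later-record linkage failure and 97% school
enrolment.  Deterministic under STUDY_SEED.
"""

from __future__ import annotations

import pathlib

import pandas as pd

from chcincidence.codelist import extract_events_frame
from chcincidence.synth import SimulationConfig, SyntheticData, default_code_list, generate
from chcincidence.ages import year_label

STUDY_SEED = 2026
RESULTS = pathlib.Path(__file__).resolve().parent.parent / "results"


def study_config(seed: int = STUDY_SEED) -> SimulationConfig:
    return SimulationConfig(
        seed=seed,
        cohorts=tuple((year_label(y), 4_000) for y in range(2002, 2012)),
        immigration={year_label(y): (50,) * 16 for y in range(2002, 2012)},
    )


def study_data(seed: int = STUDY_SEED) -> tuple[SimulationConfig, SyntheticData, pd.DataFrame]:
    cfg = study_config(seed)
    data = generate(cfg)
    events = extract_events_frame(data.episodes, default_code_list())
    return cfg, data, events


def write_result(df: pd.DataFrame, name: str) -> pathlib.Path:
    RESULTS.mkdir(exist_ok=True)
    path = RESULTS / name
    df.to_csv(path, index=False)
    return path
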