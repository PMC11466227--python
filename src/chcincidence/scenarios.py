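"""Canonical synthetic study scenarios and convenience estimation drivers.

Each scenario fixes the study conditions for one validation question — the
generator parameters are part of the scientific design, chosen to embody the
mechanism under study, not tuning knobs:

- :func:`recovery_scenario`: a clean closed population (no migration, no
  mortality, no linkage loss, universal schooling) with a constant any-CHC
  hazard of 0.02/year, so both the closed and the open estimator should
  recover the analytic truth ``1 - exp(-0.32)`` at age 16.
- :func:`sensitivity_scenario`: unrecorded emigration plus activity-correlated
  inclusion (children with a chronic condition have three times the
  background admission rate), the two forces that make eligibility variants
  diverge: birth-record-only cohorts are deflated by phantom denominators,
  activity-demanding cohorts are inflated by selecting sicker stayers.
- :func:`competing_scenario`: heavy childhood mortality (5%/year), where the
  competing-risk estimator must sit at or below the censoring-based one.
- :func:`multimorbidity_scenario`: three independent subtype hazards with no
  attrition, so the multimorbid proportion has a closed form.

Sample sizes are 50 000 (or 30 000 for the variant sweep) — large enough that
Monte-Carlo error is well inside the stated tolerances, small enough to run
on a single CPU in seconds.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .ages import AGE16_DAYS
from .codelist import ANY, CodeList, extract_events_frame
from .cohort import eligibility_mask, followup_frame, summarize_children
from .surv_closed import IncidenceCurve, km_cuminc
from .surv_open import PopulationSeries, count_incident_by_age, open_cuminc
from .synth import SimulationConfig, SyntheticData, default_code_list, generate

ZERO = (0.0,) * 16


def recovery_scenario(seed: int, n: int = 50_000) -> SimulationConfig:
    return SimulationConfig(
        seed=seed,
        cohorts=(("2002/3", n),),
        subtype_hazards={"respiratory": (0.02,) * 16},
        mortality_hazard=ZERO,
        emigration_hazard=ZERO,
        linkage_failure_prob=0.0,
        enrolment_prob=1.0,
    )


def sensitivity_scenario(seed: int, n: int = 30_000) -> SimulationConfig:
    return SimulationConfig(
        seed=seed,
        cohorts=(("2002/3", n),),
        emigration_hazard=(0.03,) * 16,
        domicile_recording_prob=0.0,  # departures leave no trace
        mortality_hazard=ZERO,
        chc_admission_multiplier=3.0,
        linkage_failure_prob=0.02,
        enrolment_prob=0.9,
        background_admission_rate=0.15,
        outpatient_rate=0.2,
        ae_rate=0.15,
    )


def competing_scenario(seed: int, n: int = 20_000, mortality: float = 0.05) -> SimulationConfig:
    return SimulationConfig(
        seed=seed,
        cohorts=(("2002/3", n),),
        subtype_hazards={"respiratory": (0.015,) * 16},
        mortality_hazard=(mortality,) * 16,
        emigration_hazard=ZERO,
        linkage_failure_prob=0.0,
        enrolment_prob=1.0,
    )


MULTIMORBIDITY_HAZARDS = {
    "respiratory": (0.010,) * 16,
    "neurological": (0.008,) * 16,
    "metabolic and other": (0.006,) * 16,
}


def multimorbidity_scenario(seed: int, n: int = 50_000) -> SimulationConfig:
    return SimulationConfig(
        seed=seed,
        cohorts=(("2002/3", n),),
        subtype_hazards=dict(MULTIMORBIDITY_HAZARDS),
        mortality_hazard=ZERO,
        emigration_hazard=ZERO,
        linkage_failure_prob=0.0,
        enrolment_prob=1.0,
    )


def multimorbid_closed_form(hazards: dict[str, tuple], landmark_age: int) -> float:
    """P(>=2 subtypes | >=1) by a landmark age under independent onsets."""
    q = [1.0 - math.exp(-landmark_age * h[0]) for h in hazards.values()]
    p_none = math.prod(1 - x for x in q)
    p_one = sum(x * math.prod(1 - y for j, y in enumerate(q) if j != i) for i, x in enumerate(q))
    return 1.0 - p_one / (1.0 - p_none)


def ascertain(data: SyntheticData, code_list: CodeList | None = None) -> pd.DataFrame:
    return extract_events_frame(data.episodes, code_list or default_code_list())


def closed_estimate(
    data: SyntheticData, events: pd.DataFrame, variant: str = "main", subtype: str = ANY
) -> IncidenceCurve:
    """Eligibility -> follow-up -> product-limit curve for one variant."""
    summary = summarize_children(
        data.births, data.activity, data.enrolments, data.deaths,
        episodes=data.episodes, admin_end=data.config.data_end,
    )
    included = summary[eligibility_mask(summary, variant)]
    return km_cuminc(followup_frame(included, events, subtype=subtype), variant=variant, subtype=subtype)


def open_estimate(
    data: SyntheticData, events: pd.DataFrame, cohort: str, subtype: str = ANY
) -> pd.DataFrame:
    """Open-cohort curve for one financial-year cohort using ground-truth
    resident-population denominators."""
    from .synth import resident_population

    pop = resident_population(data, calendar="financial")
    series = PopulationSeries(
        cohort, pop.loc[pop["cohort"] == cohort, "population"].to_numpy()
    )
    cases = count_incident_by_age(events, data.persons, subtype=subtype)
    case_map = dict(
        zip(
            cases.loc[cases["cohort"] == cohort, "age"],
            cases.loc[cases["cohort"] == cohort, "cases"],
        )
    )
    return open_cuminc(case_map, series, max_age=15, cohort=cohort)


def closed_by_age(curve: IncidenceCurve, max_age: int = 16) -> np.ndarray:
    """Closed-design estimates 'by age a' for a = 1..max_age."""
    return np.array(
        [curve.value_at(int(a * 365.25) - 1) for a in range(1, max_age + 1)]
    )
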