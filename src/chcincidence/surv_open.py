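"""Open-cohort cumulative incidence from external population denominators.

Where the closed design follows a fixed birth cohort, the open design defines
the population at each age by an external mid-year population estimate, so
in- and out-migration are absorbed by the denominator.  Per birth cohort
(financial year of birth, 1 April - 31 March) and year of age ``a``:

    denom(a)  = population(a) - cumulative incident cases before a
    h(a)      = cases(a) / denom(a)
    IH(a)     = sum of h(k) for k <= a
    CI(a)     = 1 - exp(-IH(a))

The discount removes children already counted as cases from the pool still
at risk.  By default cases incident at the current age are not discounted
(they contributed risk time within that year); the alternative convention is
available behind ``include_current_age``.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .ages import days_to_years, financial_year, year_label
from .codelist import ANY

logger = logging.getLogger(__name__)


@dataclass
class PopulationSeries:
    """Mid-year population counts for one birth cohort at ages 0..len-1."""

    cohort: str
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, float)
        if (self.counts < 0).any():
            raise ValueError(f"cohort {self.cohort}: negative population counts")


def load_population_csv(path) -> dict[str, PopulationSeries]:
    """Read a ``cohort,age,population`` CSV into per-cohort series.

    Ages must be contiguous from 0 within each cohort.
    """
    df = pd.read_csv(path)
    out = {}
    for cohort, grp in df.groupby("cohort"):
        grp = grp.sort_values("age")
        if list(grp["age"]) != list(range(len(grp))):
            raise ValueError(f"cohort {cohort}: ages must be contiguous from 0")
        out[str(cohort)] = PopulationSeries(str(cohort), grp["population"].to_numpy())
    return out


def financial_cohort(birth_date: dt.date) -> str:
    """Financial-year cohort label (1 Apr - 31 Mar) for a birth date."""
    return year_label(financial_year(birth_date))


def count_incident_by_age(
    events: pd.DataFrame,
    persons: pd.DataFrame,
    subtype: str = ANY,
    max_age: int = 16,
) -> pd.DataFrame:
    """Incident first-instance cases per (financial-year cohort, age).

    ``events`` is the tidy ascertainment table (child_id, subtype, age_days);
    ``persons`` supplies each child's birth date (immigrants included —
    membership is by year of birth regardless of place of birth).  Events at
    age >= ``max_age`` years are excluded with a log entry.
    """
    ev = events[events["subtype"] == subtype].merge(
        persons[["child_id", "birth_date"]], on="child_id", how="left"
    )
    if ev["birth_date"].isna().any():
        missing = ev.loc[ev["birth_date"].isna(), "child_id"].tolist()[:5]
        raise ValueError(f"events for unknown children, e.g. {missing}")
    ages = days_to_years(ev["age_days"].to_numpy())
    over = ages >= max_age
    if over.any():
        logger.info("excluding %d events at age >= %d", int(over.sum()), max_age)
    ev = ev[~over]
    ages = ages[~over]
    bd = pd.to_datetime(ev["birth_date"])
    years = np.where(bd.dt.month >= 4, bd.dt.year, bd.dt.year - 1)
    cohorts = [year_label(int(y)) for y in years]
    counts = (
        pd.DataFrame({"cohort": cohorts, "age": ages})
        .value_counts()
        .rename("cases")
        .reset_index()
        .sort_values(["cohort", "age"], ignore_index=True)
    )
    return counts


def max_age_for_cohort(cohort: str, end_year: int = 2019) -> int:
    """Ages observable for a financial-year cohort with data through ``end_year``/20."""
    return max(0, min(16, end_year - int(cohort.split("/")[0]) + 1))


def open_cuminc(
    cases: Mapping[int, int] | pd.Series | Sequence[int],
    population: PopulationSeries | Sequence[float],
    max_age: int | None = None,
    include_current_age: bool = False,
    cohort: str | None = None,
) -> pd.DataFrame:
    """Integrated-hazard cumulative incidence over ages 0..max_age.

    Returns a tidy frame: age, cases, denom, hazard, IH (integrated hazard),
    cum_inc.  Raises if any required denominator is <= 0 or smaller than that
    age's case count.
    """
    pop = population.counts if isinstance(population, PopulationSeries) else np.asarray(population, float)
    if max_age is None:
        max_age = len(pop) - 1
    if max_age >= len(pop):
        raise ValueError(f"population series covers ages 0..{len(pop) - 1}; need {max_age}")
    if isinstance(cases, (pd.Series, Mapping)):
        case_arr = np.array([float(dict(cases).get(a, 0)) for a in range(max_age + 1)])
    else:
        case_arr = np.asarray(cases, float)
        if len(case_arr) < max_age + 1:
            case_arr = np.concatenate([case_arr, np.zeros(max_age + 1 - len(case_arr))])
        case_arr = case_arr[: max_age + 1]
    if (case_arr < 0).any():
        raise ValueError("negative case counts")

    cum_before = np.concatenate([[0.0], np.cumsum(case_arr)[:-1]])
    discount = cum_before + (case_arr if include_current_age else 0.0)
    denom = pop[: max_age + 1] - discount
    for a in range(max_age + 1):
        if denom[a] <= 0:
            raise ValueError(f"discounted denominator <= 0 at age {a}")
        if case_arr[a] > denom[a]:
            raise ValueError(f"cases exceed denominator at age {a}")
    hazard = case_arr / denom
    ih = np.cumsum(hazard)
    ci = 1.0 - np.exp(-ih)
    out = pd.DataFrame(
        {
            "age": np.arange(max_age + 1),
            "cases": case_arr,
            "denom": denom,
            "hazard": hazard,
            "IH": ih,
            "cum_inc": ci,
        }
    )
    if cohort is not None:
        out.insert(0, "cohort", cohort)
    return out


def reconcile(
    open_values: Sequence[float],
    closed_values: Sequence[float],
    tolerance: float,
    ages: Sequence[int] | None = None,
) -> dict:
    """Per-age comparison of open- and closed-design estimates on a common grid."""
    a = np.asarray(open_values, float)
    b = np.asarray(closed_values, float)
    if a.shape != b.shape:
        raise ValueError(f"grid mismatch: {a.shape} vs {b.shape}")
    diff = np.abs(a - b)
    return {
        "ages": list(ages) if ages is not None else list(range(len(a))),
        "abs_diff": diff.tolist(),
        "max_diff": float(diff.max()),
        "passed": bool(diff.max() <= tolerance),
        "tolerance": float(tolerance),
    }
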