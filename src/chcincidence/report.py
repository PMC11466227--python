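"""Pipeline orchestration and table production.

``linkage_rates`` derives the linkage-rate percentages that accompany a
cohort table of ONS live births, HES-recorded births and included children
(rounded half-up to one decimal, the convention that reproduces published
national-statistics tables from their printed counts).  ``run_pipeline``
drives the whole synthetic study end to end and writes the output bundle:
linkage table, closed- and open-cohort incidence curves, multimorbidity
table and a run manifest.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import pathlib
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd

from . import cohort as cohort_mod
from . import morbidity as morbidity_mod
from . import surv_closed, surv_open, synth
from .codelist import ANY, SUBTYPES, CodeList, extract_events_frame, load_code_list

logger = logging.getLogger(__name__)


def round_half_up(x: Decimal | float, places: int = 1) -> float:
    q = Decimal(1).scaleb(-places)
    return float(Decimal(x if isinstance(x, Decimal) else str(x)).quantize(q, ROUND_HALF_UP))


def percentage(numerator: int, denominator: int) -> float:
    """Exact-rational percentage rounded half-up to one decimal; NaN if undefined."""
    if denominator == 0:
        return float("nan")
    return round_half_up(Decimal(numerator) * 100 / Decimal(denominator))


def linkage_rates(counts: pd.DataFrame) -> pd.DataFrame:
    """Derived percentages for a cohort linkage table.

    ``counts`` columns: cohort, live_births, hes_births, included.  Adds
    pct_hes_of_live, pct_included_of_live, pct_included_of_hes.  Counts must
    be non-negative; included must not exceed HES births (inclusion requires
    a recorded birth); HES births exceeding live births is unusual and only
    warned about.
    """
    df = counts.copy()
    for col in ("live_births", "hes_births", "included"):
        if (df[col] < 0).any():
            raise ValueError(f"negative counts in {col}")
    if (df["included"] > df["hes_births"]).any():
        raise ValueError("included children exceed HES-recorded births")
    if (df["hes_births"] > df["live_births"]).any():
        logger.warning("HES-recorded births exceed ONS live births in some cohorts")
    df["pct_hes_of_live"] = [
        percentage(h, l) for h, l in zip(df["hes_births"], df["live_births"])
    ]
    df["pct_included_of_live"] = [
        percentage(i, l) for i, l in zip(df["included"], df["live_births"])
    ]
    df["pct_included_of_hes"] = [
        percentage(i, h) for i, h in zip(df["included"], df["hes_births"])
    ]
    return df


def england_linkage_counts() -> pd.DataFrame:
    """The published England cohort counts shipped with the package."""
    ref = resources.files("chcincidence.data") / "england_cohort_linkage_counts.csv"
    with resources.as_file(ref) as path:
        return pd.read_csv(path)


@dataclass
class RunConfig:
    """End-to-end synthetic-study configuration."""

    out_dir: str
    sim: synth.SimulationConfig = field(default_factory=synth.SimulationConfig)
    code_list_path: str | None = None  # None: packaged synthetic list
    variant: str = "main"
    subtypes: Sequence[str] = (ANY,)
    suppression_threshold: int = 10
    open_cohort: bool = True
    landmarks: Sequence[int] = morbidity_mod.LANDMARKS

    def validate(self) -> None:
        if self.variant not in cohort_mod.VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        self.sim.validate()


def run_pipeline(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Run generate -> ascertain -> cohort -> estimate -> summarize, write the bundle.

    Deterministic given the simulation config (which carries the seed).
    Returns the output tables keyed by artifact name and writes them, plus a
    manifest with the config hash and per-stage row counts, under
    ``config.out_dir``.
    """
    config.validate()
    out = pathlib.Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage_counts: dict[str, int] = {}

    code_list = (
        load_code_list(config.code_list_path)
        if config.code_list_path
        else synth.default_code_list()
    )
    data = synth.generate(config.sim, code_list)
    stage_counts["births"] = len(data.births)
    stage_counts["episodes"] = len(data.episodes)
    logger.info("generated %(births)d births, %(episodes)d episodes", stage_counts)

    events = extract_events_frame(data.episodes, code_list)
    stage_counts["events"] = len(events)

    summary = cohort_mod.summarize_children(
        data.births, data.activity, data.enrolments, data.deaths,
        episodes=data.episodes, admin_end=config.sim.data_end,
    )
    included = summary[cohort_mod.eligibility_mask(summary, config.variant)]
    stage_counts["included"] = len(included)
    logger.info("variant %s: %d of %d children included", config.variant, len(included), len(summary))

    tables: dict[str, pd.DataFrame] = {}

    # linkage table from synthetic counts: configured births play the role of
    # the external live-birth count
    live = pd.DataFrame(config.sim.cohorts, columns=["cohort", "live_births"])
    hes = data.births.groupby("cohort").size().rename("hes_births")
    inc = included.groupby("cohort").size().rename("included")
    counts = live.join(hes, on="cohort").join(inc, on="cohort").fillna(0).astype({"hes_births": int, "included": int})
    tables["linkage_table"] = linkage_rates(counts)

    # closed-cohort curves per cohort and subtype
    curve_rows = []
    followups_by_cohort: dict[str, dict[str, pd.DataFrame]] = {}
    for cohort_label, grp in included.groupby("cohort"):
        horizon = surv_closed.cohort_horizon_years(
            cohort_label, end_year=config.sim.data_end.year
        )
        for st in config.subtypes:
            fu = cohort_mod.followup_frame(grp, events, subtype=st)
            followups_by_cohort.setdefault(st, {})[cohort_label] = fu
            curve = surv_closed.km_cuminc(fu, cohort=cohort_label, variant=config.variant, subtype=st)
            yearly = curve.at_year_ages(horizon)
            yearly, reportable = surv_closed.suppress_small(yearly, config.suppression_threshold)
            yearly.insert(0, "subtype", st)
            yearly.insert(0, "variant", config.variant)
            yearly.insert(0, "cohort", cohort_label)
            yearly["reportable"] = reportable
            curve_rows.append(yearly)
    tables["closed_curves"] = pd.concat(curve_rows, ignore_index=True)

    # paired-cohort subtype curves
    pair_rows = []
    for st in config.subtypes:
        if st == ANY:
            continue
        paired = surv_closed.pair_cohorts(
            followups_by_cohort[st], variant=config.variant, subtype=st
        )
        for key, curve in paired.items():
            horizon = dict(
                (f"{a}+{b}", h) for (a, b), h in surv_closed.COHORT_PAIRS
            )[key]
            yearly, reportable = surv_closed.suppress_small(
                curve.at_year_ages(horizon), config.suppression_threshold
            )
            yearly.insert(0, "subtype", st)
            yearly.insert(0, "variant", config.variant)
            yearly.insert(0, "cohort", key)
            yearly["reportable"] = reportable
            pair_rows.append(yearly)
    if pair_rows:
        tables["paired_subtype_curves"] = pd.concat(pair_rows, ignore_index=True)

    # open-cohort curves
    if config.open_cohort:
        pop = synth.resident_population(data, calendar="financial")
        open_rows = []
        for st in config.subtypes:
            cases = surv_open.count_incident_by_age(events, data.persons, subtype=st)
            for cohort_label, grp in cases.groupby("cohort"):
                series = pop[pop["cohort"] == cohort_label].sort_values("age")
                if series.empty:
                    continue
                pseries = surv_open.PopulationSeries(cohort_label, series["population"].to_numpy())
                max_age = min(
                    len(pseries.counts) - 1,
                    surv_open.max_age_for_cohort(cohort_label, config.sim.data_end.year) - 1,
                )
                if max_age < 0:
                    continue
                case_map = dict(zip(grp["age"], grp["cases"]))
                curve = surv_open.open_cuminc(case_map, pseries, max_age, cohort=cohort_label)
                curve.insert(1, "subtype", st)
                open_rows.append(curve)
        if open_rows:
            tables["open_curves"] = pd.concat(open_rows, ignore_index=True)

    # multimorbidity among included children, per cohort
    mm_rows = []
    inc_ids = set(included["child_id"])
    ev_inc = events[events["child_id"].isin(inc_ids)]
    for cohort_label, grp in included.groupby("cohort"):
        horizon = surv_closed.cohort_horizon_years(cohort_label, end_year=config.sim.data_end.year)
        lms = [lm for lm in config.landmarks if lm <= horizon]
        if not lms:
            continue
        ev_c = ev_inc[ev_inc["child_id"].isin(set(grp["child_id"]))]
        mm_rows.append(
            morbidity_mod.summarize(ev_c, landmarks=lms, followup_years=horizon, cohort=cohort_label)
        )
    tables["multimorbidity"] = pd.concat(mm_rows, ignore_index=True)

    for name, df in tables.items():
        df.to_csv(out / f"{name}.csv", index=False)
        stage_counts[name] = len(df)
    manifest = {
        "seed": config.sim.seed,
        "config_hash": config.sim.config_hash(),
        "variant": config.variant,
        "stage_counts": stage_counts,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return tables
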