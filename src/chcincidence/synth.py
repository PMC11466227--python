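"""Synthetic linked child-records generator with known ground truth.

Emulates the statistical structure of linked hospital/education
administrative data for England: per-cohort births, inpatient episodes
carrying up to 20 ICD-10 codes (including a birth episode), outpatient and
emergency-department activity, school enrolments, deaths, emigration (with
cessation of all records and optionally one final non-England-domicile
episode), immigration (children with no birth record), and linkage failure
between the birth record and all later records.

Chronic-condition onsets, mortality and emigration are independent
competing processes with piecewise-constant yearly hazards over ages 0-15,
sampled by the standard competing-exponential-clocks construction; event
days are uniform within the sampled year of age.  This makes the ground
truth analytic: the net cumulative incidence of a subtype at whole age ``a``
is ``1 - exp(-sum of its hazards below a)`` (:func:`truth_curve`), which
parameter-recovery tests compare against pipeline estimates.

The default code list shipped with the package is a small synthetic
stand-in phenotype list (three to six plausible ICD-10 codes per body-system
subtype); any CSV in the documented ``code,description,group`` layout can be
supplied instead.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .ages import (
    AGE16_DAYS,
    YEAR_START_DAYS,
    academic_year_window,
    year_label,
    years_to_days,
)
from .codelist import ANY, SUBTYPES, CodeList, load_code_list

#: sentinel day meaning "no event before age 16"
NO_EVENT = 1 << 30

#: filler (non-CHC) codes: liveborn-infant code on birth episodes, and a
#: general observation code on background admissions
BIRTH_CODE = "Z380"
FILLER_CODE = "Z038"

N_AGE_BANDS = 16


def default_code_list() -> CodeList:
    """The packaged synthetic stand-in CHC code list."""
    ref = resources.files("chcincidence.data") / "synthetic_chc_codes.csv"
    with resources.as_file(ref) as path:
        return load_code_list(path)


def _const(x: float) -> tuple[float, ...]:
    return (float(x),) * N_AGE_BANDS


#: default yearly subtype hazards (events per person-year, ages 0-15);
#: infancy excess for congenital/perinatal groups, late rise for mental
#: health, summing to an any-CHC cumulative incidence near one quarter by 16
DEFAULT_SUBTYPE_HAZARDS: dict[str, tuple[float, ...]] = {
    "metabolic and other": (0.020,) + (0.004,) * 15,
    "neurological": (0.008,) + (0.003,) * 15,
    "respiratory": (0.006,) + (0.003,) * 15,
    "cancer/blood": _const(0.001),
    "cardiovascular": (0.006,) + (0.0008,) * 15,
    "mental health/behavioural": (0.0002,) * 5 + (0.002,) * 6 + (0.005,) * 5,
    "musculoskeletal/skin": _const(0.001),
    "chronic infections": _const(0.0001),
    "non-specific": _const(0.0015),
}

DEFAULT_MORTALITY = (0.004,) + (0.0002,) * 15
DEFAULT_EMIGRATION = _const(0.005)


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic run.

    Hazards are per person-year, piecewise constant over ages 0-15.
    ``immigration`` maps a cohort label to 16 per-age arrival counts.
    ``chc_admission_multiplier`` scales the background admission rate for
    children with any CHC, the knob that induces activity-correlated
    inclusion (sicker children more likely to satisfy activity-based
    eligibility).
    """

    seed: int = 0
    cohorts: tuple[tuple[str, int], ...] = tuple(
        (year_label(y), 20_000) for y in range(2002, 2012)
    )
    subtype_hazards: Mapping[str, Sequence[float]] = field(
        default_factory=lambda: dict(DEFAULT_SUBTYPE_HAZARDS)
    )
    mortality_hazard: Sequence[float] = DEFAULT_MORTALITY
    emigration_hazard: Sequence[float] = DEFAULT_EMIGRATION
    immigration: Mapping[str, Sequence[int]] = field(default_factory=dict)
    linkage_failure_prob: float = 0.05
    enrolment_prob: float = 0.97
    background_admission_rate: float = 0.1
    chc_admission_multiplier: float = 1.0
    domicile_recording_prob: float = 0.3
    outpatient_rate: float = 0.4
    ae_rate: float = 0.25
    staggered_availability: bool = False
    data_end: dt.date = dt.date(2019, 8, 31)

    def validate(self) -> None:
        if not self.cohorts:
            raise ValueError("at least one cohort is required")
        for label, n in self.cohorts:
            if int(n) != n or n < 0:
                raise ValueError(f"cohort {label}: birth count {n} must be >= 0 int")
        for name, arr in [
            ("mortality_hazard", self.mortality_hazard),
            ("emigration_hazard", self.emigration_hazard),
            *((f"hazard[{s}]", h) for s, h in self.subtype_hazards.items()),
        ]:
            a = np.asarray(arr, float)
            if a.shape != (N_AGE_BANDS,):
                raise ValueError(f"{name} must have {N_AGE_BANDS} yearly values")
            if (a < 0).any():
                raise ValueError(f"{name} has negative values")
        unknown = set(self.subtype_hazards) - set(SUBTYPES)
        if unknown:
            raise ValueError(f"unknown subtypes in hazards: {sorted(unknown)}")
        for name, p in [
            ("linkage_failure_prob", self.linkage_failure_prob),
            ("enrolment_prob", self.enrolment_prob),
            ("domicile_recording_prob", self.domicile_recording_prob),
        ]:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}={p} outside [0, 1]")
        for name, r in [
            ("background_admission_rate", self.background_admission_rate),
            ("outpatient_rate", self.outpatient_rate),
            ("ae_rate", self.ae_rate),
            ("chc_admission_multiplier", self.chc_admission_multiplier),
        ]:
            if r < 0:
                raise ValueError(f"{name}={r} must be >= 0")
        for label, counts in self.immigration.items():
            c = np.asarray(counts)
            if c.shape != (N_AGE_BANDS,) or (c < 0).any() or c.dtype.kind not in "iu":
                raise ValueError(
                    f"immigration[{label}] must be {N_AGE_BANDS} non-negative ints"
                )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cohorts"] = [list(c) for c in self.cohorts]
        d["subtype_hazards"] = {k: list(map(float, v)) for k, v in self.subtype_hazards.items()}
        d["mortality_hazard"] = list(map(float, self.mortality_hazard))
        d["emigration_hazard"] = list(map(float, self.emigration_hazard))
        d["immigration"] = {k: list(map(int, v)) for k, v in self.immigration.items()}
        d["data_end"] = self.data_end.isoformat()
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        d = dict(d)
        if "cohorts" in d:
            d["cohorts"] = tuple((str(lbl), int(n)) for lbl, n in d["cohorts"])
        if "data_end" in d and isinstance(d["data_end"], str):
            d["data_end"] = dt.date.fromisoformat(d["data_end"])
        return cls(**d)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def truth_curve(config: SimulationConfig, subtype: str = ANY) -> np.ndarray:
    """Analytic net cumulative incidence at whole ages 0..16 (17 values).

    ``CI(a) = 1 - exp(-sum of the subtype's yearly hazards below age a)``;
    for ``subtype="any"`` the hazards of all configured subtypes are summed
    (subtype onsets are independent by construction).
    """
    if subtype == ANY:
        h = np.sum([np.asarray(v, float) for v in config.subtype_hazards.values()], axis=0)
    elif subtype in config.subtype_hazards:
        h = np.asarray(config.subtype_hazards[subtype], float)
    elif subtype in SUBTYPES:
        h = np.zeros(N_AGE_BANDS)
    else:
        raise ValueError(f"unknown subtype {subtype!r}")
    return 1.0 - np.exp(-np.concatenate([[0.0], np.cumsum(h)]))


@dataclass
class SyntheticTruth:
    """Analytic per-subtype cumulative-incidence curves at ages 0..16."""

    cuminc: dict[str, np.ndarray]


def sample_event_days(
    rng: np.random.Generator,
    hazards: Sequence[float],
    n: int,
    start_band: int = 0,
) -> np.ndarray:
    """Event days under piecewise-constant yearly hazards; NO_EVENT if none by 16.

    Inverse-transform over the cumulative hazard picks the year-of-age band;
    the day within the band is uniform.  ``start_band`` zeroes hazards below
    that age (left truncation for in-migrating children).
    """
    h = np.asarray(hazards, float).copy()
    if start_band:
        h[:start_band] = 0.0
    cum = np.concatenate([[0.0], np.cumsum(h)])
    e = rng.exponential(size=n)
    band = np.searchsorted(cum, e, side="right") - 1
    days = np.full(n, NO_EVENT, dtype=np.int64)
    hit = band < N_AGE_BANDS
    b = band[hit]
    start = YEAR_START_DAYS[b]
    width = YEAR_START_DAYS[b + 1] - start
    days[hit] = start + np.floor(rng.random(hit.sum()) * width).astype(np.int64)
    return days


@dataclass
class SyntheticData:
    """One generated dataset: linked record tables plus analytic truth.

    Tables (all pandas, dates as ``datetime64[ns]``):

    - ``births``: child_id, birth_date, cohort — HES-recorded live births
    - ``persons``: every simulated child incl. immigrants, with birth_date,
      cohort (academic year), immigrant flag, arrival_day, and the latent
      exit days used for ground-truth population counts
    - ``episodes``: child_id, date, age_days, domicile, diag_01..diag_20
    - ``activity``: child_id, date, age_days, source (APC/OP/AE)
    - ``enrolments``: child_id, date, age_days
    - ``deaths``: child_id, date, age_days
    """

    config: SimulationConfig
    persons: pd.DataFrame
    births: pd.DataFrame
    episodes: pd.DataFrame
    activity: pd.DataFrame
    enrolments: pd.DataFrame
    deaths: pd.DataFrame
    truth: SyntheticTruth

    def write_dir(self, path) -> None:
        """Dump tables as CSV plus a manifest recording seed and config hash."""
        import pathlib

        out = pathlib.Path(path)
        out.mkdir(parents=True, exist_ok=True)
        for name in ("persons", "births", "episodes", "activity", "enrolments", "deaths"):
            getattr(self, name).to_csv(out / f"{name}.csv", index=False)
        manifest = {
            "seed": self.config.seed,
            "config_hash": self.config.config_hash(),
            "rows": {
                name: int(len(getattr(self, name)))
                for name in ("persons", "births", "episodes", "activity", "enrolments", "deaths")
            },
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


def _expand_diag_columns(codes: pd.Series) -> pd.DataFrame:
    """Lists of codes -> diag_01..diag_20 string columns."""
    width = 20
    arr = np.full((len(codes), width), "", dtype=object)
    for i, lst in enumerate(codes):
        if len(lst) > width:
            raise ValueError(f"episode with {len(lst)} codes exceeds 20 positions")
        arr[i, : len(lst)] = lst
    return pd.DataFrame(arr, columns=[f"diag_{j + 1:02d}" for j in range(width)])


def generate(config: SimulationConfig, code_list: CodeList | None = None) -> SyntheticData:
    """Generate one linked synthetic dataset; reproducible given the seed."""
    config.validate()
    if code_list is None:
        code_list = default_code_list()
    codes_by_subtype: dict[str, np.ndarray] = {}
    for s in config.subtype_hazards:
        codes = sorted(c for c, e in code_list.entries.items() if e.subtype == s)
        if np.asarray(config.subtype_hazards[s]).sum() > 0 and not codes:
            raise ValueError(f"no codes available for subtype {s!r} with positive hazard")
        codes_by_subtype[s] = np.array(codes, dtype=object)

    rng = np.random.default_rng(config.seed)
    subtypes = sorted(config.subtype_hazards)
    end64 = np.datetime64(config.data_end, "D")

    person_rows = []
    epi_child, epi_day, epi_code, epi_dom = [], [], [], []
    act_rows = []  # (child, day, source)
    enr_rows = []
    death_rows = []
    birth_rows = []

    for label, n_born in config.cohorts:
        imm_counts = np.asarray(
            config.immigration.get(label, np.zeros(N_AGE_BANDS, int)), int
        )
        start, last = academic_year_window(int(label.split("/")[0]))
        span = (last - start).days + 1
        start64 = np.datetime64(start, "D")
        tag = label.replace("/", "_")

        groups: list[tuple[np.ndarray, np.ndarray, int, bool]] = []
        # natives: ids, birth offsets, arrival band 0
        if n_born:
            ids = np.array([f"{tag}-{i:06d}" for i in range(n_born)], dtype=object)
            offs = rng.integers(0, span, n_born)
            groups.append((ids, offs, 0, False))
        for a in range(N_AGE_BANDS):
            m = int(imm_counts[a])
            if m:
                ids = np.array([f"{tag}-m{a:02d}-{i:06d}" for i in range(m)], dtype=object)
                offs = rng.integers(0, span, m)
                groups.append((ids, offs, a, True))

        for ids, offs, band, is_imm in groups:
            k = len(ids)
            bdates = start64 + offs.astype("timedelta64[D]")
            if is_imm:
                lo, hi = YEAR_START_DAYS[band], YEAR_START_DAYS[band + 1]
                arrival = rng.integers(lo, hi, k)
            else:
                arrival = np.zeros(k, dtype=np.int64)
            ev = {
                s: np.maximum(
                    sample_event_days(rng, config.subtype_hazards[s], k, band), arrival
                )
                for s in subtypes
            }
            death = np.maximum(sample_event_days(rng, config.mortality_hazard, k, band), arrival)
            emig = np.maximum(sample_event_days(rng, config.emigration_hazard, k, band), arrival)
            link_fail = (
                rng.random(k) < config.linkage_failure_prob if not is_imm else np.zeros(k, bool)
            )

            days_to_end = (end64 - bdates).astype("timedelta64[D]").astype(np.int64)
            # last day (exclusive) on which any record can exist
            horizon = np.minimum.reduce(
                [death + 1, emig, days_to_end + 1, np.full(k, AGE16_DAYS, dtype=np.int64)]
            )
            horizon = np.maximum(horizon, arrival)

            any_chc_day = np.minimum.reduce(list(ev.values())) if ev else np.full(k, NO_EVENT)

            # CHC-coded admissions (visible onsets only)
            for s in subtypes:
                d = ev[s]
                vis = d < horizon
                if vis.any():
                    idx = np.flatnonzero(vis)
                    epi_child.extend(ids[idx])
                    epi_day.extend(d[idx])
                    epi_code.extend(rng.choice(codes_by_subtype[s], size=idx.size))
                    epi_dom.extend([False] * idx.size)

            # birth episodes for all HES-recorded births
            if not is_imm:
                epi_child.extend(ids)
                epi_day.extend(np.zeros(k, dtype=np.int64))
                epi_code.extend([BIRTH_CODE] * k)
                epi_dom.extend([False] * k)
                birth_rows.append(pd.DataFrame({"child_id": ids, "birth_date": bdates, "cohort": label}))

            # background (non-CHC) admissions; rate boosted for CHC children
            rate = np.where(
                any_chc_day < NO_EVENT,
                config.background_admission_rate * config.chc_admission_multiplier,
                config.background_admission_rate,
            )
            expo = np.maximum(horizon - arrival, 0) / 365.25
            nbg = rng.poisson(rate * expo)
            rep = np.repeat(np.arange(k), nbg)
            if rep.size:
                u = rng.random(rep.size)
                bg_days = arrival[rep] + np.floor(u * (horizon[rep] - arrival[rep])).astype(np.int64)
                epi_child.extend(ids[rep])
                epi_day.extend(bg_days)
                epi_code.extend([FILLER_CODE] * rep.size)
                epi_dom.extend([False] * rep.size)

            # emigrants: optional single final episode with non-England domicile
            emigrated = (emig < death) & (emig <= days_to_end) & (emig < AGE16_DAYS)
            recorded = emigrated & (rng.random(k) < config.domicile_recording_prob)
            if recorded.any():
                idx = np.flatnonzero(recorded)
                epi_child.extend(ids[idx])
                epi_day.extend(emig[idx])
                epi_code.extend([FILLER_CODE] * idx.size)
                epi_dom.extend([True] * idx.size)

            # outpatient / A&E contacts
            for source, r in (("OP", config.outpatient_rate), ("AE", config.ae_rate)):
                ncontact = rng.poisson(r * expo)
                rep = np.repeat(np.arange(k), ncontact)
                if rep.size:
                    u = rng.random(rep.size)
                    ds = arrival[rep] + np.floor(u * (horizon[rep] - arrival[rep])).astype(np.int64)
                    act_rows.append(
                        pd.DataFrame({"child_id": ids[rep], "day": ds, "source": source, "birth_date": bdates[rep]})
                    )

            # school enrolments at ages 4..15 while present
            enrolled = rng.random(k) < config.enrolment_prob
            for a in range(4, 16):
                d_a = years_to_days(a)
                mask = enrolled & (arrival <= d_a) & (d_a < horizon)
                if mask.any():
                    idx = np.flatnonzero(mask)
                    enr_rows.append(
                        pd.DataFrame({"child_id": ids[idx], "day": d_a, "birth_date": bdates[idx]})
                    )

            died = (death < emig) & (death <= days_to_end) & (death < AGE16_DAYS)
            if died.any():
                idx = np.flatnonzero(died & ~link_fail)
                death_rows.append(
                    pd.DataFrame({"child_id": ids[idx], "day": death[idx], "birth_date": bdates[idx]})
                )

            person_rows.append(
                pd.DataFrame(
                    {
                        "child_id": ids,
                        "birth_date": bdates,
                        "cohort": label,
                        "immigrant": is_imm,
                        "arrival_day": arrival,
                        "linkage_failed": link_fail,
                        "death_day": np.where(death < NO_EVENT, death, -1),
                        "emigration_day": np.where(emig < NO_EVENT, emig, -1),
                        "end_of_data_day": days_to_end,
                    }
                )
            )
            if link_fail.any():
                # later records of linkage-failure children are unlinkable:
                # mark them for removal below
                pass

    persons = pd.concat(person_rows, ignore_index=True)
    births = (
        pd.concat(birth_rows, ignore_index=True)
        if birth_rows
        else pd.DataFrame(columns=["child_id", "birth_date", "cohort"])
    )
    failed = set(persons.loc[persons["linkage_failed"], "child_id"])

    epi = pd.DataFrame(
        {
            "child_id": epi_child,
            "age_days": np.asarray(epi_day, dtype=np.int64),
            "code": epi_code,
            "non_england": epi_dom,
        }
    )
    if failed:
        epi = epi[~(epi["child_id"].isin(failed) & (epi["age_days"] > 0))]
    # one episode row per (child, day): codes pooled across positions
    grouped = (
        epi.sort_values(["child_id", "age_days", "code"], kind="stable")
        .groupby(["child_id", "age_days"], sort=True)
        .agg(codes=("code", lambda s: list(dict.fromkeys(s))), non_england=("non_england", "any"))
        .reset_index()
    )
    diag = _expand_diag_columns(grouped["codes"])
    bdate_map = persons.set_index("child_id")["birth_date"]
    episodes = pd.concat(
        [
            grouped[["child_id", "age_days"]].reset_index(drop=True),
            pd.DataFrame(
                {
                    "date": pd.to_datetime(grouped["child_id"].map(bdate_map))
                    + pd.to_timedelta(grouped["age_days"], unit="D"),
                    "domicile": np.where(grouped["non_england"], "non-England", "England"),
                }
            ),
            diag,
        ],
        axis=1,
    )[["child_id", "date", "age_days", "domicile"] + list(diag.columns)]

    apc = episodes[["child_id", "age_days"]].assign(source="APC")
    apc["date"] = episodes["date"]
    if act_rows:
        opae = pd.concat(act_rows, ignore_index=True)
        opae = opae[~opae["child_id"].isin(failed)]
        opae["date"] = pd.to_datetime(opae["birth_date"]) + pd.to_timedelta(opae["day"], unit="D")
        opae = opae.rename(columns={"day": "age_days"})[["child_id", "age_days", "source", "date"]]
    else:
        opae = pd.DataFrame(columns=["child_id", "age_days", "source", "date"])
    if config.staggered_availability and len(opae):
        cutoffs = {"OP": pd.Timestamp(2004, 4, 1), "AE": pd.Timestamp(2007, 4, 1)}
        keep = opae.apply(lambda r: r["date"] >= cutoffs[r["source"]], axis=1)
        opae = opae[keep]
    frames = [apc] + ([opae] if len(opae) else [])
    activity = (
        pd.concat(frames, ignore_index=True)
        .sort_values(["child_id", "age_days", "source"], kind="stable")
        .reset_index(drop=True)[["child_id", "date", "age_days", "source"]]
    )

    def _datestamp(rows, cols):
        if not rows:
            return pd.DataFrame(columns=["child_id", "date", "age_days"])
        df = pd.concat(rows, ignore_index=True)
        df = df[~df["child_id"].isin(failed)]
        df["date"] = pd.to_datetime(df["birth_date"]) + pd.to_timedelta(df["day"], unit="D")
        return (
            df.rename(columns={"day": "age_days"})[cols]
            .sort_values(["child_id", "age_days"], kind="stable")
            .reset_index(drop=True)
        )

    enrolments = _datestamp(enr_rows, ["child_id", "date", "age_days"])
    deaths = _datestamp(death_rows, ["child_id", "date", "age_days"])

    truth = SyntheticTruth(
        cuminc={s: truth_curve(config, s) for s in list(subtypes) + [ANY]}
    )
    persons = persons.sort_values("child_id", kind="stable").reset_index(drop=True)
    births = births.sort_values("child_id", kind="stable").reset_index(drop=True)
    return SyntheticData(
        config=config,
        persons=persons,
        births=births,
        episodes=episodes.reset_index(drop=True),
        activity=activity,
        enrolments=enrolments,
        deaths=deaths,
        truth=truth,
    )


def resident_population(
    data: SyntheticData, ages: Sequence[int] | None = None, calendar: str = "financial"
) -> pd.DataFrame:
    """Ground-truth mid-year resident population per cohort and age.

    A child counts toward age ``a`` if resident (arrived, alive, not yet
    emigrated) at exact age ``a + 0.5`` and that day falls within the data
    window.  This plays the role of an external population-estimate series
    for the open-cohort estimator.  ``calendar`` selects financial- or
    academic-year birth cohorts.
    """
    from .ages import academic_year, financial_year, year_label as _yl

    ages = list(range(N_AGE_BANDS)) if ages is None else list(ages)
    p = data.persons
    bdates = pd.to_datetime(p["birth_date"])
    if calendar == "financial":
        years = np.where(bdates.dt.month >= 4, bdates.dt.year, bdates.dt.year - 1)
    elif calendar == "academic":
        years = np.where(bdates.dt.month >= 9, bdates.dt.year, bdates.dt.year - 1)
    else:
        raise ValueError("calendar must be 'financial' or 'academic'")
    cohorts = pd.Series([_yl(int(y)) for y in years], index=p.index)
    death = p["death_day"].to_numpy()
    emig = p["emigration_day"].to_numpy()
    death = np.where(death < 0, NO_EVENT, death)
    emig = np.where(emig < 0, NO_EVENT, emig)
    arrival = p["arrival_day"].to_numpy()
    end = p["end_of_data_day"].to_numpy()
    out = []
    for a in ages:
        mid = years_to_days(a + 0.5)
        resident = (arrival <= mid) & (mid < death) & (mid < emig) & (mid <= end)
        counts = cohorts[resident].value_counts()
        for label, cnt in counts.items():
            out.append((label, a, int(cnt)))
    return (
        pd.DataFrame(out, columns=["cohort", "age", "population"])
        .sort_values(["cohort", "age"], ignore_index=True)
    )
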