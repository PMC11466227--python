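"""Per-child histories, eligibility variants and censored follow-up.

The closed design follows academic-year birth cohorts (Sep-Aug, 2002/3 to
2011/12 by default) from birth to the earliest of: first chronic-condition
record, death, first hospital contact with a non-England domicile, the 16th
birthday, or the administrative end of data (31 August 2019).  A
chronic-condition record on the same day as a censoring cause counts as an
event (birth-episode conditions at day 0 must be countable).  Events on the
16th birthday itself are out of window: censoring is at the day count of the
16th birthday (5844 days), events strictly before it.

Eligibility: every variant requires a recorded live birth; the main analysis
additionally requires any later hospital activity before 16 and/or a link to
school (NPD) records, and seven sensitivity variants tighten or relax these
requirements.  "Subsequent HES activity" means any admitted-patient,
outpatient or emergency-department contact after the birth day.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .ages import AGE16_DAYS, academic_year, year_label, years_to_days
from .codelist import ANY, ChcEvent

logger = logging.getLogger(__name__)

AGE5_DAYS = years_to_days(5)  # 1826

#: censor reasons, in tie-break priority order
CENSOR_REASONS = ("death", "non-England domicile", "16th birthday", "administrative end")

DEFAULT_ADMIN_END = dt.date(2019, 8, 31)


class DataQualityError(ValueError):
    """Raised when assembled records are internally impossible (e.g. dated after death)."""


def assign_cohort(
    birth_date: dt.date, first_year: int = 2002, last_year: int = 2011
) -> str | None:
    """Academic-year cohort label for a birth date, or None if out of scope."""
    y = academic_year(birth_date)
    if not first_year <= y <= last_year:
        return None
    return year_label(y)


@dataclass(frozen=True)
class ChildHistory:
    """One child's assembled timeline (all ages in days since birth)."""

    child_id: str
    birth_date: dt.date | None  # None: no recorded birth (immigrant / unlinked)
    cohort: str | None = None
    activity: tuple[tuple[int, str], ...] = ()  # (age_days, source APC/OP/AE)
    enrolment_ages: tuple[int, ...] = ()
    death_age: int | None = None
    non_england_age: int | None = None
    events: tuple[ChcEvent, ...] = ()

    def event_age(self, subtype: str = ANY) -> int | None:
        for e in self.events:
            if e.subtype == subtype:
                return e.age_days
        return None

    def flags(self) -> dict[str, bool]:
        """Eligibility components; activity on the birth day is not 'subsequent'."""
        ages = [a for a, _ in self.activity if a > 0]
        return {
            "birth": self.birth_date is not None,
            "hes_lt5": any(a < AGE5_DAYS for a in ages),
            "hes_5to16": any(AGE5_DAYS <= a < AGE16_DAYS for a in ages),
            "hes_lt16": any(a < AGE16_DAYS for a in ages),
            "npd": len(self.enrolment_ages) > 0,
        }


@dataclass(frozen=True)
class EligibilitySpec:
    """One inclusion rule: conjunction of required components.

    ``hes_or_npd`` encodes the main analysis's disjunction (any HES activity
    before 16 OR any NPD record).
    """

    label: str
    hes_lt5: bool = False
    hes_5to16: bool = False
    hes_lt16: bool = False
    npd: bool = False
    hes_or_npd: bool = False

    def required(self) -> list[str]:
        req = ["birth"]
        for name in ("hes_lt5", "hes_5to16", "hes_lt16", "npd"):
            if getattr(self, name):
                req.append(name)
        if self.hes_or_npd:
            req.append("hes_lt16 OR npd")
        return req


#: the main analysis and the seven sensitivity variants
VARIANTS: dict[str, EligibilitySpec] = {
    "main": EligibilitySpec("main", hes_or_npd=True),
    "s1": EligibilitySpec("s1"),
    "s2": EligibilitySpec("s2", hes_lt5=True),
    "s3": EligibilitySpec("s3", hes_lt16=True),
    "s4": EligibilitySpec("s4", npd=True),
    "s5": EligibilitySpec("s5", hes_lt5=True, npd=True),
    "s6": EligibilitySpec("s6", hes_lt5=True, hes_5to16=True),
    "s7": EligibilitySpec("s7", hes_lt5=True, hes_5to16=True, npd=True),
}


def apply_eligibility(
    history: ChildHistory | Mapping[str, bool], spec: EligibilitySpec
) -> tuple[bool, str]:
    """(included, reason).  A child with no birth record is excluded, never an error."""
    flags = history.flags() if isinstance(history, ChildHistory) else dict(history)
    if not flags["birth"]:
        return False, "no birth record"
    for name in ("hes_lt5", "hes_5to16", "hes_lt16", "npd"):
        if getattr(spec, name) and not flags[name]:
            return False, f"missing {name}"
    if spec.hes_or_npd and not (flags["hes_lt16"] or flags["npd"]):
        return False, "missing hes_lt16 or npd"
    return True, "included"


@dataclass(frozen=True)
class FollowUp:
    child_id: str
    time: int  # days from birth to endpoint
    event: bool
    reason: str  # "event" or a CENSOR_REASONS member


def build_followup(
    history: ChildHistory,
    admin_end: dt.date = DEFAULT_ADMIN_END,
    subtype: str = ANY,
) -> FollowUp:
    """Censored time-to-first-record for one included child.

    Endpoint is the earliest of first matching chronic-condition record,
    death, first non-England-domicile contact, 16th birthday, administrative
    end of data.  Same-day ties between the event and a censoring cause are
    resolved in favour of the event.
    """
    if history.birth_date is None:
        raise ValueError(f"child {history.child_id}: follow-up requires a birth date")
    admin_days = (admin_end - history.birth_date).days
    if admin_days < 0:
        raise ValueError(f"child {history.child_id}: born after administrative end")
    candidates = [
        (history.death_age, "death"),
        (history.non_england_age, "non-England domicile"),
        (AGE16_DAYS, "16th birthday"),
        (admin_days, "administrative end"),
    ]
    cens_time, cens_reason = min(
        ((t, r) for t, r in candidates if t is not None),
        key=lambda tr: (tr[0], CENSOR_REASONS.index(tr[1])),
    )
    ev = history.event_age(subtype)
    if ev is not None and ev < 0:
        raise DataQualityError(f"child {history.child_id}: negative event time {ev}")
    if ev is not None and ev <= cens_time and ev < AGE16_DAYS:
        return FollowUp(history.child_id, int(ev), True, "event")
    return FollowUp(history.child_id, int(cens_time), False, cens_reason)


# ---------------------------------------------------------------------------
# frame-level assembly (vectorized path used by the pipeline)
# ---------------------------------------------------------------------------


def summarize_children(
    births: pd.DataFrame,
    activity: pd.DataFrame,
    enrolments: pd.DataFrame,
    deaths: pd.DataFrame,
    episodes: pd.DataFrame | None = None,
    admin_end: dt.date = DEFAULT_ADMIN_END,
) -> pd.DataFrame:
    """One row per born child: eligibility flags and censoring ages.

    ``births`` needs child_id, birth_date, cohort; ``activity`` child_id,
    age_days, source; ``enrolments``/``deaths`` child_id, age_days;
    ``episodes`` (optional) supplies non-England-domicile contacts via its
    ``domicile`` column.  Records dated after a child's death raise
    :class:`DataQualityError`.
    """
    out = births[["child_id", "birth_date", "cohort"]].copy()
    out["birth_date"] = pd.to_datetime(out["birth_date"])
    out["admin_days"] = (pd.Timestamp(admin_end) - out["birth_date"]).dt.days
    if (out["admin_days"] < 0).any():
        raise ValueError("children born after the administrative end of data")

    death_age = deaths.groupby("child_id")["age_days"].min()
    out["death_age"] = out["child_id"].map(death_age)

    act = activity[activity["age_days"] > 0]
    merged = act.merge(out[["child_id", "death_age"]], on="child_id", how="inner")
    late = merged["death_age"].notna() & (merged["age_days"] > merged["death_age"])
    if late.any():
        bad = merged.loc[late, "child_id"].unique()[:5]
        logger.error("records dated after death for children %s", list(bad))
        raise DataQualityError(f"activity recorded after death (e.g. {bad[0]})")

    ages = act["age_days"]
    out["hes_lt5"] = out["child_id"].isin(set(act.loc[ages < AGE5_DAYS, "child_id"]))
    out["hes_5to16"] = out["child_id"].isin(
        set(act.loc[(ages >= AGE5_DAYS) & (ages < AGE16_DAYS), "child_id"])
    )
    out["hes_lt16"] = out["child_id"].isin(set(act.loc[ages < AGE16_DAYS, "child_id"]))
    out["npd"] = out["child_id"].isin(set(enrolments["child_id"])).astype(bool)
    out["birth"] = True

    if episodes is not None and "domicile" in episodes.columns:
        ne = episodes[episodes["domicile"] == "non-England"]
        ne_age = ne.groupby("child_id")["age_days"].min()
        out["non_england_age"] = out["child_id"].map(ne_age)
    else:
        out["non_england_age"] = np.nan
    return out


def eligibility_mask(summary: pd.DataFrame, variant: str) -> pd.Series:
    """Boolean inclusion per child under a named variant (vectorized)."""
    spec = VARIANTS[variant]
    mask = summary["birth"].astype(bool)
    for name in ("hes_lt5", "hes_5to16", "hes_lt16", "npd"):
        if getattr(spec, name):
            mask &= summary[name]
    if spec.hes_or_npd:
        mask &= summary["hes_lt16"] | summary["npd"]
    return mask


def followup_frame(
    summary: pd.DataFrame,
    events: pd.DataFrame,
    subtype: str = ANY,
    admin_end: dt.date | None = None,
) -> pd.DataFrame:
    """Vectorized :func:`build_followup` over a child summary frame.

    ``events`` is the tidy ascertainment output (child_id, subtype,
    age_days).  Returns child_id, time, event, reason.  ``admin_end`` is
    already baked into ``summary.admin_days``; passing it here recomputes.
    """
    df = summary.copy()
    if admin_end is not None:
        df["admin_days"] = (pd.Timestamp(admin_end) - pd.to_datetime(df["birth_date"])).dt.days
    ev = events[events["subtype"] == subtype].set_index("child_id")["age_days"]
    ev_age = df["child_id"].map(ev)

    cand = np.column_stack(
        [
            df["death_age"].fillna(np.inf).to_numpy(float),
            df["non_england_age"].fillna(np.inf).to_numpy(float),
            np.full(len(df), AGE16_DAYS, float),
            df["admin_days"].to_numpy(float),
        ]
    )
    cens_time = cand.min(axis=1)
    cens_idx = cand.argmin(axis=1)  # argmin takes the first minimum: priority order
    e = ev_age.to_numpy(float)
    is_event = ~np.isnan(e) & (e <= cens_time) & (e < AGE16_DAYS)
    time = np.where(is_event, e, cens_time).astype(int)
    if (time < 0).any():
        raise DataQualityError("negative follow-up time")
    reason = np.where(is_event, "event", np.array(CENSOR_REASONS, dtype=object)[cens_idx])
    return pd.DataFrame(
        {"child_id": df["child_id"], "time": time, "event": is_event, "reason": reason}
    )


def history_from_row(
    row: pd.Series,
    activity: pd.DataFrame,
    enrolments: pd.DataFrame,
    events: pd.DataFrame,
) -> ChildHistory:
    """Materialize one ChildHistory from the frame representation (test aid)."""
    cid = row["child_id"]
    act = activity[activity["child_id"] == cid]
    enr = enrolments[enrolments["child_id"] == cid]
    evs = events[events["child_id"] == cid]
    return ChildHistory(
        child_id=cid,
        birth_date=pd.Timestamp(row["birth_date"]).date(),
        cohort=row.get("cohort"),
        activity=tuple(zip(act["age_days"].astype(int), act["source"])),
        enrolment_ages=tuple(enr["age_days"].astype(int)),
        death_age=None if pd.isna(row.get("death_age")) else int(row["death_age"]),
        non_england_age=None
        if pd.isna(row.get("non_england_age"))
        else int(row["non_england_age"]),
        events=tuple(
            ChcEvent(cid, r["subtype"], int(r["age_days"]), r.get("code", ""))
            for _, r in evs.iterrows()
        ),
    )
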