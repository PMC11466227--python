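"""Closed-cohort cumulative incidence: product-limit and competing-risk estimators.

The cumulative incidence of a first chronic-condition record is one minus
the Kaplan-Meier survival estimate, with right censoring at death, first
non-England-domicile contact, the 16th birthday or the administrative end of
data.  A competing-risk variant (Aalen-Johansen) treats death as a competing
event instead of censoring.  Both estimators are implemented here directly —
ties are resolved by evaluating events before removing same-time censorings,
i.e. censored children remain in the risk set at their censoring time — so
they can be validated against exhaustive risk-set oracles and third-party
cross-checks in tests.

Curves are step functions, right-continuous, evaluated at every distinct
event time and reported at whole-year ages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .ages import years_to_days
from .cohort import FollowUp

#: cohort pairs used for subtype reporting, with pooled follow-up horizons
COHORT_PAIRS: tuple[tuple[tuple[str, str], int], ...] = (
    (("2002/3", "2003/4"), 16),
    (("2004/5", "2005/6"), 14),
    (("2006/7", "2007/8"), 12),
    (("2008/9", "2009/10"), 10),
    (("2010/11", "2011/12"), 8),
)


def cohort_horizon_years(label: str, end_year: int = 2019) -> int:
    """Maximum attained age (whole years) for a cohort followed to ``end_year``."""
    return min(16, end_year - int(label.split("/")[0]))


@dataclass
class IncidenceCurve:
    """A right-continuous cumulative-incidence step function.

    ``times`` are the distinct event days (sorted); ``cum_inc[i]`` is the
    estimate at and after ``times[i]``; ``at_risk``/``events`` are the risk
    set size and event count at each time.  ``se`` is the Greenwood-type
    standard error of the estimate (diagnostic only).
    """

    times: np.ndarray
    cum_inc: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray
    se: np.ndarray | None = None
    cohort: str | None = None
    variant: str | None = None
    subtype: str | None = None
    method: str = "km"

    def __post_init__(self) -> None:
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(np.diff(self.cum_inc) < -1e-12) or np.any(self.cum_inc < -1e-12):
            raise ValueError("cumulative incidence must be non-decreasing and >= 0")
        if np.any(self.cum_inc > 1 + 1e-12):
            raise ValueError("cumulative incidence must be <= 1")

    def value_at(self, day: float) -> float:
        """Estimate just after ``day`` (0 before the first event time)."""
        i = np.searchsorted(self.times, day, side="right") - 1
        return 0.0 if i < 0 else float(self.cum_inc[i])

    def at_year_ages(self, max_year: int = 16) -> pd.DataFrame:
        """Whole-year-age table: value by step interpolation, events within year."""
        rows = []
        for a in range(max_year + 1):
            day = years_to_days(a)
            lo = years_to_days(a - 1) if a else 0
            in_year = (self.times >= lo) & (self.times < day)
            n_at = int(self.at_risk[self.times >= lo][0]) if (self.times >= lo).any() else 0
            rows.append(
                {
                    "age_years": a,
                    # value strictly before the a-th birthday ("by age a")
                    "cum_inc": self.value_at(day - 1),
                    "n_at_risk": n_at,
                    "n_events": int(self.events[in_year].sum()),
                }
            )
        return pd.DataFrame(rows)


def _extract(followups) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(times, event?, death?) from FollowUp objects or a tidy frame."""
    if isinstance(followups, pd.DataFrame):
        t = followups["time"].to_numpy(float)
        e = followups["event"].to_numpy(bool)
        d = (followups["reason"] == "death").to_numpy() if "reason" in followups else np.zeros(len(t), bool)
    else:
        fus = list(followups)
        t = np.array([f.time for f in fus], float)
        e = np.array([f.event for f in fus], bool)
        d = np.array([(not f.event) and f.reason == "death" for f in fus], bool)
    if len(t) == 0:
        raise ValueError("no follow-up records")
    if (t < 0).any():
        raise ValueError("negative follow-up times")
    return t, e, d


def km_cuminc(followups, **meta) -> IncidenceCurve:
    """One minus the product-limit survival estimate.

    At each distinct event time t: ``S <- S * (1 - d_t / n_t)`` with
    ``n_t = #{time >= t}`` (same-time censorings still at risk).
    """
    t, e, _ = _extract(followups)
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    ut, inv = np.unique(t, return_inverse=True)
    d = np.bincount(inv, weights=e.astype(float))
    n_leaving = np.bincount(inv)
    n_at = len(t) - np.concatenate([[0], np.cumsum(n_leaving)[:-1]])
    keep = d > 0
    td, dd, nd = ut[keep], d[keep], n_at[keep]
    frac = 1.0 - dd / nd
    surv = np.cumprod(frac)
    # Greenwood variance of S, hence of 1-S
    green = np.cumsum(dd / (nd * (nd - dd + (dd == nd))))  # guard 0-division when S hits 0
    se = surv * np.sqrt(green)
    return IncidenceCurve(
        times=td.astype(int),
        cum_inc=1.0 - surv,
        at_risk=nd.astype(int),
        events=dd.astype(int),
        se=se,
        method="km",
        **meta,
    )


def aj_cuminc(followups, **meta) -> IncidenceCurve:
    """Aalen-Johansen cause-specific cumulative incidence with death competing.

    Deaths (censor reason "death") become competing events: they leave the
    risk set through the overall survival factor but do not contribute to the
    condition-specific incidence.  Without deaths this reduces exactly to
    :func:`km_cuminc`.
    """
    t, e, death = _extract(followups)
    order = np.argsort(t, kind="stable")
    t, e, death = t[order], e[order], death[order]
    ut, inv = np.unique(t, return_inverse=True)
    d1 = np.bincount(inv, weights=e.astype(float))
    d2 = np.bincount(inv, weights=death.astype(float))
    n_leaving = np.bincount(inv)
    n_at = len(t) - np.concatenate([[0], np.cumsum(n_leaving)[:-1]])
    any_d = (d1 + d2) > 0
    tt, dd1, dd2, nn = ut[any_d], d1[any_d], d2[any_d], n_at[any_d]
    surv_all = np.cumprod(1.0 - (dd1 + dd2) / nn)
    s_minus = np.concatenate([[1.0], surv_all[:-1]])
    cif = np.cumsum(s_minus * dd1 / nn)
    keep = dd1 > 0  # report at event times of the cause of interest
    return IncidenceCurve(
        times=tt[keep].astype(int),
        cum_inc=cif[keep],
        at_risk=nn[keep].astype(int),
        events=dd1[keep].astype(int),
        method="aj",
        **meta,
    )


def clip_followups(followups: pd.DataFrame, horizon_days: int) -> pd.DataFrame:
    """Re-censor follow-ups at a shorter horizon (administrative end of the pair)."""
    df = followups.copy()
    over = df["time"] > horizon_days
    df.loc[over, "time"] = horizon_days
    df.loc[over, "event"] = False
    df.loc[over, "reason"] = "administrative end"
    return df


def pair_cohorts(
    followups_by_cohort: Mapping[str, pd.DataFrame],
    pairs: Sequence[tuple[tuple[str, str], int]] = COHORT_PAIRS,
    estimator=km_cuminc,
    variant: str | None = None,
    subtype: str | None = None,
) -> dict[str, IncidenceCurve]:
    """Pooled re-estimation for paired cohorts (not an average of curves).

    The pooled follow-up horizon is the pair's configured horizon (the
    shorter member's maximum attainable age); longer follow-ups are
    re-censored at it.
    """
    out: dict[str, IncidenceCurve] = {}
    for (a, b), horizon in pairs:
        if a not in followups_by_cohort or b not in followups_by_cohort:
            continue
        fa, fb = followups_by_cohort[a], followups_by_cohort[b]
        for f in (fa, fb):
            if variant is not None and "variant" in getattr(f, "attrs", {}) and f.attrs["variant"] != variant:
                raise ValueError(f"variant mismatch pooling {a}+{b}")
        pooled = pd.concat([fa, fb], ignore_index=True)
        pooled = clip_followups(pooled, years_to_days(horizon))
        out[f"{a}+{b}"] = estimator(
            pooled, cohort=f"{a}+{b}", variant=variant, subtype=subtype
        )
    return out


def suppress_small(
    yearly: pd.DataFrame, threshold: int = 10
) -> tuple[pd.DataFrame, bool]:
    """Mask small cells in a whole-year-age table for disclosure control.

    Grid points whose within-year event count is below ``threshold`` get a
    masked (NaN) ``cum_inc`` and ``suppressed=True``; if the table's total
    event count is below the threshold the whole subtype is flagged as not
    reportable.  The underlying estimation is untouched.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    out = yearly.copy()
    out["suppressed"] = (out["n_events"] < threshold) & (threshold > 0)
    out.loc[out["suppressed"], "cum_inc"] = np.nan
    reportable = int(yearly["n_events"].sum()) >= threshold
    return out, reportable


def curves_to_table(curves: Mapping[str, IncidenceCurve], max_year_by_key=None) -> pd.DataFrame:
    """Tidy export: cohort, variant, subtype, age_years, cum_inc, n_at_risk, n_events."""
    frames = []
    for key, c in curves.items():
        max_year = 16 if max_year_by_key is None else max_year_by_key[key]
        t = c.at_year_ages(max_year)
        t.insert(0, "subtype", c.subtype)
        t.insert(0, "variant", c.variant)
        t.insert(0, "cohort", c.cohort if c.cohort is not None else key)
        frames.append(t)
    return pd.concat(frames, ignore_index=True)
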