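"""Multimorbidity: distinct body-system subtypes per child by landmark ages.

A child is multimorbid at a landmark age if chronic-condition records in two
or more distinct body-system subtype groups were first recorded strictly
before that birthday.  The reported proportion conditions on having at least
one subtype recorded, so it is a measure of complexity among affected
children.  Repeat records within a subtype never add to the count, and
multiple distinct conditions within one subtype are invisible by design — a
documented limitation of body-system counting.

Chronic infections count toward the subtype tally by default even though
their incidence curve is suppressed from reporting elsewhere (the reporting
exclusion is presentational); pass ``exclude=("chronic infections",)`` to
drop them.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import pandas as pd

from .ages import years_to_days
from .codelist import ANY, ChcEvent

LANDMARKS = (5, 11, 16)


def subtype_count(events: Iterable[ChcEvent], landmark_age: int, exclude: Sequence[str] = ()) -> int:
    """Distinct subtypes first recorded strictly before the landmark birthday."""
    cutoff = years_to_days(landmark_age)
    return len(
        {
            e.subtype
            for e in events
            if e.subtype != ANY and e.subtype not in exclude and e.age_days < cutoff
        }
    )


def summarize(
    events: pd.DataFrame,
    landmarks: Sequence[int] = LANDMARKS,
    followup_years: int = 16,
    cohort: str | None = None,
    exclude: Sequence[str] = (),
) -> pd.DataFrame:
    """Per-landmark multimorbidity table for one cohort's ascertained events.

    ``events`` is the tidy ascertainment output (child_id, subtype,
    age_days) for the children under analysis.  Returns one row per landmark:
    cohort, landmark_age, n_ge1, n_ge2, prop_multimorbid (= n_ge2 / n_ge1;
    children with no recorded subtype are excluded from the denominator).
    A landmark beyond the cohort's follow-up raises ``ValueError``.
    """
    for lm in landmarks:
        if lm > followup_years:
            raise ValueError(f"landmark {lm} beyond follow-up of {followup_years} years")
    ev = events[(events["subtype"] != ANY) & ~events["subtype"].isin(exclude)]
    rows = []
    for lm in landmarks:
        cutoff = years_to_days(lm)
        sub = ev[ev["age_days"] < cutoff]
        counts = sub.groupby("child_id")["subtype"].nunique()
        n_ge1 = int((counts >= 1).sum())
        n_ge2 = int((counts >= 2).sum())
        rows.append(
            {
                "cohort": cohort,
                "landmark_age": lm,
                "n_ge1": n_ge1,
                "n_ge2": n_ge2,
                "prop_multimorbid": (n_ge2 / n_ge1) if n_ge1 else float("nan"),
            }
        )
    return pd.DataFrame(rows)
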