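"""Multimorbidity: children with more than one body system affected.

Among included children with at least one recorded subtype, the proportion
with two or more distinct body-system subtypes by ages 5, 11 and 16
(landmarks truncated to each cohort's follow-up horizon).
"""

import pandas as pd

from study import study_data, write_result

from chcincidence.cohort import eligibility_mask, summarize_children
from chcincidence.morbidity import LANDMARKS, summarize
from chcincidence.surv_closed import cohort_horizon_years


def main() -> None:
    cfg, data, events = study_data()
    summary = summarize_children(
        data.births, data.activity, data.enrolments, data.deaths,
        episodes=data.episodes, admin_end=cfg.data_end,
    )
    included = summary[eligibility_mask(summary, "main")]
    ev_inc = events[events["child_id"].isin(set(included["child_id"]))]

    tables = []
    for cohort, grp in included.groupby("cohort"):
        horizon = cohort_horizon_years(cohort, cfg.data_end.year)
        lms = [lm for lm in LANDMARKS if lm <= horizon]
        if not lms:
            continue
        ev_c = ev_inc[ev_inc["child_id"].isin(set(grp["child_id"]))]
        tables.append(summarize(ev_c, landmarks=lms, followup_years=horizon, cohort=cohort))
    out = pd.concat(tables, ignore_index=True)
    path = write_result(out, "multimorbidity.csv")

    full = out[out["cohort"] == "2002/3"].set_index("landmark_age")
    print("2002/3 cohort (followed to 16): of children with any subtype,")
    for lm in LANDMARKS:
        r = full.loc[lm]
        print(f"  {r['prop_multimorbid']:.0%} have more than one body system by age {lm} "
              f"({r['n_ge2']}/{r['n_ge1']})")
    print(f"table -> {path}")


if __name__ == "__main__":
    main()
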