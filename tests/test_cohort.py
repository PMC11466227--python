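"""Cohort assignment, Table-style eligibility variants, censored follow-up."""

import datetime as dt
import itertools

import numpy as np
import pandas as pd
import pytest

from chcincidence.ages import AGE16_DAYS
from chcincidence.codelist import ANY, ChcEvent, extract_events_frame
from chcincidence.cohort import (
    DEFAULT_ADMIN_END,
    VARIANTS,
    ChildHistory,
    DataQualityError,
    FollowUp,
    apply_eligibility,
    assign_cohort,
    build_followup,
    eligibility_mask,
    followup_frame,
    history_from_row,
    summarize_children,
)
from chcincidence.synth import default_code_list


@pytest.mark.parametrize(
    "date,label",
    [
        (dt.date(2002, 9, 1), "2002/3"),
        (dt.date(2003, 8, 31), "2002/3"),
        (dt.date(2011, 9, 1), "2011/12"),
        (dt.date(2012, 8, 31), "2011/12"),
    ],
)
def test_academic_cohort_boundaries(date, label):
    assert assign_cohort(date) == label


def test_cohort_out_of_scope_marker():
    assert assign_cohort(dt.date(2002, 8, 31)) is None
    assert assign_cohort(dt.date(2012, 9, 1)) is None


def hist(**kw) -> ChildHistory:
    base = dict(child_id="c", birth_date=dt.date(2002, 9, 1))
    base.update(kw)
    return ChildHistory(**base)


class TestEligibility:
    def test_birth_record_only(self):
        h = hist()
        assert apply_eligibility(h, VARIANTS["main"])[0] is False
        assert apply_eligibility(h, VARIANTS["s1"])[0] is True

    def test_birth_plus_npd_no_later_hes(self):
        h = hist(enrolment_ages=(1826,))
        assert apply_eligibility(h, VARIANTS["main"])[0] is True
        assert apply_eligibility(h, VARIANTS["s4"])[0] is True
        assert apply_eligibility(h, VARIANTS["s2"])[0] is False

    def test_single_outpatient_contact_age_six(self):
        h = hist(activity=((2200, "OP"),))
        results = {
            v: apply_eligibility(h, VARIANTS[v])[0] for v in ("main", "s3", "s2", "s6")
        }
        assert results == {"main": True, "s3": True, "s2": False, "s6": False}

    def test_no_birth_record_excluded_never_error(self):
        h = ChildHistory(child_id="imm", birth_date=None, activity=((100, "APC"),))
        for v in VARIANTS.values():
            ok, reason = apply_eligibility(h, v)
            assert not ok and reason == "no birth record"

    def test_truth_table_against_brute_force(self):
        """All 16 flag combinations against an independent restatement of the rules."""

        def oracle(variant, lt5, b516, npd):
            lt16 = lt5 or b516
            return {
                "main": lt16 or npd,
                "s1": True,
                "s2": lt5,
                "s3": lt16,
                "s4": npd,
                "s5": lt5 and npd,
                "s6": lt5 and b516,
                "s7": lt5 and b516 and npd,
            }[variant]

        for lt5, b516, npd in itertools.product([False, True], repeat=3):
            activity = ()
            if lt5:
                activity += ((100, "APC"),)
            if b516:
                activity += ((3000, "AE"),)
            h = hist(activity=activity, enrolment_ages=(1900,) if npd else ())
            for v, spec in VARIANTS.items():
                assert apply_eligibility(h, spec)[0] == oracle(v, lt5, b516, npd), (
                    v,
                    lt5,
                    b516,
                    npd,
                )

    def test_birth_day_activity_not_subsequent(self):
        h = hist(activity=((0, "APC"),))
        assert apply_eligibility(h, VARIANTS["s2"])[0] is False


class TestFollowUp:
    def test_birth_episode_event_time_zero(self):
        h = hist(events=(ChcEvent("c", ANY, 0, "K529"),))
        fu = build_followup(h)
        assert fu == FollowUp("c", 0, True, "event")

    def test_death_censoring(self):
        h = hist(death_age=3 * 365)
        fu = build_followup(h)
        assert (fu.time, fu.event, fu.reason) == (1095, False, "death")

    def test_sixteenth_birthday_vs_administrative_end(self):
        # born at the start of the earliest cohort: the 16th birthday comes first
        fu = build_followup(hist(birth_date=dt.date(2002, 9, 1)))
        assert (fu.time, fu.reason) == (AGE16_DAYS, "16th birthday")
        # born at the start of the last cohort: administrative end at ~age 8
        fu = build_followup(hist(birth_date=dt.date(2011, 9, 1)))
        assert fu.reason == "administrative end"
        assert fu.time == (dt.date(2019, 8, 31) - dt.date(2011, 9, 1)).days
        assert 7.9 < fu.time / 365.25 <= 8.01

    def test_event_on_censor_day_wins(self):
        h = hist(death_age=200, events=(ChcEvent("c", ANY, 200, "J45"),))
        fu = build_followup(h)
        assert fu.event and fu.time == 200

    def test_event_on_sixteenth_birthday_out_of_window(self):
        h = hist(events=(ChcEvent("c", ANY, AGE16_DAYS, "J45"),))
        fu = build_followup(h)
        assert not fu.event and fu.time == AGE16_DAYS

    def test_non_england_domicile_censoring(self):
        h = hist(non_england_age=500, events=(ChcEvent("c", ANY, 600, "J45"),))
        fu = build_followup(h)
        assert (fu.time, fu.event, fu.reason) == (500, False, "non-England domicile")

    def test_subtype_specific_followup(self):
        h = hist(
            events=(
                ChcEvent("c", ANY, 100, "J45"),
                ChcEvent("c", "respiratory", 100, "J45"),
            )
        )
        assert build_followup(h, subtype="respiratory").event
        assert not build_followup(h, subtype="neurological").event


@pytest.fixture(scope="module")
def world(quiet_cohort_data):
    cfg, data = quiet_cohort_data
    code_list = default_code_list()
    events = extract_events_frame(data.episodes, code_list)
    summary = summarize_children(
        data.births, data.activity, data.enrolments, data.deaths,
        episodes=data.episodes,
    )
    return data, events, summary


class TestFrameAssembly:
    def test_variant_nesting_on_synthetic_data(self, world):
        _, _, summary = world
        inc = {v: set(summary.loc[eligibility_mask(summary, v), "child_id"]) for v in VARIANTS}
        assert inc["s7"] <= inc["s6"] <= inc["s2"] <= inc["s1"]
        assert inc["s3"] | inc["s4"] <= inc["main"]
        assert inc["s7"] <= inc["s5"] <= inc["s4"]

    def test_followup_time_bounds_and_tallies(self, world):
        _, events, summary = world
        inc = summary[eligibility_mask(summary, "main")]
        fu = followup_frame(inc, events)
        assert len(fu) == len(inc)
        assert ((fu["time"] >= 0) & (fu["time"] <= AGE16_DAYS)).all()
        assert (fu["event"] == (fu["reason"] == "event")).all()
        assert fu["event"].sum() + (~fu["event"]).sum() == len(inc)

    def test_frame_path_agrees_with_scalar_path(self, world):
        data, events, summary = world
        inc = summary[eligibility_mask(summary, "main")]
        fu = followup_frame(inc, events).set_index("child_id")
        rng = np.random.default_rng(1)
        sample = inc.iloc[rng.choice(len(inc), size=40, replace=False)]
        for _, row in sample.iterrows():
            h = history_from_row(row, data.activity, data.enrolments, events)
            scalar = build_followup(h, admin_end=DEFAULT_ADMIN_END)
            got = fu.loc[row["child_id"]]
            assert (scalar.time, scalar.event, scalar.reason) == (
                int(got["time"]),
                bool(got["event"]),
                got["reason"],
            )
            for v, spec in VARIANTS.items():
                assert apply_eligibility(h, spec)[0] == bool(
                    eligibility_mask(summary, v)[row.name]
                )

    def test_records_after_death_rejected(self):
        births = pd.DataFrame(
            {"child_id": ["a"], "birth_date": [pd.Timestamp("2003-01-01")], "cohort": ["2002/3"]}
        )
        activity = pd.DataFrame({"child_id": ["a"], "age_days": [900], "source": ["OP"]})
        deaths = pd.DataFrame({"child_id": ["a"], "age_days": [100]})
        enrol = pd.DataFrame({"child_id": [], "age_days": []})
        with pytest.raises(DataQualityError, match="after death"):
            summarize_children(births, activity, enrol, deaths)
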