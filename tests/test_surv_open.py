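"""Open-cohort estimator: formula fixtures, invariants, migration robustness."""

import datetime as dt
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chcincidence.ages import AGE16_DAYS
from chcincidence.codelist import ANY, extract_events_frame
from chcincidence.cohort import eligibility_mask, followup_frame, summarize_children
from chcincidence.surv_closed import km_cuminc
from chcincidence.surv_open import (
    PopulationSeries,
    count_incident_by_age,
    financial_cohort,
    load_population_csv,
    max_age_for_cohort,
    open_cuminc,
    reconcile,
)
from chcincidence.synth import (
    SimulationConfig,
    default_code_list,
    generate,
    resident_population,
    truth_curve,
)

ZERO = (0.0,) * 16


class TestFormula:
    def test_single_age_fixture(self):
        curve = open_cuminc([10], [100])
        # independent evaluation: h = 10/100, CI = 1 - e^{-0.1}
        assert curve["hazard"].iloc[0] == pytest.approx(0.1, abs=1e-12)
        assert curve["cum_inc"].iloc[0] == pytest.approx(1 - math.exp(-0.1), abs=1e-9)

    def test_two_age_discounted_fixture(self):
        curve = open_cuminc([10, 10], [100, 100])
        # age 1 denominator discounted by the 10 prior cases
        assert curve["denom"].tolist() == [100, 90]
        ih = 10 / 100 + 10 / 90
        assert curve["IH"].iloc[1] == pytest.approx(ih, abs=1e-12)
        assert curve["cum_inc"].iloc[1] == pytest.approx(1 - math.exp(-ih), abs=1e-9)

    def test_all_zero_cases(self):
        curve = open_cuminc([0] * 16, [100] * 16)
        assert (curve["cum_inc"] == 0).all()

    def test_discount_alternative_includes_current_age(self):
        curve = open_cuminc([10, 10], [100, 100], include_current_age=True)
        assert curve["denom"].tolist() == [90, 80]

    def test_denominator_errors_name_the_age(self):
        with pytest.raises(ValueError, match="age 1"):
            open_cuminc([10, 0], [100, 5])
        with pytest.raises(ValueError, match="age 0"):
            open_cuminc([150], [100])


class TestInvariants:
    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        cases=st.lists(st.integers(0, 20), min_size=1, max_size=16),
        factor=st.integers(2, 50),
    )
    def test_scaling_invariance(self, cases, factor):
        pop = [1000.0] * len(cases)
        a = open_cuminc(cases, pop)
        b = open_cuminc([c * factor for c in cases], [p * factor for p in pop])
        assert np.allclose(a["cum_inc"], b["cum_inc"], atol=1e-14)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(cases=st.lists(st.integers(0, 6), min_size=1, max_size=16))
    def test_small_hazard_limit(self, cases):
        pop = [10_000.0] * len(cases)
        crude = sum(cases) / 10_000.0
        if crude > 0.01:
            return
        curve = open_cuminc(cases, pop)
        assert abs(curve["cum_inc"].iloc[-1] - crude) <= 5e-5 + crude**2

    def test_monotone_and_below_one(self):
        rng = np.random.default_rng(0)
        cases = rng.integers(0, 50, 16)
        curve = open_cuminc(cases, [1000.0] * 16)
        assert (np.diff(curve["cum_inc"]) >= -1e-15).all()
        assert (curve["cum_inc"] < 1).all()


class TestCaseCounting:
    def test_financial_year_boundaries(self):
        assert financial_cohort(dt.date(2003, 3, 31)) == "2002/3"
        assert financial_cohort(dt.date(2003, 4, 1)) == "2003/4"

    def test_counts_by_completed_year_of_age(self):
        persons = pd.DataFrame(
            {
                "child_id": ["a", "b", "c"],
                "birth_date": pd.to_datetime(["2003-05-01"] * 3),
            }
        )
        events = pd.DataFrame(
            {
                "child_id": ["a", "b", "c"],
                "subtype": [ANY] * 3,
                "age_days": [0, 100, 5 * 366],
            }
        )
        counts = count_incident_by_age(events, persons)
        assert dict(zip(counts["age"], counts["cases"])) == {0: 2, 5: 1}
        assert (counts["cohort"] == "2003/4").all()

    def test_no_events_empty(self):
        persons = pd.DataFrame({"child_id": ["a"], "birth_date": pd.to_datetime(["2003-05-01"])})
        counts = count_incident_by_age(
            pd.DataFrame({"child_id": [], "subtype": [], "age_days": []}), persons
        )
        assert counts.empty

    def test_events_at_or_beyond_sixteen_excluded(self, caplog):
        persons = pd.DataFrame({"child_id": ["a", "b"], "birth_date": pd.to_datetime(["2003-05-01"] * 2)})
        events = pd.DataFrame(
            {"child_id": ["a", "b"], "subtype": [ANY, ANY], "age_days": [AGE16_DAYS, 10]}
        )
        with caplog.at_level("INFO"):
            counts = count_incident_by_age(events, persons)
        assert counts["cases"].sum() == 1

    def test_max_age_shrinks_for_later_cohorts(self):
        assert max_age_for_cohort("2002/3", 2019) == 16
        assert max_age_for_cohort("2018/19", 2019) == 2  # ages 0..1 observable
        assert max_age_for_cohort("2010/11", 2019) == 10


def test_population_csv_roundtrip(tmp_path):
    p = tmp_path / "pop.csv"
    p.write_text("cohort,age,population\n2002/3,0,100\n2002/3,1,90\n")
    series = load_population_csv(p)
    assert series["2002/3"].counts.tolist() == [100.0, 90.0]
    p.write_text("cohort,age,population\n2002/3,1,90\n")
    with pytest.raises(ValueError, match="contiguous"):
        load_population_csv(p)


class TestReconcile:
    def test_identical_curves_pass(self):
        rep = reconcile([0.1, 0.2], [0.1, 0.2], tolerance=0.0)
        assert rep["max_diff"] == 0.0 and rep["passed"]

    def test_zero_tolerance_fails_on_any_difference(self):
        rep = reconcile([0.1], [0.100001], tolerance=0.0)
        assert not rep["passed"]

    def test_grid_mismatch(self):
        with pytest.raises(ValueError, match="grid mismatch"):
            reconcile([0.1, 0.2], [0.1], tolerance=0.01)


def test_immigration_robustness_open_recovers_truth_closed_s1_biased():
    """With unrecorded emigration and immigration, the open design stays close
    to truth while a birth-record-only closed cohort is biased low."""
    cfg = SimulationConfig(
        seed=42,
        cohorts=(("2002/3", 20_000),),
        subtype_hazards={"respiratory": (0.02,) * 16},
        mortality_hazard=ZERO,
        emigration_hazard=(0.03,) * 16,
        immigration={"2002/3": (500,) * 16},
        domicile_recording_prob=0.0,  # departures invisible to the data
        linkage_failure_prob=0.0,
        enrolment_prob=0.97,
    )
    data = generate(cfg)
    truth16 = truth_curve(cfg)[16]
    code_list = default_code_list()
    events = extract_events_frame(data.episodes, code_list)

    summary = summarize_children(
        data.births, data.activity, data.enrolments, data.deaths,
        episodes=data.episodes, admin_end=cfg.data_end,
    )
    s1 = summary[eligibility_mask(summary, "s1")]
    closed = km_cuminc(followup_frame(s1, events))
    closed16 = closed.value_at(AGE16_DAYS - 1)

    pop = resident_population(data, calendar="financial")
    cases = count_incident_by_age(events, data.persons)
    label = "2002/3"
    series = PopulationSeries(
        label, pop.loc[pop["cohort"] == label, "population"].to_numpy()
    )
    case_map = dict(
        zip(*cases.loc[cases["cohort"] == label, ["age", "cases"]].T.values)
    )
    open16 = open_cuminc(case_map, series, 15)["cum_inc"].iloc[-1]

    assert closed16 < truth16 - 0.02  # unmeasured emigration deflates the closed estimate
    assert abs(open16 - truth16) < abs(closed16 - truth16)
    assert open16 == pytest.approx(truth16, abs=0.02)
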