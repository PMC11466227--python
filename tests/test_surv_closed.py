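"""Product-limit and Aalen-Johansen estimators against hand and library oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chcincidence.ages import AGE16_DAYS, years_to_days
from chcincidence.cohort import FollowUp
from chcincidence.surv_closed import (
    COHORT_PAIRS,
    aj_cuminc,
    clip_followups,
    cohort_horizon_years,
    km_cuminc,
    pair_cohorts,
    suppress_small,
)


def fu(time, event, reason=None):
    return FollowUp("c", time, event, reason or ("event" if event else "administrative end"))


def frame(pairs):
    return pd.DataFrame(
        {
            "child_id": [f"c{i}" for i in range(len(pairs))],
            "time": [t for t, _ in pairs],
            "event": [e for _, e in pairs],
            "reason": ["event" if e else "administrative end" for _, e in pairs],
        }
    )


class TestKaplanMeier:
    def test_no_informative_censoring_empirical_fraction(self):
        fus = [fu(100, True), fu(200, True), fu(AGE16_DAYS, False), fu(AGE16_DAYS, False)]
        curve = km_cuminc(fus)
        assert curve.cum_inc[-1] == pytest.approx(0.5)

    def test_all_censored_identically_zero(self):
        curve = km_cuminc([fu(10, False), fu(20, False)])
        assert curve.times.size == 0
        assert curve.value_at(10**6) == 0.0

    def test_hand_product_limit_with_censoring(self):
        # events {2}, censored {1, 3}: at t=2 the risk set is 2, one event
        curve = km_cuminc([fu(1, False), fu(2, True), fu(3, False)])
        assert curve.value_at(2) == pytest.approx(0.5)
        assert curve.at_risk.tolist() == [2]

    def test_same_day_censoring_stays_at_risk(self):
        # censoring at an event time is evaluated after the event
        curve = km_cuminc([fu(5, True), fu(5, False)])
        assert curve.value_at(5) == pytest.approx(0.5)

    def test_order_and_duplication_invariance(self):
        base = [fu(3, True), fu(1, False), fu(7, True), fu(7, False), fu(2, True)]
        c1 = km_cuminc(base)
        c2 = km_cuminc(list(reversed(base)))
        assert np.array_equal(c1.times, c2.times)
        assert np.allclose(c1.cum_inc, c2.cum_inc)
        c3 = km_cuminc(base + base)
        assert np.allclose(c1.cum_inc, c3.cum_inc)
        assert np.array_equal(c3.at_risk, 2 * c1.at_risk)

    def test_errors(self):
        with pytest.raises(ValueError, match="no follow-up"):
            km_cuminc([])
        with pytest.raises(ValueError, match="negative"):
            km_cuminc([fu(-1, True)])

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(
        times=st.lists(st.integers(1, 6), min_size=1, max_size=8),
    )
    def test_zero_censoring_equals_empirical_cdf(self, times):
        fus = [fu(t, True) for t in times]
        curve = km_cuminc(fus)
        n = len(times)
        for t in range(0, 8):
            assert curve.value_at(t) == pytest.approx(
                sum(1 for x in times if x <= t) / n
            )

    def test_cross_check_against_lifelines(self):
        from lifelines import KaplanMeierFitter

        rng = np.random.default_rng(2)
        t = rng.integers(1, 2000, 300)
        e = rng.random(300) < 0.6
        curve = km_cuminc(frame(list(zip(t, e))))
        kmf = KaplanMeierFitter().fit(t, e)
        for day in [50, 300, 900, 1900]:
            assert curve.value_at(day) == pytest.approx(
                1 - kmf.predict(day), abs=1e-10
            )


class TestAalenJohansen:
    def test_no_deaths_equals_km(self):
        fus = [fu(3, True), fu(5, False), fu(9, True), fu(11, False)]
        km, aj = km_cuminc(fus), aj_cuminc(fus)
        assert np.array_equal(km.times, aj.times)
        assert np.allclose(km.cum_inc, aj.cum_inc, atol=1e-15)

    def test_two_child_hand_calculation(self):
        fus = [fu(10, True), fu(5, False, reason="death")]
        aj = aj_cuminc(fus)
        km = km_cuminc(fus)
        assert aj.value_at(10) == pytest.approx(0.5)
        assert km.value_at(10) == pytest.approx(1.0)

    def test_dominance_under_heavy_mortality(self):
        rng = np.random.default_rng(5)
        n = 2000
        t_ev = rng.exponential(3000, n)
        t_death = rng.exponential(1500, n)
        t_cens = np.full(n, AGE16_DAYS)
        time = np.minimum.reduce([t_ev, t_death, t_cens]).astype(int) + 1
        event = (t_ev <= t_death) & (t_ev <= t_cens)
        death = (t_death < t_ev) & (t_death <= t_cens)
        df = pd.DataFrame(
            {
                "child_id": [f"c{i}" for i in range(n)],
                "time": time,
                "event": event,
                "reason": np.where(event, "event", np.where(death, "death", "administrative end")),
            }
        )
        km, aj = km_cuminc(df), aj_cuminc(df)
        grid = np.arange(0, AGE16_DAYS, 200)
        km_v = np.array([km.value_at(d) for d in grid])
        aj_v = np.array([aj.value_at(d) for d in grid])
        assert (aj_v <= km_v + 1e-12).all()
        assert aj_v[-1] < km_v[-1]  # strict somewhere under heavy mortality

    def test_cause_specific_incidences_sum_below_one(self):
        rng = np.random.default_rng(8)
        n = 500
        time = rng.integers(1, 5000, n)
        kind = rng.integers(0, 3, n)  # 0 censored, 1 chc, 2 death
        df = pd.DataFrame(
            {
                "child_id": [f"c{i}" for i in range(n)],
                "time": time,
                "event": kind == 1,
                "reason": np.select([kind == 1, kind == 2], ["event", "death"], "administrative end"),
            }
        )
        chc = aj_cuminc(df)
        # swap the roles to get the death CIF
        df2 = df.assign(
            event=kind == 2,
            reason=np.select([kind == 2, kind == 1], ["event", "death"], "administrative end"),
        )
        death = aj_cuminc(df2)
        for d in range(0, 5100, 250):
            assert chc.value_at(d) + death.value_at(d) <= 1 + 1e-12

    def test_cross_check_against_lifelines(self):
        from lifelines import AalenJohansenFitter

        rng = np.random.default_rng(3)
        n = 300
        # distinct times: the library resolves ties by random jitter, which
        # would break exact agreement
        time = rng.choice(np.arange(1, 2001), size=n, replace=False)
        kind = rng.integers(0, 3, n)
        df = pd.DataFrame(
            {
                "child_id": range(n),
                "time": time,
                "event": kind == 1,
                "reason": np.select([kind == 1, kind == 2], ["event", "death"], "administrative end"),
            }
        )
        aj = aj_cuminc(df)
        ajf = AalenJohansenFitter(calculate_variance=False).fit(
            time, kind, event_of_interest=1
        )
        for d in [100, 500, 1500]:
            lib = float(ajf.cumulative_density_.loc[: d].iloc[-1, 0]) if (ajf.cumulative_density_.index <= d).any() else 0.0
            assert aj.value_at(d) == pytest.approx(lib, abs=1e-9)


class TestPairingAndSuppression:
    def test_pair_horizons(self):
        assert cohort_horizon_years("2002/3") == 16
        assert cohort_horizon_years("2011/12") == 8
        horizons = {f"{a}+{b}": h for (a, b), h in COHORT_PAIRS}
        assert horizons["2002/3+2003/4"] == 16
        assert horizons["2010/11+2011/12"] == 8

    def test_pooling_identical_cohorts_reproduces_curve(self):
        fus = frame([(100, True), (900, True), (2000, False), (5844, False)])
        single = km_cuminc(clip_followups(fus, years_to_days(16)))
        paired = pair_cohorts(
            {"2002/3": fus, "2003/4": fus},
            pairs=((("2002/3", "2003/4"), 16),),
        )["2002/3+2003/4"]
        assert np.allclose(single.cum_inc, paired.cum_inc)

    def test_clip_recensors_beyond_horizon(self):
        fus = frame([(100, True), (4000, True)])
        clipped = clip_followups(fus, years_to_days(8))
        assert clipped.loc[1, "time"] == years_to_days(8)
        assert not clipped.loc[1, "event"]

    def test_suppression(self):
        yearly = pd.DataFrame(
            {"age_years": [1, 2, 3], "cum_inc": [0.1, 0.2, 0.3], "n_at_risk": [100, 90, 80], "n_events": [12, 3, 0]}
        )
        none, ok = suppress_small(yearly, threshold=0)
        assert not none["suppressed"].any() and ok
        some, ok = suppress_small(yearly, threshold=10)
        assert some["suppressed"].tolist() == [False, True, True]
        assert some["cum_inc"].isna().tolist() == [False, True, True]
        assert ok  # 15 total events >= 10
        allm, ok = suppress_small(yearly, threshold=100)
        assert allm["suppressed"].all() and not ok
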