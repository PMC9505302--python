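"""Competing-risk estimators: Aalen–Johansen CIF, MH hazard ratio, Gray's test."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from repgvhd.errors import (EmptyCohortError, UndefinedStatisticError,
                            ValidationError)
from repgvhd.survival import (apply_administrative_censoring,
                              cumulative_incidence, grays_test,
                              mantel_haenszel_hr)


def events_df(times, codes, groups=None):
    df = pd.DataFrame({"time": times, "event": codes})
    if groups is not None:
        df["group"] = groups
    return df


class TestEventValidation:
    def test_nonpositive_time_rejected(self):
        with pytest.raises(ValidationError):
            cumulative_incidence(events_df([0.0, 1.0], ["event", "event"]))

    def test_unknown_code_rejected(self):
        with pytest.raises(ValidationError):
            cumulative_incidence(events_df([1.0], ["relapse"]))

    def test_empty_cohort(self):
        with pytest.raises(EmptyCohortError):
            cumulative_incidence(events_df([], []))

    def test_administrative_censoring_caps_at_36_months(self):
        df = events_df([10.0, 40.0, 50.0], ["event", "event", "competing"])
        capped = apply_administrative_censoring(df)
        assert capped["time"].max() == 36.0
        assert list(capped["event"]) == ["event", "censored", "censored"]


class TestAalenJohansen:
    def test_all_events_reduce_to_empirical_cdf(self):
        c = cumulative_incidence(events_df([1, 2, 3, 4], ["event"] * 4))
        np.testing.assert_allclose(c.cif, [0.25, 0.5, 0.75, 1.0])

    def test_all_censored_gives_zero(self):
        c = cumulative_incidence(events_df([1, 2, 3], ["censored"] * 3))
        np.testing.assert_allclose(c.cif, 0.0)

    def test_hand_worked_competing_risk_example(self):
        # 3 subjects: event at 1, competing at 2, event at 3.
        # CIF(1) = 1/3; S(3-) = 1/3; CIF(3) = 1/3 + (1/3)(1/1) = 2/3.
        c = cumulative_incidence(events_df([1, 2, 3],
                                           ["event", "competing", "event"]))
        np.testing.assert_allclose(c.cif, [1 / 3, 1 / 3, 2 / 3])
        np.testing.assert_allclose(c.n_risk, [3, 2, 1])

    def test_conservation_without_censoring(self):
        # endpoint CIF + competing CIF + all-cause survival == 1 at any time
        rng = np.random.default_rng(7)
        times = rng.exponential(10, 30).round(1) + 0.1
        codes = rng.choice(["event", "competing"], 30)
        df = events_df(times, codes)
        c1 = cumulative_incidence(df)
        flipped = df.assign(event=df["event"].map(
            {"event": "competing", "competing": "event"}))
        c2 = cumulative_incidence(flipped)
        total = c1.cif + c2.cif + c1.survival
        np.testing.assert_allclose(total, 1.0, atol=1e-12)

    def test_matches_lifelines_aalen_johansen(self):
        from lifelines import AalenJohansenFitter

        rng = np.random.default_rng(11)
        times = rng.exponential(12, 40).round(2) + 0.01
        status = rng.choice([0, 1, 2], 40, p=[0.3, 0.4, 0.3])
        df = events_df(times, pd.Series(status).map(
            {0: "censored", 1: "event", 2: "competing"}))
        mine = cumulative_incidence(df)
        ajf = AalenJohansenFitter(calculate_variance=False)
        ajf.fit(times, status, event_of_interest=1)
        for t in mine.times:
            theirs = float(ajf.cumulative_density_.loc[
                ajf.cumulative_density_.index <= t].iloc[-1, 0]) \
                if (ajf.cumulative_density_.index <= t).any() else 0.0
            assert mine.at(t) == pytest.approx(theirs, abs=1e-10)

    def test_step_evaluation(self):
        c = cumulative_incidence(events_df([2, 4], ["event", "event"]))
        assert c.at(1.0) == 0.0
        assert c.at(2.0) == pytest.approx(0.5)
        assert c.at(100.0) == pytest.approx(1.0)


class TestMantelHaenszelHR:
    def test_identical_histories_give_unit_hr(self):
        df = events_df([1, 2, 3, 1, 2, 3], ["event"] * 6,
                       ["A"] * 3 + ["B"] * 3)
        r = mantel_haenszel_hr(df)
        assert r.effect == pytest.approx(1.0)

    def test_hand_built_risk_table_worksheet(self):
        # A: events at 1, 2 (n=2); B: events at 3, 4 (n=2).
        # t=1: n=(2,2), d=(1,0): E1 += 1/2.  t=2: n=(1,2): E1 += 1/3.
        # t=3,4: A exhausted, E1 += 0.  O1=2, E1=5/6; O2=2, E2=1/2+2/3+1+1=19/6.
        # HR = (2/(5/6)) / (2/(19/6)) = 19/5 = 3.8
        # V = (1/4)(3/3) + (2/9)(2/2) = 17/36
        df = events_df([1, 2, 3, 4], ["event"] * 4, ["A", "A", "B", "B"])
        r = mantel_haenszel_hr(df)
        assert r.effect == pytest.approx(3.8, rel=1e-12)
        half = 1.96 / np.sqrt(17 / 36)
        assert r.ci_low == pytest.approx(3.8 * np.exp(-half), rel=1e-9)
        assert r.ci_high == pytest.approx(3.8 * np.exp(half), rel=1e-9)

    def test_label_swap_inverts_hr(self):
        rng = np.random.default_rng(3)
        df = events_df(rng.exponential(10, 30) + 0.1,
                       rng.choice(["event", "censored"], 30, p=[0.7, 0.3]),
                       rng.choice(["A", "B"], 30))
        r1 = mantel_haenszel_hr(df)
        r2 = mantel_haenszel_hr(df.assign(group=df["group"].map({"A": "B", "B": "A"})))
        assert r1.effect == pytest.approx(1.0 / r2.effect, rel=1e-9)

    def test_competing_events_censored_for_hr(self):
        base = events_df([1, 2, 3, 4], ["event", "censored", "event", "censored"],
                         ["A", "A", "B", "B"])
        comp = events_df([1, 2, 3, 4], ["event", "competing", "event", "competing"],
                         ["A", "A", "B", "B"])
        assert mantel_haenszel_hr(base).effect == \
            pytest.approx(mantel_haenszel_hr(comp).effect)

    def test_no_events_anywhere_is_undefined(self):
        df = events_df([1, 2], ["censored", "censored"], ["A", "B"])
        with pytest.raises(UndefinedStatisticError):
            mantel_haenszel_hr(df)

    def test_zero_events_in_one_group_flagged(self):
        df = events_df([1, 2, 3, 4], ["event", "event", "censored", "censored"],
                       ["A", "A", "B", "B"])
        r = mantel_haenszel_hr(df)
        assert r.effect == float("inf")
        assert "zero events" in r.notes


TOY8 = pd.DataFrame({
    "time": [1, 2, 3, 4, 5, 6, 7, 8],
    "event": ["event", "competing", "event", "censored",
              "event", "event", "competing", "censored"],
    "group": ["A", "B", "A", "B", "A", "B", "A", "B"],
})


class TestGraysTest:
    def test_identical_groups_give_null(self):
        df = events_df([1, 2, 3, 1, 2, 3],
                       ["event", "competing", "event"] * 2,
                       ["A"] * 3 + ["B"] * 3)
        r = grays_test(df)
        assert r.statistic == pytest.approx(0.0, abs=1e-12)
        assert r.p_value == pytest.approx(1.0)

    def test_reduces_to_logrank_without_competing_events(self):
        rng = np.random.default_rng(19)
        for _ in range(5):
            n = 20
            df = events_df(rng.exponential(10, n).round(2) + 0.01,
                           ["event"] * n, rng.choice(["A", "B"], n))
            gray = grays_test(df)
            logrank = mantel_haenszel_hr(df)  # same chi2 as the log-rank test
            assert gray.statistic == pytest.approx(logrank.statistic, abs=1e-9)
            assert gray.p_value == pytest.approx(logrank.p_value, abs=1e-6)

    def test_label_swap_invariant(self):
        r1 = grays_test(TOY8)
        r2 = grays_test(TOY8.assign(group=TOY8["group"].map({"A": "B", "B": "A"})))
        assert r1.statistic == pytest.approx(r2.statistic, rel=1e-12)
        assert r1.p_value == r2.p_value

    def test_no_endpoint_events_degenerate(self):
        df = events_df([1, 2], ["competing", "censored"], ["A", "B"])
        with pytest.raises(EmptyCohortError):
            grays_test(df)

    def test_agrees_with_exact_permutation_distribution(self):
        # all C(8,4)=70 label assignments; the chi-square reference is
        # asymptotic, so agreement on n=8 is coarse (support step 1/70)
        obs = grays_test(TOY8).statistic
        stats = []
        for combo in combinations(range(8), 4):
            lab = np.array(["B"] * 8)
            lab[list(combo)] = "A"
            stats.append(grays_test(TOY8.assign(group=lab)).statistic)
        p_perm = float(np.mean(np.asarray(stats) >= obs - 1e-12))
        assert grays_test(TOY8).p_value == pytest.approx(p_perm, abs=0.1)

    def test_close_to_reference_implementation_value(self):
        # frozen from R cmprsk::cuminc on this exact table; the simplified
        # variance makes the statistic differ by a few percent
        toy = pd.DataFrame({
            "time": [2, 3, 5, 6, 8, 10, 12, 15, 18, 20, 24, 30],
            "event": ["event", "competing", "event", "censored", "event",
                      "competing", "event", "censored", "event", "competing",
                      "censored", "event"],
            "group": ["A"] * 6 + ["B"] * 6,
        })
        r = grays_test(toy)
        assert r.statistic == pytest.approx(4.0569781506, rel=0.10)
        assert r.p_value == pytest.approx(0.0439891517, abs=0.02)
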