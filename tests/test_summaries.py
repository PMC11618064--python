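"""Step 3 — lag windows, risk sets, case-crossover sets, distributed lags."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import envlink as el


def _series(sid, start, values, flags=None):
    values = np.asarray(values, float)
    n = len(values)
    flags = np.array(flags if flags is not None else [el.FLAG_OK] * n, dtype=object)
    src = np.array(["a"] * n, dtype=object)
    return el.SubjectExposureSeries(sid, pd.Timestamp(start), values, src, flags)


class TestLagWindowSummary:
    def test_constant_series(self):
        s = _series("s", "2010-01-01", [7.0] * 30)
        v, c = el.lag_window_summary(s, "2010-01-20", el.LagWindow(0, 3))
        assert (v, c) == (7.0, 1.0)

    def test_hand_computed_mean(self):
        # values 1,2,3,4 on the four days ending at the index date
        s = _series("s", "2010-01-01", [9, 9, 1, 2, 3, 4])
        v, c = el.lag_window_summary(s, "2010-01-06", el.LagWindow(0, 3))
        assert v == pytest.approx(2.5) and c == 1.0

    def test_lag0_is_index_day(self):
        s = _series("s", "2010-01-01", [1, 2, 3, 4])
        v, _ = el.lag_window_summary(s, "2010-01-04", el.LagWindow(0, 0))
        assert v == 4.0

    def test_annual_window_equals_brute_force(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(10, 3, 400)
        s = _series("s", "2010-01-01", vals)
        idx = pd.Timestamp("2010-01-01") + pd.Timedelta(days=399)
        v, c = el.lag_window_summary(s, idx, el.LagWindow(0, 364))
        # brute-force loop over the 365 days ending at the index date
        brute = np.mean([vals[399 - lag] for lag in range(365)])
        assert c == 1.0 and v == pytest.approx(brute, rel=1e-12)

    def test_partial_window_below_threshold_is_missing(self):
        s = _series("s", "2010-01-10", [5.0] * 5)
        v, c = el.lag_window_summary(s, "2010-01-12", el.LagWindow(0, 9))
        assert np.isnan(v) and c == pytest.approx(0.3)

    def test_partial_window_mean_over_available_days(self):
        s = _series("s", "2010-01-10", [4.0, 6.0])
        w = el.LagWindow(0, 3, min_completeness=0.5)
        v, c = el.lag_window_summary(s, "2010-01-11", w)
        assert c == 0.5 and v == pytest.approx(5.0)

    def test_sum_aggregation(self):
        s = _series("s", "2010-01-01", [1, 2, 3, 4])
        v, _ = el.lag_window_summary(s, "2010-01-04", el.LagWindow(0, 3, aggregation="sum"))
        assert v == 10.0

    def test_gap_days_reduce_completeness(self):
        flags = [el.FLAG_OK, el.FLAG_NO_RESIDENCE, el.FLAG_OK, el.FLAG_OK]
        s = _series("s", "2010-01-01", [1, np.nan, 3, 4], flags)
        v, c = el.lag_window_summary(s, "2010-01-04", el.LagWindow(0, 3, min_completeness=0.5))
        assert c == 0.75 and v == pytest.approx((1 + 3 + 4) / 3)

    def test_backward_only_never_reads_future(self):
        base = [1.0] * 20
        clean = _series("s", "2010-01-01", base)
        poisoned_vals = list(base)
        for k in range(11, 20):  # poison every day after the index date
            poisoned_vals[k] = 1e15
        poisoned = _series("s", "2010-01-01", poisoned_vals)
        idx = "2010-01-11"
        for w in (el.LagWindow(0, 3), el.LagWindow(2, 9), el.LagWindow(0, 0)):
            assert el.lag_window_summary(clean, idx, w) == el.lag_window_summary(
                poisoned, idx, w
            )

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 5), st.integers(0, 10))
    def test_window_vs_brute_force_property(self, min_lag, extra):
        max_lag = min_lag + extra
        rng = np.random.default_rng(min_lag * 100 + extra)
        vals = rng.normal(size=40)
        s = _series("s", "2010-01-01", vals)
        idx = pd.Timestamp("2010-02-05")  # offset 35
        v, c = el.lag_window_summary(s, idx, el.LagWindow(min_lag, max_lag, min_completeness=0))
        days = [35 - lag for lag in range(min_lag, max_lag + 1) if 0 <= 35 - lag < 40]
        assert c == pytest.approx(len(days) / (max_lag - min_lag + 1))
        if days:
            assert v == pytest.approx(np.mean(vals[days]))


class TestCaseCrossoverControls:
    def test_known_wednesday_enumeration(self):
        controls = el.casecrossover_controls("2010-06-16")
        assert [str(d.date()) for d in controls] == [
            "2010-06-02", "2010-06-09", "2010-06-23", "2010-06-30",
        ]

    def test_four_occurrence_month_gives_three_controls(self):
        # February 2010 has exactly four Mondays
        assert len(el.casecrossover_controls("2010-02-08")) == 3

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.dates(pd.Timestamp("1980-01-01").date(), pd.Timestamp("2019-12-31").date()))
    def test_structural_properties(self, day):
        d = pd.Timestamp(day)
        controls = el.casecrossover_controls(d)
        assert d not in controls
        assert 3 <= len(controls) <= 4
        for c in controls:
            assert (c.year, c.month, c.dayofweek) == (d.year, d.month, d.dayofweek)
        # stratum symmetry: the case date is a control of each of its controls
        for c in controls:
            assert d in el.casecrossover_controls(c)


class TestRiskSets:
    @staticmethod
    def _cohort(n=3):
        rows = []
        for k in range(n):
            rows.append(
                {
                    "subject_id": f"s{k}",
                    "enrolment_date": "2010-01-01",
                    "last_followup_date": "2015-12-31",
                    "birth_date": str(pd.Timestamp("1955-01-01") + pd.Timedelta(days=200 * k)),
                }
            )
        subs = pd.DataFrame(rows)
        ev = pd.DataFrame(
            [{"subject_id": "s0", "icd_code": "C34", "event_date": "2012-06-01"}]
        )
        res = pd.DataFrame(
            [
                {"subject_id": f"s{k}", "location_id": f"l{k}", "start_date": "2009-01-01",
                 "end_date": "Present", "easting": 0.0, "northing": 0.0}
                for k in range(n)
            ]
        )
        return el.validate_cohort_frames(subs, ev, res, "2016-01-01")

    def test_single_subject_cohort_emits_warning_set(self):
        c = self._cohort(n=1)
        rs = el.build_risk_sets(c.subjects, c.events, {}, ["C34"], "time_on_study",
                                el.LagWindow(0, 0, min_completeness=0))
        assert len(rs) == 1 and len(rs[0].members) == 1
        assert rs[0].warnings

    def test_age_axis_exhaustive_eligibility(self):
        c = self._cohort(n=3)
        rs = el.build_risk_sets(c.subjects, c.events, {}, ["C34"], "age",
                                el.LagWindow(0, 0, min_completeness=0))
        (s,) = rs
        case_age = (pd.Timestamp("2012-06-01") - c.subjects["s0"].birth_date).days
        assert s.index_time_days == case_age
        # brute-force eligibility: control attains the case's age within follow-up
        expected = set()
        for sid, rec in c.subjects.items():
            if sid == "s0":
                continue
            attain = rec.birth_date + pd.Timedelta(days=case_age)
            if rec.enrolment_date <= attain <= rec.last_followup_date:
                expected.add(sid)
        assert {m.subject_id for m in s.controls} == expected
        for m in s.controls:
            rec = c.subjects[m.subject_id]
            assert (m.index_date - rec.birth_date).days == case_age

    def test_age_axis_requires_birth_dates(self):
        c = self._cohort(n=2)
        c.subjects["s1"].birth_date = None
        with pytest.raises(el.summaries.SummaryError, match="birth date"):
            el.build_risk_sets(c.subjects, c.events, {}, ["C34"], "age", el.LagWindow(0, 0))

    def test_controls_must_be_event_free_at_index(self):
        c = self._cohort(n=3)
        # give s1 a prior outcome event: no longer an eligible control
        c.events.append(
            el.HealthEvent("s1", "C34.1", pd.Timestamp("2011-01-01"))
        )
        rs = el.build_risk_sets(c.subjects, c.events, {}, ["C34"], "time_on_study",
                                el.LagWindow(0, 0, min_completeness=0))
        first = next(s for s in rs if s.event.subject_id == "s0")
        assert "s1" not in {m.subject_id for m in first.controls}

    def test_sampling_reproducible_and_bounded(self):
        c = self._cohort(n=3)
        a = el.build_risk_sets(c.subjects, c.events, {}, ["C34"], "time_on_study",
                               el.LagWindow(0, 0, min_completeness=0), n_controls=1, seed=5)
        b = el.build_risk_sets(c.subjects, c.events, {}, ["C34"], "time_on_study",
                               el.LagWindow(0, 0, min_completeness=0), n_controls=1, seed=5)
        assert [m.subject_id for m in a[0].members] == [m.subject_id for m in b[0].members]
        assert len(a[0].controls) == 1

    def test_icd_prefix_matching(self):
        assert el.summaries.matches_outcome("C34.1", ["C34"])
        assert el.summaries.matches_outcome("C341", ["C34"])
        assert not el.summaries.matches_outcome("C3", ["C34"])


class TestCaseCrossoverSets:
    def test_fully_observed_event(self):
        s = _series("s", "2010-05-01", np.arange(61.0))
        events = [el.HealthEvent("s", "J45", pd.Timestamp("2010-06-16"))]
        (cc,) = el.build_casecrossover_sets(events, {"s": s}, ["J45"], el.LagWindow(0, 3))
        assert len(cc.control_dates) in (3, 4)
        assert not cc.case_missing
        assert all(c == 1.0 for (_, c) in cc.exposures.values())

    def test_gap_on_control_date_lowers_completeness(self):
        flags = [el.FLAG_OK] * 61
        # poke a gap into the lag window of the 2010-06-02 control
        start = pd.Timestamp("2010-05-01")
        gap_k = (pd.Timestamp("2010-06-01") - start).days
        flags[gap_k] = el.FLAG_NO_RESIDENCE
        vals = np.arange(61.0)
        vals[gap_k] = np.nan
        s = _series("s", start, vals, flags)
        events = [el.HealthEvent("s", "J45", pd.Timestamp("2010-06-16"))]
        (cc,) = el.build_casecrossover_sets(
            events, {"s": s}, ["J45"], el.LagWindow(0, 3, min_completeness=1.0)
        )
        v, c = cc.exposures[pd.Timestamp("2010-06-02")]
        assert c == pytest.approx(0.75) and np.isnan(v)
        assert cc.exposures[cc.case_date][1] == 1.0

    def test_missing_case_summary_flagged_not_dropped(self):
        s = _series("s", "2010-06-14", [1.0, 2.0])  # window reaches before start
        events = [el.HealthEvent("s", "J45", pd.Timestamp("2010-06-16"))]
        (cc,) = el.build_casecrossover_sets(events, {"s": s}, ["J45"], el.LagWindow(0, 3))
        assert cc.case_missing

    def test_long_table_shape(self):
        s = _series("s", "2010-05-01", np.arange(61.0))
        events = [el.HealthEvent("s", "J45", pd.Timestamp("2010-06-16"))]
        df = el.casecrossover_sets_to_frame(
            el.build_casecrossover_sets(events, {"s": s}, ["J45"], el.LagWindow(0, 3))
        )
        assert df.case_flag.sum() == 1 and len(df) in (4, 5)


class TestDistributedLag:
    def test_single_stratum_consistent_with_lag_window(self):
        s = _series("s", "2010-01-01", np.random.default_rng(1).normal(size=50))
        idx = "2010-02-10"
        vals, comps = el.distributed_lag_matrix(s, idx, el.LagStrata(((0, 9),)))
        v, c = el.lag_window_summary(s, idx, el.LagWindow(0, 9))
        assert vals[0] == pytest.approx(v) and comps[0] == c

    def test_daily_strata_return_raw_lagged_values(self):
        s = _series("s", "2010-01-01", [1, 2, 3, 4])
        vals, _ = el.distributed_lag_matrix(s, "2010-01-04", el.LagStrata.daily(0, 3))
        assert np.allclose(vals, [4, 3, 2, 1])  # lag 0 = index-day value

    def test_yearly_strata_match_brute_force_split(self):
        rng = np.random.default_rng(8)
        vals = rng.normal(10, 2, 730)
        s = _series("s", "2010-01-01", vals)
        idx = pd.Timestamp("2010-01-01") + pd.Timedelta(days=729)
        out, comps = el.distributed_lag_matrix(s, idx, el.LagStrata.yearly(2))
        recent = np.mean([vals[729 - lag] for lag in range(0, 365)])
        older = np.mean([vals[729 - lag] for lag in range(365, 730)])
        assert np.allclose(out, [recent, older]) and np.allclose(comps, 1.0)

    def test_non_contiguous_strata_rejected(self):
        with pytest.raises(el.summaries.SummaryError):
            el.LagStrata(((0, 3), (5, 9)))

    def test_backward_only_with_poisoned_future(self):
        vals = np.ones(30)
        clean = _series("s", "2010-01-01", vals.copy())
        vals[16:] = 1e15
        poisoned = _series("s", "2010-01-01", vals)
        a, _ = el.distributed_lag_matrix(clean, "2010-01-16", el.LagStrata.yearly(1, min_completeness=0))
        b, _ = el.distributed_lag_matrix(poisoned, "2010-01-16", el.LagStrata.yearly(1, min_completeness=0))
        assert np.allclose(a, b, equal_nan=True)
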