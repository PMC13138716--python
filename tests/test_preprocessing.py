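"""Tests of the daily-record cleaning and cohort construction filters."""

import numpy as np
import pandas as pd
import pytest

from steptraj.preprocess import (PreprocessConfig, build_cohort,
                                 exclude_high_variance, filter_daily_range,
                                 preprocess, resolve_device_duplicates,
                                 select_shc_pair, weekly_average)


def _steps(rows):
    return pd.DataFrame(rows, columns=["participant_id", "date", "source",
                                       "steps"]).assign(
        date=lambda d: pd.to_datetime(d["date"]))


class TestDeviceDuplicates:
    def test_larger_value_wins(self):
        df = _steps([("a", "2022-01-01", "ios", 5000),
                     ("a", "2022-01-01", "android", 6000)])
        out = resolve_device_duplicates(df)
        assert len(out) == 1 and out["steps"].iloc[0] == 6000

    def test_single_source_kept(self):
        df = _steps([("a", "2022-01-01", "ios", 5000)])
        out = resolve_device_duplicates(df)
        pd.testing.assert_frame_equal(out, df)

    def test_tie_kept_once(self):
        df = _steps([("a", "2022-01-01", "ios", 5000),
                     ("a", "2022-01-01", "android", 5000)])
        out = resolve_device_duplicates(df)
        assert len(out) == 1 and out["steps"].iloc[0] == 5000

    def test_idempotent(self):
        df = _steps([("a", "2022-01-01", "ios", 100),
                     ("a", "2022-01-01", "android", 900),
                     ("b", "2022-01-02", "ios", 700)])
        once = resolve_device_duplicates(df)
        twice = resolve_device_duplicates(once)
        pd.testing.assert_frame_equal(once, twice)


class TestDailyRange:
    @pytest.mark.parametrize("steps, kept", [
        (199, False), (200, True), (50000, True), (50001, False),
        (0, False), (7000, True),
    ])
    def test_strict_bounds(self, steps, kept):
        df = _steps([("a", "2022-01-01", "ios", steps)])
        out = filter_daily_range(df)
        assert (len(out) == 1) is kept

    def test_invalid_bounds_rejected(self):
        df = _steps([("a", "2022-01-01", "ios", 100)])
        with pytest.raises(ValueError):
            filter_daily_range(df, lo=500, hi=500)


def _shc(pid, dates):
    n = len(dates)
    return pd.DataFrame({
        "participant_id": pid, "date": pd.to_datetime(dates),
        "weight_kg": 80.0, "bmi": 27.0, "age": 60, "sex": 1,
        "smoking": 0, "medication": 0,
    })


class TestShcPair:
    def test_closest_to_twelve_months(self):
        shc = _shc("a", ["2022-01-01", "2022-12-25", "2023-02-16"])
        first, second = select_shc_pair(shc)
        assert pd.Timestamp(second["date"]) == pd.Timestamp("2022-12-25")

    def test_single_eligible_pair(self):
        shc = _shc("a", ["2022-01-01", "2023-01-01"])
        first, second = select_shc_pair(shc)
        assert pd.Timestamp(second["date"]) == pd.Timestamp("2023-01-01")

    def test_nine_month_followup_excluded(self):
        shc = _shc("a", ["2022-01-01", "2022-10-01"])
        assert select_shc_pair(shc) is None

    def test_fifteen_month_followup_excluded(self):
        shc = _shc("a", ["2022-01-01", "2023-04-02"])
        assert select_shc_pair(shc) is None

    def test_calendar_month_window_boundaries(self):
        # 10 and 14 calendar months after Jan 31 clamp to month ends
        shc = _shc("a", ["2022-01-31", "2022-11-30"])
        assert select_shc_pair(shc) is not None
        shc = _shc("a", ["2022-01-31", "2022-11-29"])
        assert select_shc_pair(shc) is None

    def test_fewer_than_two_checkups(self):
        assert select_shc_pair(_shc("a", ["2022-01-01"])) is None


class TestWeeklyAverage:
    def _records(self, offsets, steps):
        d0 = pd.Timestamp("2022-01-01")
        return _steps([("a", (d0 + pd.Timedelta(days=o)).date().isoformat(),
                        "ios", s) for o, s in zip(offsets, steps)])

    def test_full_week_mean(self):
        rec = self._records(range(1, 8), [7000] * 7)
        out = weekly_average(rec, "2022-01-01", "2022-01-08")
        assert out["mean_steps"].tolist() == [7000.0]

    def test_mean_of_available_days(self):
        rec = self._records([1, 5], [6000, 8000])
        out = weekly_average(rec, "2022-01-01", "2022-01-08")
        assert out["mean_steps"].tolist() == [7000.0]

    def test_empty_week_excludes_participant(self):
        rec = self._records(list(range(1, 8)), [7000] * 7)  # week 2 empty
        assert weekly_average(rec, "2022-01-01", "2022-01-15") is None

    def test_checkup_day_not_counted(self):
        rec = self._records([0, 1], [100000, 5000])
        out = weekly_average(rec, "2022-01-01", "2022-01-08")
        assert out["mean_steps"].tolist() == [5000.0]

    def test_series_truncated_at_56_weeks(self):
        offsets = range(1, 7 * 60 + 1)
        rec = self._records(offsets, [6000] * (7 * 60))
        out = weekly_average(rec, "2022-01-01",
                             pd.Timestamp("2022-01-01") + pd.Timedelta(days=420))
        assert out["week"].max() == 56

    def test_reversed_dates_rejected(self):
        rec = self._records([1], [5000])
        with pytest.raises(ValueError):
            weekly_average(rec, "2022-02-01", "2022-01-01")


class TestHighVariance:
    def test_constant_series_never_excluded(self):
        df = _steps([("a", f"2022-01-{d:02d}", "ios", 5000) for d in range(1, 10)]
                    + [("b", f"2022-01-{d:02d}", "ios", 5000)
                       for d in range(1, 10)])
        out, excluded = exclude_high_variance(df)
        assert excluded == set()
        pd.testing.assert_frame_equal(out, df)

    def test_extreme_alternator_excluded(self):
        rows = []
        for pid in ("a", "b", "c"):
            rows += [(pid, f"2022-01-{d:02d}", "ios", 5000 + 10 * d)
                     for d in range(1, 15)]
        rows += [("z", f"2022-01-{d:02d}", "ios",
                  200 if d % 2 else 50000) for d in range(1, 15)]
        df = _steps(rows)
        # direct oracle: compare each participant's variance to the pooled one
        pooled = df["steps"].var(ddof=1)
        per = df.groupby("participant_id")["steps"].var(ddof=1)
        assert per["z"] > pooled > per["a"]
        out, excluded = exclude_high_variance(df)
        assert excluded == {"z"}
        assert set(out["participant_id"]) == {"a", "b", "c"}

    def test_infinite_multiplier_disables_filter(self):
        df = _steps([("a", "2022-01-01", "ios", 200),
                     ("a", "2022-01-02", "ios", 50000),
                     ("b", "2022-01-01", "ios", 5000)])
        out, excluded = exclude_high_variance(df, c=float("inf"))
        assert excluded == set()
        pd.testing.assert_frame_equal(out, df)


class TestBuildCohort:
    def _inputs(self, bmi=27.0, age=60):
        weekly = pd.DataFrame({"week": [1, 2], "mean_steps": [6000.0, 7000.0]})
        shc = _shc("a", ["2022-01-01", "2023-01-01"])
        shc["bmi"] = bmi
        shc["age"] = age
        pair = (shc.iloc[0], shc.iloc[1])
        return {"a": weekly}, {"a": pair}

    @pytest.mark.parametrize("bmi, age, kept", [
        (24.9, 60, False), (25.0, 40, True), (25.0, 74, True),
        (30.0, 39, False), (30.0, 75, False),
    ])
    def test_eligibility_boundaries(self, bmi, age, kept):
        series, pairs = self._inputs(bmi=bmi, age=age)
        cohort, counts = build_cohort(series, pairs)
        assert (len(cohort) == 1) is kept
        assert sum(counts.values()) == (0 if kept else 1)

    def test_mean_steps_over_series(self):
        series, pairs = self._inputs()
        cohort, _ = build_cohort(series, pairs)
        assert cohort["mean_steps"].iloc[0] == pytest.approx(6500.0)
        assert cohort["elapsed_weeks"].iloc[0] == 2

    def test_empty_input(self):
        cohort, counts = build_cohort({}, {})
        assert cohort.empty and sum(counts.values()) == 0

    def test_missing_checkup_pair_is_error(self):
        series, _ = self._inputs()
        with pytest.raises(ValueError):
            build_cohort(series, {})


class TestFullPipeline:
    def test_counts_are_bookkept(self, default_population, preprocessed):
        exc = preprocessed.exclusions
        n_in = exc["n_participants_input"]
        dropped = (exc["no_shc_pair"] + exc["empty_week"]
                   + exc["high_variance"] + exc["low_bmi"]
                   + exc["age_out_of_range"])
        assert exc["n_final"] == n_in - dropped
        assert exc["records_input"] >= exc["records_duplicates_merged"] >= 0
        assert exc["records_out_of_range"] > 0

    def test_weekly_series_complete(self, preprocessed):
        sizes = preprocessed.weekly.groupby("participant_id")["week"].agg(
            ["min", "max", "count"])
        assert (sizes["min"] == 1).all()
        assert (sizes["count"] == sizes["max"]).all()
        assert (sizes["max"] <= 56).all()

    def test_range_filter_removes_exactly_injected_artifacts(
            self, default_population):
        steps = default_population["steps"]
        truth = default_population["truth"]
        dedup = resolve_device_duplicates(steps)
        kept = filter_daily_range(dedup)
        removed = pd.merge(dedup, kept, how="outer", indicator=True)
        removed = removed[removed["_merge"] == "left_only"]
        got = set(zip(removed["participant_id"],
                      pd.to_datetime(removed["date"])))
        expected = set(zip(truth.artifact_days["participant_id"],
                           pd.to_datetime(truth.artifact_days["date"])))
        assert got == expected

    def test_idempotent_on_clean_records(self, preprocessed, default_population):
        """Records surviving the filters pass a second application unchanged."""
        steps = default_population["steps"]
        once = filter_daily_range(resolve_device_duplicates(steps))
        twice = filter_daily_range(resolve_device_duplicates(once))
        pd.testing.assert_frame_equal(once, twice)

    def test_zero_rate_config_drops_nothing(self):
        from steptraj.generate import default_config, generate_population

        cfg = default_config(
            n_participants=25, seed=21, missing_day_prob=0.0,
            artifact_low_prob=0.0, artifact_high_prob=0.0,
            dual_device_prob=0.0)
        steps, shc, _ = generate_population(cfg)
        res = preprocess(steps, shc)
        exc = res.exclusions
        for key in ("records_duplicates_merged", "records_out_of_range",
                    "no_shc_pair", "empty_week", "high_variance", "low_bmi",
                    "age_out_of_range"):
            assert exc[key] == 0, key
        assert exc["n_final"] == 25
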