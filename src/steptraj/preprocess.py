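"""Preprocessing of raw daily step records and health-checkup records.

Turns device-level daily step counts and per-participant checkup rows into
the weekly mean series and the analysis cohort the trajectory model
consumes:

* same-day records from two device platforms are merged keeping the larger
  value;
* implausible days (< 200 or > 50,000 steps) are dropped, the bounds
  themselves are retained;
* each participant needs a pair of checkups 10-14 calendar months apart,
  choosing the pair closest to 12 months;
* participants with any week lacking step data, or with a daily-step
  variance above the pooled variance of all retained records, are excluded;
* the cohort keeps adults aged 40-74 with baseline BMI >= 25 kg/m^2.

Week ``j`` covers days ``7(j-1)+1 .. 7j`` after the first checkup (the
checkup day itself is excluded); series run to the second checkup, capped
at 56 started weeks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MAX_WEEKS = 56

__all__ = [
    "PreprocessConfig",
    "PreprocessResult",
    "resolve_device_duplicates",
    "filter_daily_range",
    "select_shc_pair",
    "weekly_average",
    "exclude_high_variance",
    "build_cohort",
    "preprocess",
]


@dataclass(frozen=True)
class PreprocessConfig:
    step_lo: int = 200
    step_hi: int = 50000
    interval_min_months: int = 10
    interval_max_months: int = 14
    target_months: int = 12
    variance_multiplier: float = 1.0   # c in var_i > c * pooled variance
    bmi_min: float = 25.0
    age_min: int = 40
    age_max: int = 74
    max_weeks: int = MAX_WEEKS


@dataclass
class PreprocessResult:
    """Weekly series (long format), cohort table and exclusion bookkeeping."""

    weekly: pd.DataFrame
    cohort: pd.DataFrame
    exclusions: dict = field(default_factory=dict)


def resolve_device_duplicates(records: pd.DataFrame) -> pd.DataFrame:
    """One record per participant-day, keeping the larger reported steps."""
    if records.empty:
        return records.copy()
    idx = records.groupby(["participant_id", "date"])["steps"].idxmax()
    out = records.loc[np.sort(idx.to_numpy())].reset_index(drop=True)
    return out


def filter_daily_range(records: pd.DataFrame, lo: int = 200,
                       hi: int = 50000) -> pd.DataFrame:
    """Drop implausible days; the bounds themselves are kept (strict < and >)."""
    if lo >= hi:
        raise ValueError("lower bound must be below upper bound")
    mask = (records["steps"] >= lo) & (records["steps"] <= hi)
    return records.loc[mask].reset_index(drop=True)


def _months_offset(date: pd.Timestamp, months: int) -> pd.Timestamp:
    # same day-of-month, clamped to month end (calendar-month arithmetic)
    return date + pd.DateOffset(months=months)


def select_shc_pair(shc_records: pd.DataFrame, config: PreprocessConfig
                    = PreprocessConfig()):
    """Pick one participant's checkup pair with interval closest to 12 months.

    Pairs the participant's first checkup with any later one whose interval
    lies in the 10-14 calendar-month window; returns ``None`` when no pair
    qualifies (the participant is excluded).
    """
    if len(shc_records) < 2:
        return None
    shc = shc_records.sort_values("date").reset_index(drop=True)
    first = shc.iloc[0]
    d1 = pd.Timestamp(first["date"])
    lo = _months_offset(d1, config.interval_min_months)
    hi = _months_offset(d1, config.interval_max_months)
    target = _months_offset(d1, config.target_months)
    best = None
    best_gap = None
    for _, row in shc.iloc[1:].iterrows():
        d2 = pd.Timestamp(row["date"])
        if not (lo <= d2 <= hi):
            continue
        gap = abs((d2 - target).days)
        if best is None or gap < best_gap:
            best, best_gap = row, gap
    if best is None:
        return None
    return first, best


def weekly_average(records: pd.DataFrame, first_shc_date, second_shc_date,
                   max_weeks: int = MAX_WEEKS):
    """Weekly mean steps between the two checkups, or ``None`` if any week
    in 1..T has no valid day.

    T is the number of started weeks in the interval, capped at
    ``max_weeks``; a partial final week counts if it has at least one day.
    """
    d1 = pd.Timestamp(first_shc_date)
    d2 = pd.Timestamp(second_shc_date)
    if d2 <= d1:
        raise ValueError("second checkup must be after the first")
    n_days = (d2 - d1).days
    T = min(int(np.ceil(n_days / 7)), max_weeks)
    offsets = (pd.to_datetime(records["date"]) - d1).dt.days
    in_window = (offsets >= 1) & (offsets <= min(n_days, 7 * T))
    sub = records.loc[in_window].copy()
    sub["week"] = (offsets[in_window] - 1) // 7 + 1
    means = sub.groupby("week")["steps"].mean()
    if len(means) < T:
        return None
    return pd.DataFrame({"week": means.index.to_numpy(dtype=int),
                         "mean_steps": means.to_numpy(dtype=float)})


def exclude_high_variance(records: pd.DataFrame, c: float = 1.0):
    """Drop participants whose daily-step variance exceeds ``c`` times the
    pooled variance of all retained daily records.

    Returns (filtered records, set of excluded participant ids).  ``c`` is
    configurable because the comparison statistic behind "higher variance
    than all step count data" admits several readings; the default is the
    literal one (multiplier 1 on the pooled daily variance).
    """
    if records.empty or not np.isfinite(c):
        return records.copy(), set()
    pooled = float(records["steps"].var(ddof=1))
    if not np.isfinite(pooled):
        return records.copy(), set()
    per = records.groupby("participant_id")["steps"].var(ddof=1).fillna(0.0)
    excluded = set(per.index[per > c * pooled])
    out = records[~records["participant_id"].isin(excluded)].reset_index(drop=True)
    return out, excluded


def build_cohort(series: dict, shc_pairs: dict,
                 config: PreprocessConfig = PreprocessConfig()):
    """Join weekly series with checkup pairs and apply eligibility filters.

    ``series`` maps participant id to a weekly DataFrame, ``shc_pairs`` to
    (first, second) checkup rows.  Returns (cohort DataFrame, counts dict);
    boundary values (BMI 25.0, ages 40 and 74) are eligible.
    """
    counts = {"low_bmi": 0, "age_out_of_range": 0}
    rows = []
    for pid, weekly in series.items():
        if pid not in shc_pairs:
            raise ValueError(f"participant {pid} has a series but no checkup pair")
        first, second = shc_pairs[pid]
        if float(first["bmi"]) < config.bmi_min:
            counts["low_bmi"] += 1
            continue
        age = int(first["age"])
        if not (config.age_min <= age <= config.age_max):
            counts["age_out_of_range"] += 1
            continue
        rows.append({
            "participant_id": pid,
            "first_date": pd.Timestamp(first["date"]),
            "second_date": pd.Timestamp(second["date"]),
            "elapsed_weeks": int(weekly["week"].max()),
            "mean_steps": float(weekly["mean_steps"].mean()),
            "pre_weight": float(first["weight_kg"]),
            "post_weight": float(second["weight_kg"]),
            "pre_bmi": float(first["bmi"]),
            "age": age,
            "sex": int(first["sex"]),
            "smoking": int(first["smoking"]),
            "medication": int(first["medication"]),
        })
    cohort = pd.DataFrame(rows)
    return cohort, counts


def preprocess(steps: pd.DataFrame, shc: pd.DataFrame,
               config: PreprocessConfig = PreprocessConfig()) -> PreprocessResult:
    """Run the full preprocessing pipeline; see the module docstring."""
    steps = steps.copy()
    steps["date"] = pd.to_datetime(steps["date"])
    shc = shc.copy()
    shc["date"] = pd.to_datetime(shc["date"])

    n_raw = len(steps)
    dedup = resolve_device_duplicates(steps)
    n_dedup = len(dedup)
    ranged = filter_daily_range(dedup, config.step_lo, config.step_hi)
    n_ranged = len(ranged)

    participants = sorted(shc["participant_id"].unique())
    exclusions = {
        "n_participants_input": len(participants),
        "records_input": n_raw,
        "records_duplicates_merged": n_raw - n_dedup,
        "records_out_of_range": n_dedup - n_ranged,
        "no_shc_pair": 0,
        "empty_week": 0,
        "high_variance": 0,
    }

    pairs = {}
    for pid, grp in shc.groupby("participant_id"):
        pair = select_shc_pair(grp, config)
        if pair is None:
            exclusions["no_shc_pair"] += 1
        else:
            pairs[pid] = pair

    # restrict each participant's daily data to their checkup interval
    by_pid = {pid: grp for pid, grp in ranged.groupby("participant_id")}
    windowed = []
    for pid, (first, second) in pairs.items():
        grp = by_pid.get(pid)
        if grp is None:
            continue
        d1, d2 = pd.Timestamp(first["date"]), pd.Timestamp(second["date"])
        n_days = (d2 - d1).days
        T = min(int(np.ceil(n_days / 7)), config.max_weeks)
        off = (grp["date"] - d1).dt.days
        windowed.append(grp[(off >= 1) & (off <= min(n_days, 7 * T))])
    window_df = (pd.concat(windowed, ignore_index=True)
                 if windowed else ranged.iloc[0:0])

    filtered, high_var = exclude_high_variance(
        window_df, config.variance_multiplier)
    exclusions["high_variance"] = len(high_var)

    filtered_by_pid = {pid: grp for pid, grp in
                       filtered.groupby("participant_id")}
    empty = filtered.iloc[0:0]
    series = {}
    for pid, (first, second) in pairs.items():
        if pid in high_var:
            continue
        grp = filtered_by_pid.get(pid, empty)
        weekly = weekly_average(grp, first["date"], second["date"],
                                config.max_weeks)
        if weekly is None:
            exclusions["empty_week"] += 1
        else:
            series[pid] = weekly

    cohort, cohort_counts = build_cohort(
        series, {p: pairs[p] for p in series}, config)
    exclusions.update(cohort_counts)
    exclusions["n_final"] = len(cohort)

    keep = set(cohort["participant_id"]) if len(cohort) else set()
    weekly_frames = [
        s.assign(participant_id=pid)[["participant_id", "week", "mean_steps"]]
        for pid, s in series.items() if pid in keep
    ]
    weekly_long = (pd.concat(weekly_frames, ignore_index=True)
                   if weekly_frames else
                   pd.DataFrame(columns=["participant_id", "week", "mean_steps"]))
    return PreprocessResult(weekly=weekly_long, cohort=cohort,
                            exclusions=exclusions)
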