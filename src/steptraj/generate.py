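"""Synthetic cohort generator for step-trajectory analyses.

Emulates roughly one year of daily step records from a mobile-health app
linked to two annual health checkups, with the latent-class structure the
downstream mixture model assumes: each participant belongs to one of four
trajectory archetypes (DOWN, UP/DOWN, FLAT, UP) with a quadratic mean curve
of daily steps over elapsed weeks, a person-level random intercept, daily
Gaussian noise, missing days, out-of-range device artifacts, duplicated
same-day records from a second device platform, and a binary >=3%
weight-loss outcome whose log-odds depend on class and covariates.

Default curve coefficients are calibrated so each archetype's mean daily
steps over weeks 1-28 and weeks 29-52 reproduce published cohort values
(e.g. UP rises from about 6469 to 8894 steps/day), and the class shares
match the published class sizes (355/193/2045/185 of 2778 participants).
"""

from __future__ import annotations

import datetime
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

ARCHETYPES = ("DOWN", "UP_DOWN", "FLAT", "UP")

# published per-class mean daily steps over weeks 1-28 and 29-52
_PERIOD_MEANS = {
    "DOWN": (8023.8, 6278.0),
    "UP_DOWN": (7347.1, 7763.0),
    "FLAT": (5243.2, 5270.2),
    "UP": (6469.0, 8894.1),
}

# mean elapsed-week of each calibration period and mean squared week,
# for weeks 1..28 and 29..52
_T1_MEAN, _T2_MEAN = 14.5, 40.5
_T1_SQ_MEAN = 275.5            # sum(t^2, t=1..28) / 28
_T2_SQ_MEAN = 40516.0 / 24.0   # sum(t^2, t=29..52) / 24


class ConfigError(ValueError):
    """Invalid generator configuration."""


def _linear_from_period_means(m1: float, m2: float) -> tuple:
    """Line whose averages over weeks 1-28 and 29-52 equal m1 and m2."""
    b1 = (m2 - m1) / (_T2_MEAN - _T1_MEAN)
    b0 = m1 - _T1_MEAN * b1
    return (b0, b1, 0.0)


def _quadratic_from_period_means(m1: float, m2: float,
                                 vertex_week: float) -> tuple:
    """Concave quadratic with given period means and turning point."""
    # b1 = -2 * vertex * b2 forces the vertex; solve the period-mean system
    d_sq = _T2_SQ_MEAN - _T1_SQ_MEAN
    d_t = _T2_MEAN - _T1_MEAN
    b2 = (m2 - m1) / (d_sq - 2.0 * vertex_week * d_t)
    b1 = -2.0 * vertex_week * b2
    b0 = m1 - _T1_MEAN * b1 - _T1_SQ_MEAN * b2
    return (b0, b1, b2)


@dataclass(frozen=True)
class OutcomeModel:
    """Logistic model for the binary >=3% weight-loss outcome.

    Class effects are log odds ratios against the FLAT archetype; covariate
    effects apply to centered covariates so the intercept is the FLAT-class
    log-odds at average covariate values.
    """

    intercept: float = math.log(0.223 / 0.777)
    class_log_odds: tuple = (
        math.log(0.92),   # DOWN
        math.log(1.12),   # UP_DOWN
        0.0,              # FLAT (reference)
        math.log(2.45),   # UP
    )
    age_per_year: float = -0.005
    male: float = 0.05
    per_1000_steps: float = 0.01
    smoking: float = -0.05
    medication: float = -0.05
    age_center: float = 65.0
    steps_center_k: float = 5.822


@dataclass(frozen=True)
class CovariateModel:
    """Marginal distributions of checkup covariates (cohort-like defaults)."""

    age_mean: float = 65.0
    age_sd: float = 8.1
    age_min: int = 40
    age_max: int = 74
    male_prob: float = 0.576
    smoking_prob: float = 0.075
    medication_prob: float = 0.638
    weight_mean: float = 72.1
    weight_sd: float = 9.8
    bmi_mean: float = 27.2
    bmi_sd: float = 2.3
    bmi_min: float = 25.0


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-condition parameters of the synthetic cohort.

    Curves are quadratics on the elapsed-week scale (steps/day,
    steps/day/week, steps/day/week^2); shares follow the archetype order
    DOWN, UP_DOWN, FLAT, UP.
    """

    n_participants: int = 400
    n_weeks: int = 52
    class_shares: tuple = (355 / 2778, 193 / 2778, 2045 / 2778, 185 / 2778)
    class_curves: tuple = tuple(
        _linear_from_period_means(*_PERIOD_MEANS[a]) if a != "UP_DOWN"
        else _quadratic_from_period_means(*_PERIOD_MEANS[a], vertex_week=32.0)
        for a in ARCHETYPES
    )
    random_intercept_sd: float = 2000.0
    daily_noise_sd: float = 1500.0
    missing_day_prob: float = 0.05
    artifact_low_prob: float = 0.01
    artifact_high_prob: float = 0.002
    dual_device_prob: float = 0.02
    outcome_model: OutcomeModel = field(default_factory=OutcomeModel)
    covariates: CovariateModel = field(default_factory=CovariateModel)
    first_checkup_date: datetime.date = datetime.date(2022, 4, 1)
    start_jitter_days: int = 28
    seed: int = 0

    def validate(self) -> None:
        shares = np.asarray(self.class_shares, dtype=float)
        if shares.size != len(ARCHETYPES) or (shares < 0).any():
            raise ConfigError("class_shares must be non-negative, one per archetype")
        if abs(shares.sum() - 1.0) > 1e-12:
            raise ConfigError("class_shares must sum to 1 within 1e-12")
        if self.n_weeks < 2:
            raise ConfigError("n_weeks must be >= 2")
        if self.n_participants < 1:
            raise ConfigError("n_participants must be >= 1")
        for name in ("random_intercept_sd", "daily_noise_sd"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ConfigError(f"{name} must be finite and >= 0")
        for name in ("missing_day_prob", "artifact_low_prob",
                     "artifact_high_prob", "dual_device_prob"):
            v = getattr(self, name)
            if not np.isfinite(v) or not 0 <= v <= 1:
                raise ConfigError(f"{name} must be a probability")
        if self.artifact_low_prob + self.artifact_high_prob > 1:
            raise ConfigError("artifact probabilities may not exceed 1 combined")
        curves = np.asarray(self.class_curves, dtype=float)
        if curves.shape != (len(ARCHETYPES), 3) or not np.isfinite(curves).all():
            raise ConfigError("class_curves must be one finite quadratic per archetype")


@dataclass
class SyntheticTruth:
    """Ground truth for recovery tests.

    participants : per-participant true class (1-based index and label),
                   random intercept, outcome probability and drawn outcome.
    artifact_days: the injected out-of-range device-days (participant_id,
                   date, kind in {low, high}); these are exactly the records
                   a correct daily range filter must drop.
    """

    participants: pd.DataFrame
    artifact_days: pd.DataFrame


def default_config(n_participants: int = 400, seed: int = 0,
                   **overrides) -> GeneratorConfig:
    """The calibrated 4-archetype configuration (see module docstring)."""
    cfg = GeneratorConfig(n_participants=n_participants, seed=seed, **overrides)
    cfg.validate()
    return cfg


def curve_value(curve, week):
    """Evaluate a quadratic mean curve at elapsed week(s)."""
    b0, b1, b2 = curve
    week = np.asarray(week, dtype=float)
    out = b0 + b1 * week + b2 * week * week
    return float(out) if out.ndim == 0 else out


def _participant_rng(seed: int, i: int) -> np.random.Generator:
    # substream keyed by (seed, participant index): subsetting or growing the
    # cohort never changes the records of participants already generated
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(i)]))


def generate_population(config: GeneratorConfig):
    """Generate (daily step records, checkup records, ground truth).

    Returns a long daily-steps DataFrame (participant_id, date, source,
    steps), a checkup DataFrame with two rows per participant
    (participant_id, date, weight_kg, bmi, age, sex, smoking, medication;
    sex is 1 for men), and a :class:`SyntheticTruth`.  Identical config and
    seed give identical output.
    """
    config.validate()
    shares = np.asarray(config.class_shares, dtype=float)
    curves = np.asarray(config.class_curves, dtype=float)
    om, cov = config.outcome_model, config.covariates
    n_days = 7 * config.n_weeks
    day_offsets = np.arange(1, n_days + 1)
    week_of_day = (day_offsets - 1) // 7 + 1
    mean_week_value = {
        g: float(curve_value(curves[g], np.arange(1, config.n_weeks + 1)).mean())
        for g in range(len(ARCHETYPES))
    }

    step_frames = []
    shc_rows = []
    truth_rows = []
    artifact_rows = []
    base_date = pd.Timestamp(config.first_checkup_date)

    for i in range(config.n_participants):
        rng = _participant_rng(config.seed, i)
        pid = f"P{i:05d}"
        g = int(rng.choice(len(ARCHETYPES), p=shares))
        u = float(rng.normal(0.0, config.random_intercept_sd))
        first_date = base_date + pd.Timedelta(
            days=int(rng.integers(0, config.start_jitter_days + 1)))
        second_date = first_date + pd.Timedelta(days=n_days)

        mu = curve_value(curves[g], week_of_day) + u
        noise = rng.normal(0.0, config.daily_noise_sd, size=n_days)
        steps = np.rint(mu + noise)
        # genuine wear days stay inside the plausibility window so injected
        # artifacts are the only out-of-range records
        steps = np.clip(steps, 200, 50000).astype(np.int64)

        keep = rng.random(n_days) >= config.missing_day_prob
        kind = rng.random(n_days)
        low_mask = keep & (kind < config.artifact_low_prob)
        high_mask = keep & ~low_mask & (
            kind < config.artifact_low_prob + config.artifact_high_prob)
        steps[low_mask] = rng.integers(0, 200, size=int(low_mask.sum()))
        steps[high_mask] = rng.integers(50001, 80001, size=int(high_mask.sum()))

        primary = "ios" if rng.random() < 0.5 else "android"
        other = "android" if primary == "ios" else "ios"
        dual = keep & (rng.random(n_days) < config.dual_device_prob)
        dual_factor = rng.uniform(0.3, 1.0, size=int(dual.sum()))

        dates = first_date + pd.to_timedelta(day_offsets, unit="D")
        kept_dates = dates[keep]
        kept_steps = steps[keep]
        frame = pd.DataFrame({
            "participant_id": pid,
            "date": kept_dates,
            "source": primary,
            "steps": kept_steps,
        })
        if dual.any():
            dual_dates = dates[dual]
            dual_steps = np.floor(steps[dual] * dual_factor).astype(np.int64)
            frame = pd.concat([frame, pd.DataFrame({
                "participant_id": pid,
                "date": dual_dates,
                "source": other,
                "steps": dual_steps,
            })], ignore_index=True)
        step_frames.append(frame)

        for d, k in zip(dates[low_mask], ["low"] * int(low_mask.sum())):
            artifact_rows.append((pid, d, k))
        for d, k in zip(dates[high_mask], ["high"] * int(high_mask.sum())):
            artifact_rows.append((pid, d, k))

        age = int(np.clip(round(rng.normal(cov.age_mean, cov.age_sd)),
                          cov.age_min, cov.age_max))
        sex = int(rng.random() < cov.male_prob)
        smoking = int(rng.random() < cov.smoking_prob)
        medication = int(rng.random() < cov.medication_prob)
        pre_weight = float(max(rng.normal(cov.weight_mean, cov.weight_sd), 40.0))
        # truncated-normal BMI so every participant meets the >=25 entry rule
        bmi = cov.bmi_mean + cov.bmi_sd * rng.standard_normal()
        while bmi < cov.bmi_min:
            bmi = cov.bmi_mean + cov.bmi_sd * rng.standard_normal()

        steps_k = (mean_week_value[g] + u) / 1000.0
        lp = (om.intercept + om.class_log_odds[g]
              + om.age_per_year * (age - om.age_center)
              + om.male * sex
              + om.per_1000_steps * (steps_k - om.steps_center_k)
              + om.smoking * smoking
              + om.medication * medication)
        p_loss = float(expit(lp))
        outcome = int(rng.random() < p_loss)
        if outcome:
            loss_frac = rng.uniform(0.03, 0.12)
        else:
            loss_frac = rng.uniform(-0.10, 0.03)
        post_weight = pre_weight * (1.0 - loss_frac)
        post_bmi = bmi * post_weight / pre_weight

        shc_rows.append((pid, first_date, pre_weight, bmi, age, sex,
                         smoking, medication))
        shc_rows.append((pid, second_date, post_weight, post_bmi, age, sex,
                         smoking, medication))
        truth_rows.append((pid, g + 1, ARCHETYPES[g], u, p_loss, outcome))

    steps_df = pd.concat(step_frames, ignore_index=True)
    steps_df = steps_df.sort_values(
        ["participant_id", "date", "source"]).reset_index(drop=True)
    shc_df = pd.DataFrame(shc_rows, columns=[
        "participant_id", "date", "weight_kg", "bmi", "age", "sex",
        "smoking", "medication"])
    truth = SyntheticTruth(
        participants=pd.DataFrame(truth_rows, columns=[
            "participant_id", "class_index", "class_label",
            "random_intercept", "outcome_prob", "outcome"]),
        artifact_days=pd.DataFrame(artifact_rows, columns=[
            "participant_id", "date", "kind"]),
    )
    return steps_df, shc_df, truth


def write_population(outdir, steps_df, shc_df, truth) -> None:
    """Write the generated tables as CSV using ISO-8601 dates."""
    import pathlib

    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    steps = steps_df.copy()
    steps["date"] = pd.to_datetime(steps["date"]).dt.strftime("%Y-%m-%d")
    steps.to_csv(outdir / "steps.csv", index=False)
    shc = shc_df.copy()
    shc["date"] = pd.to_datetime(shc["date"]).dt.strftime("%Y-%m-%d")
    shc.to_csv(outdir / "checkups.csv", index=False)
    truth.participants.to_csv(outdir / "truth_participants.csv", index=False)
    art = truth.artifact_days.copy()
    if len(art):
        art["date"] = pd.to_datetime(art["date"]).dt.strftime("%Y-%m-%d")
    art.to_csv(outdir / "truth_artifacts.csv", index=False)
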