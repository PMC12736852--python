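"""Synthetic cohorts with the structure the trajectory analysis assumes.

Generates, from a single seeded RNG consumed in a fixed documented order:

1. baseline covariates (age, sex, partner status, COVID-era indicator,
   randomization arm, first-week MVPA, baseline BMI);
2. latent trajectory-group labels, either directly from a probability
   vector or through a multinomial-logit membership model on covariates;
3. weekly goal-adherence truth: per-group polynomial mean in the week
   index plus normal noise, left-censored at zero, with a configurable
   fraction of invalid (missing) weeks and optional monotone dropout;
4. daily tracker records that invert the adherence formula, so the
   adherence module can be exercised end to end; and
5. baseline / 6-month / 12-month weights with group-dependent percent
   change, an in-person / home-scale / missing assessment mix, and
   covariate-dependent missingness.

The default configuration is parameterized to the published fitted model:
four trajectory groups (lower stable, moderate, increasing, high) with
polynomial mean trajectories on adherence-% scale, shared residual SD
40.01, group probabilities (0.345, 0.398, 0.193, 0.064), and group mean
percent weight changes (-0.33, -2.59, -4.29, -6.16).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .adherence import GOAL_MIN_PER_WEEK

MEMBERSHIP_COVARIATES = (
    "age",
    "female",
    "partnered",
    "sqrt_first_week_mvpa",
    "covid_era",
    "arm",
)


@dataclass(frozen=True)
class CohortConfig:
    """Everything needed to draw one synthetic cohort.

    Trajectory coefficients are on the adherence-% scale with the week
    index t = 1..n_weeks entering the polynomials untransformed.
    ``membership_coefficients`` holds, per non-reference group, a constant
    followed by log-odds for the covariates in ``MEMBERSHIP_COVARIATES``
    order; when None, groups are drawn directly from
    ``group_probabilities``.
    """

    n_subjects: int
    n_weeks: int = 52
    group_probabilities: tuple[float, ...] = (0.345, 0.398, 0.193, 0.064)
    trajectory_coefficients: tuple[tuple[float, ...], ...] = (
        (32.20,),
        (82.18, -1.29, 0.06, -0.0008),
        (112.38, 2.69, -0.08, 0.0006),
        (182.44, 2.14, -0.03),
    )
    residual_sd: float = 40.01
    membership_coefficients: tuple[tuple[float, ...], ...] | None = None
    covariate_distributions: Mapping[str, float] = field(
        default_factory=lambda: dict(
            age_mean=45.0, age_sd=14.4, age_min=18.0,
            prop_female=0.795, prop_partnered=0.655,
            prop_covid_era=0.522, prop_arm=0.5,
            fw_mvpa_mean=244.1, fw_mvpa_sd=171.9,
            bmi_mean=33.7, bmi_sd=4.0, bmi_min=27.0, bmi_max=43.0,
        )
    )
    wear_probability: float = 0.9
    missing_week_rate: float = 0.125
    dropout_model: tuple[float, float, float, float] = (-1.3925, -0.3, 0.3, -0.3)
    weight_outcome_means: tuple[float, ...] = (-0.33, -2.59, -4.29, -6.16)
    weight_outcome_sd: float = 7.1
    assessment_mix: tuple[float, float, float] = (0.38, 0.41, 0.21)
    link_first_week: bool = True
    apply_dropout: bool = True
    ar1_noise_rho: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        p = np.asarray(self.group_probabilities, dtype=float)
        if abs(p.sum() - 1.0) > 1e-12:
            raise ValueError("group_probabilities must sum to 1")
        if np.any(p < 0) or np.any(p > 1):
            raise ValueError("group_probabilities must lie in [0, 1]")
        if self.residual_sd <= 0:
            raise ValueError("residual_sd must be positive")
        if self.n_weeks < 2:
            raise ValueError("n_weeks must be at least 2")
        if len(self.trajectory_coefficients) != len(p):
            raise ValueError("one coefficient vector per group required")
        for prob in (
            self.wear_probability, self.missing_week_rate, *self.assessment_mix
        ):
            if not 0.0 <= prob <= 1.0:
                raise ValueError(f"probability {prob} outside [0, 1]")
        if self.membership_coefficients is not None:
            if len(self.membership_coefficients) != len(p) - 1:
                raise ValueError("membership coefficients: one row per non-reference group")

    @property
    def n_groups(self) -> int:
        return len(self.group_probabilities)


def published_model_config(n_subjects: int = 502, seed: int = 0) -> CohortConfig:
    """The published fitted model as a generating configuration.

    Membership log-odds (constant; age, female, partnered, sqrt first-week
    MVPA, COVID-era, arm) per non-reference group are the published
    estimates; covariate marginals match the published sample description.
    """
    return CohortConfig(
        n_subjects=n_subjects,
        seed=seed,
        membership_coefficients=(
            (-4.37, 0.03, -0.83, -0.57, 0.45, -0.22, 0.18),
            (-8.10, 0.04, -1.37, -1.11, 0.67, -0.72, 0.41),
            (-19.23, 0.05, -1.95, -0.39, 1.22, -0.70, -0.01),
        ),
    )


@dataclass
class SyntheticCohort:
    config: CohortConfig
    covariates: pd.DataFrame
    true_group: pd.Series
    weekly_truth: pd.DataFrame
    daily: pd.DataFrame
    weights: pd.DataFrame
    dropout_week: pd.Series


# ---------------------------------------------------------------- covariates

def draw_covariates(config: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Draw the baseline covariate table.

    Age is truncated normal (>= 18); binary covariates are Bernoulli;
    first-week MVPA is gamma matched by moments to the configured mean/SD
    (right-skewed, non-negative); baseline BMI is truncated normal on the
    trial's eligibility range.
    """
    cd = config.covariate_distributions
    n = config.n_subjects
    for key in ("prop_female", "prop_partnered", "prop_covid_era", "prop_arm"):
        if not 0.0 <= cd[key] <= 1.0:
            raise ValueError(f"{key}={cd[key]} is not a probability")

    a = (cd["age_min"] - cd["age_mean"]) / cd["age_sd"]
    age = stats.truncnorm.rvs(
        a, np.inf, loc=cd["age_mean"], scale=cd["age_sd"], size=n, random_state=rng
    )
    female = (rng.random(n) < cd["prop_female"]).astype(int)
    partnered = (rng.random(n) < cd["prop_partnered"]).astype(int)
    covid = (rng.random(n) < cd["prop_covid_era"]).astype(int)
    arm = (rng.random(n) < cd["prop_arm"]).astype(int)
    var = cd["fw_mvpa_sd"] ** 2
    shape = cd["fw_mvpa_mean"] ** 2 / var
    scale = var / cd["fw_mvpa_mean"]
    fw = rng.gamma(shape, scale, size=n)
    b_lo = (cd["bmi_min"] - cd["bmi_mean"]) / cd["bmi_sd"]
    b_hi = (cd["bmi_max"] - cd["bmi_mean"]) / cd["bmi_sd"]
    bmi = stats.truncnorm.rvs(
        b_lo, b_hi, loc=cd["bmi_mean"], scale=cd["bmi_sd"], size=n, random_state=rng
    )
    return pd.DataFrame(
        {
            "subject_id": np.arange(1, n + 1),
            "age": age,
            "female": female,
            "partnered": partnered,
            "covid_era": covid,
            "arm": arm,
            "first_week_mvpa": fw,
            "sqrt_first_week_mvpa": np.sqrt(fw),
            "bmi": bmi,
        }
    )


# -------------------------------------------------------------- group labels

def membership_probabilities(
    covariates: pd.DataFrame,
    membership_coefficients: Sequence[Sequence[float]],
) -> np.ndarray:
    """Multinomial-logit group probabilities, group 1 as reference.

    p_j(x) is proportional to exp(constant_j + x'theta_j) for j >= 2 and to
    1 for the reference group.
    """
    theta = np.asarray(membership_coefficients, dtype=float)
    missing = [c for c in MEMBERSHIP_COVARIATES if c not in covariates.columns]
    if missing:
        raise KeyError(f"covariate table lacks membership predictors: {missing}")
    X = covariates[list(MEMBERSHIP_COVARIATES)].to_numpy(dtype=float)
    lp = np.column_stack(
        [np.zeros(len(X)), theta[:, 0] + X @ theta[:, 1:].T]
    )
    lp -= lp.max(axis=1, keepdims=True)
    p = np.exp(lp)
    p /= p.sum(axis=1, keepdims=True)
    return p


def assign_groups(
    covariates: pd.DataFrame,
    config: CohortConfig,
    rng: np.random.Generator,
) -> tuple[pd.Series, np.ndarray]:
    """Draw latent group labels (1..K); returns labels and the probability
    matrix used, for audit."""
    n = len(covariates)
    if config.membership_coefficients is not None:
        probs = membership_probabilities(covariates, config.membership_coefficients)
    else:
        probs = np.tile(np.asarray(config.group_probabilities), (n, 1))
    u = rng.random(n)
    labels = (u[:, None] >= np.cumsum(probs, axis=1)).sum(axis=1) + 1
    return pd.Series(labels, index=covariates.index, name="true_group"), probs


# ---------------------------------------------------------- weekly adherence

def trajectory_means(config: CohortConfig) -> np.ndarray:
    """K x n_weeks matrix of polynomial trajectory means, t = 1..n_weeks."""
    t = np.arange(1, config.n_weeks + 1, dtype=float)
    mu = np.zeros((config.n_groups, config.n_weeks))
    for j, coefs in enumerate(config.trajectory_coefficients):
        mu[j] = np.polynomial.polynomial.polyval(t, np.asarray(coefs, dtype=float))
    return mu


def draw_dropout(
    covariates: pd.DataFrame, config: CohortConfig, rng: np.random.Generator
) -> pd.Series:
    """Per-subject dropout week (NaN = completer).

    A subject drops out with logistic probability on standardized age,
    baseline BMI, and first-week MVPA (younger, heavier, less active
    subjects drop out more); dropouts get a uniform dropout week in 5..52
    after which no valid tracker weeks occur and the 12-month weight is
    missing.
    """
    cd = config.covariate_distributions
    b0, b_age, b_bmi, b_fw = config.dropout_model
    z_age = (covariates["age"].to_numpy() - cd["age_mean"]) / cd["age_sd"]
    z_bmi = (covariates["bmi"].to_numpy() - cd["bmi_mean"]) / cd["bmi_sd"]
    z_fw = (covariates["first_week_mvpa"].to_numpy() - cd["fw_mvpa_mean"]) / cd["fw_mvpa_sd"]
    from scipy.special import expit

    p = expit(b0 + b_age * z_age + b_bmi * z_bmi + b_fw * z_fw)
    drops = rng.random(len(p)) < p
    week = rng.integers(5, config.n_weeks + 1, size=len(p)).astype(float)
    week[~drops] = np.nan
    return pd.Series(week, index=covariates.index, name="dropout_week")


def generate_weekly_adherence(
    true_group: pd.Series,
    config: CohortConfig,
    rng: np.random.Generator,
    covariates: pd.DataFrame | None = None,
    dropout_week: pd.Series | None = None,
) -> pd.DataFrame:
    """Weekly adherence truth: polynomial mean + noise, censored at 0.

    Noise is i.i.d. Normal(0, residual_sd) by default, matching the
    conditional-independence assumption of the trajectory model; setting
    ``ar1_noise_rho`` induces within-subject AR(1) correlation instead.
    Weeks are invalid (missing) with ``missing_week_rate``, plus all weeks
    after a subject's dropout week.  With ``link_first_week`` and a
    covariate table, the week-1 value is replaced by the drawn first-week
    MVPA expressed as % of the 300-minute goal, keeping the membership
    covariate and the response coherent.
    """
    n = len(true_group)
    mu = trajectory_means(config)
    g = true_group.to_numpy() - 1
    mean = mu[g]  # n x n_weeks

    if config.ar1_noise_rho:
        rho = config.ar1_noise_rho
        eps = np.empty((n, config.n_weeks))
        eps[:, 0] = rng.normal(0.0, config.residual_sd, n)
        innov_sd = config.residual_sd * np.sqrt(1 - rho**2)
        for t in range(1, config.n_weeks):
            eps[:, t] = rho * eps[:, t - 1] + rng.normal(0.0, innov_sd, n)
    else:
        eps = rng.normal(0.0, config.residual_sd, size=(n, config.n_weeks))
    y = np.maximum(mean + eps, 0.0)

    if config.link_first_week and covariates is not None:
        y[:, 0] = covariates["first_week_mvpa"].to_numpy() / GOAL_MIN_PER_WEEK * 100.0

    invalid = rng.random((n, config.n_weeks)) < config.missing_week_rate
    if dropout_week is not None:
        dw = dropout_week.to_numpy()
        weeks = np.arange(1, config.n_weeks + 1)
        dropped = np.where(np.isnan(dw), np.inf, dw)[:, None] < weeks[None, :]
        invalid |= dropped

    subj = np.repeat(true_group.index.to_numpy(), config.n_weeks)
    sid = np.repeat(np.arange(1, n + 1), config.n_weeks)
    out = pd.DataFrame(
        {
            "subject_id": sid,
            "week": np.tile(np.arange(1, config.n_weeks + 1), n),
            "true_mean": mean.ravel(),
            "adherence_pct": np.where(invalid, np.nan, y).ravel(),
            "is_valid": ~invalid.ravel(),
        }
    )
    del subj
    return out


# -------------------------------------------------------------- daily render

def render_daily_records(
    weekly_truth: pd.DataFrame, config: CohortConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Daily tracker records consistent with the weekly truth.

    Inverts the adherence formula: each valid week gets >= 4 wear days whose
    integer MVPA minutes sum to adherence/100 * (300/7) * n_wear, so that
    re-aggregating with the adherence module reproduces the weekly value
    within integer-minute rounding (< 1 percentage point).  Invalid weeks
    get <= 3 wear days; non-wear days log < 500 steps and 0 MVPA minutes.
    """
    wt = weekly_truth
    n_rows = len(wt)
    valid = wt["is_valid"].to_numpy()
    adh = wt["adherence_pct"].to_numpy()

    # wear-day counts: truncated binomial(7, wear_probability) >= 4 on valid
    # weeks, uniform 0..3 on invalid weeks
    k = np.arange(8)
    pmf = stats.binom.pmf(k, 7, config.wear_probability)
    p_valid = pmf[4:] / pmf[4:].sum()
    n_wear = np.where(
        valid,
        rng.choice(np.arange(4, 8), size=n_rows, p=p_valid),
        rng.integers(0, 4, size=n_rows),
    )

    daily_goal = GOAL_MIN_PER_WEEK / 7.0
    total_min = np.where(
        valid, np.round(np.nan_to_num(adh) / 100.0 * daily_goal * n_wear), 0
    ).astype(int)

    sid = np.repeat(wt["subject_id"].to_numpy(), 7)
    week = np.repeat(wt["week"].to_numpy(), 7)
    day = (week - 1) * 7 + np.tile(np.arange(1, 8), n_rows)

    # choose wear days uniformly within each week
    order = rng.random((n_rows, 7)).argsort(axis=1)
    wear_mask = order < n_wear[:, None]

    # split integer weekly totals uniformly over wear slots: sequential
    # binomial thinning is an exact multinomial draw, fully vectorized
    slots = np.zeros((n_rows, 7), dtype=int)
    remaining = np.where(valid, total_min, 0)
    for s in range(7):
        left = n_wear - s
        p = np.where(left > 0, 1.0 / np.maximum(left, 1), 0.0)
        draw = rng.binomial(remaining, p)
        slots[:, s] = draw
        remaining = remaining - draw
    minutes = np.take_along_axis(slots, order, axis=1)
    minutes[~wear_mask] = 0
    # invalid weeks: modest unstructured activity on their few wear days
    invalid_wear = ~valid[:, None] & wear_mask
    minutes[invalid_wear] = rng.poisson(20, size=int(invalid_wear.sum()))

    very = rng.binomial(minutes, 0.35)
    fairly = minutes - very
    steps = np.where(
        wear_mask,
        rng.integers(500, 15000, size=(n_rows, 7)),
        rng.integers(0, 500, size=(n_rows, 7)),
    )
    # non-wear days carry no MVPA: the 500-step rule is the wear indicator
    fairly = np.where(wear_mask, fairly, 0)
    very = np.where(wear_mask, very, 0)

    return pd.DataFrame(
        {
            "subject_id": sid,
            "day": day,
            "steps": steps.ravel(),
            "fairly_active_min": fairly.ravel(),
            "very_active_min": very.ravel(),
        }
    )


# ------------------------------------------------------------------- weights

def generate_weights(
    true_group: pd.Series,
    covariates: pd.DataFrame,
    config: CohortConfig,
    rng: np.random.Generator,
    dropout_week: pd.Series | None = None,
) -> pd.DataFrame:
    """Baseline / 6-month / 12-month weight table.

    Baseline weight comes from the drawn BMI and a height draw
    (Normal(1.66 m, 0.09), truncated to [1.45, 2.05]); only relative change
    matters downstream.  Twelve-month percent change is Normal(group mean,
    common SD).  The 12-month assessment is missing for dropouts (flagged
    by ``dropout_week``); the rest split between the research scale and the
    study-issued home scale per ``assessment_mix``.  Dropouts carry a last
    self-monitored weight and day for the imputation rule to use.
    """
    n = len(true_group)
    height = stats.truncnorm.rvs(
        (1.45 - 1.66) / 0.09, (2.05 - 1.66) / 0.09,
        loc=1.66, scale=0.09, size=n, random_state=rng,
    )
    baseline = covariates["bmi"].to_numpy() * height**2
    means = np.asarray(config.weight_outcome_means)
    pct12 = rng.normal(means[true_group.to_numpy() - 1], config.weight_outcome_sd)
    w12 = baseline * (1 + pct12 / 100.0)
    # most loss happens early: 6-month weight sits ~70% of the way down
    pct6 = 0.7 * pct12 + rng.normal(0.0, 1.0, n)
    w6 = baseline * (1 + pct6 / 100.0)

    if dropout_week is None:
        dropped = np.zeros(n, dtype=bool)
        dw = np.full(n, np.nan)
    else:
        dw = dropout_week.to_numpy()
        dropped = np.isfinite(dw)

    p_res, p_home, _ = config.assessment_mix
    research = rng.random(n) < p_res / (p_res + p_home)
    measured = np.where(research, "research", "home")
    source12 = np.where(dropped, "missing", measured)
    source6 = np.where(dropped & (dw < 26), "missing", measured)

    # last self-monitored weight: partial progress up to the dropout week
    frac = np.where(dropped, np.clip(dw / config.n_weeks, 0, 1), np.nan)
    last_sm_w = baseline * (1 + 0.8 * frac * pct12 / 100.0)
    last_sm_day = np.where(dropped, dw * 7, np.nan)

    jitter6 = rng.integers(-7, 8, n)
    jitter12 = rng.integers(-7, 8, n)
    sid = covariates["subject_id"].to_numpy()
    rows = []
    for visit, wgt, src, off in (
        ("baseline", baseline, np.full(n, "research"), np.zeros(n, dtype=int)),
        ("6mo", w6, source6, 182 + jitter6),
        ("12mo", w12, source12, 364 + jitter12),
    ):
        rows.append(
            pd.DataFrame(
                {
                    "subject_id": sid,
                    "visit": visit,
                    "weight_kg": np.where(src == "missing", np.nan, wgt),
                    "source": src,
                    "date_offset_days": off,
                    "last_sm_weight_kg": np.where(dropped, last_sm_w, np.nan),
                    "last_sm_day": last_sm_day,
                }
            )
        )
    out = pd.concat(rows, ignore_index=True)
    out["true_pct_change_12mo"] = np.full(len(out), np.nan)
    out.loc[out["visit"] == "12mo", "true_pct_change_12mo"] = pct12
    return out


# ------------------------------------------------------------------ pipeline

def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Draw a full cohort; all randomness from one RNG seeded by the config.

    Draw order: covariates, group labels, dropout, weekly adherence noise
    and missingness, daily rendering, weights.
    """
    rng = np.random.default_rng(config.seed)
    cov = draw_covariates(config, rng)
    group, probs = assign_groups(cov, config, rng)
    for j in range(config.n_groups):
        cov[f"p_group_{j + 1}"] = probs[:, j]
    if config.apply_dropout:
        dropout = draw_dropout(cov, config, rng)
    else:
        dropout = pd.Series(np.full(len(cov), np.nan), index=cov.index, name="dropout_week")
    weekly = generate_weekly_adherence(group, config, rng, cov, dropout)
    daily = render_daily_records(weekly, config, rng)
    weights = generate_weights(group, cov, config, rng, dropout)
    return SyntheticCohort(
        config=config,
        covariates=cov,
        true_group=group,
        weekly_truth=weekly,
        daily=daily,
        weights=weights,
        dropout_week=dropout,
    )


def write_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> dict[str, Path]:
    """Write the cohort's CSV artifacts; returns {name: path}."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    tables = {
        "daily_activity": cohort.daily,
        "covariates": cohort.covariates,
        "weights": cohort.weights,
        "truth": pd.DataFrame(
            {
                "subject_id": cohort.covariates["subject_id"],
                "true_group": cohort.true_group.to_numpy(),
            }
        ),
        "weekly_truth": cohort.weekly_truth,
    }
    for name, df in tables.items():
        p = out / f"{name}.csv"
        df.to_csv(p, index=False)
        paths[name] = p
    return paths


def acceptance_simulation_config(
    n_subjects: int = 502, seed: int = 0, missing_week_rate: float = 0.20
) -> CohortConfig:
    """Covariate-free generating model for simulate-and-refit experiments:
    groups drawn directly from the published probabilities, weekly adherence
    purely from the polynomial-plus-censored-noise model (no first-week
    linkage, no dropout layered on the weekly series)."""
    return replace(
        published_model_config(n_subjects=n_subjects, seed=seed),
        membership_coefficients=None,
        link_first_week=False,
        apply_dropout=False,
        missing_week_rate=missing_week_rate,
    )


def simulate_weekly_panel(
    config: CohortConfig, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, pd.Series]:
    """Shortcut for simulate-and-refit experiments: latent groups drawn
    from ``group_probabilities`` and the weekly adherence panel, skipping
    covariates, daily rendering, and weights.  Returns (weekly, true_group).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    probs = np.asarray(config.group_probabilities)
    u = rng.random(n)
    labels = (u[:, None] >= np.cumsum(probs)[None, :]).sum(axis=1) + 1
    group = pd.Series(labels, name="true_group")
    weekly = generate_weekly_adherence(group, config, rng)
    return weekly, group
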