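"""Weekly MVPA-goal adherence from daily wearable-tracker records.

The response variable of the trajectory analysis is the percentage of
adherence to a 300 min/week moderate-to-vigorous physical activity (MVPA)
goal.  A tracker-day counts as a *wear day* when it logs at least 500 steps
(evidence the device was worn, as opposed to sedentary behaviour); a week is
*valid* when it contains at least 4 wear days.  Weekly MVPA is the sum of
"fairly active" and "very active" minutes over wear days, divided by the
number of wear days and multiplied by seven (extrapolation to a full week),
and adherence is that figure divided by the 300-minute goal, times 100.
Adherence is left-bounded at 0 and deliberately uncapped above 100.

Weeks are fixed 7-day blocks anchored at day 1 (days 1-7 form week 1).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

WEAR_DAY_STEPS = 500
MIN_WEAR_DAYS = 4
GOAL_MIN_PER_WEEK = 300.0

DAILY_COLUMNS = ["subject_id", "day", "steps", "fairly_active_min", "very_active_min"]
WEEKLY_COLUMNS = [
    "subject_id",
    "week",
    "n_wear_days",
    "mvpa_sum_min",
    "weekly_mvpa_min",
    "adherence_pct",
    "is_valid",
]


def classify_wear_day(steps) -> bool | np.ndarray:
    """True when the step count marks the day as a wear day (>= 500 steps).

    Accepts a scalar or an array; negative step counts are malformed input.
    """
    steps = np.asarray(steps)
    if np.any(steps < 0):
        raise ValueError("negative step counts are not a valid tracker record")
    out = steps >= WEAR_DAY_STEPS
    return bool(out) if out.ndim == 0 else out


def summarize_weeks(daily: pd.DataFrame) -> pd.DataFrame:
    """Collapse daily records into one row per subject-week.

    Days absent from the table are treated as non-wear days, so a week with
    only k < 7 recorded days is identical to the same week padded with
    zero-step days.  MVPA minutes on non-wear days are ignored entirely:
    the 500-step rule distinguishes non-wear from sedentary behaviour, and a
    day failing it contributes neither minutes nor a wear day.

    Parameters
    ----------
    daily
        Long table with columns ``subject_id, day, steps, fairly_active_min,
        very_active_min``; ``day`` is a 1-based integer index and must be
        unique within subject.

    Returns
    -------
    DataFrame with one row per subject-week: wear-day count, MVPA sum over
    wear days, extrapolated weekly minutes, adherence %, and a validity
    flag.  Invalid weeks (< 4 wear days) carry NaN adherence.
    """
    df = daily.copy()
    missing = [c for c in DAILY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"daily table missing columns: {missing}")
    if df.duplicated(["subject_id", "day"]).any():
        bad = df[df.duplicated(["subject_id", "day"])].iloc[0]
        raise ValueError(
            f"duplicate day index {bad['day']} for subject {bad['subject_id']}"
        )
    if (df["day"] < 1).any():
        raise ValueError("day indices must be >= 1")

    df["week"] = (df["day"].to_numpy() - 1) // 7 + 1
    wear = classify_wear_day(df["steps"].to_numpy())
    mvpa = (df["fairly_active_min"].to_numpy() + df["very_active_min"].to_numpy())
    df["_wear"] = wear.astype(int)
    df["_mvpa_wear"] = np.where(wear, mvpa, 0.0)

    grp = df.groupby(["subject_id", "week"], sort=True)
    weekly = grp.agg(
        n_wear_days=("_wear", "sum"), mvpa_sum_min=("_mvpa_wear", "sum")
    ).reset_index()

    n_wear = weekly["n_wear_days"].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        weekly_min = np.where(
            n_wear > 0, weekly["mvpa_sum_min"].to_numpy() / n_wear * 7.0, 0.0
        )
    weekly["weekly_mvpa_min"] = weekly_min
    weekly["is_valid"] = n_wear >= MIN_WEAR_DAYS
    weekly["adherence_pct"] = np.where(
        weekly["is_valid"], weekly_min / GOAL_MIN_PER_WEEK * 100.0, np.nan
    )
    return weekly[WEEKLY_COLUMNS]


def adherence_without_extrapolation(weekly: pd.DataFrame) -> pd.Series:
    """Sensitivity variant: daily MVPA average against the daily goal.

    Computes (MVPA sum / wear days) / (300/7) x 100 on valid weeks.  This is
    algebraically identical to the extrapolated adherence — multiplying by 7
    and dividing by a weekly goal equals dividing the daily mean by the daily
    goal — but it is kept as a separate code path mirroring the published
    sensitivity analysis.  Invalid weeks return NaN.
    """
    n_wear = weekly["n_wear_days"].to_numpy().astype(float)
    daily_goal = GOAL_MIN_PER_WEEK / 7.0
    with np.errstate(divide="ignore", invalid="ignore"):
        daily_mean = weekly["mvpa_sum_min"].to_numpy() / n_wear
    pct = daily_mean / daily_goal * 100.0
    pct = np.where(weekly["is_valid"].to_numpy(), pct, np.nan)
    return pd.Series(pct, index=weekly.index, name="adherence_pct_noextrap")


def first_week_mvpa(
    weekly: pd.DataFrame, fallback_first_valid: bool = False
) -> pd.DataFrame:
    """Per-subject first-week MVPA minutes and their square root.

    First-week MVPA proxies baseline activity and (square-root transformed)
    enters the group-membership model.  Subjects whose week 1 is invalid get
    NaN by default and are meant to be excluded from the membership model; a
    fallback to the first *valid* week is available behind a flag.
    """
    rows = []
    for sid, sub in weekly.groupby("subject_id", sort=True):
        sub = sub.sort_values("week")
        wk1 = sub[sub["week"] == 1]
        val = np.nan
        if len(wk1) and bool(wk1["is_valid"].iloc[0]):
            val = float(wk1["weekly_mvpa_min"].iloc[0])
        elif fallback_first_valid:
            valid = sub[sub["is_valid"]]
            if len(valid):
                val = float(valid["weekly_mvpa_min"].iloc[0])
        rows.append(
            {
                "subject_id": sid,
                "first_week_mvpa": val,
                "sqrt_first_week_mvpa": np.sqrt(val) if np.isfinite(val) else np.nan,
            }
        )
    return pd.DataFrame(rows)


def met_goal_first_week(weekly: pd.DataFrame) -> pd.Series:
    """Flag per subject: week-1 extrapolated MVPA >= 300 min (inclusive).

    NaN where week 1 is invalid or absent.
    """
    fw = first_week_mvpa(weekly)
    flag = fw["first_week_mvpa"] >= GOAL_MIN_PER_WEEK
    flag = flag.where(fw["first_week_mvpa"].notna())
    return pd.Series(flag.to_numpy(), index=pd.Index(fw["subject_id"]), name="met_goal_first_week")
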