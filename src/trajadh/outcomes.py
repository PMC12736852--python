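"""Twelve-month percent weight change by trajectory group.

Implements the weight-imputation chain (research scale, then home scale
within two weeks of the scheduled visit, then last-recorded weight plus a
conservative 0.01 kg/day regain), percent change, the one-way ANOVA across
trajectory groups, and Cohen's d of each group against the lowest
(reference) trajectory, for the full sample and for completers only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

SCHEDULED_12MO_DAY = 364
HOME_SCALE_WINDOW_DAYS = 14
REGAIN_KG_PER_DAY = 0.01
Z_95 = 1.96


def impute_weight_12mo(weights: pd.DataFrame) -> pd.DataFrame:
    """Resolve one 12-month weight per subject with its provenance.

    Priority per subject: (1) the research-scale 12-month value; (2) a
    home-scale value dated within +/-14 days (inclusive) of the scheduled
    day-364 visit; (3) the last recorded weight anywhere in the subject's
    history (including self-monitored weights) plus 0.01 kg per day from
    that record to day 364, labeled ``imputed``.  A subject with no weight
    history at all violates the baseline-always-present invariant.

    Returns a table (subject_id, weight_12mo_kg, source, baseline_kg).
    """
    required = {"subject_id", "visit", "weight_kg", "source", "date_offset_days"}
    missing = required - set(weights.columns)
    if missing:
        raise ValueError(f"weights table missing columns: {sorted(missing)}")
    out = []
    for sid, sub in weights.groupby("subject_id", sort=True):
        base = sub[(sub["visit"] == "baseline") & sub["weight_kg"].notna()]
        if base.empty:
            raise ValueError(f"subject {sid!r} has no baseline weight")
        baseline = float(base["weight_kg"].iloc[0])
        m12 = sub[sub["visit"] == "12mo"]

        w, src = None, None
        res = m12[(m12["source"] == "research") & m12["weight_kg"].notna()]
        if len(res):
            w, src = float(res["weight_kg"].iloc[0]), "research"
        if w is None:
            home = m12[
                (m12["source"] == "home")
                & m12["weight_kg"].notna()
                & (
                    (m12["date_offset_days"] - SCHEDULED_12MO_DAY).abs()
                    <= HOME_SCALE_WINDOW_DAYS
                )
            ]
            if len(home):
                w, src = float(home["weight_kg"].iloc[0]), "home"
        if w is None:
            # last recorded weight at or before the scheduled visit, from
            # measured visits or self-monitoring, plus the regain rate
            cand = []
            meas = sub[sub["weight_kg"].notna() & (sub["date_offset_days"] <= SCHEDULED_12MO_DAY)]
            cand += list(zip(meas["date_offset_days"], meas["weight_kg"]))
            if "last_sm_weight_kg" in sub.columns:
                sm = sub.dropna(subset=["last_sm_weight_kg", "last_sm_day"])
                sm = sm[sm["last_sm_day"] <= SCHEDULED_12MO_DAY]
                cand += list(zip(sm["last_sm_day"], sm["last_sm_weight_kg"]))
            day, last_w = max(cand, key=lambda t: t[0])
            gap = SCHEDULED_12MO_DAY - day
            w, src = float(last_w) + REGAIN_KG_PER_DAY * gap, "imputed"
        out.append(
            dict(subject_id=sid, weight_12mo_kg=w, source=src, baseline_kg=baseline)
        )
    return pd.DataFrame(out)


def percent_weight_change(baseline_kg, followup_kg):
    """Signed percent change from baseline; negative = loss."""
    baseline_kg = np.asarray(baseline_kg, dtype=float)
    if np.any(baseline_kg <= 0):
        raise ValueError("baseline weight must be positive")
    return (np.asarray(followup_kg, dtype=float) - baseline_kg) / baseline_kg * 100.0


def cohens_d(values: np.ndarray, reference: np.ndarray) -> float:
    """|mean difference| / pooled SD, (n-1)-weighted over the two groups."""
    x = np.asarray(values, dtype=float)
    r = np.asarray(reference, dtype=float)
    if len(x) < 2 or len(r) < 2:
        raise ValueError("both samples need at least 2 observations")
    nx, nr = len(x), len(r)
    pooled_var = ((nx - 1) * x.var(ddof=1) + (nr - 1) * r.var(ddof=1)) / (nx + nr - 2)
    if pooled_var == 0:
        raise ValueError("zero pooled SD: effect size undefined")
    return float(abs(x.mean() - r.mean()) / np.sqrt(pooled_var))


@dataclass
class OutcomeResult:
    population: str                 # "full" or "completers"
    group_table: pd.DataFrame       # group, n, mean, ci_low, ci_high, cohens_d
    f_statistic: float
    p_value: float
    n_total: int

    def to_dict(self) -> dict:
        return {
            "population": self.population,
            "f_statistic": self.f_statistic,
            "p_value": self.p_value,
            "n_total": self.n_total,
            "groups": self.group_table.to_dict(orient="records"),
        }


def anova_by_group(
    pct_change: pd.Series | np.ndarray,
    group: pd.Series | np.ndarray,
    population: str = "full",
    reference_group=None,
) -> OutcomeResult:
    """One-way ANOVA of percent weight change across trajectory groups.

    For a single-factor design the Type III decomposition coincides with
    the standard between/within mean-square F ratio.  Groups with a single
    subject are excluded with a warning-level note (they cannot contribute
    a within-group variance).  Cohen's d compares each group with the
    reference (lowest group label unless given), using the two-group
    pooled SD.
    """
    y = np.asarray(pct_change, dtype=float)
    g = np.asarray(group)
    keep = np.isfinite(y)
    y, g = y[keep], g[keep]
    labels = np.unique(g)
    samples = {lab: y[g == lab] for lab in labels}
    usable = [lab for lab in labels if len(samples[lab]) >= 2]
    if len(usable) < 2:
        raise ValueError("need at least two groups with >= 2 subjects")
    if reference_group is None:
        reference_group = usable[0]
    ref = samples[reference_group]

    F, p = stats.f_oneway(*[samples[lab] for lab in usable])
    # identical groups: guard the degenerate 0/0
    if not np.isfinite(F):
        F, p = 0.0, 1.0

    rows = []
    for lab in usable:
        x = samples[lab]
        se = x.std(ddof=1) / np.sqrt(len(x))
        d = np.nan if lab == reference_group else cohens_d(x, ref)
        rows.append(
            dict(
                group=lab, n=len(x), mean=x.mean(),
                ci_low=x.mean() - Z_95 * se, ci_high=x.mean() + Z_95 * se,
                cohens_d=d,
            )
        )
    return OutcomeResult(
        population=population,
        group_table=pd.DataFrame(rows),
        f_statistic=float(F),
        p_value=float(p),
        n_total=int(len(y)),
    )


def completers_filter(resolved_12mo: pd.DataFrame) -> pd.Series:
    """Subjects with a measured (research or home) 12-month weight."""
    keep = resolved_12mo["source"].isin(["research", "home"])
    return resolved_12mo.loc[keep, "subject_id"]


def outcome_analysis(
    weights: pd.DataFrame,
    modal_groups: pd.DataFrame,
    population: str = "full",
) -> OutcomeResult:
    """End-to-end: impute 12-month weights, compute percent change, join the
    modal trajectory assignment, and run the group comparison.

    ``modal_groups`` needs columns subject_id and modal_group.  With
    ``population="completers"`` subjects whose 12-month weight had to be
    imputed are dropped first; the analysis code path is otherwise
    identical.
    """
    resolved = impute_weight_12mo(weights)
    if population == "completers":
        keep = completers_filter(resolved)
        resolved = resolved[resolved["subject_id"].isin(set(keep))]
    elif population != "full":
        raise ValueError("population must be 'full' or 'completers'")
    resolved = resolved.merge(
        modal_groups[["subject_id", "modal_group"]], on="subject_id", how="inner"
    )
    pct = percent_weight_change(resolved["baseline_kg"], resolved["weight_12mo_kg"])
    return anova_by_group(pct, resolved["modal_group"], population=population)
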