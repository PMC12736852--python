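import numpy as np
import pandas as pd
import pytest

from trajadh import gbtm
from trajadh.synthetic_data import (
    acceptance_simulation_config,
    simulate_weekly_panel,
)

PAPER_BETA = [
    (32.20,),
    (82.18, -1.29, 0.06, -0.0008),
    (112.38, 2.69, -0.08, 0.0006),
    (182.44, 2.14, -0.03),
]
PAPER_PI = (0.345, 0.398, 0.193, 0.064)
PAPER_SIGMA = 40.01
PAPER_ORDERS = (0, 3, 3, 2)


def make_daily_week(subject_id, week, wear_mvpa, nonwear_days=0, steps_wear=3000):
    """One subject-week of daily records: ``wear_mvpa`` is the MVPA minutes
    per wear day (list), remaining days filled as non-wear."""
    days = []
    base = (week - 1) * 7
    for i, m in enumerate(wear_mvpa):
        days.append((subject_id, base + i + 1, steps_wear, m, 0))
    for i in range(len(wear_mvpa), len(wear_mvpa) + nonwear_days):
        days.append((subject_id, base + i + 1, 100, 0, 0))
    return pd.DataFrame(
        days,
        columns=["subject_id", "day", "steps", "fairly_active_min", "very_active_min"],
    )


@pytest.fixture(scope="session")
def small_panel():
    """A small, quickly fittable cohort from the published generating model
    (covariate-free): 150 subjects x 30 weeks."""
    import dataclasses

    cfg = dataclasses.replace(
        acceptance_simulation_config(n_subjects=150, seed=42), n_weeks=30
    )
    weekly, group = simulate_weekly_panel(cfg)
    return weekly, group, cfg


@pytest.fixture(scope="session")
def paper_spec():
    return gbtm.GbtmSpec(4, PAPER_ORDERS)


@pytest.fixture(scope="session")
def recovery_replicates():
    """Simulate-and-refit replicates of the published model at trial scale
    (N=502, 52 weeks, ~20% invalid weeks); shared across recovery tests."""
    reps = []
    for seed in range(20):
        cfg = acceptance_simulation_config(n_subjects=502, seed=100 + seed)
        weekly, group = simulate_weekly_panel(cfg)
        f = gbtm.fit(
            gbtm.GbtmSpec(4, PAPER_ORDERS), weekly, n_starts=2, seed=seed
        )
        post = gbtm.posteriors(f, weekly)
        modal_share = (post["modal_group"] == 1).mean()
        reps.append({"fit": f, "modal_share_1": modal_share, "true_group": group})
    return reps
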