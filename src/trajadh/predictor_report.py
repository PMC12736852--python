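"""Membership-model inference table: adjusted odds ratios with CIs,
t-statistics, p-values, and Benjamini-Hochberg FDR-adjusted q-values.

Each non-reference trajectory group contributes one row per predictor.
AOR = exp(estimate); the 95% CI uses the normal multiplier 1.96 on the
log-odds scale.  The FDR family is the set of predictor tests only —
membership constants are reported but excluded from the adjustment.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .gbtm import GbtmFit

Z_95 = 1.96


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving with input.

    q_(i) = min_{j >= i} p_(j) * m / j, capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def build_rows(fit: GbtmFit, group_names: list[str] | None = None) -> pd.DataFrame:
    """One row per (non-reference group x predictor), constants included.

    Returns columns: group, predictor, estimate, se, aor, ci_low, ci_high,
    t, p, q.  AOR/CI/q are NaN on constant rows; q comes from a single BH
    adjustment across all non-constant rows.
    """
    if fit.theta.size == 0:
        raise ValueError("fit has no membership model to report")
    covs = ("constant",) + fit.spec.membership_covariates
    K = fit.spec.n_groups
    rows = []
    for j in range(2, K + 1):
        name = group_names[j - 1] if group_names else f"group_{j}"
        for c, pred in enumerate(covs):
            est = float(fit.theta[j - 2, c])
            se = float(fit.se_theta[j - 2, c])
            t = est / se if se > 0 else np.nan
            p = 2.0 * stats.norm.sf(abs(t)) if np.isfinite(t) else np.nan
            is_const = pred == "constant"
            rows.append(
                dict(
                    group=name,
                    predictor=pred,
                    estimate=est,
                    se=se,
                    aor=np.nan if is_const else np.exp(est),
                    ci_low=np.nan if is_const else np.exp(est - Z_95 * se),
                    ci_high=np.nan if is_const else np.exp(est + Z_95 * se),
                    t=t,
                    p=p,
                )
            )
    out = pd.DataFrame(rows)
    out["q"] = np.nan
    mask = out["predictor"] != "constant"
    out.loc[mask, "q"] = fdr_adjust(out.loc[mask, "p"].to_numpy())
    return out
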