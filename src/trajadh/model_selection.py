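"""Choosing and vetting the trajectory model: fit indices, group-count
scan, polynomial simplification, and classification-adequacy diagnostics.

Sign convention: BIC and AIC are reported on the "larger is better" scale
used by PROC TRAJ output — log-likelihood minus the penalty (0.5 k ln n for
BIC, k for AIC) — not the textbook -2 log L + penalty.  Two BICs are
reported: one with n = total valid weekly observations, one with n = number
of subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import gbtm


@dataclass(frozen=True)
class FitIndices:
    loglik: float
    k_params: int
    n_obs: int
    n_subjects: int
    bic_obs: float
    bic_subj: float
    aic: float


def fit_indices(loglik: float, k_params: int, n_obs: int, n_subjects: int) -> FitIndices:
    """BIC (both observation counts) and AIC on the larger-is-better scale."""
    if not n_obs >= n_subjects >= 1:
        raise ValueError("need n_obs >= n_subjects >= 1")
    return FitIndices(
        loglik=loglik,
        k_params=k_params,
        n_obs=n_obs,
        n_subjects=n_subjects,
        bic_obs=loglik - 0.5 * k_params * np.log(n_obs),
        bic_subj=loglik - 0.5 * k_params * np.log(n_subjects),
        aic=loglik - k_params,
    )


def indices_for_fit(fit: gbtm.GbtmFit) -> FitIndices:
    return fit_indices(fit.loglik, fit.k_params, fit.n_obs, fit.n_subjects)


def scan_groups(
    weekly: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    k_max: int = 6,
    seed: int | None = None,
    membership_covariates: tuple[str, ...] = (),
    scan_order: int = 3,
    n_starts: int = 3,
    min_share: float = 0.05,
) -> pd.DataFrame:
    """Fit K = 1..k_max (cubic trajectories by default) and tabulate indices.

    The recommendation is the largest K whose observation-count BIC improves
    on the current best and whose smallest modal group still holds at least
    ``min_share`` of subjects.  Non-convergent K are reported with NaN
    indices rather than dropped.
    """
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    rows = []
    recommended = None
    best_bic = -np.inf
    for K in range(1, k_max + 1):
        spec = gbtm.GbtmSpec(
            K, (scan_order,) * K, membership_covariates=membership_covariates
        )
        try:
            f = gbtm.fit(spec, weekly, covariates, n_starts=n_starts, seed=seed)
            idx = indices_for_fit(f)
            post = gbtm.posteriors(f, weekly, covariates)
            shares = (
                post["modal_group"].value_counts(normalize=True)
                .reindex(range(1, K + 1), fill_value=0.0)
            )
            mshare = float(shares.min())
            rows.append(
                dict(K=K, loglik=idx.loglik, k_params=idx.k_params,
                     bic_obs=idx.bic_obs, bic_subj=idx.bic_subj, aic=idx.aic,
                     min_group_share=mshare, converged=f.converged)
            )
            if idx.bic_obs > best_bic and mshare >= min_share:
                best_bic = idx.bic_obs
                recommended = K
        except gbtm.FitError as exc:
            rows.append(
                dict(K=K, loglik=np.nan, k_params=gbtm.count_parameters(spec),
                     bic_obs=np.nan, bic_subj=np.nan, aic=np.nan,
                     min_group_share=np.nan, converged=False, error=str(exc))
            )
    out = pd.DataFrame(rows)
    out.attrs["recommended_K"] = recommended
    return out


def simplify_polynomials(
    weekly: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    n_groups: int = 4,
    alpha: float = 0.05,
    seed: int | None = None,
    start_order: int = 5,
    membership_covariates: tuple[str, ...] = (),
    n_starts: int = 3,
) -> tuple[gbtm.GbtmSpec, gbtm.GbtmFit]:
    """Backward simplification of per-group polynomial orders.

    Starts with order ``start_order`` (quintic) in every group and, while
    any group's highest-order coefficient has p >= alpha, decrements the
    order of the single group with the worst (largest) such p and refits.
    Stops when every remaining highest-order term is significant or the
    group is down to an intercept.  Orders never increase, so the loop
    terminates in at most sum(orders) refits.  At the boundary alpha = 1
    no term can ever be retained as significant, so every group reduces
    to an intercept.
    """
    spec = gbtm.GbtmSpec(
        n_groups, (start_order,) * n_groups,
        membership_covariates=membership_covariates,
    )
    while True:
        f = gbtm.fit(spec, weekly, covariates, n_starts=n_starts, seed=seed)
        spec = f.spec  # canonical ordering may permute group orders
        summ = f.summary_table()
        worst_p, worst_group = -1.0, None
        for j, order in enumerate(spec.polynomial_orders, start=1):
            if order == 0:
                continue
            row = summ[(summ["block"] == "trajectory") & (summ["group"] == j)].iloc[order]
            p = float(row["p"]) if np.isfinite(row["p"]) else 1.0
            if (alpha >= 1.0 or p >= alpha) and p > worst_p:
                worst_p, worst_group = p, j
        if worst_group is None:
            return spec, f
        orders = list(spec.polynomial_orders)
        orders[worst_group - 1] -= 1
        spec = replace(spec, polynomial_orders=tuple(orders))


@dataclass
class AdequacyDiagnostics:
    app: np.ndarray            # average posterior probability per group
    occ: np.ndarray            # odds of correct classification per group
    pi_hat: np.ndarray
    modal_proportions: np.ndarray
    pi_gap: np.ndarray         # |pi_hat - modal proportion|
    pi_ci: np.ndarray | None   # (K, 2) bootstrap CI, when requested
    app_pass: np.ndarray
    occ_pass: np.ndarray
    min_group_share: float

    APP_THRESHOLD = 0.70
    OCC_THRESHOLD = 5.0

    def all_pass(self) -> bool:
        return bool(np.all(self.app_pass) and np.all(self.occ_pass))

    def to_dict(self) -> dict:
        return {
            "app": self.app.tolist(),
            "occ": [None if not np.isfinite(v) else v for v in self.occ.tolist()],
            "pi_hat": self.pi_hat.tolist(),
            "modal_proportions": self.modal_proportions.tolist(),
            "pi_gap": self.pi_gap.tolist(),
            "pi_ci": None if self.pi_ci is None else self.pi_ci.tolist(),
            "app_pass": self.app_pass.tolist(),
            "occ_pass": self.occ_pass.tolist(),
            "min_group_share": self.min_group_share,
            "app_threshold": self.APP_THRESHOLD,
            "occ_threshold": self.OCC_THRESHOLD,
        }


def adequacy(
    posterior_table: pd.DataFrame,
    fit: gbtm.GbtmFit,
    pi_ci_boot: int = 0,
    seed: int | None = None,
    weekly: pd.DataFrame | None = None,
    covariates: pd.DataFrame | None = None,
) -> AdequacyDiagnostics:
    """Classification-adequacy diagnostics of a fitted model.

    APP_j is the mean maximum posterior among subjects modally assigned to
    group j (pass at >= 0.70); OCC_j = [APP_j/(1-APP_j)] / [pi_j/(1-pi_j)]
    (pass at >= 5.0, with APP = 1 giving +inf, a pass); the gap between
    model pi and modal classification shares is reported.  An empty modal
    group yields NaN diagnostics and a failing flag.  With ``pi_ci_boot``
    > 0 and the fitting data supplied, percentile confidence intervals for
    pi come from a parametric bootstrap (simulate from the fitted model on
    the observed missingness pattern, refit warm-started, collect pi_hat).
    """
    K = fit.spec.n_groups
    modal = posterior_table["modal_group"].to_numpy()
    maxp = posterior_table["max_posterior"].to_numpy()
    app = np.full(K, np.nan)
    modal_prop = np.zeros(K)
    for j in range(1, K + 1):
        sel = modal == j
        modal_prop[j - 1] = sel.mean()
        if sel.any():
            app[j - 1] = maxp[sel].mean()
    pi = np.asarray(fit.pi_hat)
    with np.errstate(divide="ignore", invalid="ignore"):
        app_odds = app / (1.0 - app)
        occ = app_odds / (pi / (1.0 - pi))
    app_pass = app >= AdequacyDiagnostics.APP_THRESHOLD
    occ_pass = np.where(np.isnan(occ), False, occ >= AdequacyDiagnostics.OCC_THRESHOLD)
    occ_pass |= app == 1.0  # perfect classification passes even if occ overflows

    pi_ci = None
    if pi_ci_boot > 0:
        if weekly is None:
            raise ValueError("parametric bootstrap needs the fitting data")
        pi_ci = _pi_bootstrap_ci(fit, weekly, covariates, pi_ci_boot, seed)

    return AdequacyDiagnostics(
        app=app,
        occ=occ,
        pi_hat=pi,
        modal_proportions=modal_prop,
        pi_gap=np.abs(pi - modal_prop),
        pi_ci=pi_ci,
        app_pass=app_pass,
        occ_pass=occ_pass,
        min_group_share=float(modal_prop.min()),
    )


def _pi_bootstrap_ci(fit, weekly, covariates, n_boot, seed, level=0.95):
    rng = np.random.default_rng(seed)
    panel = gbtm._Panel(fit.spec, weekly, covariates)
    pi_subj = np.exp(panel._log_pi(np.asarray(fit.theta)))
    mu_by_group = np.column_stack(
        [panel.TP[:, : len(b)] @ b for b in fit.beta]
    )
    draws = np.empty((n_boot, fit.spec.n_groups))
    base = weekly[weekly["is_valid"].astype(bool)].dropna(subset=["adherence_pct"])
    base = base.sort_values(["subject_id", "week"], kind="mergesort").reset_index(drop=True)
    for b in range(n_boot):
        u = rng.random(panel.n_subjects)
        g = (u[:, None] >= np.cumsum(pi_subj, axis=1)).sum(axis=1)
        mu = mu_by_group[np.arange(panel.n_obs), g[panel.subj_idx]]
        y = np.maximum(
            mu + rng.normal(0.0, fit.sigma, panel.n_obs), fit.spec.censor_min
        )
        sim = base.copy()
        sim["adherence_pct"] = y
        f = gbtm.fit(fit.spec, sim, covariates, n_starts=1, seed=int(rng.integers(2**31)))
        draws[b] = f.pi_hat
    a = (1.0 - level) / 2.0
    return np.quantile(draws, [a, 1.0 - a], axis=0).T
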