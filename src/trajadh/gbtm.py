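"""Censored-normal group-based trajectory modeling (GBTM).

The model: each subject i belongs to one of K latent groups.  Group j has a
polynomial mean trajectory mu_j(t) = beta_j0 + beta_j1 t + ... in the week
index t, and weekly adherence observations follow a censored ("Tobit-type")
normal observation model with shared residual SD sigma: the latent response
is Normal(mu_j(t), sigma), values at or below ``censor_min`` contribute the
lower-tail mass log Phi((censor_min - mu)/sigma), values at or above
``censor_max`` the upper-tail mass, interior values the normal density.
Group membership probabilities follow a multinomial logit in baseline
covariates x_i with group 1 as the reference:

    pi_j(x) = exp(theta_j' [1, x]) / sum_m exp(theta_m' [1, x]),  theta_1 = 0.

Observed-data log-likelihood (weeks are conditionally independent given the
group; invalid/missing weeks contribute nothing):

    sum_i log sum_j pi_j(x_i) * prod_t f_j(y_it)

Estimation maximizes this directly by multi-start quasi-Newton (L-BFGS-B
with an analytic gradient); the first start comes from a quantile split of
subject mean adherence, the rest are jittered.  Standard errors come from
the inverse of a central-difference Hessian of the observed-data
log-likelihood at the optimum, in the natural (sigma, not log-sigma)
parametrization; t-statistics use the normal reference.  Fitted groups are
canonically reordered by intercept ascending, so group 1 is always the
lowest trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import log_ndtr, logsumexp

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


def _inverse_mills(z: np.ndarray) -> np.ndarray:
    """phi(z) / Phi(z), switching to the asymptotic -z - 1/z deep in the
    lower tail where the log-ratio overflows."""
    z = np.asarray(z, dtype=float)
    out = np.empty_like(z)
    deep = z < -25.0
    safe = ~deep
    out[safe] = np.exp(stats.norm.logpdf(z[safe]) - log_ndtr(z[safe]))
    zd = z[deep]
    out[deep] = -zd - 1.0 / zd
    return out


@dataclass(frozen=True)
class GbtmSpec:
    """Model definition: groups, per-group polynomial orders, censoring
    bounds, and the ordered list of membership covariates (may be empty)."""

    n_groups: int
    polynomial_orders: tuple[int, ...]
    censor_min: float = 0.0
    censor_max: float = np.inf
    membership_covariates: tuple[str, ...] = ()
    time_coding: Callable[[np.ndarray], np.ndarray] | None = None

    def __post_init__(self) -> None:
        if self.n_groups < 1:
            raise ValueError("need at least one group")
        if len(self.polynomial_orders) != self.n_groups:
            raise ValueError("one polynomial order per group required")
        if any(o < 0 or o > 5 for o in self.polynomial_orders):
            raise ValueError("polynomial orders must lie in 0..5")
        if not self.censor_min < self.censor_max:
            raise ValueError("censor_min must be below censor_max")


def count_parameters(spec: GbtmSpec) -> int:
    """Free parameters: trajectory coefficients + shared sigma + membership
    (constant plus one slope per covariate, per non-reference group)."""
    return (
        sum(o + 1 for o in spec.polynomial_orders)
        + 1
        + (spec.n_groups - 1) * (1 + len(spec.membership_covariates))
    )


def censored_normal_loglik(y, mu, sigma, censor_min=0.0, censor_max=np.inf):
    """Log-density of the censored-normal observation model (vectorized).

    ``y <= censor_min`` contributes log Phi((censor_min - mu)/sigma);
    ``y >= censor_max`` contributes log Phi(-(censor_max - mu)/sigma);
    interior values the normal log density.
    """
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if not np.all(np.isfinite(y)) or not np.all(np.isfinite(mu)):
        raise ValueError("non-finite observations or means")
    if not np.all(np.asarray(sigma) > 0):
        raise ValueError("sigma must be positive")
    z = (y - mu) / sigma
    out = -np.log(sigma) - _LOG_SQRT_2PI - 0.5 * z * z
    lo = y <= censor_min
    hi = y >= censor_max
    if np.any(lo):
        zlo = (censor_min - mu) / sigma
        out = np.where(lo, log_ndtr(np.broadcast_to(zlo, out.shape)), out)
    if np.any(hi) and np.isfinite(censor_max):
        zhi = (censor_max - mu) / sigma
        out = np.where(hi, log_ndtr(np.broadcast_to(-zhi, out.shape)), out)
    return out


# ----------------------------------------------------------------- internals


class _Panel:
    """Prepared long-format data: observations sorted by subject, with the
    polynomial time basis and the membership design matrix."""

    def __init__(
        self,
        spec: GbtmSpec,
        weekly: pd.DataFrame,
        covariates: pd.DataFrame | None,
    ) -> None:
        w = weekly
        if "is_valid" in w.columns:
            w = w[w["is_valid"].astype(bool)]
        w = w.dropna(subset=["adherence_pct"])
        w = w.sort_values(["subject_id", "week"], kind="mergesort")

        self.subject_ids = w["subject_id"].unique()
        all_ids = weekly["subject_id"].unique()
        empty = np.setdiff1d(all_ids, self.subject_ids)
        if empty.size:
            raise ValueError(
                f"{empty.size} subject(s) have zero valid weeks (e.g. {empty[0]!r})"
            )
        self.n_subjects = len(self.subject_ids)
        self.y = w["adherence_pct"].to_numpy(dtype=float)
        t = w["week"].to_numpy(dtype=float)
        if spec.time_coding is not None:
            t = np.asarray(spec.time_coding(t), dtype=float)
        self.n_obs = len(self.y)
        codes = pd.factorize(w["subject_id"].to_numpy(), sort=False)[0]
        self.subj_idx = codes
        self.seg_starts = np.searchsorted(codes, np.arange(self.n_subjects))

        self.max_order = max(spec.polynomial_orders)
        self.TP = t[:, None] ** np.arange(self.max_order + 1)[None, :]
        # per-power scale factors: optimizing in the scaled basis t^m / c_m
        # keeps the problem well conditioned (raw powers of t reach 1e5+)
        tmax = max(np.abs(t).max(), 1.0)
        self.power_scale = tmax ** np.arange(self.max_order + 1)
        self.beta_scale = np.concatenate(
            [self.power_scale[: o + 1] for o in spec.polynomial_orders]
        )
        self.spec = spec
        self.lo_mask = self.y <= spec.censor_min
        self.hi_mask = np.isfinite(spec.censor_max) & (self.y >= spec.censor_max)
        self.interior = ~(self.lo_mask | self.hi_mask)

        p = len(spec.membership_covariates)
        if p:
            if covariates is None:
                raise ValueError("spec names membership covariates but none supplied")
            cov = covariates.set_index("subject_id") if "subject_id" in covariates.columns else covariates
            missing = [c for c in spec.membership_covariates if c not in cov.columns]
            if missing:
                raise KeyError(f"covariate table lacks columns: {missing}")
            sub = cov.loc[self.subject_ids, list(spec.membership_covariates)]
            if sub.isna().any().any():
                raise ValueError("missing covariate values for modeled subjects")
            self.X = np.column_stack([np.ones(self.n_subjects), sub.to_numpy(dtype=float)])
        else:
            self.X = np.ones((self.n_subjects, 1))
        self.n_theta = (spec.n_groups - 1) * self.X.shape[1]
        self.n_beta = sum(o + 1 for o in spec.polynomial_orders)

    # --- parameter packing: [beta_flat, log_sigma, theta_flat] -------------

    def pack(self, beta: Sequence[np.ndarray], sigma: float, theta: np.ndarray) -> np.ndarray:
        return np.concatenate(
            [np.concatenate([np.asarray(b, float) for b in beta]),
             [np.log(sigma)], np.asarray(theta, float).ravel()]
        )

    def unpack(self, x: np.ndarray):
        beta, pos = [], 0
        for o in self.spec.polynomial_orders:
            beta.append(x[pos : pos + o + 1])
            pos += o + 1
        sigma = np.exp(x[pos])
        pos += 1
        theta = x[pos:].reshape(self.spec.n_groups - 1, self.X.shape[1])
        return beta, sigma, theta

    # --- likelihood ---------------------------------------------------------

    def _group_logf_and_derivs(self, beta, sigma, want_derivs=True):
        K = self.spec.n_groups
        n = self.n_obs
        logf = np.empty((n, K))
        dmu = np.empty((n, K)) if want_derivs else None
        dsig = np.empty((n, K)) if want_derivs else None
        cmin, cmax = self.spec.censor_min, self.spec.censor_max
        for j in range(K):
            mu = self.TP[:, : len(beta[j])] @ beta[j]
            z = (self.y - mu) / sigma
            lf = -np.log(sigma) - _LOG_SQRT_2PI - 0.5 * z * z
            if want_derivs:
                dm = z / sigma
                ds = (z * z - 1.0) / sigma
            if self.lo_mask.any():
                zlo = (cmin - mu[self.lo_mask]) / sigma
                lf[self.lo_mask] = log_ndtr(zlo)
                if want_derivs:
                    r = _inverse_mills(zlo)
                    dm[self.lo_mask] = -r / sigma
                    ds[self.lo_mask] = -r * zlo / sigma
            if self.hi_mask.any():
                zhi = (cmax - mu[self.hi_mask]) / sigma
                lf[self.hi_mask] = log_ndtr(-zhi)
                if want_derivs:
                    r = _inverse_mills(-zhi)
                    dm[self.hi_mask] = r / sigma
                    ds[self.hi_mask] = r * zhi / sigma
            logf[:, j] = lf
            if want_derivs:
                dmu[:, j] = dm
                dsig[:, j] = ds
        return logf, dmu, dsig

    def _log_pi(self, theta):
        A = np.column_stack([np.zeros(self.n_subjects), self.X @ theta.T])
        return A - logsumexp(A, axis=1, keepdims=True)

    def _subject_sums(self, logf):
        K = logf.shape[1]
        S = np.empty((self.n_subjects, K))
        for j in range(K):
            S[:, j] = np.add.reduceat(logf[:, j], self.seg_starts)
        return S

    def loglik(self, x: np.ndarray) -> float:
        beta, sigma, theta = self.unpack(x)
        logf, _, _ = self._group_logf_and_derivs(beta, sigma, want_derivs=False)
        M = self._log_pi(theta) + self._subject_sums(logf)
        return float(logsumexp(M, axis=1).sum())

    def loglik_grad(self, x: np.ndarray):
        """Observed-data log-likelihood and its gradient in packed
        (beta, log sigma, theta) coordinates."""
        beta, sigma, theta = self.unpack(x)
        logf, dmu, dsig = self._group_logf_and_derivs(beta, sigma)
        logpi = self._log_pi(theta)
        S = self._subject_sums(logf)
        M = logpi + S
        ll_i = logsumexp(M, axis=1)
        W = np.exp(M - ll_i[:, None])  # posterior weights, subjects x K

        wobs = W[self.subj_idx]
        grad = np.empty_like(x)
        pos = 0
        for j, o in enumerate(self.spec.polynomial_orders):
            g = (wobs[:, j] * dmu[:, j]) @ self.TP[:, : o + 1]
            grad[pos : pos + o + 1] = g
            pos += o + 1
        grad[pos] = sigma * float((wobs * dsig).sum())
        pos += 1
        resid = W - np.exp(logpi)
        gtheta = resid[:, 1:].T @ self.X
        grad[pos:] = gtheta.ravel()
        return float(ll_i.sum()), grad

    def posteriors_matrix(self, x: np.ndarray) -> np.ndarray:
        beta, sigma, theta = self.unpack(x)
        logf, _, _ = self._group_logf_and_derivs(beta, sigma, want_derivs=False)
        M = self._log_pi(theta) + self._subject_sums(logf)
        return np.exp(M - logsumexp(M, axis=1, keepdims=True))

    # --- natural-parametrization gradient, for the Hessian ------------------

    def natural_grad(self, xnat: np.ndarray) -> np.ndarray:
        x = xnat.copy()
        isig = self.n_beta
        x[isig] = np.log(xnat[isig])
        _, g = self.loglik_grad(x)
        g[isig] = g[isig] / xnat[isig]  # d/d log sigma -> d/d sigma
        return g


def mixture_loglik(
    spec: GbtmSpec,
    beta: Sequence[Sequence[float]],
    sigma: float,
    theta: np.ndarray | None,
    weekly: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
) -> float:
    """Observed-data log-likelihood at the given parameter values."""
    panel = _Panel(spec, weekly, covariates)
    if theta is None:
        theta = np.zeros((spec.n_groups - 1, panel.X.shape[1]))
    x = panel.pack([np.asarray(b, float) for b in beta], sigma, np.asarray(theta, float))
    return panel.loglik(x)


# ----------------------------------------------------------------------- fit


@dataclass
class GbtmFit:
    spec: GbtmSpec
    beta: list[np.ndarray]
    sigma: float
    theta: np.ndarray  # (K-1, 1 + n_covariates), group 1 reference
    loglik: float
    n_obs: int
    n_subjects: int
    k_params: int
    se_beta: list[np.ndarray]
    se_sigma: float
    se_theta: np.ndarray
    pi_hat: np.ndarray
    converged: bool
    start_logliks: list[float] = field(default_factory=list)
    vcov: np.ndarray | None = None

    def summary_table(self) -> pd.DataFrame:
        """Every free parameter with estimate, SE, t (normal reference), p."""
        term_names = ["Intercept", "Linear", "Quadratic", "Cubic", "Quartic", "Quintic"]
        rows = []
        for j, (b, s) in enumerate(zip(self.beta, self.se_beta), start=1):
            for m, (est, se) in enumerate(zip(b, s)):
                rows.append(("trajectory", j, term_names[m], est, se))
        rows.append(("sigma", 0, "Sigma", self.sigma, self.se_sigma))
        covs = ("constant",) + self.spec.membership_covariates
        for j in range(self.theta.shape[0]):
            for c, name in enumerate(covs):
                rows.append(
                    ("membership", j + 2, name, self.theta[j, c], self.se_theta[j, c])
                )
        df = pd.DataFrame(rows, columns=["block", "group", "term", "estimate", "se"])
        with np.errstate(divide="ignore", invalid="ignore"):
            df["t"] = df["estimate"] / df["se"]
        df["p"] = 2.0 * stats.norm.sf(np.abs(df["t"]))
        return df

    def to_dict(self) -> dict:
        return {
            "n_groups": self.spec.n_groups,
            "polynomial_orders": list(self.spec.polynomial_orders),
            "censor_min": self.spec.censor_min,
            "censor_max": None if np.isinf(self.spec.censor_max) else self.spec.censor_max,
            "membership_covariates": list(self.spec.membership_covariates),
            "beta": [b.tolist() for b in self.beta],
            "se_beta": [s.tolist() for s in self.se_beta],
            "sigma": self.sigma,
            "se_sigma": self.se_sigma,
            "theta": self.theta.tolist(),
            "se_theta": self.se_theta.tolist(),
            "pi_hat": self.pi_hat.tolist(),
            "loglik": self.loglik,
            "n_obs": self.n_obs,
            "n_subjects": self.n_subjects,
            "k_params": self.k_params,
            "converged": self.converged,
        }


class FitError(RuntimeError):
    """Raised when no optimization start converges to a usable optimum."""


def _kmeans_1d(values: np.ndarray, k: int) -> np.ndarray:
    """Exact (globally optimal) 1-D k-means by dynamic programming over the
    sorted values; returns cluster labels 0..k-1 ordered by cluster mean.
    Lloyd iterations from heuristic centers routinely merge small extreme
    clusters, which is precisely the failure mode a trajectory-group start
    must avoid."""
    n = len(values)
    k = min(k, n)
    order = np.argsort(values, kind="mergesort")
    v = values[order]
    s1 = np.concatenate([[0.0], np.cumsum(v)])
    s2 = np.concatenate([[0.0], np.cumsum(v * v)])

    def seg_cost(a, b):  # SSE of v[a:b], vectorized in a
        cnt = b - a
        sm = s1[b] - s1[a]
        sq = s2[b] - s2[a]
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(cnt > 0, sq - sm * sm / np.maximum(cnt, 1), np.inf)

    INF = np.inf
    D = np.full((k + 1, n + 1), INF)
    arg = np.zeros((k + 1, n + 1), dtype=int)
    D[0, 0] = 0.0
    for kk in range(1, k + 1):
        for i in range(kk, n + 1):
            j = np.arange(kk - 1, i)
            cand = D[kk - 1, j] + seg_cost(j, i)
            best = int(np.argmin(cand))
            D[kk, i] = cand[best]
            arg[kk, i] = j[best]
    # backtrack segment boundaries
    labels_sorted = np.empty(n, dtype=int)
    i = n
    for kk in range(k, 0, -1):
        a = arg[kk, i]
        labels_sorted[a:i] = kk - 1
        i = a
    labels = np.empty(n, dtype=int)
    labels[order] = labels_sorted
    return labels


def _quantile_start(panel: _Panel, rng: np.random.Generator):
    """K-means-style first start: cluster subjects on mean adherence, fit
    each cluster's polynomial by least squares."""
    spec = panel.spec
    K = spec.n_groups
    means = np.array(
        [seg.mean() for seg in np.split(panel.y, panel.seg_starts[1:])]
    )
    assign = _kmeans_1d(means, K)
    obs_assign = assign[panel.subj_idx]
    beta = []
    resid_ss, resid_n = 0.0, 0
    for j, o in enumerate(spec.polynomial_orders):
        mask = obs_assign == j
        if mask.sum() < o + 1:
            mask = np.ones(panel.n_obs, dtype=bool)
        A = panel.TP[mask][:, : o + 1]
        yj = panel.y[mask]
        coef, *_ = np.linalg.lstsq(A, yj, rcond=None)
        beta.append(coef)
        r = yj - A @ coef
        resid_ss += float(r @ r)
        resid_n += len(yj)
    sigma = max(np.sqrt(resid_ss / max(resid_n, 1)), 1e-2)
    counts = np.maximum(np.bincount(assign, minlength=K), 1)
    logits = np.log(counts / counts[0])
    theta = np.zeros((K - 1, panel.X.shape[1]))
    theta[:, 0] = logits[1:]
    return beta, sigma, theta


def _jittered(panel, base, rng):
    beta0, sigma0, theta0 = base
    scale = max(np.std(panel.y), 1.0)
    beta = [b + rng.normal(0.0, 0.3 * scale / (10.0 ** np.arange(len(b))), len(b)) for b in beta0]
    sigma = sigma0 * np.exp(rng.normal(0.0, 0.2))
    theta = theta0.copy()
    theta[:, 0] += rng.normal(0.0, 0.5, theta.shape[0])
    return beta, sigma, theta


def _canonicalize(spec, beta, sigma, theta):
    """Reorder groups by intercept ascending; re-reference membership logits
    to the new group 1."""
    intercepts = np.array([b[0] for b in beta])
    perm = np.argsort(intercepts, kind="mergesort")
    new_orders = tuple(spec.polynomial_orders[p] for p in perm)
    new_spec = GbtmSpec(
        n_groups=spec.n_groups,
        polynomial_orders=new_orders,
        censor_min=spec.censor_min,
        censor_max=spec.censor_max,
        membership_covariates=spec.membership_covariates,
        time_coding=spec.time_coding,
    )
    new_beta = [beta[p].copy() for p in perm]
    alpha = np.vstack([np.zeros((1, theta.shape[1] if theta.size else 1)), theta]) \
        if theta.size else np.zeros((spec.n_groups, 1))
    alpha_perm = alpha[perm]
    new_theta = alpha_perm[1:] - alpha_perm[0]
    if not theta.size:
        new_theta = theta
    return new_spec, new_beta, sigma, new_theta


def fit(
    spec: GbtmSpec,
    weekly: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    n_starts: int = 10,
    seed: int | None = None,
    maxiter: int = 2000,
) -> GbtmFit:
    """Maximum-likelihood fit of the censored-normal trajectory mixture.

    Runs ``n_starts`` L-BFGS-B maximizations (analytic gradient) and keeps
    the best; raises :class:`FitError` when none converges.  Groups in the
    returned fit are ordered by intercept ascending, standard errors come
    from the central-difference Hessian at the optimum, and ``pi_hat`` is
    the average membership probability across subjects (equal to the
    softmax of the membership constants when no covariates are modeled).
    """
    rng = np.random.default_rng(seed)
    panel = _Panel(spec, weekly, covariates)

    base = _quantile_start(panel, rng)
    starts = [base] + [_jittered(panel, base, rng) for _ in range(max(n_starts - 1, 0))]

    # optimize in the scaled polynomial basis: x_scaled = beta * c_m for the
    # trajectory block, identity elsewhere
    scale = np.ones(panel.n_beta + 1 + panel.n_theta)
    scale[: panel.n_beta] = panel.beta_scale

    def negfun(xs):
        ll, g = panel.loglik_grad(xs / scale)
        return -ll, -g / scale

    best = None
    start_lls = []
    for s in starts:
        x0 = panel.pack(*s) * scale
        res = optimize.minimize(
            negfun, x0, jac=True, method="L-BFGS-B",
            options={"maxiter": maxiter, "ftol": 1e-12, "gtol": 1e-8},
        )
        start_lls.append(-res.fun)
        if not np.isfinite(res.fun):
            continue
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise FitError("no optimization start reached a finite optimum")

    beta, sigma, theta = panel.unpack(best.x / scale)
    if sigma < 1e-6:
        raise FitError("sigma collapsed to the boundary; data degenerate")
    cspec, cbeta, csigma, ctheta = _canonicalize(spec, beta, sigma, theta)

    # SEs on the canonical parametrization
    cpanel = _Panel(cspec, weekly, covariates)
    xnat = np.concatenate(
        [np.concatenate(cbeta), [csigma], np.asarray(ctheta).ravel()]
    )
    H = _numerical_hessian(cpanel.natural_grad, xnat)
    se = _se_from_hessian(H)
    nb = cpanel.n_beta
    se_beta, pos = [], 0
    for o in cspec.polynomial_orders:
        se_beta.append(se[pos : pos + o + 1])
        pos += o + 1
    se_sigma = float(se[nb])
    se_theta = se[nb + 1 :].reshape(ctheta.shape) if ctheta.size else ctheta.copy()

    xpacked = cpanel.pack(cbeta, csigma, ctheta)
    W = cpanel.posteriors_matrix(xpacked)
    pi_subj = np.exp(cpanel._log_pi(np.asarray(ctheta)))
    pi_hat = pi_subj.mean(axis=0)

    try:
        vcov = np.linalg.inv(-H)
    except np.linalg.LinAlgError:
        vcov = None

    return GbtmFit(
        spec=cspec,
        beta=[np.asarray(b) for b in cbeta],
        sigma=float(csigma),
        theta=np.asarray(ctheta),
        loglik=float(-best.fun),
        n_obs=cpanel.n_obs,
        n_subjects=cpanel.n_subjects,
        k_params=count_parameters(cspec),
        se_beta=se_beta,
        se_sigma=se_sigma,
        se_theta=se_theta,
        pi_hat=pi_hat,
        converged=bool(best.success),
        start_logliks=start_lls,
        vcov=vcov,
    )


def _numerical_hessian(grad_fn, x, rel_step=1e-5):
    d = len(x)
    H = np.empty((d, d))
    for i in range(d):
        h = rel_step * max(abs(x[i]), 1.0)
        xp, xm = x.copy(), x.copy()
        xp[i] += h
        xm[i] -= h
        H[:, i] = (grad_fn(xp) - grad_fn(xm)) / (2.0 * h)
    return 0.5 * (H + H.T)


def _se_from_hessian(H):
    try:
        cov = np.linalg.inv(-H)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(-H)
    diag = np.diag(cov).copy()
    diag[diag < 0] = np.nan
    return np.sqrt(diag)


def posteriors(
    fit_: GbtmFit,
    weekly: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-subject posterior group probabilities and modal assignment.

    Posterior_ij is proportional to pi_j(x_i) times the product of the
    subject's censored-normal week densities under group j.  Modal ties
    break to the lowest group index.
    """
    panel = _Panel(fit_.spec, weekly, covariates)
    x = panel.pack(fit_.beta, fit_.sigma, fit_.theta)
    W = panel.posteriors_matrix(x)
    out = pd.DataFrame(
        W, columns=[f"prob_{j + 1}" for j in range(fit_.spec.n_groups)]
    )
    out.insert(0, "subject_id", panel.subject_ids)
    out["modal_group"] = W.argmax(axis=1) + 1
    out["max_posterior"] = W.max(axis=1)
    return out
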