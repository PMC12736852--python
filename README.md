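# trajadh

Trajectories of adherence to a weekly physical-activity goal, from
wearable-tracker data.

Behavioral weight-loss trials prescribe moderate-to-vigorous physical
activity (MVPA) goals — here ≥300 min/week — and track them with consumer
wearables over a year. Participants do not follow one average curve: some
never approach the goal, some hover near it, some build up to it, a few
exceed it throughout. `trajadh` implements the full analysis pipeline for
characterizing that heterogeneity:

1. **Adherence metrics** — daily tracker records (steps, "fairly active"
   and "very active" minutes) are reduced to weekly goal-adherence
   percentages. A day with ≥500 steps is a *wear day*; a week with ≥4 wear
   days is *valid*; weekly MVPA is the wear-day sum scaled to seven days
   (`sum / wear days × 7`), and adherence is that figure over the
   300-minute goal, ×100 (uncapped above 100).
2. **Group-based trajectory modeling (GBTM)** — a finite mixture of
   censored-normal polynomial trajectories. Subject *i* in latent group
   *j* has weekly adherence

   ```
   y_it = max(0,  β_j0 + β_j1 t + … + β_jp t^p + ε_it),   ε_it ~ N(0, σ²)
   ```

   with left-censoring at 0 handled Tobit-style (mass `Φ((0−μ_jt)/σ)` at
   the bound), a shared σ, and group membership following a multinomial
   logit in baseline covariates, `π_j(x) ∝ exp(θ_j'[1, x])` with group 1 as
   reference. Everything is estimated jointly by maximum likelihood.
3. **Model selection & adequacy** — BIC (on both observation and subject
   counts) and AIC in the larger-is-better convention, a group-count scan
   with a 5% minimum-group-size rule, backward simplification of
   polynomial orders at p < 0.05, and the classification diagnostics APP
   (average posterior probability, ≥0.70) and OCC (odds of correct
   classification, ≥5.0).
4. **Predictor report** — adjusted odds ratios `exp(θ)` with normal 95%
   CIs and Benjamini–Hochberg FDR-adjusted p-values for the membership
   model.
5. **Weight outcomes** — 12-month percent weight change by trajectory
   group: measured-weight priority with a home-scale ±14-day window and a
   conservative +0.01 kg/day imputation for dropouts, one-way ANOVA, and
   Cohen's d against the lowest-adherence group, for the full sample and
   completers.
6. **Synthetic cohorts** — a first-class generator that draws covariates,
   latent groups, weekly adherence, daily tracker records (inverting the
   adherence formula), and weight outcomes from a published fitted model,
   so every stage is testable without access to trial data.

## Worked example

Simulate a trial-scale cohort (502 subjects × 52 weeks) from the built-in
generating model and refit the four-group censored-normal GBTM:

```python
import numpy as np
from trajadh import GbtmSpec, fit_gbtm, posteriors, adequacy
from trajadh.synthetic_data import acceptance_simulation_config, simulate_weekly_panel

cfg = acceptance_simulation_config(n_subjects=502, seed=1)
weekly, truth = simulate_weekly_panel(cfg)

fit = fit_gbtm(GbtmSpec(4, (0, 3, 3, 2)), weekly, n_starts=3, seed=1)
print(f"log-likelihood: {fit.loglik:.1f}  (k = {fit.k_params}, n_obs = {fit.n_obs})")
print(f"sigma: {fit.sigma:.2f} +/- {fit.se_sigma:.2f}")
for j, (b, se) in enumerate(zip(fit.beta, fit.se_beta), start=1):
    print(f"group {j}: intercept {b[0]:7.2f} +/- {se[0]:.2f}   pi_hat {fit.pi_hat[j-1]:.3f}")
post = posteriors(fit, weekly)
diag = adequacy(post, fit)
print("APP:", np.round(diag.app, 3), " OCC:", np.round(diag.occ, 1))
```

Output:

```
log-likelihood: -100045.8  (k = 16, n_obs = 20939)
sigma: 39.75 +/- 0.21
group 1: intercept   31.83 +/- 0.48   pi_hat 0.352
group 2: intercept   80.78 +/- 1.90   pi_hat 0.393
group 3: intercept  108.81 +/- 2.74   pi_hat 0.185
group 4: intercept  183.06 +/- 3.26   pi_hat 0.070
APP: [1. 1. 1. 1.]  OCC: [7.2649e+03 2.8359e+05 3.5912e+11 inf]
```

The fit recovers the generating model: groups ordered by intercept
(lowest trajectory is always group 1), σ near the generating 40.01,
mixture weights near (0.345, 0.398, 0.193, 0.064), and — with 40+ valid
weeks per subject and well-separated trajectories — essentially perfect
posterior classification (APP ≈ 1, OCC far above the 5.0 adequacy bar).

The same stages are available from the shell:

```bash
trajadh simulate --out data/ --seed 1
trajadh adherence --daily data/daily_activity.csv --out weekly.csv
trajadh fit --weekly weekly.csv --groups 4 --orders 0,3,3,2 --seed 1
trajadh run --seed 1 --out run1/        # full pipeline with manifest
```

## Layout

- `src/trajadh/adherence.py` — wear-day / valid-week rules, weekly metrics
- `src/trajadh/synthetic_data.py` — cohort generator and configurations
- `src/trajadh/gbtm.py` — censored-normal mixture likelihood, fitting,
  posteriors
- `src/trajadh/model_selection.py` — fit indices, scans, simplification,
  APP/OCC
- `src/trajadh/predictor_report.py` — AOR table, FDR adjustment
- `src/trajadh/outcomes.py` — weight imputation, ANOVA, effect sizes
- `src/trajadh/pipeline.py`, `cli.py` — validated IO, runner, `trajadh` CLI
- `docs/methods.md` — modeling assumptions, numerical choices, limitations
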