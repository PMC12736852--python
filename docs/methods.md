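# Methods

## The observation model

Weekly goal adherence is a percentage bounded below at zero: a subject who
records no MVPA in a valid week contributes an exact 0, and zeros are
common in the low-adherence range. Treating these as ordinary normal
observations would bias both the trajectory means and the residual SD
downward, so the package uses the censored-normal (Tobit-type)
observation model standard in group-based trajectory modeling of bounded
continuous outcomes: a latent Normal(μ_jt, σ²) response of which values at
or below `censor_min` are observed as the bound and contribute the tail
mass log Φ((censor_min − μ_jt)/σ) to the likelihood. The defaults are
`censor_min = 0` and no upper bound — adherence legitimately exceeds 100%
(the highest trajectory group sits near 180–200% for much of the year),
so capping at 100 would be wrong.

μ_jt is a polynomial in the week index t = 1…52, used raw (no centering
or scaling of t at the model level). The time coding is a genuine free
choice — published trajectory tables rarely state it — and the generator
and the fitter share this convention, so simulate-and-refit experiments
are self-consistent. A `time_coding` hook on the model spec accepts any
transform if a different convention is needed.

σ is shared across groups and weeks (a single residual-SD row is the
convention in trajectory-model output). Weeks are conditionally
independent given group membership; see "What the generator does not
emulate" for the consequences.

## Membership submodel and joint estimation

Group probabilities follow a multinomial logit in baseline covariates
with group 1 (lowest trajectory) as reference: π_j(x) ∝ exp(θ_j'[1, x]),
θ_1 ≡ 0. Membership coefficients are estimated *jointly* with the
trajectories by maximizing the observed-data log-likelihood

    Σ_i log Σ_j π_j(x_i) Π_t f_j(y_it),

the risk-factor extension of the classic model. A two-stage alternative
(fit without covariates, then multinomial regression on modal
assignments) understates uncertainty because it conditions on the
classification; it is deliberately not the primary path.

`pi_hat` reported with a fit is the average of π_j(x_i) across subjects;
without covariates this is the softmax of the membership constants. At
the MLE it equals the average posterior probability vector (mixture score
stationarity), which the test suite asserts to 1e-5.

## Optimization

The log-likelihood is maximized directly by multi-start L-BFGS-B with an
analytic gradient (posterior-weighted score contributions; the censored
branch uses the inverse Mills ratio with an asymptotic switch deep in the
tail). Two numerical points matter in practice:

- **Basis conditioning.** Raw powers of t reach 1.4 × 10⁵ by t = 52 at
  cubic order; quasi-Newton methods stall badly on that scaling. The
  optimizer works in a scaled basis (t^m / max(t)^m) and converts back,
  which is exact.
- **Starting values.** The first start clusters subjects on their mean
  adherence with an *exact* 1-D k-means (dynamic programming over sorted
  values), then fits each cluster's polynomial by least squares. Lloyd
  iterations from heuristic centers routinely merge a small extreme
  cluster (the ~6% high-adherence group) into its neighbor and split the
  large middle mass instead — a local optimum the likelihood surface then
  preserves. The remaining starts jitter the first; the best final
  log-likelihood is kept, and the fit records every start's value so
  monotone improvement is checkable.

A direct quasi-Newton ascent was chosen over an EM loop with a
quasi-Newton polish: with the exact-k-means start the direct maximization
reaches the same optima in a few seconds at trial scale, and the EM
stationarity property that motivates the alternative holds at the MLE
regardless of the route taken.

Convergence uses L-BFGS-B's relative-reduction rule at `ftol = 1e-12`
with gradient tolerance 1e-8. Standard errors come from a
central-difference Hessian of the observed-data log-likelihood at the
optimum in the natural parametrization (σ, not log σ); t-statistics use
the normal reference, the convention of trajectory-model software
(degrees of freedom are not well defined here). Fitted groups are
canonically reordered by intercept ascending, with membership logits
re-referenced to the new group 1, before any SEs are computed.

## Fit indices and selection

BIC and AIC are reported as log-likelihood minus penalty (0.5 k ln n and
k) — the "larger is better" orientation of PROC-TRAJ-style output, which
is the sign convention the published statistics use; most textbooks print
−2 log L + penalty instead, so the sign is documented prominently. Two
BICs are computed because both appear in practice: n = total valid weekly
observations and n = subjects.

The group-count scan fits K = 1…k_max with cubic trajectories (the full
quintic start is reserved for order simplification, keeping the scan
cheap) and recommends the largest K that improves the observation-count
BIC while every modal group keeps ≥5% of subjects. Order simplification
starts each group at the quintic and repeatedly removes the single worst
non-significant highest-order term (largest p ≥ α) across groups —
one term per refit, which makes the procedure deterministic given the
seed; at the boundary α = 1 no term can be retained and all groups reduce
to intercepts. Diagnostics: APP_j ≥ 0.70 and OCC_j = [APP_j/(1−APP_j)] /
[π_j/(1−π_j)] ≥ 5.0 per group, the gap between π̂ and modal shares, and —
optionally — percentile CIs for π from a parametric bootstrap
(simulate from the fitted model on the observed missingness pattern,
refit warm-started; 200 replicates by default, configurable because each
replicate is a full refit).

## Adherence rules

Wear day: ≥500 steps, threshold inclusive. The step rule identifies
device wear, not activity, so MVPA minutes on a sub-500-step day are
discarded entirely. Valid week: ≥4 wear days, inclusive. Weeks are fixed
7-day blocks from day 1. Weekly MVPA extrapolates the wear-day mean to
seven days; the "no extrapolation" variant (wear-day mean against the
daily-equivalent goal of 300/7 min) is algebraically identical and kept
only as a separate code path mirroring the published sensitivity
analysis. Subjects with an invalid first week get a missing
square-root-transformed first-week MVPA and drop out of the membership
model by default; a fallback to the first valid week is available behind
a flag.

## The synthetic-data generator

Defaults are the published fitted model: four trajectory groups
(intercept-only 32.20; two cubics starting at 82.18 and 112.38; a
quadratic at 182.44), shared residual SD 40.01, group probabilities
(0.345, 0.398, 0.193, 0.064), membership log-odds per the published
predictor table, covariate marginals per the published sample description
(age 45.0 ± 14.4 truncated at 18; 79.5% female; 65.5% partnered; 52.2%
COVID-era; first-week MVPA gamma moment-matched to mean 244.1 / SD 171.9,
giving shape ≈ 2.016, scale ≈ 121.1), group mean percent weight changes
(−0.33, −2.59, −4.29, −6.16) with common SD 7.1, and a 38/41/21
research/home/missing assessment mix at 12 months.

Calibrations the source material leaves open, fixed once:

- **Weight-outcome SD.** Back-solving pooled SD from the published
  effect sizes gives 7.06, 7.20 and 8.21 across the three group
  contrasts; 7.1 is adopted (the two large-group contrasts agree there).
- **Missingness.** Dropout is logistic on standardized age (−0.3),
  baseline BMI (+0.3) and first-week MVPA (−0.3) — the published
  direction of attrition — with intercept −1.3925 calibrated by numerical
  root-finding so marginal 12-month missingness is 21%. Dropouts stop
  contributing valid weeks after a uniform dropout week (5–52).
- **Invalid weeks.** Missing at random at rate 0.125, set so the
  expected number of valid weeks per subject is ≈41.2 (20,669 / 502),
  with dropout layered on top. The covariate-free configuration used in
  simulate-and-refit experiments uses a flat 20% with no dropout.
- **Week-1 coherence.** By default the week-1 adherence value is the
  drawn first-week-MVPA covariate expressed as % of goal, keeping
  predictor and response coherent; the covariate-free experiment
  configuration turns this off so the weekly series is purely the
  polynomial-plus-censored-noise model.
- **Heights** for baseline weight: Normal(1.66 m, 0.09) truncated to
  [1.45, 2.05]; only relative change matters downstream.

Daily records are rendered by inverting the adherence formula: each valid
week draws ≥4 wear days (binomial(7, 0.9) truncated), integer MVPA
minutes summing to adherence × (300/7) × wear-days distributed
multinomially over wear days (via exact sequential binomial thinning), so
recomputing adherence from the rendered days reproduces the weekly truth
within integer rounding — under 1 percentage point, which is the
tolerance the round-trip tests use.

**What the generator does not emulate.** Real covariates are drawn with
independent marginals; the trial's joint distribution differs, and in
fact the published membership coefficients integrated over independent
marginals give group shares of roughly (0.18, 0.46, 0.20, 0.16), not the
published (0.345, 0.398, 0.193, 0.064). Share-matching experiments
therefore draw groups directly from the published probabilities. For the
same reason the moment-matched gamma puts ≈29.6% (not the published
32.1%) of subjects above 300 first-week minutes. Weekly residuals are
conditionally independent given group — exactly the model's assumption,
so recovery tests validate the estimator, not robustness to serial
correlation; an AR(1) option (`ar1_noise_rho`) exists for sensitivity
work but is off by default. No minute-level bout structure, heart rate,
sleep, or mechanistic sync failures are modeled; invalid weeks stand in
for their net effect. Passing tests show the pipeline recovers a
correctly specified generating process at trial scale, not that the model
is right for any particular real cohort.

## Weight outcomes

Twelve-month weight resolution order: research-scale value; else a
home-scale value within ±14 days (inclusive) of the scheduled day-364
visit; else the last recorded weight at or before day 364 — measured
visits or self-monitoring — plus 0.01 kg/day to day 364 (a conservative
regain assumption of ~0.3 kg/month). The imputation horizon is anchored
at the scheduled visit day, not the last observed visit. Percent change
is (12-month − baseline)/baseline × 100. The group comparison is a
one-way ANOVA (for a single factor, the Type III decomposition is the
standard between/within F); group CIs use per-group normal SEs. Cohen's d
uses the two-group pooled SD of each group against the lowest-adherence
reference — the pairwise form matching the pairwise framing — rather
than the omnibus residual SD. Completers (measured 12-month weight,
research or home) re-run the identical code path after a filter.

## Problem sizes and reproducibility

Trial scale throughout is 502 subjects × 52 weeks (~20,900 weekly
observations), at which one four-group fit takes a few seconds on one
CPU. The recovery experiments in the test suite use 20 seeded replicates
at trial scale; the acceptance script uses 10. All randomness flows from
explicit integer seeds through `numpy.random.default_rng`; a fixed seed
and configuration reproduce every artifact byte-for-byte, and the
pipeline manifest records seeds, schema version, library versions, and
SHA-256 hashes of every output.

## Known limitations

- Standard errors are curvature-based (observed information); they do not
  account for model selection performed on the same data.
- The parametric bootstrap for π CIs resamples from the fitted model on
  the observed missingness pattern; it treats missingness as fixed.
- The group-count scan's improvement rule is greedy (largest K improving
  the current best BIC with admissible shares); it does not enumerate
  non-monotone BIC paths.
- With heavily overlapping trajectories or few weeks per subject the
  likelihood surface is genuinely multimodal; more starts
  (`n_starts`) are the remedy, and the per-start log-likelihoods are
  exposed for inspection.
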