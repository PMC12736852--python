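import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from trajadh import adherence as adh
from trajadh import synthetic_data as sd


@pytest.fixture(scope="module")
def paper_cfg():
    return sd.published_model_config(n_subjects=2000, seed=1)


class TestDefaultConfig:
    def test_published_values(self, paper_cfg):
        assert paper_cfg.residual_sd == 40.01
        assert paper_cfg.group_probabilities == (0.345, 0.398, 0.193, 0.064)
        assert paper_cfg.weight_outcome_means == (-0.33, -2.59, -4.29, -6.16)
        assert paper_cfg.trajectory_coefficients[0] == (32.20,)
        assert paper_cfg.trajectory_coefficients[3] == (182.44, 2.14, -0.03)

    def test_weight_sd_consistent_with_effect_sizes(self, paper_cfg):
        # pooled SD back-solved from |group mean - reference mean| / d
        implied = [abs(m + 0.33) / d for m, d in
                   [(-2.59, 0.32), (-4.29, 0.55), (-6.16, 0.71)]]
        assert min(implied) <= paper_cfg.weight_outcome_sd <= max(implied)
        assert paper_cfg.weight_outcome_sd == pytest.approx(implied[0], abs=0.15)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            sd.CohortConfig(n_subjects=10, group_probabilities=(0.5, 0.4))
        with pytest.raises(ValueError):
            dataclasses.replace(sd.published_model_config(10), residual_sd=0.0)
        with pytest.raises(ValueError):
            dataclasses.replace(sd.published_model_config(10), n_weeks=1)


class TestCovariates:
    def test_marginals_match_configuration(self):
        cfg = sd.published_model_config(n_subjects=100_000, seed=5)
        cov = sd.draw_covariates(cfg, np.random.default_rng(5))
        # truncation at 18 shifts the mean above 45 by ~0.4; compare to the
        # truncated-normal mean, not the location parameter
        a = (18 - 45.0) / 14.4
        expected_age = stats.truncnorm.mean(a, np.inf, loc=45.0, scale=14.4)
        assert cov["age"].mean() == pytest.approx(expected_age, abs=3 * 14.4 / np.sqrt(1e5))
        assert cov["age"].min() >= 18.0
        assert cov["female"].mean() == pytest.approx(0.795, abs=3 * 0.4 / np.sqrt(1e5))
        assert cov["first_week_mvpa"].mean() == pytest.approx(
            244.1, abs=3 * 171.9 / np.sqrt(1e5)
        )
        assert (cov["first_week_mvpa"] >= 0).all()
        assert stats.skew(cov["first_week_mvpa"]) > 0.5
        np.testing.assert_allclose(
            cov["sqrt_first_week_mvpa"], np.sqrt(cov["first_week_mvpa"])
        )

    def test_gamma_moment_match(self):
        cd = sd.published_model_config(10).covariate_distributions
        shape = cd["fw_mvpa_mean"] ** 2 / cd["fw_mvpa_sd"] ** 2
        scale = cd["fw_mvpa_sd"] ** 2 / cd["fw_mvpa_mean"]
        assert shape == pytest.approx(2.016, abs=0.001)
        assert scale == pytest.approx(121.06, abs=0.01)

    def test_degenerate_proportion(self):
        cfg = sd.published_model_config(n_subjects=500, seed=2)
        cdist = dict(cfg.covariate_distributions, prop_female=1.0)
        cfg = dataclasses.replace(cfg, covariate_distributions=cdist)
        cov = sd.draw_covariates(cfg, np.random.default_rng(0))
        assert (cov["female"] == 1).all()

    def test_bad_proportion_rejected(self):
        cfg = sd.published_model_config(n_subjects=10)
        cdist = dict(cfg.covariate_distributions, prop_female=1.5)
        cfg = dataclasses.replace(cfg, covariate_distributions=cdist)
        with pytest.raises(ValueError):
            sd.draw_covariates(cfg, np.random.default_rng(0))


class TestGroupAssignment:
    def test_null_coefficients_uniform(self):
        cfg = sd.published_model_config(n_subjects=2000, seed=3)
        cfg = dataclasses.replace(
            cfg, membership_coefficients=((0.0,) * 7, (0.0,) * 7, (0.0,) * 7)
        )
        cov = sd.draw_covariates(cfg, np.random.default_rng(3))
        _, probs = sd.assign_groups(cov, cfg, np.random.default_rng(3))
        np.testing.assert_allclose(probs, 0.25)

    def test_softmax_of_constants(self):
        # single subject with all covariates 0: softmax over the constants
        cov = pd.DataFrame(
            {
                "subject_id": [1], "age": [0.0], "female": [0], "partnered": [0],
                "covid_era": [0], "arm": [0], "first_week_mvpa": [0.0],
                "sqrt_first_week_mvpa": [0.0],
            }
        )
        theta = ((-4.37, 0, 0, 0, 0, 0, 0), (-8.10,) + (0,) * 6, (-19.23,) + (0,) * 6)
        p = sd.membership_probabilities(cov, theta)
        assert p[0, 0] == pytest.approx(0.987, abs=0.001)

    def test_unknown_covariate_rejected(self):
        cov = pd.DataFrame({"subject_id": [1], "age": [50.0]})
        with pytest.raises(KeyError):
            sd.membership_probabilities(cov, ((0.0,) * 7,) * 3)

    def test_categorical_draws_match_probabilities(self):
        # chi-square goodness of fit of empirical shares against the
        # multinomial-logit probabilities, alpha = 0.001
        cfg = sd.published_model_config(n_subjects=100_000, seed=11)
        rng = np.random.default_rng(11)
        cov = sd.draw_covariates(cfg, rng)
        labels, probs = sd.assign_groups(cov, cfg, rng)
        observed = np.bincount(labels, minlength=5)[1:]
        expected = probs.sum(axis=0)
        chi2 = ((observed - expected) ** 2 / expected).sum()
        assert chi2 < stats.chi2.ppf(0.999, df=3)

    def test_direct_probability_shares(self):
        cfg = dataclasses.replace(
            sd.acceptance_simulation_config(n_subjects=100_000, seed=9), n_weeks=2
        )
        _, group = sd.simulate_weekly_panel(cfg)
        shares = np.bincount(group, minlength=5)[1:] / len(group)
        for s, p in zip(shares, cfg.group_probabilities):
            se = np.sqrt(p * (1 - p) / len(group))
            assert abs(s - p) < 3 * se


class TestWeeklyAdherence:
    def test_noiseless_intercept_group(self):
        cfg = dataclasses.replace(
            sd.acceptance_simulation_config(n_subjects=50, seed=0),
            residual_sd=1e-12, missing_week_rate=0.0,
        )
        group = pd.Series(np.ones(50, dtype=int))
        wk = sd.generate_weekly_adherence(group, cfg, np.random.default_rng(0))
        np.testing.assert_allclose(wk["adherence_pct"], 32.20, atol=1e-9)

    def test_quadratic_group_midyear_mean(self):
        cfg = sd.acceptance_simulation_config(n_subjects=1, seed=0)
        mu = sd.trajectory_means(cfg)
        assert mu[3, 25] == pytest.approx(217.8, abs=0.01)  # group 4, t=26

    def test_censoring_nonnegative(self):
        cfg = sd.acceptance_simulation_config(n_subjects=300, seed=4)
        wk, _ = sd.simulate_weekly_panel(cfg)
        vals = wk["adherence_pct"].dropna()
        assert (vals >= 0).all()
        assert (vals == 0).any()  # censoring actually binds for low groups

    def test_linked_first_week_matches_covariate(self):
        cfg = sd.published_model_config(n_subjects=200, seed=6)
        cohort = sd.generate_cohort(cfg)
        wk1 = cohort.weekly_truth[
            (cohort.weekly_truth["week"] == 1) & cohort.weekly_truth["is_valid"]
        ]
        merged = wk1.merge(cohort.covariates, on="subject_id")
        np.testing.assert_allclose(
            merged["adherence_pct"], merged["first_week_mvpa"] / 300 * 100
        )


class TestDailyRender:
    def test_round_trip_within_one_point(self):
        cfg = sd.acceptance_simulation_config(n_subjects=120, seed=8)
        cohort_weekly, _ = sd.simulate_weekly_panel(cfg)
        daily = sd.render_daily_records(cohort_weekly, cfg, np.random.default_rng(8))
        recomputed = adh.summarize_weeks(daily)
        merged = cohort_weekly.merge(
            recomputed, on=["subject_id", "week"], suffixes=("_truth", "_rec")
        )
        valid = merged[merged["is_valid_truth"]]
        assert (valid["is_valid_rec"]).all()
        err = (valid["adherence_pct_truth"] - valid["adherence_pct_rec"]).abs()
        assert err.max() < 1.0

    def test_invalid_weeks_rendered_invalid(self):
        cfg = sd.acceptance_simulation_config(n_subjects=80, seed=12)
        weekly, _ = sd.simulate_weekly_panel(cfg)
        daily = sd.render_daily_records(weekly, cfg, np.random.default_rng(12))
        recomputed = adh.summarize_weeks(daily)
        merged = weekly.merge(
            recomputed, on=["subject_id", "week"], suffixes=("_truth", "_rec")
        )
        invalid = merged[~merged["is_valid_truth"]]
        assert not invalid["is_valid_rec"].any()

    def test_zero_adherence_zero_minutes(self):
        cfg = dataclasses.replace(
            sd.acceptance_simulation_config(n_subjects=30, seed=0),
            trajectory_coefficients=((-500.0,),) * 4, missing_week_rate=0.0,
        )
        weekly, _ = sd.simulate_weekly_panel(cfg)
        daily = sd.render_daily_records(weekly, cfg, np.random.default_rng(1))
        assert (daily["fairly_active_min"] + daily["very_active_min"] == 0).all()


class TestWeights:
    def test_noiseless_group_change(self):
        cfg = dataclasses.replace(
            sd.acceptance_simulation_config(n_subjects=40, seed=0),
            weight_outcome_sd=1e-12,
        )
        rng = np.random.default_rng(0)
        cov = sd.draw_covariates(cfg, rng)
        group = pd.Series(np.full(40, 4))
        w = sd.generate_weights(group, cov, cfg, rng)
        pct = w.loc[w["visit"] == "12mo", "true_pct_change_12mo"]
        np.testing.assert_allclose(pct, -6.16, atol=1e-9)

    def test_group_mean_change_recovers_table(self):
        cfg = sd.acceptance_simulation_config(n_subjects=20_000, seed=13)
        rng = np.random.default_rng(13)
        cov = sd.draw_covariates(cfg, rng)
        group, _ = sd.assign_groups(cov, cfg, rng)
        w = sd.generate_weights(group, cov, cfg, rng)
        m12 = w[w["visit"] == "12mo"].reset_index(drop=True)
        g1 = m12.loc[group.to_numpy() == 1, "true_pct_change_12mo"]
        se = cfg.weight_outcome_sd / np.sqrt(len(g1))
        assert abs(g1.mean() - (-0.33)) < 3 * se

    def test_missingness_rate_near_calibration(self):
        cfg = sd.published_model_config(n_subjects=50_000, seed=14)
        rng = np.random.default_rng(cfg.seed)
        cov = sd.draw_covariates(cfg, rng)
        group, _ = sd.assign_groups(cov, cfg, rng)
        dropout = sd.draw_dropout(cov, cfg, rng)
        w = sd.generate_weights(group, cov, cfg, rng, dropout)
        m12 = w[w["visit"] == "12mo"]
        miss = (m12["source"] == "missing").mean()
        assert miss == pytest.approx(0.21, abs=0.01)

    def test_dropout_targets_young_heavy_inactive(self):
        cfg = sd.published_model_config(n_subjects=50_000, seed=15)
        rng = np.random.default_rng(cfg.seed)
        cov = sd.draw_covariates(cfg, rng)
        dropped = sd.draw_dropout(cov, cfg, rng).notna().to_numpy()
        assert cov.loc[dropped, "age"].mean() < cov.loc[~dropped, "age"].mean()
        assert cov.loc[dropped, "bmi"].mean() > cov.loc[~dropped, "bmi"].mean()
        assert (
            cov.loc[dropped, "first_week_mvpa"].mean()
            < cov.loc[~dropped, "first_week_mvpa"].mean()
        )

    def test_zero_dropout_coefficients_independent(self):
        cfg = dataclasses.replace(
            sd.published_model_config(n_subjects=30_000, seed=16),
            dropout_model=(-1.3925, 0.0, 0.0, 0.0),
        )
        rng = np.random.default_rng(cfg.seed)
        cov = sd.draw_covariates(cfg, rng)
        dropped = sd.draw_dropout(cov, cfg, rng).notna().to_numpy()
        age = cov["age"]
        diff = abs(age[dropped].mean() - age[~dropped].mean())
        assert diff < 3 * age.std() * np.sqrt(1 / dropped.sum() + 1 / (~dropped).sum())


def test_determinism_byte_identical():
    cfg = sd.published_model_config(n_subjects=100, seed=77)
    a = sd.generate_cohort(cfg)
    b = sd.generate_cohort(cfg)
    for x, y in [
        (a.covariates, b.covariates), (a.daily, b.daily),
        (a.weekly_truth, b.weekly_truth), (a.weights, b.weights),
    ]:
        assert x.to_csv(index=False) == y.to_csv(index=False)


def test_expected_valid_weeks_near_trial_average():
    # the published panel averaged ~41.2 valid weeks per subject
    cfg = sd.published_model_config(n_subjects=8_000, seed=18)
    cohort = sd.generate_cohort(cfg)
    per_subject = cohort.weekly_truth.groupby("subject_id")["is_valid"].sum()
    assert per_subject.mean() == pytest.approx(41.2, abs=1.0)
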