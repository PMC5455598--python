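"""Adjusted effect models: logistic stage migration, Cox survival, series."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from elncut import (eln_effect_series, fit_stage_migration, fit_survival_model,
                    interaction_test, mean_positive_series,
                    positive_vs_examined_regression)

from conftest import toy_cohort


class TestStageMigration:
    def test_two_by_two_table_matches_cross_product_odds_ratio(self):
        # ELN 1: 30 positive / 70 negative; ELN 2: 50 positive / 50 negative
        eln = [1] * 100 + [2] * 100
        positive = [1] * 30 + [0] * 70 + [1] * 50 + [0] * 50
        cohort = toy_cohort(eln=eln, positive=positive)
        fit = fit_stage_migration(cohort, adjusters=())
        want = (50 / 50) / (30 / 70)  # cross-product ratio per one-unit ELN step
        assert fit.ratio("eln_count")["estimate"] == pytest.approx(want, rel=1e-6)

    def test_null_generator_confidence_interval_contains_one(self, null_cohort):
        # stage migration is still real under the null survival generator
        # (detection is mechanistic), so build an ELN-independent outcome
        rng = np.random.default_rng(0)
        cohort = null_cohort.copy()
        flip = rng.permutation(len(cohort))
        cohort["positive_count"] = cohort["positive_count"].to_numpy()[flip]
        cohort["eln_count"] = np.maximum(cohort["eln_count"].to_numpy(),
                                         cohort["positive_count"].to_numpy())
        cohort["n_stage"] = np.where(cohort["positive_count"] == 0, "N0", "N1")
        fit = fit_stage_migration(cohort, adjusters=())
        r = fit.ratio("eln_count")
        # permuted outcome: effect should be near the null
        assert r["ci_low"] < 1.02 and r["ci_high"] > 0.98

    def test_single_stage_category_is_an_error(self):
        cohort = toy_cohort(eln=[5] * 50, positive=[0] * 50)
        with pytest.raises(ValueError, match="both node-stage categories"):
            fit_stage_migration(cohort)

    def test_estimates_invariant_to_row_order(self, small_cohort):
        fit1 = fit_stage_migration(small_cohort)
        shuffled = small_cohort.sample(frac=1.0, random_state=1)
        fit2 = fit_stage_migration(shuffled)
        assert fit1.ratio("eln_count")["estimate"] == pytest.approx(
            fit2.ratio("eln_count")["estimate"], rel=1e-8)


class TestSurvivalModel:
    def test_two_group_exponential_matches_closed_form_rate_ratio(self):
        rng = np.random.default_rng(2)
        n = 4_000
        eln = np.repeat([1, 2], n // 2)
        lam = np.where(eln == 2, 0.2, 0.1)
        time = rng.exponential(1 / lam)
        cohort = toy_cohort(eln=eln, positive=np.zeros(n, dtype=int),
                            time=time, event=np.ones(n, dtype=int))
        fit = fit_survival_model(cohort, adjusters=())
        g1, g2 = time[eln == 1], time[eln == 2]
        rate_ratio = (len(g2) / g2.sum()) / (len(g1) / g1.sum())  # exponential MLEs
        assert fit.ratio("eln_count")["estimate"] == pytest.approx(rate_ratio, rel=0.02)

    def test_null_generator_confidence_interval_contains_one(self, null_cohort):
        fit = fit_survival_model(null_cohort, subset="node-negative")
        r = fit.ratio("eln_count")
        assert r["ci_low"] <= 1.0 <= r["ci_high"]

    def test_benefit_generator_is_protective(self, benefit_cohort):
        fit = fit_survival_model(benefit_cohort, subset="node-negative")
        r = fit.ratio("eln_count")
        assert r["ci_high"] < 1.0

    def test_positive_count_flag_adds_term(self, benefit_cohort):
        fit = fit_survival_model(benefit_cohort, subset="node-positive",
                                 include_positive_count=True)
        assert "positive_count" in fit.coefficients.index

    def test_n2_subset_supported(self, benefit_cohort):
        fit = fit_survival_model(benefit_cohort, subset="N2-only")
        assert 0 < fit.n_used < len(benefit_cohort)

    def test_no_events_is_an_error(self):
        cohort = toy_cohort(eln=[3, 4, 5, 6, 7] * 4, positive=[0] * 20,
                            event=np.zeros(20, dtype=int))
        with pytest.raises(ValueError, match="at least one event"):
            fit_survival_model(cohort, adjusters=())


class TestEffectSeries:
    def test_reference_level_is_exactly_zero(self, benefit_cohort):
        series = eln_effect_series(benefit_cohort, outcome="survival",
                                   subset="node-negative")
        ref = series.table.loc[series.table["x"] == series.reference_x]
        assert ref["estimate"].item() == 0.0
        assert ref["se"].item() == 0.0

    def test_every_retained_level_meets_sparsity_floor(self, benefit_cohort):
        series = eln_effect_series(benefit_cohort, outcome="stage-migration",
                                   sparsity_floor=30)
        assert (series.table["n_patients"] >= 30).all()
        # pooling map covers every raw level present
        raw_levels = set(benefit_cohort["eln_count"].unique())
        assert raw_levels <= set(series.pooling)

    def test_benefit_series_trends_downward(self, benefit_cohort):
        series = eln_effect_series(benefit_cohort, outcome="survival",
                                   subset="node-negative")
        rho, p = stats.spearmanr(series.table["x"], series.table["estimate"])
        assert rho < 0 and p < 0.05

    def test_too_few_levels_is_an_error(self):
        cohort = toy_cohort(eln=[1] * 50 + [2] * 50, positive=[0, 1] * 50)
        with pytest.raises(ValueError, match="at least 5"):
            eln_effect_series(cohort, outcome="stage-migration", sparsity_floor=10)


class TestInteraction:
    def test_single_histology_is_an_error(self, benefit_cohort):
        cohort = benefit_cohort.copy()
        cohort["histology"] = "adenocarcinoma"
        with pytest.raises(ValueError, match="at least 2"):
            interaction_test(cohort, outcome="stage-migration")

    def test_degenerate_group_failure_names_the_group(self, benefit_cohort):
        cohort = benefit_cohort.copy()
        dead = cohort["histology"] == "bronchoalveolar"
        cohort.loc[dead, "positive_count"] = 0
        cohort.loc[dead, "n_stage"] = "N0"
        with pytest.raises(ValueError, match="bronchoalveolar"):
            interaction_test(cohort, outcome="stage-migration")

    def test_null_interaction_p_value_is_unremarkable(self, null_cohort):
        # generator gives every histology the same detection mechanism
        p = interaction_test(null_cohort, outcome="stage-migration")
        assert 0.0 < p <= 1.0

    def test_grouped_partition_accepted(self, benefit_cohort):
        grouping = {"bronchoalveolar": "indolent", "large_cell": "indolent",
                    "adenocarcinoma": "rest", "squamous": "rest", "other": "rest"}
        p = interaction_test(benefit_cohort, grouping=grouping, outcome="survival")
        assert 0.0 < p <= 1.0


class TestMeanPositiveSeries:
    def test_all_negative_cohort_gives_zero_series(self):
        cohort = toy_cohort(eln=list(range(1, 21)) * 3, positive=[0] * 60)
        series = mean_positive_series(cohort)
        assert (series["mean_positive"] == 0).all()

    def test_hand_tabulated_toy_cohort(self):
        cohort = toy_cohort(eln=[2, 2, 2, 5, 5, 5, 5, 9, 9, 9],
                            positive=[0, 1, 2, 0, 0, 2, 2, 3, 3, 0])
        series = mean_positive_series(cohort)
        means = dict(zip(series["x"], series["mean_positive"]))
        assert means[2.0] == pytest.approx(1.0)
        assert means[5.0] == pytest.approx(1.0)
        assert means[9.0] == pytest.approx(2.0)

    def test_matches_independent_groupby_tabulation(self, small_cohort):
        series = mean_positive_series(small_cohort)
        direct = small_cohort.groupby("eln_count")["positive_count"].mean()
        for x, m in zip(series["x"], series["mean_positive"]):
            if float(x).is_integer() and int(x) in direct.index:
                assert m == pytest.approx(direct.loc[int(x)], abs=1e-12)


class TestPositiveVsExamined:
    def test_exactly_proportional_series_gives_r_squared_one(self):
        eln = np.repeat([5, 10, 15, 20, 25, 30], 4)
        positive = eln // 5
        cohort = toy_cohort(eln=eln, positive=positive)
        slope, r2 = positive_vs_examined_regression(cohort, sparsity_floor=1)
        assert slope == pytest.approx(0.2, abs=1e-10)
        assert r2 == pytest.approx(1.0, abs=1e-10)

    def test_constant_series_reports_undefined_r_squared(self):
        eln = np.repeat([5, 10, 15, 20, 25], 4)
        cohort = toy_cohort(eln=eln, positive=np.ones_like(eln))
        slope, r2 = positive_vs_examined_regression(cohort, sparsity_floor=1)
        assert slope == pytest.approx(0.0, abs=1e-10)
        assert np.isnan(r2)

    def test_zero_slope_noise_gives_near_zero_r_squared(self):
        eln = np.repeat(np.arange(1, 21), 2)
        positive = np.tile([0, 1], 20)  # mean 0.5 at every level
        rng = np.random.default_rng(3)
        positive = rng.permutation(positive)
        cohort = toy_cohort(eln=eln, positive=positive)
        _, r2 = positive_vs_examined_regression(cohort, sparsity_floor=1)
        assert r2 < 0.3

    def test_matches_independent_least_squares(self, small_cohort):
        slope, r2 = positive_vs_examined_regression(small_cohort)
        series = mean_positive_series(small_cohort, sparsity_floor=20,
                                      terminal_percentile=99.0)
        x = series["x"].to_numpy()
        y = series["mean_positive"].to_numpy()
        # normal equations by hand
        xc = x - x.mean()
        beta = (xc * (y - y.mean())).sum() / (xc ** 2).sum()
        yhat = y.mean() + beta * xc
        r2_hand = 1 - ((y - yhat) ** 2).sum() / ((y - y.mean()) ** 2).sum()
        assert slope == pytest.approx(beta, abs=1e-10)
        assert r2 == pytest.approx(r2_hand, abs=1e-10)

    def test_too_few_levels_is_an_error(self):
        cohort = toy_cohort(eln=[5, 5, 10, 10], positive=[0, 1, 0, 1])
        with pytest.raises(ValueError, match=">= 5 distinct"):
            positive_vs_examined_regression(cohort, sparsity_floor=1)


class TestAdjusterStability:
    def test_independent_random_covariate_barely_moves_the_estimate(self, benefit_cohort):
        fit = fit_survival_model(benefit_cohort, subset="node-negative")
        base = fit.coefficients.loc["eln_count"]
        cohort = benefit_cohort.copy()
        rng = np.random.default_rng(4)
        # an ELN-independent relabeling of tumor_location acts as a noise covariate
        cohort["tumor_location"] = rng.permutation(cohort["tumor_location"].to_numpy())
        fit2 = fit_survival_model(cohort, subset="node-negative",
                                  adjusters=("sex", "age", "histology", "t_stage",
                                             "operation_type", "tumor_location"))
        moved = abs(fit2.coefficients.loc["eln_count", "estimate"] - base["estimate"])
        assert moved < 0.5 * base["se"]
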