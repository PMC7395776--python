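"""Association statistics: closed-form oracles and calibration checks."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import prs_transfer as pt
from prs_transfer.association import (
    AssociationError,
    EstimateCI,
    PercentileBinScheme,
    attenuation_percent,
    fixed_effect_meta,
    fh_attenuation,
    fit_cox_per_sd,
    fit_logistic_per_sd,
    interaction_test,
    percentile_bin_or,
    rescale_or,
    study_adjusted_auc,
)


def two_by_two_cohort(case_exposed, case_not, control_exposed, control_not):
    status = [1] * (case_exposed + case_not) + [0] * (control_exposed + control_not)
    x = ([1.0] * case_exposed + [0.0] * case_not
         + [1.0] * control_exposed + [0.0] * control_not)
    return pd.DataFrame({"status": status, "x": x})


class TestLogisticPerSd:
    def test_matches_two_by_two_closed_form(self):
        cohort = two_by_two_cohort(30, 70, 10, 90)
        est = fit_logistic_per_sd(cohort, prs_col="x", covariates=(),
                                  stratum_col=None)
        assert est.point == pytest.approx((30 * 90) / (70 * 10), rel=1e-4)

    def test_null_prs_recovers_unit_or(self):
        rng = np.random.default_rng(0)
        n = 50_000
        cohort = pd.DataFrame({
            "status": rng.integers(0, 2, n),
            "prs_std": rng.normal(size=n),
        })
        est = fit_logistic_per_sd(cohort, covariates=(), stratum_col=None)
        assert 0.97 < est.point < 1.03

    def test_recovers_generating_effect(self, tiny_study, tiny_config):
        cohort, _, _ = tiny_study
        est = fit_logistic_per_sd(cohort)
        assert est.lcl < math.exp(tiny_config.per_sd_log_or) < est.ucl

    def test_single_class_rejected(self):
        cohort = pd.DataFrame({"status": [1, 1, 1], "prs_std": [0.1, 0.2, 0.3]})
        with pytest.raises(AssociationError):
            fit_logistic_per_sd(cohort, covariates=(), stratum_col=None)

    def test_wald_interval_ordered(self, tiny_study):
        cohort, _, _ = tiny_study
        est = fit_logistic_per_sd(cohort)
        assert est.lcl <= est.point <= est.ucl


class TestPercentileBins:
    def test_reference_bin_is_exactly_one(self, tiny_study):
        cohort, _, _ = tiny_study
        out = percentile_bin_or(cohort)
        ref = PercentileBinScheme().reference_index
        assert out[ref].point == 1.0 and out[ref].lcl == 1.0

    def test_two_bin_toy_matches_closed_form(self):
        """30/10 in the top bin vs 50/50 in the reference: OR = 3."""
        cohort = pd.DataFrame({
            "status": [1] * 80 + [0] * 60,
            "prs_std": [1.0] * 30 + [0.0] * 50 + [1.0] * 10 + [0.0] * 50,
        })
        scheme = PercentileBinScheme(boundaries=(0.0, 50 / 60, 1.0),
                                     reference_index=0)
        out = percentile_bin_or(cohort, scheme, covariates=(),
                                stratum_col=None)
        assert out[1].point == pytest.approx(3.0, rel=1e-4)

    def test_null_generator_bins_near_one(self):
        cfg = pt.SimulationConfig(n_snps=25, n_low_info=0, per_sd_log_or=0.0,
                                  n_cases=6000, n_controls=6000, seed=30)
        panel = pt.gen_weight_panel(cfg)
        cohort, _, _ = pt.gen_case_control_cohort(panel, cfg)
        cohort["prs_std"] = cohort["prs_raw"] / cfg.control_sd_pop1
        out = percentile_bin_or(cohort, covariates=(), stratum_col=None)
        for est in out:
            assert est.lcl < 1.0 < est.ucl or abs(math.log(est.point)) < 0.35

    def test_empty_bin_rejected(self):
        cohort = pd.DataFrame({"status": [1, 0] * 10,
                               "prs_std": [0.5] * 20})
        with pytest.raises(AssociationError):
            percentile_bin_or(cohort, covariates=(), stratum_col=None)

    def test_boundary_value_goes_to_upper_bin(self):
        scheme = PercentileBinScheme(boundaries=(0.0, 0.5, 1.0),
                                     reference_index=0)
        controls = np.arange(101, dtype=float)  # median 50
        bins = scheme.assign(np.array([49.9, 50.0, 50.1]), controls)
        assert list(bins) == [0, 1, 1]


class TestCox:
    def test_exponential_rate_ratio_oracle(self):
        """Two-group exponential hazards with ratio 2, no censoring."""
        rng = np.random.default_rng(5)
        n = 3000
        group = np.repeat([0.0, 1.0], n // 2)
        rate = np.where(group == 1, 0.2, 0.1)
        t = rng.exponential(1 / rate)
        cohort = pd.DataFrame({
            "entry_age": np.zeros(n), "exit_age": t,
            "event": np.ones(n, int), "prs_std": group,
        })
        est = fit_cox_per_sd(cohort, covariates=())
        assert abs(est.beta - math.log(2)) < 3.5 * est.se

    def test_no_events_rejected(self):
        cohort = pd.DataFrame({"entry_age": [50.0], "exit_age": [60.0],
                               "event": [0], "prs_std": [0.0]})
        with pytest.raises(AssociationError):
            fit_cox_per_sd(cohort, covariates=())

    def test_recovers_generating_hazard_ratio_across_seeds(self):
        """Ground-truth HR lies inside the fitted CI in most replicates."""
        hits = 0
        n_seeds = 8
        for seed in range(n_seeds):
            cfg = pt.SimulationConfig(n_snps=30, n_low_info=0, seed=100 + seed,
                                      n_prospective=10_255,
                                      baseline_hazard=0.0021)
            panel = pt.gen_weight_panel(cfg)
            prosp, _ = pt.gen_prospective_cohort(panel, cfg)
            prosp["prs_std"] = prosp["prs_raw"] / cfg.control_sd_pop1
            est = fit_cox_per_sd(prosp)
            if est.lcl < math.exp(cfg.per_sd_log_or) < est.ucl:
                hits += 1
        assert hits >= n_seeds - 1


class TestStudyAdjustedAuc:
    def test_perfect_within_stratum_separation(self):
        cohort = pd.DataFrame({
            "status": [1, 1, 0, 0, 1, 0],
            "prs_std": [5.0, 6.0, 1.0, 2.0, -1.0, -3.0],
            "stratum": ["a", "a", "a", "a", "b", "b"],
        })
        assert study_adjusted_auc(cohort) == 1.0

    def test_constant_score_is_half(self):
        cohort = pd.DataFrame({"status": [1, 0, 1, 0],
                               "prs_std": [1.0] * 4, "stratum": ["s"] * 4})
        assert study_adjusted_auc(cohort) == 0.5

    def test_matches_exhaustive_pair_enumeration(self):
        rng = np.random.default_rng(2)
        cohort = pd.DataFrame({
            "status": [1, 1, 0, 0] * 2,
            "prs_std": rng.normal(size=8),
            "stratum": ["a"] * 4 + ["b"] * 4,
        })
        num = den = 0.0
        for _, g in cohort.groupby("stratum"):
            for _, case in g[g.status == 1].iterrows():
                for _, ctrl in g[g.status == 0].iterrows():
                    den += 1
                    if case.prs_std > ctrl.prs_std:
                        num += 1
                    elif case.prs_std == ctrl.prs_std:
                        num += 0.5
        assert study_adjusted_auc(cohort) == pytest.approx(num / den)

    def test_invariant_to_within_stratum_monotone_transform(self, tiny_study):
        cohort, _, _ = tiny_study
        a = study_adjusted_auc(cohort)
        t = cohort.copy()
        t["prs_std"] = np.exp(t["prs_std"] * 3.0)
        assert study_adjusted_auc(t) == pytest.approx(a)

    def test_no_valid_pairs_rejected(self):
        cohort = pd.DataFrame({"status": [1, 1], "prs_std": [0.0, 1.0],
                               "stratum": ["a", "a"]})
        with pytest.raises(AssociationError):
            study_adjusted_auc(cohort)


def _est(beta, se):
    return EstimateCI(point=math.exp(beta), lcl=math.exp(beta - 1.959964 * se),
                      ucl=math.exp(beta + 1.959964 * se), beta=beta, se=se)


class TestMeta:
    def test_single_study_passthrough(self):
        est = _est(math.log(2), 0.1)
        meta = fixed_effect_meta([est])
        assert meta.pooled.point == pytest.approx(2.0)
        assert meta.Q == 0.0 and meta.I2 == 0.0

    def test_identical_studies_have_no_heterogeneity(self):
        meta = fixed_effect_meta([_est(math.log(2), 0.1)] * 2)
        assert meta.pooled.point == pytest.approx(2.0)
        assert meta.Q == pytest.approx(0.0, abs=1e-12)

    def test_hand_arithmetic_example(self):
        """b = (0.2, 0.4), SE = 0.1 each: pooled 0.3, Q = 2, I2 = 50%."""
        meta = fixed_effect_meta([_est(0.2, 0.1), _est(0.4, 0.1)])
        assert meta.pooled.beta == pytest.approx(0.3)
        assert meta.Q == pytest.approx(2.0)
        assert meta.I2 == pytest.approx(50.0)
        assert meta.p_het == pytest.approx(stats.chi2.sf(2.0, 1))

    def test_se_recovered_from_ci_when_missing(self):
        est = EstimateCI(point=2.0, lcl=1.5, ucl=2.667)
        assert est.log_se == pytest.approx(
            (math.log(2.667) - math.log(1.5)) / (2 * 1.959964))

    def test_pooled_within_convex_hull(self, tiny_study):
        cohort, _, _ = tiny_study
        per_study = [fit_logistic_per_sd(g, stratum_col=None)
                     for _, g in cohort.groupby("stratum")]
        meta = fixed_effect_meta(per_study)
        betas = [e.beta for e in per_study]
        assert min(betas) <= meta.pooled.beta <= max(betas)

    def test_zero_width_ci_rejected(self):
        with pytest.raises(AssociationError):
            fixed_effect_meta([EstimateCI(point=2.0, lcl=2.0, ucl=2.0)])


class TestInteraction:
    def test_collinear_modifier_rejected(self, tiny_study):
        cohort, _, _ = tiny_study
        cohort = cohort.assign(mod=cohort["prs_std"])
        with pytest.raises(AssociationError):
            interaction_test(cohort, "mod", covariates=(), stratum_col=None)

    def test_constant_modifier_rejected(self, tiny_study):
        cohort, _, _ = tiny_study
        cohort = cohort.assign(mod=1.0)
        with pytest.raises(AssociationError, match="constant"):
            interaction_test(cohort, "mod", covariates=(), stratum_col=None)

    def test_type_one_error_calibrated_under_null(self):
        """With no interaction, rejection at alpha = 0.05 stays near 5%."""
        rng = np.random.default_rng(42)
        n = 1200
        rejections = 0
        n_reps = 250
        pvals = []
        for _ in range(n_reps):
            prs = rng.normal(size=n)
            mod = rng.normal(size=n)
            p = 1 / (1 + np.exp(-(-0.5 + 0.4 * prs)))
            cohort = pd.DataFrame({
                "status": (rng.random(n) < p).astype(int),
                "prs_std": prs, "mod": mod,
            })
            est = interaction_test(cohort, "mod", covariates=(),
                                   stratum_col=None)
            pvals.append(est.p)
            rejections += est.p < 0.05
        assert 0.02 <= rejections / n_reps <= 0.09
        assert stats.kstest(pvals, "uniform").pvalue > 1e-3

    def test_power_against_injected_interaction(self):
        """A log-OR 0.2 product term at n = 30,000 is reliably detected."""
        rng = np.random.default_rng(7)
        n = 30_000
        hits = 0
        for _ in range(5):
            prs = rng.normal(size=n)
            mod = rng.normal(size=n)
            p = 1 / (1 + np.exp(-(-0.5 + 0.4 * prs + 0.2 * prs * mod)))
            cohort = pd.DataFrame({
                "status": (rng.random(n) < p).astype(int),
                "prs_std": prs, "mod": mod,
            })
            est = interaction_test(cohort, "mod", covariates=(),
                                   stratum_col=None)
            hits += est.p < 0.05
        assert hits >= 4


class TestFamilyHistoryAttenuation:
    @pytest.mark.parametrize("or_u, or_a, expected", [
        (1.35, 1.31, 10.0),
        (1.36, 1.33, 7.3),
        (1.21, 1.18, 13.2),
    ])
    def test_published_attenuation_arithmetic(self, or_u, or_a, expected):
        assert attenuation_percent(or_u, or_a) == pytest.approx(expected,
                                                                abs=0.05)

    def test_equal_ors_give_zero(self):
        assert attenuation_percent(1.4, 1.4) == 0.0

    def test_unadjusted_or_below_one_flagged(self):
        with pytest.raises(AssociationError):
            attenuation_percent(0.9, 0.8)

    def test_prs_adjustment_attenuates_fh_effect(self, strong_fh_cohort):
        cohort, _, _ = strong_fh_cohort
        res = fh_attenuation(cohort, covariates=("pc1", "pc2"),
                             stratum_col="stratum")
        assert res.defined
        assert res.or_unadjusted.point > 1.0
        assert res.attenuation_pct > 0.0
        assert res.or_adjusted.beta < res.or_unadjusted.beta

    def test_missing_family_history_rows_excluded(self, strong_fh_cohort):
        cohort, _, _ = strong_fh_cohort
        holed = cohort.copy()
        holed.loc[holed.index[:500], "family_history"] = np.nan
        res = fh_attenuation(holed, covariates=(), stratum_col=None)
        assert res.or_unadjusted.point > 0


class TestRescaleOr:
    def test_published_sd_recalibration(self):
        """OR 1.52 per European SD 0.597 is 1.48 per Asian SD 0.556."""
        assert round(rescale_or(1.52, 0.597, 0.556), 2) == 1.48

    def test_same_sd_is_identity(self):
        assert rescale_or(1.7, 0.5, 0.5) == pytest.approx(1.7)

    def test_unit_or_fixed_point(self):
        assert rescale_or(1.0, 0.9, 0.3) == pytest.approx(1.0)

    def test_invalid_inputs(self):
        with pytest.raises(AssociationError):
            rescale_or(-1.0, 0.5, 0.5)
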