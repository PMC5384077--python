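"""ANOVA and random-intercept mixed models on simulated cohorts."""

import warnings

import numpy as np
import pandas as pd
import pytest
import statsmodels.formula.api as smf

from conjflow.stats import (fit_mixed_model, group_anova,
                            velocity_diameter_slopes)
from conjflow.synthetic import CohortSpec, simulate_cohort

warnings.filterwarnings("ignore", module="statsmodels")


def _cohort(groups, means, sigma_b=0.05, sigma_e=0.15, n_vessels=8,
            seed=0, **kw):
    spec = CohortSpec(group_sizes=groups,
                      descriptor_means={"V": means},
                      sigma_b=sigma_b, sigma_e=sigma_e,
                      vessels_per_subject_mean=n_vessels,
                      vessels_per_subject_sd=0.0, seed=seed, **kw)
    return simulate_cohort(spec)


class TestGroupAnova:
    def test_single_group_rejected(self):
        _, vessels = _cohort({"C": 10}, {"C": 0.6})
        with pytest.raises(ValueError, match="2 groups"):
            group_anova(vessels, "V")

    def test_small_group_named_in_error(self):
        _, vessels = _cohort({"C": 10, "PDR": 1}, {"C": 0.6, "PDR": 0.6})
        with pytest.raises(ValueError, match="PDR"):
            group_anova(vessels, "V")

    def test_detects_large_effect(self):
        _, vessels = _cohort({"C": 34, "NDR": 47},
                             {"C": 0.70, "NDR": 0.54}, seed=1)
        p, summary = group_anova(vessels, "V")
        assert p < 0.01
        assert summary.loc["C", "mean"] == pytest.approx(0.70, abs=0.05)
        assert set(summary.columns) >= {"n_subjects", "mean", "sd"}

    def test_type_one_error_calibrated(self):
        # identical distributions: P < 0.05 in about 5% of replicates
        hits = 0
        n = 400
        for seed in range(n):
            _, vessels = _cohort({"C": 50, "NDR": 50}, {"C": 0.6, "NDR": 0.6},
                                 seed=seed)
            p, _ = group_anova(vessels, "V")
            hits += p < 0.05
        assert abs(hits / n - 0.05) <= 0.03

    def test_power_at_printed_arteriolar_effect(self):
        # means 0.70 vs 0.54 at n = 34/47 subjects: comfortably detectable
        hits = 0
        n = 100
        for seed in range(n):
            _, vessels = _cohort({"C": 34, "NDR": 47},
                                 {"C": 0.70, "NDR": 0.54},
                                 sigma_b=0.10, sigma_e=0.21, seed=seed)
            p, _ = group_anova(vessels, "V")
            hits += p < 0.05
        assert hits / n > 0.8


class TestMixedModel:
    def test_recovers_injected_group_effect(self):
        betas = []
        for seed in range(25):
            _, vessels = _cohort({"C": 40, "NDR": 40},
                                 {"C": 0.70, "NDR": 0.54},
                                 n_vessels=12, seed=seed)
            res = fit_mixed_model(vessels, "V")
            betas.append(res.group_effects.loc["NDR", "beta"])
        assert np.mean(betas) == pytest.approx(-0.16, abs=0.02)

    def test_reference_group_absent_from_effects(self):
        _, vessels = _cohort({"C": 10, "NDR": 10, "PDR": 10},
                             {"C": 0.6, "NDR": 0.6, "PDR": 0.6})
        res = fit_mixed_model(vessels, "V")
        assert "C" not in res.group_effects.index
        assert set(res.group_effects.index) == {"NDR", "PDR"}
        lo, hi = res.group_effects["ci_low"], res.group_effects["ci_high"]
        assert (lo <= res.group_effects["beta"]).all()
        assert (res.group_effects["beta"] <= hi).all()

    def test_zero_between_subject_variance_matches_ols(self):
        # with no subject effect the REML fit sits on the boundary and the
        # fixed effects coincide with ordinary least squares
        _, vessels = _cohort({"C": 15, "NDR": 15}, {"C": 0.6, "NDR": 0.5},
                             sigma_b=0.0, n_vessels=6, seed=1)
        res = fit_mixed_model(vessels, "V")
        ols = smf.ols("V ~ C(group, Treatment('C'))", vessels).fit()
        assert res.random_intercept_var < 1e-8
        assert res.group_effects.loc["NDR", "beta"] == pytest.approx(
            ols.params.iloc[1], abs=1e-6)

    def test_one_vessel_per_subject_equals_ols(self):
        _, vessels = _cohort({"C": 25, "NDR": 25}, {"C": 0.6, "NDR": 0.5},
                             n_vessels=1, seed=3, min_vessels=1)
        res = fit_mixed_model(vessels, "V")
        ols = smf.ols("V ~ C(group, Treatment('C'))", vessels).fit()
        assert res.group_effects.loc["NDR", "beta"] == pytest.approx(
            ols.params.iloc[1], abs=1e-6)

    def test_fixed_effects_invariant_to_row_order(self):
        _, vessels = _cohort({"C": 12, "NPDR": 12}, {"C": 0.6, "NPDR": 0.55},
                             seed=4)
        res1 = fit_mixed_model(vessels, "V")
        shuffled = vessels.sample(frac=1, random_state=9).reset_index(drop=True)
        res2 = fit_mixed_model(shuffled, "V")
        assert res1.group_effects["beta"].values == pytest.approx(
            res2.group_effects["beta"].values, abs=1e-8)

    def test_adjusted_model_includes_covariates(self):
        subjects, vessels = simulate_cohort(CohortSpec(
            group_sizes={"C": 15, "NDR": 15}, seed=6))
        merged = vessels.merge(subjects.drop(columns=["group"]),
                               on="subject_id")
        res = fit_mixed_model(merged, "V", adjusted=True)
        assert res.model_tag == "adjusted"
        names = set(res.covariate_effects.index)
        assert {"age", "map", "hr", "hct", "hba1c"} <= names
        assert any(n.startswith("C(race)") for n in names)
        assert any(n.startswith("C(sex)") for n in names)

    def test_missing_covariates_dropped_and_reported(self):
        subjects, vessels = simulate_cohort(CohortSpec(
            group_sizes={"C": 15, "NDR": 15}, seed=6))
        merged = vessels.merge(subjects.drop(columns=["group"]),
                               on="subject_id")
        merged.loc[merged.index[:7], "hba1c"] = np.nan
        res = fit_mixed_model(merged, "V", adjusted=True)
        assert any("dropped 7 rows" in w for w in res.warnings)


class TestVelocityDiameterSlopes:
    def test_common_slope_recovered_in_all_groups(self):
        spec = CohortSpec(
            group_sizes={"C": 30, "NDR": 30, "NPDR": 30, "PDR": 30},
            vd_slope_s=18.0, seed=5)
        _, vessels = simulate_cohort(spec)
        results = velocity_diameter_slopes(vessels)
        for r in results:
            assert r.ci_low <= 18.0 <= r.ci_high
            assert r.model_tag == "unadjusted"
        assert results[0].group == "C" and results[0].p_vs_control is None
        assert all(r.p_vs_control > 0.05 for r in results[1:])

    def test_injected_slope_difference_detected(self):
        # +4 1/s slope difference vs control at the study's group sizes
        hits = 0
        n = 40
        for seed in range(n):
            spec = CohortSpec(
                group_sizes={"C": 34, "NDR": 47},
                vd_slope_s={"C": 18.0, "NDR": 22.0}, seed=seed)
            _, vessels = simulate_cohort(spec)
            results = velocity_diameter_slopes(vessels)
            ndr = [r for r in results if r.group == "NDR"][0]
            hits += ndr.p_vs_control <= 0.05
        assert hits / n > 0.7

    def test_constant_diameter_rejected(self):
        _, vessels = _cohort({"C": 10, "NDR": 10}, {"C": 0.6, "NDR": 0.6})
        vessels["D"] = 20.0
        with pytest.raises(ValueError, match="no diameter variation"):
            velocity_diameter_slopes(vessels)
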