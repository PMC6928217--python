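"""Accuracy ratios, mixed-model estimators and residual diagnostics."""

import numpy as np
import pandas as pd
import pytest

from reefstress import (
    ValidationError,
    accuracy_ratio,
    accuracy_table,
    compare_model_families,
    diagnostics,
    fit_accuracy_model,
    fit_bias_depth_lmm,
    fit_severity_depth_glmm,
    simulate_bias_table,
    simulate_event_table,
    simulate_log2_ratios,
)
from reefstress.events import HeatEvent


def _event(sst, adj):
    return HeatEvent(
        site=None,
        start_date=pd.Timestamp("2015-01-01"),
        end_date=pd.Timestamp("2015-02-01"),
        max_dhw_sst=sst,
        max_dhw_str_unadj=0.0,
        max_dhw_str_adj=adj,
    )


class TestAccuracyRatio:
    @pytest.mark.parametrize(
        "sst,adj,pct,log2,case,included",
        [
            (4.0, 8.0, 50.0, -1.0, "none", True),
            (5.0, 0.0, 800.0, 3.0, "str_zero", False),
            (0.0, 4.0, 12.5, -3.0, "sst_zero", False),
            (0.0, 0.0, 100.0, 0.0, "both_zero", True),
            (6.0, 6.0, 100.0, 0.0, "none", True),
        ],
    )
    def test_zero_case_constants_and_inclusion(self, sst, adj, pct, log2, case, included):
        r = accuracy_ratio(_event(sst, adj))
        assert r.percent == pytest.approx(pct)
        assert r.log2_ratio == pytest.approx(log2)
        assert r.zero_case == case
        assert r.included_in_stats is included

    def test_swap_negates_log2(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a, b = rng.uniform(0.5, 12, 2)
            fwd = accuracy_ratio(_event(a, b)).log2_ratio
            rev = accuracy_ratio(_event(b, a)).log2_ratio
            assert fwd == pytest.approx(-rev)

    def test_table_carries_flags(self):
        df = accuracy_table([_event(4, 8), _event(5, 0)])
        assert list(df["included_in_stats"]) == [True, False]
        assert df["ratio_pct"].tolist() == pytest.approx([50.0, 800.0])


class TestBiasDepthLMM:
    def test_recovers_injected_slope(self):
        rng = np.random.default_rng(10)
        df = simulate_bias_table(rng, slope_c_per_10m=-0.15)
        fit = fit_bias_depth_lmm(df, "summer")
        c = fit.coef("depth_per_10m")
        assert abs(c["estimate"] - (-0.15)) <= 2 * c["se"]
        assert fit.converged

    def test_matches_ols_when_no_random_variation(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(11)
        df = simulate_bias_table(rng, region_sd_c=0.0, island_sd_c=0.0, resid_sd_c=0.05)
        fit = fit_bias_depth_lmm(df, "summer")
        X = sm.add_constant(df["depth_m"].to_numpy())
        ols = sm.OLS(df["mean_bias_c"].to_numpy(), X).fit()
        assert fit.coef("depth_m")["estimate"] == pytest.approx(
            ols.params[1], abs=5e-3
        )

    def test_null_slope_usually_not_significant(self):
        hits = 0
        for rep in range(25):
            rng = np.random.default_rng(600 + rep)
            df = simulate_bias_table(rng, slope_c_per_10m=0.0)
            z = fit_bias_depth_lmm(df, "summer").coef("depth_per_10m")["z"]
            hits += abs(z) >= 1.96
        assert hits <= 4  # ~5% expected at alpha=0.05


class TestSeverityGLMM:
    def test_reduces_to_fixed_effects_nb_oracle(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(12)
        df = simulate_event_table(
            rng, n_events=600, zero_inflation=0.0,
            region_sd=0.0, island_sd=0.0, site_sd=0.0, beta_depth_per_10m=0.15,
        )
        fit = fit_severity_depth_glmm(df, family="nb", random_effects=(), seed=0)
        X = sm.add_constant(df["depth_m"].to_numpy())
        oracle = sm.NegativeBinomial(
            np.round(df["max_dhw_str_adj"].to_numpy()), X
        ).fit(disp=0)
        got = fit.fixed_effects.set_index("term")
        assert got.loc["Intercept", "estimate"] == pytest.approx(
            oracle.params[0], rel=1e-3, abs=1e-5
        )
        assert got.loc["depth_m", "estimate"] == pytest.approx(
            oracle.params[1], rel=1e-3, abs=1e-5
        )
        assert fit.dispersion_k == pytest.approx(1.0 / oracle.params[2], rel=1e-3)

    def test_zinb_recovers_slope_with_random_effects(self):
        rng = np.random.default_rng(13)
        df = simulate_event_table(
            rng, n_events=500, beta_depth_per_10m=0.3, zero_inflation=0.25,
            dispersion_k=2.0, region_sd=0.15, island_sd=0.15, site_sd=0.15,
        )
        fit = fit_severity_depth_glmm(df, family="zinb", seed=1, n_restarts=1)
        c = fit.coef("depth_per_10m")
        assert abs(c["estimate"] - 0.3) <= 2 * c["se"]
        assert 0.05 <= fit.zero_inflation_prob <= 0.5

    def test_all_zero_response_rejected(self):
        df = pd.DataFrame(
            {
                "site_id": ["a"] * 40, "island": ["i"] * 40, "region": ["r"] * 40,
                "depth_m": np.linspace(1, 38, 40),
                "max_dhw_sst": 0.0, "max_dhw_str_unadj": 0.0, "max_dhw_str_adj": 0.0,
            }
        )
        with pytest.raises(ValidationError):
            fit_severity_depth_glmm(df, seed=0)

    def test_severe_subset_filters_on_either_decisive_metric(self):
        rng = np.random.default_rng(14)
        df = simulate_event_table(rng, n_events=400)
        fit = fit_severity_depth_glmm(df, subset="severe_only", family="nb",
                                      random_effects=(), seed=0, n_restarts=1)
        expected = ((df["max_dhw_sst"] >= 4) | (df["max_dhw_str_adj"] >= 4)).sum()
        assert fit.n_obs == expected


class TestAccuracyModel:
    def test_identity_when_all_ratios_100pct(self):
        df = pd.DataFrame({"log2_ratio": np.zeros(40), "included_in_stats": True})
        fit = fit_accuracy_model(df)
        assert fit.extra["mean_ratio_pct"] == pytest.approx(100.0)

    def test_recovers_injected_mean_ratio(self):
        rng = np.random.default_rng(15)
        df = simulate_log2_ratios(rng, n=500, mean_log2=float(np.log2(0.607)), sd_log2=0.8)
        fit = fit_accuracy_model(df)
        half_width = 1.96 * 0.8 / np.sqrt(500)
        lo = 2.0 ** (np.log2(0.607) - half_width) * 100
        hi = 2.0 ** (np.log2(0.607) + half_width) * 100
        assert lo <= fit.extra["mean_ratio_pct"] <= hi

    def test_back_transform_is_exact_power_of_two(self):
        rng = np.random.default_rng(16)
        df = simulate_log2_ratios(rng, n=50)
        fit = fit_accuracy_model(df)
        est = fit.coef("Intercept")["estimate"]
        assert fit.extra["mean_ratio_pct"] == pytest.approx(2.0**est * 100.0, rel=1e-12)

    def test_too_few_rows_rejected(self):
        df = pd.DataFrame({"log2_ratio": np.zeros(5), "included_in_stats": True})
        with pytest.raises(ValidationError):
            fit_accuracy_model(df)


class TestDiagnostics:
    def test_calibrated_on_data_from_fitted_model(self):
        flagged = {"uniformity": 0, "overdispersion": 0, "zero_inflation": 0,
                   "heteroscedasticity": 0}
        reps = 20
        for rep in range(reps):
            rng = np.random.default_rng(700 + rep)
            df = simulate_event_table(
                rng, n_events=300, zero_inflation=0.3,
                region_sd=0.0, island_sd=0.0, site_sd=0.0,
            )
            fit = fit_severity_depth_glmm(
                df, family="zinb", random_effects=(), seed=rep, n_restarts=1
            )
            rep_d = diagnostics(fit, n_sim=150, seed=rep)
            for key in flagged:
                flagged[key] += rep_d[key]["flagged"]
        for key, count in flagged.items():
            assert count <= reps * 0.25, f"{key} over-flagged: {count}/{reps}"

    def test_poisson_on_nb_data_flags_overdispersion(self):
        rng = np.random.default_rng(42)
        df = simulate_event_table(
            rng, n_events=500, zero_inflation=0.0, dispersion_k=0.5,
            region_sd=0.0, island_sd=0.0, site_sd=0.0,
        )
        fit = fit_severity_depth_glmm(df, family="poisson", random_effects=(),
                                      seed=0, n_restarts=1)
        d = diagnostics(fit, n_sim=200, seed=1)
        assert d["overdispersion"]["flagged"]
        assert d["overdispersion"]["statistic"] > 1.5

    def test_gaussian_on_zinb_severities_flags_zero_inflation(self):
        rng = np.random.default_rng(43)
        df = simulate_event_table(rng, n_events=500, zero_inflation=0.3)
        fit = fit_severity_depth_glmm(df, family="gaussian", seed=0)
        d = diagnostics(fit, n_sim=200, seed=1)
        assert d["zero_inflation"]["flagged"]

    def test_family_comparison_prefers_count_models(self):
        rng = np.random.default_rng(44)
        df = simulate_event_table(rng, n_events=400, zero_inflation=0.3,
                                  region_sd=0.0, island_sd=0.0, site_sd=0.0)
        out = compare_model_families(
            df, families=("gaussian", "zinb"), seed=0, n_sim=150
        )
        assert out["gaussian"].diagnostics["zero_inflation"]["flagged"]
        assert not out["zinb"].diagnostics["zero_inflation"]["flagged"]
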