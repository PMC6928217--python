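"""Synthetic archive generator: determinism, bookkeeping and injected truth."""

import numpy as np
import pandas as pd
import pytest

from reefstress import (
    SimulationConfig,
    ValidationError,
    daily_bias,
    mmm,
    monthly_climatology,
    nighttime_daily_mean,
    pair_series,
    read_logger_csv,
    read_metadata_csv,
    read_sst_csv,
    seasonal_bias,
    simulate_archipelago,
    simulate_site,
)


QUIET = dict(
    site_bias_sd_c=0.0, island_bias_sd_c=0.0, region_bias_sd_c=0.0,
    enso_sd_c=0.0, daily_noise_sd_c=0.0, gap_prob=0.0,
    event_rate_per_year=0.0,
)


class TestSimulateSite:
    def test_degenerate_config_logger_equals_sst(self):
        cfg = SimulationConfig(
            years=2, seed=5, diurnal_amplitude_c=0.0,
            summer_bias_slope_c_per_10m=0.0, winter_bias_slope_c_per_10m=0.0,
            **QUIET,
        )
        site = simulate_site(cfg, 0)
        str_daily = nighttime_daily_mean(site.logger)
        paired = pair_series(str_daily, site.sst_daily)
        diff = (paired.str_daily.values - paired.sst_daily.values).abs()
        assert diff.max() < 2e-2  # logger sensor noise only

    def test_true_summer_bias_scales_with_depth(self):
        cfg = SimulationConfig(
            years=3, seed=6, depth_range_m=(20.0, 20.0),
            n_regions=1, islands_per_region=1, sites_per_island=1,
            site_bias_sd_c=0.0, island_bias_sd_c=0.0, region_bias_sd_c=0.0,
        )
        site = simulate_site(cfg, 0)
        # slope -0.15 °C/10 m at 20 m, summer weight ~1 in the warmest month
        assert site.truth["true_summer_bias_c"] == pytest.approx(-0.30, abs=0.02)
        assert abs(site.truth["true_winter_bias_c"]) < 0.08

    def test_pipeline_recovers_injected_bias_within_2se(self):
        cfg = SimulationConfig(
            years=3, seed=7, depth_range_m=(20.0, 20.0),
            n_regions=1, islands_per_region=1, sites_per_island=1,
            site_bias_sd_c=0.0, island_bias_sd_c=0.0, region_bias_sd_c=0.0,
        )
        site = simulate_site(cfg, 0)
        str_daily = nighttime_daily_mean(site.logger)
        paired = pair_series(str_daily, site.sst_daily)
        est = seasonal_bias(daily_bias(paired), "summer", cfg.warmest_month)
        truth = site.truth["true_summer_bias_c"]
        assert abs(est.mean_bias_c - truth) <= 2 * max(est.se_c, 5e-3)

    def test_determinism_same_seed(self):
        cfg = SimulationConfig(years=1, seed=9)
        a = simulate_site(cfg, 3)
        b = simulate_site(cfg, 3)
        pd.testing.assert_series_equal(a.logger.samples, b.logger.samples)
        pd.testing.assert_series_equal(a.sst_daily.values, b.sst_daily.values)
        assert a.truth == b.truth

    def test_sites_independent_of_order(self):
        cfg = SimulationConfig(years=1, seed=9)
        first = simulate_site(cfg, 2).logger.samples
        _ = simulate_site(cfg, 0)  # generating another site must not matter
        again = simulate_site(cfg, 2).logger.samples
        pd.testing.assert_series_equal(first, again)

    def test_invalid_month_rejected(self):
        with pytest.raises(ValidationError):
            SimulationConfig(warmest_month=13)


class TestSimulateArchipelago:
    def test_2x2x3_design_yields_12_sites(self, tmp_path):
        cfg = SimulationConfig(
            n_regions=2, islands_per_region=2, sites_per_island=3, years=1, seed=1
        )
        sites, truth = simulate_archipelago(cfg)
        assert len(sites) == 12
        assert len(truth) == 12
        depths = sorted(s.metadata.depth_m for s in sites)
        assert depths[0] == pytest.approx(1.0)
        assert depths[-1] == pytest.approx(38.0)
        assert truth["region"].nunique() == 2
        assert truth["island"].nunique() == 4

    def test_csv_round_trip_through_readers(self, tmp_path):
        cfg = SimulationConfig(
            n_regions=1, islands_per_region=1, sites_per_island=2, years=1, seed=2
        )
        sites, _ = simulate_archipelago(cfg, tmp_path)
        meta = read_metadata_csv(tmp_path / "metadata.csv")
        assert set(meta) == {s.metadata.site_id for s in sites}
        sid = sites[0].metadata.site_id
        logger = read_logger_csv(tmp_path / f"logger_{sid}.csv", meta[sid])
        assert len(logger) == len(sites[0].logger)
        sst = read_sst_csv(tmp_path / "sst.csv", meta[sid])
        assert np.allclose(
            sst.values.to_numpy(), sites[0].sst_daily.values.to_numpy(), atol=1e-9
        )

    def test_same_seed_writes_identical_files(self, tmp_path):
        cfg = SimulationConfig(
            n_regions=1, islands_per_region=1, sites_per_island=1, years=1, seed=3
        )
        simulate_archipelago(cfg, tmp_path / "a")
        simulate_archipelago(cfg, tmp_path / "b")
        for name in ("metadata.csv", "sst.csv", "logger_S000.csv", "truth.csv"):
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()

    def test_truth_table_slope_consistent_with_config(self):
        cfg = SimulationConfig(
            n_regions=2, islands_per_region=3, sites_per_island=6, years=2, seed=4,
            site_bias_sd_c=0.01, island_bias_sd_c=0.01, region_bias_sd_c=0.01,
        )
        _, truth = simulate_archipelago(cfg)
        # ordinary regression of true per-site summer bias on depth
        slope = np.polyfit(truth["depth_m"] / 10.0, truth["true_summer_bias_c"], 1)[0]
        assert slope == pytest.approx(cfg.summer_bias_slope_c_per_10m, abs=0.03)


class TestInjectedEvents:
    def test_isolated_pulses_detected_one_to_one(self):
        from reefstress import (
            adjust_threshold, detect_events, dhw_variants,
        )

        # pulses sit on successive Septembers, separated by far more than the
        # 84-day accumulation window; the threshold comes from a pulse-free
        # twin record, standing in for the long-term satellite climatology
        common = dict(
            years=3, seed=8, diurnal_amplitude_c=0.1,
            event_amplitude_c=2.5, event_duration_days=30,
            depth_range_m=(15.0, 15.0),
            n_regions=1, islands_per_region=1, sites_per_island=1,
            **QUIET,
        )
        quiet_twin = simulate_site(
            SimulationConfig(event_start_days=(), **common), 0
        )
        surface = mmm(monthly_climatology(quiet_twin.sst_daily))
        site = simulate_site(
            SimulationConfig(event_start_days=(240, 605, 970), **common), 0
        )
        str_daily = nighttime_daily_mean(site.logger)
        paired = pair_series(str_daily, site.sst_daily)
        summer = seasonal_bias(daily_bias(paired), "summer", surface.warmest_month)
        adjusted = adjust_threshold(surface, summer)
        variants = dhw_variants(site.metadata, site.sst_daily, str_daily, surface, adjusted)
        events = detect_events(variants)
        assert len(events) == 3
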