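"""Readers, nighttime reduction, continuity screening and pairing."""

import numpy as np
import pandas as pd
import pytest

from reefstress import (
    FormatError,
    LoggerSeries,
    NightRule,
    SiteMetadata,
    ValidationError,
    continuity_filter,
    nighttime_daily_mean,
    pair_series,
    read_logger_csv,
    stitch_deployments,
)

from conftest import make_daily, make_logger


class TestReadLoggerCsv:
    def test_well_formed_csv_reads_all_rows(self, tmp_path, site):
        p = tmp_path / "log.csv"
        p.write_text(
            "timestamp,temperature_c\n"
            "2014-01-01T00:00:00Z,27.0\n"
            "2014-01-01T00:30:00Z,27.1\n"
            "2014-01-01T01:00:00Z,27.2\n"
        )
        series = read_logger_csv(p, site)
        assert len(series) == 3
        assert series.n_dropped == 0
        assert series.samples.iloc[1] == 27.1

    def test_non_finite_rows_dropped_and_counted(self, tmp_path, site):
        p = tmp_path / "log.csv"
        p.write_text(
            "timestamp,temperature_c\n"
            "2014-01-01T00:00:00Z,27.0\n"
            "2014-01-01T00:30:00Z,NaN\n"
            "2014-01-01T01:00:00Z,27.2\n"
        )
        series = read_logger_csv(p, site)
        assert len(series) == 2
        assert series.n_dropped == 1

    def test_duplicate_timestamp_rejected(self, tmp_path, site):
        p = tmp_path / "log.csv"
        p.write_text(
            "timestamp,temperature_c\n"
            "2014-01-01T00:00:00Z,27.0\n"
            "2014-01-01T00:00:00Z,27.1\n"
        )
        with pytest.raises(ValidationError):
            read_logger_csv(p, site)

    def test_missing_column_is_format_error(self, tmp_path, site):
        p = tmp_path / "log.csv"
        p.write_text("timestamp,temp\n2014-01-01T00:00:00Z,27.0\n")
        with pytest.raises(FormatError):
            read_logger_csv(p, site)


class TestStitchDeployments:
    def test_non_overlapping_deployments_union(self, site):
        a = make_logger(site, [27.0] * 48, start="2014-01-01")
        b = make_logger(site, [27.5] * 48, start="2014-03-01")
        out = stitch_deployments([a, b])
        assert len(out) == 96
        assert out.samples.index.is_monotonic_increasing

    def test_overlapping_timestamp_averaged(self, site):
        idx = pd.DatetimeIndex(["2014-01-01T00:00Z"])
        a = LoggerSeries(site=site, samples=pd.Series([27.0], index=idx))
        b = LoggerSeries(site=site, samples=pd.Series([27.2], index=idx))
        out = stitch_deployments([a, b])
        assert out.samples.iloc[0] == pytest.approx(27.1)

    def test_order_insensitive(self, site):
        rng = np.random.default_rng(0)
        parts = [
            make_logger(site, rng.normal(27, 0.5, 24), start=s)
            for s in ("2014-01-01", "2014-02-01", "2014-03-01")
        ]
        fwd = stitch_deployments(parts)
        rev = stitch_deployments(parts[::-1])
        pd.testing.assert_series_equal(fwd.samples, rev.samples)

    def test_different_depths_rejected(self, site):
        other = SiteMetadata(
            site_id=site.site_id, island=site.island, region=site.region,
            latitude=site.latitude, longitude=site.longitude, depth_m=5.0,
        )
        a = make_logger(site, [27.0] * 4)
        b = make_logger(other, [27.0] * 4, start="2014-02-01")
        with pytest.raises(ValidationError):
            stitch_deployments([a, b])


class TestNighttimeDailyMean:
    def test_constant_series_gives_constant_nightly_means(self, equator_site):
        series = make_logger(equator_site, [27.0] * (48 * 10))
        daily = nighttime_daily_mean(series)
        assert len(daily) >= 9
        assert np.allclose(daily.values.to_numpy(), 27.0)

    def test_diurnal_cycle_night_mean_matches_window_integral(self, equator_site):
        # logger temp = 27 + cos peaking at local noon; at lon 0 local = UTC
        idx = pd.date_range("2014-03-01", periods=48 * 10, freq="30min", tz="UTC")
        hours = idx.hour.to_numpy(float) + idx.minute.to_numpy(float) / 60.0
        temps = 27.0 + 1.0 * np.cos(2 * np.pi * (hours - 12.0) / 24.0)
        series = LoggerSeries(site=equator_site, samples=pd.Series(temps, index=idx))
        daily = nighttime_daily_mean(series, NightRule(method="window", window="18:00-06:00"))
        # independent oracle: mean of the cosine over the 18:00-06:00 samples
        night_hours = np.r_[np.arange(18.0, 24.0, 0.5), np.arange(0.0, 6.0, 0.5)]
        expected = 27.0 + np.mean(np.cos(2 * np.pi * (night_hours - 12.0) / 24.0))
        interior = daily.values.iloc[1:-1]
        assert np.allclose(interior.to_numpy(), expected, atol=1e-9)
        assert (interior < 27.0).all()  # night is the cool half of the cycle

    def test_solar_night_is_cool_half_too(self, equator_site):
        idx = pd.date_range("2014-03-01", periods=48 * 10, freq="30min", tz="UTC")
        hours = idx.hour.to_numpy(float) + idx.minute.to_numpy(float) / 60.0
        temps = 27.0 + np.cos(2 * np.pi * (hours - 12.0) / 24.0)
        series = LoggerSeries(site=equator_site, samples=pd.Series(temps, index=idx))
        daily = nighttime_daily_mean(series)  # solar elevation rule
        assert (daily.values.iloc[1:-1] < 27.0).all()

    def test_daytime_only_samples_produce_no_dates(self, equator_site):
        stamps = []
        for d in range(5):
            day = pd.Timestamp("2014-03-01") + pd.Timedelta(days=d)
            stamps.extend(day + pd.timedelta_range("10h", "14h", freq="30min"))
        idx = pd.DatetimeIndex(stamps, tz="UTC")
        series = LoggerSeries(site=equator_site, samples=pd.Series(27.0, index=idx))
        daily = nighttime_daily_mean(series, NightRule(method="window", window="18:00-06:00"))
        assert len(daily) == 0

    def test_empty_series(self, equator_site):
        series = LoggerSeries(
            site=equator_site,
            samples=pd.Series(dtype=float, index=pd.DatetimeIndex([], tz="UTC")),
        )
        assert len(nighttime_daily_mean(series)) == 0


class TestContinuityFilter:
    def test_exactly_365_consecutive_days_pass(self):
        assert continuity_filter(make_daily([27.0] * 365)).passed

    def test_364_days_fail(self):
        res = continuity_filter(make_daily([27.0] * 364))
        assert not res.passed
        assert res.longest_run_days == 364

    def test_gap_breaks_run(self):
        vals = pd.Series(
            27.0,
            index=pd.date_range("2014-01-01", periods=200, freq="D").append(
                pd.date_range("2014-07-21", periods=200, freq="D")
            ),
        )
        from reefstress import DailySeries

        res = continuity_filter(DailySeries(values=vals))
        assert not res.passed
        assert res.longest_run_days == 200

    def test_small_gap_bridged_when_allowed(self):
        idx = pd.date_range("2014-01-01", periods=400, freq="D").delete(200)
        from reefstress import DailySeries

        daily = DailySeries(values=pd.Series(27.0, index=idx))
        assert not continuity_filter(daily, min_days=365).passed
        assert continuity_filter(daily, min_days=365, max_gap_days=1).passed


class TestPairSeries:
    def test_identical_ranges_fully_paired(self, site):
        a = make_daily(np.arange(100.0), site=site)
        b = make_daily(np.arange(100.0) + 1.0, site=site)
        paired = pair_series(a, b)
        assert len(paired) == 100

    def test_missing_dates_shrink_pairing(self, site):
        sst = make_daily(np.arange(100.0), site=site)
        str_vals = sst.values.drop(sst.values.index[10:15])
        from reefstress import DailySeries

        str_daily = DailySeries(values=str_vals, site=site)
        paired = pair_series(str_daily, sst)
        assert len(paired) == 95

    def test_values_unaltered_by_pairing(self, site):
        rng = np.random.default_rng(1)
        a = make_daily(rng.normal(27, 1, 50), site=site)
        b = make_daily(rng.normal(27, 1, 50), site=site)
        paired = pair_series(a, b)
        pd.testing.assert_series_equal(paired.str_daily.values, a.values)

    def test_disjoint_ranges_warn_and_empty(self, site):
        a = make_daily([27.0] * 10, start="2014-01-01", site=site)
        b = make_daily([27.0] * 10, start="2015-01-01", site=site)
        with pytest.warns(UserWarning):
            paired = pair_series(a, b)
        assert len(paired) == 0


def test_deep_site_warns_but_is_accepted():
    with pytest.warns(UserWarning):
        meta = SiteMetadata(site_id="X", latitude=0, longitude=0, depth_m=55.0)
    assert meta.depth_m == 55.0
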