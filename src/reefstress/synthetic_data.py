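"""Synthetic multi-site reef temperature archives with known ground truth.

Real archives of paired satellite SST and moored-logger records cannot ship
with a package, so every pipeline stage is exercised against simulated data
whose generating parameters are known exactly.  The generator emulates the
statistical structure of a Pacific reef monitoring archive:

* a seasonal cycle peaking at a configurable climatologically warmest month;
* ENSO-like low-frequency variability (monthly AR(1), interpolated to days);
* episodic warm events lasting weeks to months;
* a depth-dependent STR−SST bias, strongest in summer (default −0.15 °C per
  10 m) and weakest in winter (default −0.028 °C per 10 m), with Gaussian
  site/island/region intercepts;
* sub-daily logger sampling (5–30 min cadence) with a diurnal cycle,
  measurement noise well above instrument accuracy, and random day gaps.

It is a statistical emulation only — no mixing, internal waves or heat
budget — so agreement of the pipeline with injected truth demonstrates
correctness of the estimators, not fidelity to ocean physics.

Besides the full time-series generator, truth-level shortcuts are provided
(`simulate_bias_table`, `simulate_event_table`, `simulate_log2_ratios`) that
draw directly the per-site/per-event quantities the mixed models consume;
these make large parameter-recovery studies affordable.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .timeseries_io import (
    DailySeries,
    LoggerSeries,
    SiteMetadata,
    ValidationError,
    write_metadata_csv,
)

__all__ = [
    "SimulationConfig",
    "SyntheticSite",
    "simulate_site",
    "simulate_archipelago",
    "simulate_bias_table",
    "simulate_event_table",
    "simulate_log2_ratios",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic archive; defaults emulate the study conditions."""

    n_regions: int = 2
    islands_per_region: int = 2
    sites_per_island: int = 3
    depth_range_m: tuple[float, float] = (1.0, 38.0)
    years: int = 3
    start_year: int = 2012
    base_mean_c: float = 27.0
    seasonal_amplitude_c: float = 2.0
    warmest_month: int = 9
    enso_sd_c: float = 0.25
    enso_ar1: float = 0.9
    event_rate_per_year: float = 1.0
    event_duration_days: int = 60
    event_amplitude_c: float = 2.0
    event_start_days: tuple[int, ...] | None = None  # fixed pulse starts (day index)
    summer_bias_slope_c_per_10m: float = -0.15
    winter_bias_slope_c_per_10m: float = -0.028
    site_bias_sd_c: float = 0.05
    island_bias_sd_c: float = 0.05
    region_bias_sd_c: float = 0.05
    diurnal_amplitude_c: float = 0.3
    sample_interval_min: int = 30
    daily_noise_sd_c: float = 0.05
    gap_prob: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.warmest_month <= 12:
            raise ValidationError(f"warmest_month {self.warmest_month} outside 1-12")
        if self.event_duration_days < 0 or self.event_rate_per_year < 0:
            raise ValidationError("event rate/duration must be non-negative")
        for name in ("site_bias_sd_c", "island_bias_sd_c", "region_bias_sd_c",
                     "enso_sd_c", "daily_noise_sd_c"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if not 1 <= self.sample_interval_min <= 720:
            raise ValidationError("sample_interval_min outside 1-720")

    @property
    def n_sites(self) -> int:
        return self.n_regions * self.islands_per_region * self.sites_per_island


@dataclass
class SyntheticSite:
    """One simulated site: metadata, SST, logger record and its truth."""

    metadata: SiteMetadata
    sst_daily: DailySeries
    logger: LoggerSeries
    truth: dict


def _peak_doy(month: int) -> float:
    return float(_dt.date(2001, month, 15).timetuple().tm_yday)


def _seasonal_weight(doy: np.ndarray, warmest_month: int) -> np.ndarray:
    """Within-year bias modulation: 1 at the warmest month, 0 six months off."""
    return 0.5 * (1.0 + np.cos(2.0 * np.pi * (doy - _peak_doy(warmest_month)) / 365.25))


def _site_layout(config: SimulationConfig, site_index: int):
    """Deterministic region/island assignment and geography for a site index."""
    per_region = config.islands_per_region * config.sites_per_island
    region_idx = site_index // per_region
    island_idx_global = site_index // config.sites_per_island
    rng_r = np.random.default_rng([config.seed, 101, region_idx])
    rng_i = np.random.default_rng([config.seed, 102, island_idx_global])
    lat = float(np.clip(rng_r.uniform(-20.0, 28.0) + rng_i.normal(0, 1.0), -35.0, 35.0))
    lon = float(((rng_r.uniform(140.0, 220.0) + rng_i.normal(0, 1.0)) + 180.0) % 360.0 - 180.0)
    # depths span the range evenly but are shuffled across the hierarchy so
    # depth is not confounded with island/region intercepts
    depths = np.linspace(*config.depth_range_m, config.n_sites)
    perm = np.random.default_rng([config.seed, 300]).permutation(config.n_sites)
    depth = float(depths[perm[site_index]])
    meta = SiteMetadata(
        site_id=f"S{site_index:03d}",
        island=f"I{island_idx_global:02d}",
        region=f"R{region_idx}",
        latitude=lat,
        longitude=lon,
        depth_m=depth,
    )
    return meta, region_idx, island_idx_global


def _random_intercepts(config: SimulationConfig, region_idx: int, island_idx: int, site_index: int):
    b_region = float(
        np.random.default_rng([config.seed, 201, region_idx]).normal(0.0, config.region_bias_sd_c)
    )
    b_island = float(
        np.random.default_rng([config.seed, 202, island_idx]).normal(0.0, config.island_bias_sd_c)
    )
    b_site = float(
        np.random.default_rng([config.seed, 203, site_index]).normal(0.0, config.site_bias_sd_c)
    )
    return b_region, b_island, b_site


def simulate_site(config: SimulationConfig, site_index: int) -> SyntheticSite:
    """Generate one site's paired SST series and sub-daily logger record.

    The surface daily series is the nighttime SST value: seasonal cosine +
    AR(1) ENSO anomaly + injected boxcar warm events + white noise.  The
    logger measures the same field plus the seasonally modulated depth bias
    (summer slope at the warmest month fading to the winter slope six months
    away) and hierarchical intercepts; its sub-daily samples add a diurnal
    cycle centred so the fixed-window nighttime mean is unbiased, plus
    sensor-scale noise.  Each site consumes its own random stream keyed by
    (seed, site index), so adding sites never perturbs existing ones.
    """
    if not 0 <= site_index < config.n_sites:
        raise ValidationError(f"site_index {site_index} outside 0-{config.n_sites - 1}")
    meta, region_idx, island_idx = _site_layout(config, site_index)
    b_region, b_island, b_site = _random_intercepts(config, region_idx, island_idx, site_index)
    rng = np.random.default_rng([config.seed, 1, site_index])

    start = pd.Timestamp(config.start_year, 1, 1)
    dates = pd.date_range(start, periods=round(config.years * 365.25), freq="D")
    n = len(dates)
    doy = dates.dayofyear.to_numpy(float)

    seasonal = config.base_mean_c + config.seasonal_amplitude_c * np.cos(
        2.0 * np.pi * (doy - _peak_doy(config.warmest_month)) / 365.25
    )

    # ENSO-like anomaly: stationary monthly AR(1), linear to daily
    n_months = config.years * 12 + 2
    e = np.empty(n_months)
    e[0] = rng.normal(0.0, config.enso_sd_c)
    innov_sd = config.enso_sd_c * np.sqrt(max(1.0 - config.enso_ar1**2, 1e-12))
    for m in range(1, n_months):
        e[m] = config.enso_ar1 * e[m - 1] + rng.normal(0.0, innov_sd)
    month_day = np.arange(n_months) * 30.44
    enso = np.interp(np.arange(n, dtype=float), month_day, e)

    # injected warm events (boxcars)
    pulses = np.zeros(n)
    truth_events = []
    if config.event_start_days is not None:
        starts = [int(s) for s in config.event_start_days]
    else:
        n_events = rng.poisson(config.event_rate_per_year * config.years)
        starts = [
            int(rng.integers(0, max(n - config.event_duration_days, 1)))
            for _ in range(n_events)
        ]
    for s in starts:
        dur = config.event_duration_days
        pulses[s : s + dur] += config.event_amplitude_c
        truth_events.append(
            {"start": str(dates[s].date()),
             "end": str(dates[min(s + dur - 1, n - 1)].date()),
             "amplitude_c": config.event_amplitude_c}
        )

    surface_clean = seasonal + enso + pulses
    sst_vals = surface_clean + rng.normal(0.0, config.daily_noise_sd_c, n)
    sst_daily = DailySeries(
        values=pd.Series(sst_vals, index=dates), kind="temperature", site=meta
    )

    # depth bias, seasonally modulated between the two configured slopes
    w = _seasonal_weight(doy, config.warmest_month)
    slope = (
        config.winter_bias_slope_c_per_10m
        + (config.summer_bias_slope_c_per_10m - config.winter_bias_slope_c_per_10m) * w
    )
    bias = slope * meta.depth_m / 10.0 + b_region + b_island + b_site
    logger_level = surface_clean + bias
    day_noise = rng.normal(0.0, config.daily_noise_sd_c, n)

    months = dates.month.to_numpy()
    from .climatology import winter_month as _wm

    summer_sel = months == config.warmest_month
    winter_sel = months == _wm(config.warmest_month)
    truth = {
        "site_id": meta.site_id,
        "region": meta.region,
        "island": meta.island,
        "depth_m": meta.depth_m,
        "b_region": b_region,
        "b_island": b_island,
        "b_site": b_site,
        "true_summer_bias_c": float(bias[summer_sel].mean()),
        "true_winter_bias_c": float(bias[winter_sel].mean()),
        "events": truth_events,
    }

    # sub-daily logger samples in local clock time, stored as UTC
    offset = meta.local_utc_offset
    step_min = config.sample_interval_min
    per_day = int(round(24 * 60 / step_min))
    frac_hours = np.arange(per_day) * step_min / 60.0
    # diurnal cycle peaking at local noon, centred so the 18:00-06:00
    # nighttime mean is ~0 and daily means stay comparable to SST
    diurnal = config.diurnal_amplitude_c * (
        np.cos(2.0 * np.pi * (frac_hours - 12.0) / 24.0) + 2.0 / np.pi
    )
    gap_days = rng.random(n) < config.gap_prob
    sensor_noise_sd = 0.01  # far above the ±0.002 °C instrument accuracy
    # the daily level applies noon-to-noon so that a whole night (evening of
    # d-1 plus morning of d, attributed to d) samples the level of day d,
    # keeping nighttime means aligned with the daily SST values
    night_of = np.minimum(
        np.arange(n)[:, None] + (frac_hours[None, :] >= 12.0).astype(int), n - 1
    )
    temps = (
        logger_level[night_of]
        + day_noise[night_of]
        + diurnal[None, :]
        + rng.normal(0.0, sensor_noise_sd, (n, per_day))
    )
    keep = ~gap_days
    day_start_local = dates.tz_localize(None).asi8[keep]  # ns since epoch
    offsets_ns = (frac_hours * 3_600_000_000_000).astype(np.int64)
    stamps_local = (day_start_local[:, None] + offsets_ns[None, :]).ravel()
    stamps_utc = pd.DatetimeIndex(stamps_local - int(offset * 3_600_000_000_000)).tz_localize("UTC")
    samples = pd.Series(temps[keep].ravel(), index=stamps_utc)
    logger = LoggerSeries(site=meta, samples=samples)
    return SyntheticSite(metadata=meta, sst_daily=sst_daily, logger=logger, truth=truth)


def simulate_archipelago(
    config: SimulationConfig, out_dir: str | Path | None = None
) -> tuple[list[SyntheticSite], pd.DataFrame]:
    """Generate the full hierarchical site set, optionally writing CSVs.

    Depths span ``depth_range_m`` evenly across sites.  When ``out_dir`` is
    given, the same CSV dialects the readers consume are emitted:
    ``metadata.csv``, ``sst.csv``, one ``logger_<site>.csv`` per site, and a
    ``truth.csv`` with every injected parameter needed to score estimators.
    """
    sites = [simulate_site(config, i) for i in range(config.n_sites)]
    truth_rows = []
    for s in sites:
        row = {k: v for k, v in s.truth.items() if k != "events"}
        row["n_true_events"] = len(s.truth["events"])
        truth_rows.append(row)
    truth = pd.DataFrame(truth_rows)
    truth["true_summer_slope_c_per_10m"] = config.summer_bias_slope_c_per_10m
    truth["true_winter_slope_c_per_10m"] = config.winter_bias_slope_c_per_10m

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_metadata_csv([s.metadata for s in sites], out / "metadata.csv")
        sst_frames = [
            pd.DataFrame(
                {
                    "site_id": s.metadata.site_id,
                    "date": s.sst_daily.dates.strftime("%Y-%m-%d"),
                    "sst_c": s.sst_daily.values.to_numpy(),
                }
            )
            for s in sites
        ]
        pd.concat(sst_frames, ignore_index=True).to_csv(out / "sst.csv", index=False)
        for s in sites:
            df = pd.DataFrame(
                {
                    "site_id": s.metadata.site_id,
                    "timestamp": s.logger.samples.index.strftime("%Y-%m-%dT%H:%M:%SZ"),
                    "temperature_c": s.logger.samples.to_numpy(),
                }
            )
            df.to_csv(out / f"logger_{s.metadata.site_id}.csv", index=False)
        truth.to_csv(out / "truth.csv", index=False)
    return sites, truth


# --------------------------------------------------------------------------
# truth-level generators for the statistical models
# --------------------------------------------------------------------------


def _hierarchy(n_regions, islands_per_region, sites_per_island):
    site_ids, islands, regions = [], [], []
    i = 0
    for r in range(n_regions):
        for isl in range(islands_per_region):
            for _ in range(sites_per_island):
                site_ids.append(f"S{i:04d}")
                islands.append(f"I{r}_{isl}")
                regions.append(f"R{r}")
                i += 1
    return site_ids, islands, regions


def simulate_bias_table(
    rng: np.random.Generator,
    n_regions: int = 5,
    islands_per_region: int = 8,
    sites_per_island: int = 10,
    slope_c_per_10m: float = -0.15,
    region_sd_c: float = 0.05,
    island_sd_c: float = 0.05,
    resid_sd_c: float = 0.05,
    depth_range_m: tuple[float, float] = (1.0, 38.0),
    season: str = "summer",
) -> pd.DataFrame:
    """Per-site seasonal mean biases drawn directly from the truth model.

    Generates exactly the table ``fit_bias_depth_lmm`` consumes: bias =
    slope × depth/10 + region intercept + island intercept + residual, one
    row per site, with depths uniform over ``depth_range_m``.
    """
    site_ids, islands, regions = _hierarchy(n_regions, islands_per_region, sites_per_island)
    n = len(site_ids)
    depth = rng.uniform(*depth_range_m, n)
    b_r = rng.normal(0.0, region_sd_c, n_regions)
    b_i = rng.normal(0.0, island_sd_c, n_regions * islands_per_region)
    r_codes = pd.Categorical(regions).codes
    i_codes = pd.Categorical(islands).codes
    bias = (
        slope_c_per_10m * depth / 10.0
        + b_r[r_codes]
        + b_i[i_codes]
        + rng.normal(0.0, resid_sd_c, n)
    )
    return pd.DataFrame(
        {
            "site_id": site_ids,
            "island": islands,
            "region": regions,
            "depth_m": depth,
            "season": season,
            "mean_bias_c": bias,
            "se_c": resid_sd_c,
            "n_days": 30,
        }
    )


def simulate_event_table(
    rng: np.random.Generator,
    n_events: int = 1000,
    n_regions: int = 4,
    islands_per_region: int = 5,
    sites_per_island: int = 4,
    beta0: float = 1.0,
    beta_depth_per_10m: float = 0.0,
    dispersion_k: float = 2.0,
    zero_inflation: float = 0.3,
    region_sd: float = 0.2,
    island_sd: float = 0.2,
    site_sd: float = 0.2,
    depth_range_m: tuple[float, float] = (1.0, 38.0),
) -> pd.DataFrame:
    """Event-severity table drawn from a ZINB mixed model with known truth.

    Severities are ZINB counts with log-mean β0 + β1·depth/10 plus Gaussian
    site/island/region intercepts; events land on sites uniformly.  The
    returned frame feeds ``fit_severity_depth_glmm`` directly.
    """
    site_ids, islands, regions = _hierarchy(n_regions, islands_per_region, sites_per_island)
    n_sites = len(site_ids)
    depth_site = rng.uniform(*depth_range_m, n_sites)
    u_site = rng.normal(0.0, site_sd, n_sites)
    u_island = rng.normal(0.0, island_sd, n_regions * islands_per_region)
    u_region = rng.normal(0.0, region_sd, n_regions)
    i_codes = pd.Categorical(islands).codes
    r_codes = pd.Categorical(regions).codes
    which = rng.integers(0, n_sites, n_events)
    depth = depth_site[which]
    eta = (
        beta0
        + beta_depth_per_10m * depth / 10.0
        + u_site[which]
        + u_island[i_codes[which]]
        + u_region[r_codes[which]]
    )
    mu = np.exp(eta)
    y = rng.negative_binomial(dispersion_k, dispersion_k / (dispersion_k + mu))
    if zero_inflation > 0:
        y = np.where(rng.random(n_events) < zero_inflation, 0, y)
    return pd.DataFrame(
        {
            "site_id": np.asarray(site_ids)[which],
            "island": np.asarray(islands)[which],
            "region": np.asarray(regions)[which],
            "depth_m": depth,
            "max_dhw_sst": y.astype(float),
            "max_dhw_str_unadj": 0.0,
            "max_dhw_str_adj": y.astype(float),
            "severe": y >= 4,
        }
    )


def simulate_log2_ratios(
    rng: np.random.Generator,
    n: int = 500,
    mean_log2: float = float(np.log2(0.607)),
    sd_log2: float = 0.8,
) -> pd.DataFrame:
    """Independent log2 accuracy ratios around a known mean (no grouping)."""
    vals = rng.normal(mean_log2, sd_log2, n)
    return pd.DataFrame(
        {
            "log2_ratio": vals,
            "ratio": np.exp2(vals),
            "zero_case": "none",
            "included_in_stats": True,
        }
    )
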