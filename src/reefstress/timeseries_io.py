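"""Reading, validation and reduction of raw reef temperature records.

Two kinds of raw input feed the heat-stress pipeline:

* satellite-style sea-surface temperature (SST): one nighttime value per
  calendar day per site, and
* subsurface temperature recorder (STR) logger files: one fixed position and
  depth per site, sampled every 5-30 minutes for years.

This module reduces logger records to nighttime (local sunset to sunrise)
daily means, screens series for a minimum run of continuous daily data, and
pairs the two daily series on coincident dates so the bias and heat-stress
stages downstream work from a single aligned table.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

logger = logging.getLogger("reefstress")

__all__ = [
    "FormatError",
    "ValidationError",
    "SiteMetadata",
    "LoggerSeries",
    "DailySeries",
    "PairedSeries",
    "NightRule",
    "ContinuityResult",
    "read_logger_csv",
    "read_sst_csv",
    "read_metadata_csv",
    "write_metadata_csv",
    "stitch_deployments",
    "solar_elevation",
    "nighttime_daily_mean",
    "continuity_filter",
    "pair_series",
]


class FormatError(ValueError):
    """Input file does not match the expected CSV dialect."""


class ValidationError(ValueError):
    """Input violates a series invariant (ordering, duplication, range)."""


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

DAILY_KINDS = ("temperature", "bias", "hotspot", "dhw")


@dataclass(frozen=True)
class SiteMetadata:
    """One monitored reef site: a fixed geographic position and depth."""

    site_id: str
    island: str = ""
    region: str = ""
    latitude: float = 0.0
    longitude: float = 0.0
    depth_m: float = 1.0
    utc_offset_hours: float | None = None

    def __post_init__(self) -> None:
        if not -90.0 <= self.latitude <= 90.0:
            raise ValidationError(f"latitude {self.latitude} outside [-90, 90]")
        if not -180.0 <= self.longitude <= 180.0:
            raise ValidationError(f"longitude {self.longitude} outside [-180, 180]")
        if self.depth_m <= 0:
            raise ValidationError(f"depth_m must be > 0, got {self.depth_m}")
        if self.depth_m > 40:
            warnings.warn(
                f"site {self.site_id}: depth {self.depth_m} m is outside the "
                "0-40 m range typical of moored reef loggers",
                stacklevel=2,
            )

    @property
    def local_utc_offset(self) -> float:
        """UTC offset in hours; nearest whole-hour zone from longitude if unset."""
        if self.utc_offset_hours is not None:
            return self.utc_offset_hours
        return float(round(self.longitude / 15.0))


@dataclass
class LoggerSeries:
    """High-frequency temperature record from one subsurface logger."""

    site: SiteMetadata
    samples: pd.Series  # float °C indexed by UTC timestamps, strictly increasing
    n_dropped: int = 0  # non-finite rows removed on read (QC count)

    def __post_init__(self) -> None:
        s = self.samples
        if not isinstance(s.index, pd.DatetimeIndex):
            raise ValidationError("samples must be indexed by timestamps")
        if s.index.tz is None:
            self.samples = s.tz_localize("UTC")
            s = self.samples
        if len(s) > 1:
            diffs = np.diff(s.index.asi8)
            if (diffs <= 0).any():
                i = int(np.argmax(diffs <= 0)) + 1
                raise ValidationError(
                    f"timestamps not strictly increasing at row {i} "
                    f"({s.index[i].isoformat()})"
                )
        if len(s) and not np.isfinite(s.to_numpy(float)).all():
            raise ValidationError("non-finite temperatures in logger series")

    def __len__(self) -> int:
        return len(self.samples)


@dataclass
class DailySeries:
    """One value per calendar day: temperature, bias, HotSpot or DHW."""

    values: pd.Series  # float indexed by normalized dates, strictly increasing
    kind: str = "temperature"
    site: SiteMetadata | None = None

    def __post_init__(self) -> None:
        if self.kind not in DAILY_KINDS:
            raise ValidationError(f"unknown daily-series kind {self.kind!r}")
        idx = self.values.index
        if not isinstance(idx, pd.DatetimeIndex):
            raise ValidationError("daily values must be indexed by dates")
        if idx.tz is not None:
            self.values = self.values.tz_localize(None)
            idx = self.values.index
        if (idx != idx.normalize()).any():
            raise ValidationError("daily index must hold plain calendar dates")
        if len(idx) > 1 and (np.diff(idx.asi8) <= 0).any():
            raise ValidationError("daily dates must be strictly increasing")
        self.values = self.values.astype(float)

    def __len__(self) -> int:
        return len(self.values)

    @property
    def dates(self) -> pd.DatetimeIndex:
        return self.values.index

    def on_full_range(self) -> pd.Series:
        """Values reindexed to every calendar day in the span (NaN = missing)."""
        if self.values.empty:
            return self.values
        full = pd.date_range(self.dates[0], self.dates[-1], freq="D")
        return self.values.reindex(full)

    def dropna(self) -> "DailySeries":
        return replace(self, values=self.values.dropna())


@dataclass
class PairedSeries:
    """STR and SST daily temperatures restricted to coincident dates."""

    str_daily: DailySeries
    sst_daily: DailySeries
    site: SiteMetadata | None = None

    @property
    def dates(self) -> pd.DatetimeIndex:
        return self.str_daily.dates

    def __len__(self) -> int:
        return len(self.str_daily)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"str_c": self.str_daily.values, "sst_c": self.sst_daily.values}
        )


@dataclass(frozen=True)
class NightRule:
    """How 'night' is decided for daily averaging.

    ``method="solar"`` marks a sample as night when the sun is below the
    horizon at the site (solar elevation < 0°, no refraction correction).
    ``method="window"`` uses a fixed local-solar-time window such as
    "18:00-06:00".  Either way a night spans two calendar dates and is
    attributed to the date on which it ends (the sunrise date).
    """

    method: str = "solar"
    window: str = "18:00-06:00"

    def window_hours(self) -> tuple[float, float]:
        try:
            start, end = self.window.split("-")
            sh, sm = (int(x) for x in start.split(":"))
            eh, em = (int(x) for x in end.split(":"))
        except ValueError as exc:  # pragma: no cover - config typo path
            raise FormatError(f"bad night window {self.window!r}") from exc
        return sh + sm / 60.0, eh + em / 60.0


@dataclass(frozen=True)
class ContinuityResult:
    """Outcome of the minimum-continuous-record screen."""

    passed: bool
    longest_run_days: int
    min_days: int
    n_days: int


# --------------------------------------------------------------------------
# readers / writers
# --------------------------------------------------------------------------


def read_logger_csv(path, metadata: SiteMetadata) -> LoggerSeries:
    """Read a logger CSV (columns ``timestamp,temperature_c``) for one site.

    Rows with non-finite temperature are dropped and counted in the returned
    series' ``n_dropped`` QC field.  Timestamps are ISO-8601 and UTC.
    """
    df = pd.read_csv(path)
    missing = {"timestamp", "temperature_c"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing column(s) {sorted(missing)}")
    if "site_id" in df.columns:
        other = set(df["site_id"].unique()) - {metadata.site_id}
        if other:
            raise ValidationError(
                f"{path}: rows for unexpected site(s) {sorted(other)}"
            )
    ts = pd.to_datetime(df["timestamp"], utc=True, format="ISO8601")
    temp = pd.to_numeric(df["temperature_c"], errors="coerce")
    keep = np.isfinite(temp.to_numpy(float))
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("%s: dropped %d non-finite temperature rows", path, n_dropped)
    samples = pd.Series(temp[keep].to_numpy(float), index=pd.DatetimeIndex(ts[keep]))
    if samples.index.has_duplicates:
        dup = samples.index[samples.index.duplicated()][0]
        raise ValidationError(f"{path}: duplicated timestamp {dup.isoformat()}")
    return LoggerSeries(site=metadata, samples=samples, n_dropped=n_dropped)


def read_sst_csv(path, metadata: SiteMetadata | None = None) -> DailySeries:
    """Read a daily SST CSV with columns ``site_id,date,sst_c`` (one site)."""
    df = pd.read_csv(path)
    missing = {"date", "sst_c"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing column(s) {sorted(missing)}")
    if metadata is not None and "site_id" in df.columns:
        df = df[df["site_id"] == metadata.site_id]
    dates = pd.DatetimeIndex(pd.to_datetime(df["date"]))
    vals = pd.Series(df["sst_c"].to_numpy(float), index=dates).dropna().sort_index()
    if vals.index.has_duplicates:
        raise ValidationError(f"{path}: duplicate date in SST series")
    return DailySeries(values=vals, kind="temperature", site=metadata)


_META_COLS = ["site_id", "island", "region", "latitude", "longitude", "depth_m"]


def read_metadata_csv(path) -> dict[str, SiteMetadata]:
    """Read the per-site metadata table keyed by site_id."""
    df = pd.read_csv(path)
    missing = set(_META_COLS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing column(s) {sorted(missing)}")
    if df["site_id"].duplicated().any():
        dup = df.loc[df["site_id"].duplicated(), "site_id"].iloc[0]
        raise ValidationError(f"{path}: duplicate site_id {dup!r}")
    out: dict[str, SiteMetadata] = {}
    for row in df.itertuples(index=False):
        out[str(row.site_id)] = SiteMetadata(
            site_id=str(row.site_id),
            island=str(row.island),
            region=str(row.region),
            latitude=float(row.latitude),
            longitude=float(row.longitude),
            depth_m=float(row.depth_m),
            utc_offset_hours=(
                float(row.utc_offset_hours)
                if "utc_offset_hours" in df.columns
                and np.isfinite(getattr(row, "utc_offset_hours", np.nan))
                else None
            ),
        )
    return out


def write_metadata_csv(sites, path) -> None:
    rows = [
        {
            "site_id": s.site_id,
            "island": s.island,
            "region": s.region,
            "latitude": s.latitude,
            "longitude": s.longitude,
            "depth_m": s.depth_m,
        }
        for s in sites
    ]
    pd.DataFrame(rows, columns=_META_COLS).to_csv(path, index=False)


# --------------------------------------------------------------------------
# operations
# --------------------------------------------------------------------------


def stitch_deployments(parts: list[LoggerSeries]) -> LoggerSeries:
    """Join successive logger deployments at one site into one series.

    Loggers are swapped every few years; deployments may abut or briefly
    overlap.  Samples with coincident timestamps are averaged so the result
    does not depend on the order of ``parts``.
    """
    if not parts:
        raise ValidationError("no deployments to stitch")
    site = parts[0].site
    for p in parts[1:]:
        if p.site.site_id != site.site_id or p.site.depth_m != site.depth_m:
            raise ValidationError(
                f"cannot stitch deployments from different sites/depths: "
                f"{site.site_id}@{site.depth_m}m vs {p.site.site_id}@{p.site.depth_m}m"
            )
    merged = pd.concat([p.samples for p in parts])
    merged = merged.groupby(level=0).mean().sort_index()
    return LoggerSeries(
        site=site, samples=merged, n_dropped=sum(p.n_dropped for p in parts)
    )


def solar_elevation(times_utc: pd.DatetimeIndex, latitude: float, longitude: float) -> np.ndarray:
    """Solar elevation angle in degrees at given UTC instants.

    Low-order spherical-astronomy series for declination and the equation of
    time (accuracy a few tenths of a degree, no atmospheric refraction) —
    ample for deciding whether the sun is above or below the horizon.
    """
    t = times_utc.tz_convert("UTC") if times_utc.tz is not None else times_utc.tz_localize("UTC")
    doy = t.dayofyear.to_numpy(float)
    frac_hour = (
        t.hour.to_numpy(float)
        + t.minute.to_numpy(float) / 60.0
        + t.second.to_numpy(float) / 3600.0
    )
    gamma = 2.0 * np.pi / 365.0 * (doy - 1.0 + (frac_hour - 12.0) / 24.0)
    decl = (
        0.006918
        - 0.399912 * np.cos(gamma)
        + 0.070257 * np.sin(gamma)
        - 0.006758 * np.cos(2 * gamma)
        + 0.000907 * np.sin(2 * gamma)
        - 0.002697 * np.cos(3 * gamma)
        + 0.00148 * np.sin(3 * gamma)
    )
    eqtime_min = 229.18 * (
        0.000075
        + 0.001868 * np.cos(gamma)
        - 0.032077 * np.sin(gamma)
        - 0.014615 * np.cos(2 * gamma)
        - 0.040849 * np.sin(2 * gamma)
    )
    true_solar_min = (frac_hour * 60.0 + eqtime_min + 4.0 * longitude) % 1440.0
    hour_angle = np.deg2rad(true_solar_min / 4.0 - 180.0)
    lat = np.deg2rad(latitude)
    sin_elev = np.sin(lat) * np.sin(decl) + np.cos(lat) * np.cos(decl) * np.cos(hour_angle)
    return np.rad2deg(np.arcsin(np.clip(sin_elev, -1.0, 1.0)))


def nighttime_daily_mean(series: LoggerSeries, night_rule: NightRule | None = None) -> DailySeries:
    """Reduce a logger record to nighttime daily mean temperatures.

    A sample belongs to the night when the sun is below the horizon at the
    site (or inside the configured fixed window).  Each night spans local
    sunset to sunrise and is attributed to the calendar date on which it ends,
    so a value dated D averages the evening of D−1 and the early morning of D.
    Dates whose night has no samples are absent from the result.
    """
    rule = night_rule or NightRule()
    site = series.site
    if series.samples.empty:
        return DailySeries(
            values=pd.Series(dtype=float, index=pd.DatetimeIndex([])),
            kind="temperature",
            site=site,
        )
    t = series.samples.index
    local = t.tz_convert("UTC") + pd.Timedelta(hours=site.local_utc_offset)
    local = local.tz_localize(None)
    local_hour = (
        local.hour.to_numpy(float)
        + local.minute.to_numpy(float) / 60.0
        + local.second.to_numpy(float) / 3600.0
    )
    if rule.method == "solar":
        elev = solar_elevation(t, site.latitude, site.longitude)
        is_night = elev < 0.0
        evening = local_hour >= 12.0  # before midnight: night ends next date
    elif rule.method == "window":
        start, end = rule.window_hours()
        if start <= end:
            raise FormatError("night window must wrap midnight (start > end)")
        is_night = (local_hour >= start) | (local_hour < end)
        evening = local_hour >= start
    else:
        raise FormatError(f"unknown night rule method {rule.method!r}")
    night_date = local.normalize() + pd.to_timedelta(np.where(evening, 1, 0), unit="D")
    vals = pd.Series(series.samples.to_numpy(float)[is_night], index=night_date[is_night])
    daily = vals.groupby(level=0).mean().sort_index()
    return DailySeries(values=daily, kind="temperature", site=site)


def continuity_filter(
    daily: DailySeries, min_days: int = 365, max_gap_days: int = 0
) -> ContinuityResult:
    """Screen a daily series for a minimum run of continuous data.

    The run length counts days with data; gaps of at most ``max_gap_days``
    missing days are bridged without contributing to the run (default 0:
    strictly consecutive dates).  A site passes when its longest run reaches
    ``min_days`` (365 by default: one full year of continuous record).
    """
    present = daily.values.dropna()
    if present.empty:
        return ContinuityResult(False, 0, min_days, 0)
    dates = present.index
    gap = np.diff(dates.asi8) // 86_400_000_000_000  # whole days between samples
    run = 1
    longest = 1
    for g in gap:
        if g - 1 <= max_gap_days:
            run += 1
        else:
            run = 1
        longest = max(longest, run)
    return ContinuityResult(longest >= min_days, int(longest), min_days, len(present))


def pair_series(str_daily: DailySeries, sst_daily: DailySeries) -> PairedSeries:
    """Restrict STR and SST daily series to their coincident dates.

    Values are never altered — pairing is a pure set intersection of dates.
    An empty intersection yields an empty pairing with a warning.
    """
    common = str_daily.values.dropna().index.intersection(sst_daily.values.dropna().index)
    if len(common) == 0:
        warnings.warn("paired series is empty: no coincident dates", stacklevel=2)
    site = str_daily.site or sst_daily.site
    return PairedSeries(
        str_daily=DailySeries(str_daily.values.loc[common], "temperature", site),
        sst_daily=DailySeries(sst_daily.values.loc[common], "temperature", site),
        site=site,
    )
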