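"""Seasonal STR−SST temperature bias and the bias-adjusted MMM threshold.

A satellite SST pixel and a logger moored tens of metres below it do not read
the same temperature: under summer stratification the logger is typically
cooler, by an amount that grows with depth.  Applying the surface MMM
threshold directly to logger data therefore understates subsurface heat
stress.  The remedy estimated here is empirical: compute the mean nighttime
daily difference STR − SST during the climatologically warmest month (summer)
and its six-month offset (winter), and shift the surface MMM by the summer
bias to obtain a subsurface threshold expressed in the logger's own frame.

Sign convention: bias = STR − SST, so a negative bias (logger cooler) yields
a cooler adjusted threshold: adjusted MMM = surface MMM + bias.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .climatology import MMMThreshold, winter_month
from .timeseries_io import DailySeries, PairedSeries, SiteMetadata, ValidationError

__all__ = [
    "BiasEstimate",
    "daily_bias",
    "seasonal_bias",
    "adjust_threshold",
    "bias_table",
]

SEASONS = ("summer", "winter", "all")


@dataclass(frozen=True)
class BiasEstimate:
    """Mean daily STR−SST bias for one site and season.

    ``month_used`` is the calendar month pooled (warmest month for summer,
    its six-month offset for winter, ``None`` when all days enter).  ``se_c``
    is the standard error of the daily biases (sample SD / sqrt(n)); it is
    reported for tables and plots, not reused by the mixed models.
    """

    site: SiteMetadata | None
    season: str
    month_used: int | None
    mean_bias_c: float
    se_c: float
    n_days: int

    def __post_init__(self) -> None:
        if self.season not in SEASONS:
            raise ValidationError(f"unknown season {self.season!r}")
        if self.n_days < 1:
            raise ValidationError("bias estimate needs at least one day")
        if self.se_c < 0:
            raise ValidationError("standard error cannot be negative")


def daily_bias(paired: PairedSeries) -> DailySeries:
    """Per-date STR − SST difference of nighttime daily temperatures."""
    diff = paired.str_daily.values - paired.sst_daily.values
    return DailySeries(values=diff, kind="bias", site=paired.site)


def seasonal_bias(
    bias: DailySeries, season: str, warmest_month: int | None = None
) -> BiasEstimate:
    """Mean daily bias over one season, pooled across years.

    ``season="summer"`` pools every day of the warmest month across all
    years; ``"winter"`` uses the month six months offset; ``"all"`` uses
    every paired day.  Pooling is day-weighted (each qualifying day counts
    once), matching a mean of daily differences.
    """
    if season not in SEASONS:
        raise ValidationError(f"unknown season {season!r}")
    vals = bias.values.dropna()
    month: int | None = None
    if season != "all":
        if warmest_month is None:
            raise ValidationError(f"season {season!r} requires warmest_month")
        month = warmest_month if season == "summer" else winter_month(warmest_month)
        vals = vals[vals.index.month == month]
    if vals.empty:
        where = f"month {month}" if month else "the record"
        raise ValidationError(f"no paired days in {where} for season {season!r}")
    arr = vals.to_numpy(float)
    n = arr.size
    se = float(arr.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    return BiasEstimate(
        site=bias.site,
        season=season,
        month_used=month,
        mean_bias_c=float(arr.mean()),
        se_c=se,
        n_days=int(n),
    )


def adjust_threshold(surface: MMMThreshold, summer_bias: BiasEstimate) -> MMMThreshold:
    """Shift the surface MMM by the summer STR−SST bias.

    A bias of −0.93 °C (logger cooler) produces a threshold 0.93 °C cooler
    than the surface MMM, putting subsurface DHW on the logger's own
    temperature scale.  The warmest month is kept from the surface
    climatology.  Adjusting an already-adjusted threshold is an error.
    """
    if surface.source == "bias-adjusted":
        raise ValidationError("threshold is already bias-adjusted")
    if summer_bias.season != "summer":
        raise ValidationError(
            f"threshold adjustment uses the summer bias, got {summer_bias.season!r}"
        )
    return MMMThreshold(
        mmm_c=surface.mmm_c + summer_bias.mean_bias_c,
        warmest_month=surface.warmest_month,
        source="bias-adjusted",
        bias_applied_c=summer_bias.mean_bias_c,
        parent_mmm_c=surface.mmm_c,
    )


def bias_table(estimates: list[BiasEstimate]) -> pd.DataFrame:
    """Long-format per-site seasonal bias table (input to the depth models)."""
    rows = []
    for est in estimates:
        meta = est.site
        rows.append(
            {
                "site_id": meta.site_id if meta else "",
                "island": meta.island if meta else "",
                "region": meta.region if meta else "",
                "depth_m": meta.depth_m if meta else np.nan,
                "season": est.season,
                "month_used": est.month_used if est.month_used is not None else -1,
                "mean_bias_c": est.mean_bias_c,
                "se_c": est.se_c,
                "n_days": est.n_days,
            }
        )
    return pd.DataFrame(rows)
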