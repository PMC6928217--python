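"""Monthly climatology and the MMM bleaching-stress baseline.

The bleaching-stress baseline used throughout coral heat-stress monitoring is
the MMM: the maximum of the twelve monthly mean climatologies, i.e. the
expected temperature of the climatologically warmest month at a site.
Operational products precompute the MMM from multi-decadal satellite data;
this module computes the equivalent from any daily series (synthetic or user
supplied) and locates the warmest month and its six-month winter offset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .timeseries_io import DailySeries, ValidationError

__all__ = [
    "MonthlyClimatology",
    "MMMThreshold",
    "monthly_climatology",
    "mmm",
    "winter_month",
]


@dataclass(frozen=True)
class MonthlyClimatology:
    """Twelve monthly mean temperatures and the year counts behind them."""

    month_means: tuple  # 12 floats °C, index 0 = January; NaN = undefined
    n_years_per_month: tuple  # 12 ints

    def mean_for(self, month: int) -> float:
        if not 1 <= month <= 12:
            raise ValidationError(f"month {month} outside 1-12")
        return self.month_means[month - 1]


@dataclass(frozen=True)
class MMMThreshold:
    """Maximum-of-monthly-means threshold with its warmest month.

    ``source`` records provenance: a satellite-style climatology, a
    user-provided value, or a bias-adjusted subsurface threshold (in which
    case ``bias_applied_c`` holds the seasonal STR−SST bias that was applied
    and ``parent_mmm_c`` the surface value it derives from).
    """

    mmm_c: float
    warmest_month: int
    source: str = "satellite-climatology"
    bias_applied_c: float = 0.0
    parent_mmm_c: float | None = None

    def __post_init__(self) -> None:
        if not 1 <= self.warmest_month <= 12:
            raise ValidationError(f"warmest_month {self.warmest_month} outside 1-12")
        if self.source not in ("satellite-climatology", "provided", "bias-adjusted"):
            raise ValidationError(f"unknown threshold source {self.source!r}")


def monthly_climatology(
    daily: DailySeries, year_range: tuple[int, int] | None = None
) -> MonthlyClimatology:
    """Monthly mean climatology from a daily temperature series.

    Averaging is month-first: days are averaged within each year-month, then
    those year-month means are averaged across years, so years with uneven
    data coverage carry equal weight.  ``year_range`` is an inclusive (first,
    last) bound on the calendar years used.
    """
    vals = daily.values.dropna()
    if year_range is not None:
        y0, y1 = year_range
        vals = vals[(vals.index.year >= y0) & (vals.index.year <= y1)]
    if vals.empty:
        raise ValidationError("no data inside the requested climatology years")
    per_ym = vals.groupby([vals.index.year, vals.index.month]).mean()
    per_month = per_ym.groupby(level=1).mean()
    counts = per_ym.groupby(level=1).size()
    means = [float(per_month.get(m, np.nan)) for m in range(1, 13)]
    n_years = [int(counts.get(m, 0)) for m in range(1, 13)]
    return MonthlyClimatology(tuple(means), tuple(n_years))


def mmm(clim: MonthlyClimatology) -> MMMThreshold:
    """Maximum of the monthly means and the month achieving it.

    Requires all twelve months defined; ties resolve to the earliest month.
    """
    means = np.asarray(clim.month_means, float)
    if not np.isfinite(means).all():
        bad = [m + 1 for m in range(12) if not np.isfinite(means[m])]
        raise ValidationError(f"climatology undefined for month(s) {bad}")
    warmest = int(np.argmax(means)) + 1  # argmax takes the first maximum
    return MMMThreshold(
        mmm_c=float(means[warmest - 1]),
        warmest_month=warmest,
        source="satellite-climatology",
    )


def winter_month(warmest_month: int) -> int:
    """The month six months offset from the warmest month (1-12, wrapping)."""
    if not 1 <= int(warmest_month) == warmest_month or warmest_month > 12:
        raise ValidationError(f"warmest_month {warmest_month} outside 1-12")
    return (warmest_month + 6 - 1) % 12 + 1
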