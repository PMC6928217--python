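"""HotSpot anomalies and Degree Heating Week (DHW) accumulation.

DHW is the operational coral heat-stress metric: the daily temperature
anomaly above the MMM threshold (the HotSpot), accumulated over a rolling
12-week (84-day) window and expressed in °C-weeks.  Only days whose anomaly
reaches 1 °C contribute, and they contribute their full anomaly:

    DHW(t) = (1/7) * sum_{s=t-83..t} hotspot(s) * [hotspot(s) >= 1 °C]

Interpretation follows the standard operational guidance: 4 °C-weeks marks
likely bleaching, 8 °C-weeks likely widespread bleaching and mortality.

Three input combinations are computed per site: (i) surface MMM applied to
SST (the operational satellite product), (ii) surface MMM applied directly
to logger data — kept only as a diagnostic, because unadjusted thresholds
artefactually suppress subsurface stress — and (iii) the bias-adjusted
subsurface MMM applied to logger data, the metric this package exists for.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .climatology import MMMThreshold
from .timeseries_io import DailySeries, SiteMetadata, ValidationError

__all__ = [
    "DHW_WINDOW_DAYS",
    "HOTSPOT_MIN_C",
    "BLEACHING_CWEEKS",
    "SEVERE_CWEEKS",
    "VARIANTS",
    "HotspotSeries",
    "DHWSeries",
    "hotspot",
    "dhw",
    "dhw_variants",
    "classify_dhw",
    "dhw_table",
]

DHW_WINDOW_DAYS = 84  # rolling 12-week accumulation window
HOTSPOT_MIN_C = 1.0  # anomalies below 1 °C do not accumulate
BLEACHING_CWEEKS = 4.0
SEVERE_CWEEKS = 8.0

VARIANTS = ("surface", "subsurface_unadjusted", "subsurface_adjusted")


@dataclass
class HotspotSeries:
    """Daily anomaly above threshold with its accumulation mask."""

    anomaly: DailySeries  # kind="hotspot": max(T - MMM, 0); NaN where T missing
    mask: pd.Series  # True where T - MMM >= 1 °C (False where missing)
    raw_anomaly: pd.Series  # unfloored T - MMM, used for accumulation
    threshold: MMMThreshold
    site: SiteMetadata | None = None


@dataclass
class DHWSeries:
    """Rolling 84-day DHW accumulation for one site and input combination."""

    series: DailySeries  # kind="dhw", °C-weeks; NaN where window under-covered
    variant: str
    threshold: MMMThreshold
    window_days: int = DHW_WINDOW_DAYS
    diagnostic_only: bool = False

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValidationError(f"unknown DHW variant {self.variant!r}")

    @property
    def values(self) -> pd.Series:
        return self.series.values


def hotspot(temp: DailySeries, threshold: MMMThreshold) -> HotspotSeries:
    """Daily HotSpot anomalies of a temperature series above an MMM threshold.

    The reported anomaly is floored at zero; the accumulation mask is true
    where the unfloored anomaly is at least 1 °C (the boundary value 1.0
    accumulates).  Missing temperatures stay missing.
    """
    if temp.kind != "temperature":
        raise ValidationError(f"hotspot needs a temperature series, got {temp.kind!r}")
    t = temp.on_full_range()
    raw = t - threshold.mmm_c
    anom = raw.clip(lower=0.0)
    mask = (raw >= HOTSPOT_MIN_C).fillna(False).astype(bool)
    return HotspotSeries(
        anomaly=DailySeries(values=anom, kind="hotspot", site=temp.site),
        mask=mask,
        raw_anomaly=raw,
        threshold=threshold,
        site=temp.site,
    )


def dhw(
    hs: HotspotSeries,
    variant: str = "surface",
    min_window_coverage: float = 0.9,
    allow_partial_windows: bool = False,
) -> DHWSeries:
    """Accumulate HotSpots into Degree Heating Weeks.

    DHW at date t sums masked anomalies over the 84 days ending at t
    (inclusive) and divides by 7 to give °C-weeks.  Missing days contribute
    zero, but the value is reported missing when fewer than
    ``min_window_coverage`` of the 84 days have data; the first 83 dates are
    undefined unless ``allow_partial_windows`` is set.
    """
    anom = hs.raw_anomaly  # daily cadence guaranteed by on_full_range()
    contrib = anom.where(hs.mask.to_numpy(), 0.0).fillna(0.0)
    window = DHW_WINDOW_DAYS
    min_periods = 1 if allow_partial_windows else window
    acc = contrib.rolling(window, min_periods=min_periods).sum() / 7.0
    coverage = anom.notna().astype(float).rolling(window, min_periods=min_periods).mean()
    acc = acc.where(coverage >= min_window_coverage)
    return DHWSeries(
        series=DailySeries(values=acc, kind="dhw", site=hs.site),
        variant=variant,
        threshold=hs.threshold,
        diagnostic_only=(variant == "subsurface_unadjusted"),
    )


def dhw_variants(
    site: SiteMetadata,
    sst: DailySeries,
    str_daily: DailySeries,
    surface: MMMThreshold,
    adjusted: MMMThreshold,
    min_window_coverage: float = 0.9,
) -> dict[str, DHWSeries]:
    """The three DHW input combinations for one site.

    (i) ``surface``: surface MMM on SST; (ii) ``subsurface_unadjusted``:
    surface MMM on logger data, flagged diagnostic-only; (iii)
    ``subsurface_adjusted``: bias-adjusted MMM on logger data.  The adjusted
    threshold must derive from the given surface threshold.
    """
    if adjusted.source != "bias-adjusted" or adjusted.parent_mmm_c != surface.mmm_c:
        raise ValidationError(
            "adjusted threshold does not derive from the given surface threshold"
        )
    if adjusted.warmest_month != surface.warmest_month:
        raise ValidationError("thresholds disagree on the warmest month")
    out = {
        "surface": dhw(
            hotspot(sst, surface), "surface", min_window_coverage
        ),
        "subsurface_unadjusted": dhw(
            hotspot(str_daily, surface), "subsurface_unadjusted", min_window_coverage
        ),
        "subsurface_adjusted": dhw(
            hotspot(str_daily, adjusted), "subsurface_adjusted", min_window_coverage
        ),
    }
    # SST and logger records rarely start/end on exactly the same day; put
    # the three variants on the shared union date axis for event detection
    starts = [v.values.index[0] for v in out.values() if len(v.values)]
    ends = [v.values.index[-1] for v in out.values() if len(v.values)]
    if starts:
        full = pd.date_range(min(starts), max(ends), freq="D")
        for name, v in out.items():
            out[name] = DHWSeries(
                series=DailySeries(v.values.reindex(full), "dhw", site),
                variant=name,
                threshold=v.threshold,
                diagnostic_only=v.diagnostic_only,
            )
    return out


def classify_dhw(value: float) -> str:
    """Interpretive class of a DHW value: none, bleaching_likely or severe."""
    if not np.isfinite(value) or value < 0:
        raise ValidationError(f"DHW must be finite and >= 0, got {value}")
    if value >= SEVERE_CWEEKS:
        return "severe"
    if value >= BLEACHING_CWEEKS:
        return "bleaching_likely"
    return "none"


def dhw_table(site_id: str, variants: dict[str, DHWSeries]) -> pd.DataFrame:
    """Long-format DHW table: one row per date × variant."""
    frames = []
    for name, series in variants.items():
        vals = series.values
        frames.append(
            pd.DataFrame(
                {
                    "site_id": site_id,
                    "date": vals.index,
                    "variant": name,
                    "dhw_cweeks": vals.to_numpy(float),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
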