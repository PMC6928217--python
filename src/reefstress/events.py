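"""Heat-stress event detection and severity bookkeeping.

An event is a maximal contiguous run of dates on which any of the three DHW
variants (surface, unadjusted subsurface, bias-adjusted subsurface) is above
zero; runs split wherever all variants are simultaneously zero or missing.
Each event records the maximum DHW reached by each variant within the run
(its severity), whether the run touches either end of the record (in which
case only the observed maximum can be reported), and whether it qualifies as
severe: at least 4 °C-weeks by the surface or the bias-adjusted metric.  The
unadjusted variant is computed for every event but never decides severity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dhw_engine import BLEACHING_CWEEKS, DHWSeries, VARIANTS
from .timeseries_io import SiteMetadata, ValidationError

__all__ = ["HeatEvent", "detect_events", "severe_filter", "event_table"]


@dataclass(frozen=True)
class HeatEvent:
    """One contiguous heat-stress episode at one site."""

    site: SiteMetadata | None
    start_date: pd.Timestamp
    end_date: pd.Timestamp
    max_dhw_sst: float
    max_dhw_str_unadj: float
    max_dhw_str_adj: float
    truncated_start: bool = False
    truncated_end: bool = False
    has_missing_days: bool = False

    def __post_init__(self) -> None:
        if self.start_date > self.end_date:
            raise ValidationError("event start after end")
        for v in (self.max_dhw_sst, self.max_dhw_str_unadj, self.max_dhw_str_adj):
            if v < 0:
                raise ValidationError("event maxima must be >= 0")

    @property
    def severe(self) -> bool:
        """Severe when surface or bias-adjusted maximum reaches 4 °C-weeks."""
        return max(self.max_dhw_sst, self.max_dhw_str_adj) >= BLEACHING_CWEEKS

    @property
    def duration_days(self) -> int:
        return int((self.end_date - self.start_date).days) + 1


def detect_events(variants: dict[str, DHWSeries]) -> list[HeatEvent]:
    """Split the union of non-zero DHW support into contiguous events.

    All three variant series must share a site and date axis.  Missing DHW
    values count as zero for run-splitting but flag the event as containing
    missing days.  Runs touching the first or last date of the record are
    flagged truncated (their true maximum may lie outside the record).
    """
    missing = set(VARIANTS) - set(variants)
    if missing:
        raise ValidationError(f"missing DHW variant(s): {sorted(missing)}")
    frames = {name: variants[name].values for name in VARIANTS}
    idx = frames["surface"].index
    for name in VARIANTS[1:]:
        if not idx.equals(frames[name].index):
            raise ValidationError(f"variant {name!r} is on a different date axis")
    if len(idx) == 0:
        return []

    site = variants["surface"].series.site or variants["subsurface_adjusted"].series.site
    mat = np.column_stack([frames[name].to_numpy(float) for name in VARIANTS])
    nonzero = np.nan_to_num(mat, nan=0.0) > 0.0
    any_missing = np.isnan(mat).any(axis=1)
    active = nonzero.any(axis=1)

    events: list[HeatEvent] = []
    bounds = np.flatnonzero(np.diff(np.concatenate(([0], active.view(np.int8), [0]))))
    for lo, hi in bounds.reshape(-1, 2):  # hi is exclusive
        block = np.nan_to_num(mat[lo:hi], nan=0.0)
        maxima = block.max(axis=0)
        events.append(
            HeatEvent(
                site=site,
                start_date=idx[lo],
                end_date=idx[hi - 1],
                max_dhw_sst=float(maxima[0]),
                max_dhw_str_unadj=float(maxima[1]),
                max_dhw_str_adj=float(maxima[2]),
                truncated_start=(lo == 0),
                truncated_end=(hi == len(idx)),
                has_missing_days=bool(any_missing[lo:hi].any()),
            )
        )
    return events


def severe_filter(events: list[HeatEvent]) -> list[HeatEvent]:
    """Events reaching 4 °C-weeks by the surface or bias-adjusted metric."""
    return [e for e in events if e.severe]


def event_table(events: list[HeatEvent]) -> pd.DataFrame:
    """Flat per-event table (one row per event) for the depth analyses."""
    rows = []
    for e in events:
        meta = e.site
        rows.append(
            {
                "site_id": meta.site_id if meta else "",
                "depth_m": meta.depth_m if meta else np.nan,
                "region": meta.region if meta else "",
                "island": meta.island if meta else "",
                "start_date": e.start_date.date().isoformat(),
                "end_date": e.end_date.date().isoformat(),
                "max_dhw_sst": e.max_dhw_sst,
                "max_dhw_str_unadj": e.max_dhw_str_unadj,
                "max_dhw_str_adj": e.max_dhw_str_adj,
                "truncated_start": e.truncated_start,
                "truncated_end": e.truncated_end,
                "severe": e.severe,
            }
        )
    cols = [
        "site_id", "depth_m", "region", "island", "start_date", "end_date",
        "max_dhw_sst", "max_dhw_str_unadj", "max_dhw_str_adj",
        "truncated_start", "truncated_end", "severe",
    ]
    return pd.DataFrame(rows, columns=cols)
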