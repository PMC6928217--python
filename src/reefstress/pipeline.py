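"""End-to-end orchestration: ingest -> bias -> DHW -> events -> statistics.

Runs the whole analysis for an archive laid out in the package's CSV
dialects (``metadata.csv``, ``sst.csv``, ``logger_<site>.csv``), writing the
per-site bias table, the long DHW table, the event table, the accuracy-ratio
table and JSON fit reports into a run directory, together with the resolved
configuration, so a run is a pure function of (inputs, config, seed).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bias_adjust, climatology, depth_stats, dhw_engine, events as events_mod
from .timeseries_io import (
    ContinuityResult,
    DailySeries,
    NightRule,
    ValidationError,
    nighttime_daily_mean,
    pair_series,
    continuity_filter,
    read_logger_csv,
    read_metadata_csv,
    read_sst_csv,
)

logger = logging.getLogger("reefstress")

__all__ = ["PipelineConfig", "run", "compute_tables", "process_site", "SiteResult"]


@dataclass
class PipelineConfig:
    """Fully serializable configuration of one pipeline run.

    Defaults are the operational constants (84-day window, ≥1 °C HotSpot
    rule, 4/8 °C-weeks severity, 365-day continuity), so a default-config
    run needs no flags.
    """

    input_dir: str = "."
    out_dir: str = "run"
    night_method: str = "solar"  # or "window"
    night_window: str = "18:00-06:00"
    min_days: int = 365
    max_gap_days: int = 0
    climatology_years: tuple[int, int] | None = None
    mmm_table: str | None = None  # optional CSV site_id,mmm_c,warmest_month
    min_window_coverage: float = 0.9
    glmm_family: str = "zinb"
    stats_subset: str = "all"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config key(s): {sorted(unknown)}")
        if isinstance(raw.get("climatology_years"), list):
            raw["climatology_years"] = tuple(raw["climatology_years"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        if d["climatology_years"] is not None:
            d["climatology_years"] = list(d["climatology_years"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    def night_rule(self) -> NightRule:
        return NightRule(method=self.night_method, window=self.night_window)


@dataclass
class SiteResult:
    """Everything computed for one site that passed the continuity screen."""

    site_id: str
    continuity: ContinuityResult
    surface_mmm: climatology.MMMThreshold
    adjusted_mmm: climatology.MMMThreshold
    summer_bias: bias_adjust.BiasEstimate
    winter_bias: bias_adjust.BiasEstimate
    all_bias: bias_adjust.BiasEstimate
    variants: dict
    events: list


def process_site(
    meta,
    logger_series,
    sst_daily: DailySeries,
    config: PipelineConfig,
    provided_mmm: climatology.MMMThreshold | None = None,
) -> SiteResult | None:
    """Run every stage for one site; None when it fails the continuity screen."""
    str_daily = nighttime_daily_mean(logger_series, config.night_rule())
    cont = continuity_filter(str_daily, config.min_days, config.max_gap_days)
    if not cont.passed:
        logger.info(
            "site %s excluded: longest continuous run %d d < %d d",
            meta.site_id, cont.longest_run_days, cont.min_days,
        )
        return None
    if provided_mmm is not None:
        surface = provided_mmm
    else:
        clim = climatology.monthly_climatology(sst_daily, config.climatology_years)
        surface = climatology.mmm(clim)
    paired = pair_series(str_daily, sst_daily)
    bias_series = bias_adjust.daily_bias(paired)
    summer = bias_adjust.seasonal_bias(bias_series, "summer", surface.warmest_month)
    winter = bias_adjust.seasonal_bias(bias_series, "winter", surface.warmest_month)
    overall = bias_adjust.seasonal_bias(bias_series, "all")
    adjusted = bias_adjust.adjust_threshold(surface, summer)
    variants = dhw_engine.dhw_variants(
        meta, sst_daily, str_daily, surface, adjusted, config.min_window_coverage
    )
    evs = events_mod.detect_events(variants)
    return SiteResult(
        site_id=meta.site_id,
        continuity=cont,
        surface_mmm=surface,
        adjusted_mmm=adjusted,
        summer_bias=summer,
        winter_bias=winter,
        all_bias=overall,
        variants=variants,
        events=evs,
    )


def _fit_to_dict(fit: depth_stats.ModelFit) -> dict:
    return {
        "model_name": fit.model_name,
        "family": fit.family,
        "fixed_effects": fit.fixed_effects.to_dict(orient="records"),
        "random_effect_sds": fit.random_effect_sds,
        "zero_inflation_prob": fit.zero_inflation_prob,
        "dispersion_k": fit.dispersion_k,
        "resid_sd": fit.resid_sd,
        "n_obs": fit.n_obs,
        "converged": fit.converged,
        "loglik": None if not np.isfinite(fit.loglik) else fit.loglik,
        "extra": {k: v for k, v in fit.extra.items() if isinstance(v, (int, float, str))},
        "diagnostics": fit.diagnostics,
    }


def compute_tables(config: PipelineConfig) -> dict[str, pd.DataFrame]:
    """Run all per-site stages and return the four analysis tables."""
    in_dir = Path(config.input_dir)
    sites = read_metadata_csv(in_dir / "metadata.csv")
    logger.info("read metadata for %d sites", len(sites))
    provided = _read_mmm_table(config)
    bias_rows: list[bias_adjust.BiasEstimate] = []
    all_events = []
    dhw_frames = []
    n_excluded = 0
    for site_id, meta in sites.items():
        lg = read_logger_csv(in_dir / f"logger_{site_id}.csv", meta)
        sst = read_sst_csv(in_dir / "sst.csv", meta)
        result = process_site(meta, lg, sst, config, provided.get(site_id))
        if result is None:
            n_excluded += 1
            continue
        bias_rows.extend([result.summer_bias, result.winter_bias, result.all_bias])
        all_events.extend(result.events)
        dhw_frames.append(dhw_engine.dhw_table(site_id, result.variants))
    logger.info(
        "processed %d sites (%d excluded by continuity screen); %d events",
        len(sites) - n_excluded, n_excluded, len(all_events),
    )
    return {
        "bias": bias_adjust.bias_table(bias_rows),
        "dhw": (
            pd.concat(dhw_frames, ignore_index=True)
            if dhw_frames
            else pd.DataFrame(columns=["site_id", "date", "variant", "dhw_cweeks"])
        ),
        "events": events_mod.event_table(all_events),
        "accuracy": depth_stats.accuracy_table(all_events),
    }


def run(config: PipelineConfig) -> Path:
    """Execute the full pipeline and return the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        tables = compute_tables(config)
        bias_df = tables["bias"]
        ev_df = tables["events"]
        acc_df = tables["accuracy"]
        bias_df.to_csv(out / "bias.csv", index=False)
        tables["dhw"].to_csv(out / "dhw.csv", index=False)
        ev_df.to_csv(out / "events.csv", index=False)
        acc_df.to_csv(out / "accuracy.csv", index=False)

        fits = {}
        fits_err = {}
        for name, thunk in {
            "bias_depth_summer": lambda: depth_stats.fit_bias_depth_lmm(bias_df, "summer"),
            "bias_depth_winter": lambda: depth_stats.fit_bias_depth_lmm(bias_df, "winter"),
            "severity_depth": lambda: depth_stats.fit_severity_depth_glmm(
                ev_df, subset=config.stats_subset, family=config.glmm_family,
                seed=config.seed,
            ),
            "accuracy": lambda: depth_stats.fit_accuracy_model(
                acc_df[acc_df["severe"]] if acc_df["severe"].sum() >= 10 else acc_df
            ),
        }.items():
            try:
                fits[name] = _fit_to_dict(thunk())
            except (ValidationError, ValueError) as exc:
                fits_err[name] = str(exc)
                logger.warning("fit %s skipped: %s", name, exc)
        with open(out / "fits.json", "w") as fh:
            json.dump({"fits": fits, "skipped": fits_err}, fh, indent=2, default=float)
        config.to_yaml(out / "config_resolved.yaml")
        logger.info("run complete: %s", out)
    finally:
        logger.removeHandler(handler)
        handler.close()
    return out


def _read_mmm_table(config: PipelineConfig) -> dict:
    if config.mmm_table is None:
        return {}
    df = pd.read_csv(config.mmm_table)
    out = {}
    for row in df.itertuples(index=False):
        out[str(row.site_id)] = climatology.MMMThreshold(
            mmm_c=float(row.mmm_c),
            warmest_month=int(row.warmest_month),
            source="provided",
        )
    return out
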