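"""End-to-end pipeline: bag samples + sensors + model output → result bundle.

Stages run in dependency order — fluxes, weekly aggregation, Keeling
signatures, Monte-Carlo source partition, soil-water diagnostics, model
evaluation — and write five delimited result tables plus a JSON manifest
carrying the config hash and seed, so a rerun with the same inputs and
seed reproduces the bundle byte for byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from datetime import timedelta
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import io as nio
from .config import PipelineConfig
from .evaluation import compare_parameterizations, welch_monthly_weather
from .fluxes import compute_flux, cumulative_flux, weekly_mean_flux
from .keeling import RejectedSignature, SourceSignature, signatures_from_events
from .partition import monte_carlo_partition, partition_table
from .soil_water import daily_average_and_gapfill, wfps_diagnostics, wfps_from_vwc

logger = logging.getLogger(__name__)


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineInputs:
    """In-memory inputs; load from files with :meth:`from_paths`."""

    bag_table: pd.DataFrame
    vwc_primary: Optional[pd.DataFrame] = None
    vwc_neighbor: Optional[pd.DataFrame] = None
    weather: Optional[pd.DataFrame] = None
    weather_second_year: Optional[pd.DataFrame] = None
    model_runs: dict = field(default_factory=dict)   # name -> daily DataFrame

    @classmethod
    def from_paths(cls, bag_path, vwc_primary=None, vwc_neighbor=None,
                   weather=None, weather_second_year=None,
                   model_runs: Optional[dict] = None) -> "PipelineInputs":
        return cls(
            bag_table=nio.read_bag_table(bag_path),
            vwc_primary=nio.read_vwc_table(vwc_primary) if vwc_primary else None,
            vwc_neighbor=nio.read_vwc_table(vwc_neighbor) if vwc_neighbor else None,
            weather=nio.read_weather_table(weather) if weather else None,
            weather_second_year=(nio.read_weather_table(weather_second_year)
                                 if weather_second_year else None),
            model_runs={name: nio.read_model_daily_table(p)
                        for name, p in (model_runs or {}).items()})


def _flux_stage(events, config):
    estimates = [compute_flux(ev, r2_min=config.r2_min) for ev in events]
    table = pd.DataFrame([dict(
        chamber_id=e.chamber_id, treatment=e.treatment,
        timestamp=e.timestamp.isoformat() if e.timestamp else "",
        flux=e.flux, slope_ppb_h=e.slope,
        r2=e.r2 if e.r2 is not None else np.nan,
        se_flux=e.se_flux, accepted=e.accepted, n_bags=e.n_bags)
        for e in estimates])
    return estimates, table


def _signature_table(signatures, rejected):
    rows = [dict(chamber_id=s.chamber_id, timestamp=s.timestamp.isoformat(),
                 d15a_src=s.d15a_src, d15b_src=s.d15b_src,
                 d18o_src=s.d18o_src if s.d18o_src is not None else np.nan,
                 d15_bulk=s.d15_bulk, d15_sp=s.d15_sp, quality=s.quality,
                 flux=s.flux, se_flux=s.se_flux, status="accepted")
            for s in signatures]
    rows += [dict(chamber_id=r.chamber_id, timestamp=r.timestamp.isoformat(),
                  d15a_src=np.nan, d15b_src=np.nan, d18o_src=np.nan,
                  d15_bulk=np.nan, d15_sp=np.nan, quality="rejected",
                  flux=np.nan, se_flux=np.nan, status=f"rejected: {r.reason}")
             for r in rejected]
    cols = ["chamber_id", "timestamp", "d15a_src", "d15b_src", "d18o_src",
            "d15_bulk", "d15_sp", "quality", "flux", "se_flux", "status"]
    df = pd.DataFrame(rows, columns=cols)
    return df.sort_values(["timestamp", "chamber_id"]).reset_index(drop=True)


def observed_cumulative_curve(weekly: pd.DataFrame) -> pd.DataFrame:
    """Cumulative observed flux (kg N ha⁻¹) at the end of each reported week."""
    wk = weekly.sort_values("week_start").reset_index(drop=True)
    dates, cums = [], []
    start = wk["week_start"].iloc[0]
    for i in range(len(wk)):
        end = wk["week_start"].iloc[i] + timedelta(days=7)
        cums.append(cumulative_flux(wk.iloc[:i + 1], period=(start, end)))
        dates.append(end)
    return pd.DataFrame({"date": dates, "cum_kg_n_ha": cums})


def run_pipeline(config: PipelineConfig, inputs: PipelineInputs,
                 out_dir) -> dict:
    """Run every stage and write the result bundle under ``out_dir``.

    Returns a dict of the in-memory results keyed like the files.  Any
    stage failure aborts with the stage name and the original cause.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}

    def stage(name):
        def wrap(fn):
            try:
                return fn()
            except Exception as exc:     # noqa: BLE001 - reported with stage
                raise PipelineStageError(name, exc) from exc
        return wrap

    # -- fluxes -----------------------------------------------------------
    events = stage("read-events")(lambda: nio.table_to_events(inputs.bag_table))
    estimates, flux_table = stage("fluxes")(lambda: _flux_stage(events, config))
    nio.write_table(flux_table, out / "fluxes.csv")
    results["fluxes"] = flux_table

    weekly = stage("weekly-fluxes")(
        lambda: weekly_mean_flux(estimates, grouping="treatment"))
    nio.write_table(weekly.assign(
        week_start=weekly["week_start"].map(lambda t: t.isoformat())
        if len(weekly) else weekly.get("week_start")),
        out / "weekly_fluxes.csv")
    results["weekly_fluxes"] = weekly

    # -- Keeling signatures ----------------------------------------------
    signatures, rejected = stage("keeling")(
        lambda: signatures_from_events(events, config))
    sig_table = _signature_table(signatures, rejected)
    nio.write_table(sig_table, out / "signatures.csv")
    results["signatures"] = sig_table
    if not signatures:
        logger.warning("no closure passed the flux/Keeling gates; "
                       "signature and partition tables are empty")

    # -- source partition -------------------------------------------------
    def _partition():
        res = []
        for i, sig in enumerate(signatures):
            res.append(monte_carlo_partition(
                sig, (config.den_box, config.nit_box), config.reduction,
                n_draws=config.n_draws,
                seed=(config.seed * 100003 + i) % (2**31 - 1),
                obs_sd_sp=config.obs_sd_sp, obs_sd_bulk=config.obs_sd_bulk,
                likelihood_sd_bulk=config.likelihood_sd_bulk))
        return res
    part_results = stage("partition")(_partition)
    part_df = partition_table(part_results)
    if len(part_df):
        part_df = part_df.assign(date=part_df["date"].map(
            lambda t: t.isoformat() if t is not None else ""))
    nio.write_table(part_df, out / "partition.csv")
    results["partition"] = part_df

    # -- soil water --------------------------------------------------------
    def _soil_water():
        if inputs.vwc_primary is None:
            return None
        daily = daily_average_and_gapfill(inputs.vwc_primary, inputs.vwc_neighbor)
        daily["wfps"] = wfps_from_vwc(daily["vwc"].to_numpy(),
                                      config.bulk_density,
                                      config.particle_density)
        sim = None
        for run in inputs.model_runs.values():
            if "wfps_sim" in run.columns:
                sim = run.rename(columns={"wfps_sim": "wfps"})[["date", "wfps"]]
                break
        diag = None
        if sim is not None:
            diag = wfps_diagnostics(daily.rename(columns={"date": "date"}),
                                    sim, fc=config.fc_wfps, wp=config.wp_wfps)
        return daily, diag
    sw = stage("soil-water")(_soil_water)
    if sw is not None:
        daily, diag = sw
        nio.write_table(daily.assign(date=daily["date"].map(lambda t: t.date().isoformat())),
                        out / "wfps_daily.csv")
        results["wfps_daily"] = daily
        if diag is not None:
            diag_d = {k: (v if v is not None else float("nan"))
                      for k, v in vars(diag).items()}
            (out / "wfps_diagnostics.json").write_text(
                json.dumps(diag_d, indent=2, sort_keys=True) + "\n")
            results["wfps_diagnostics"] = diag

    # -- evaluation --------------------------------------------------------
    def _evaluation():
        if not inputs.model_runs or weekly.empty:
            return None
        group = weekly["group"].iloc[0]
        obs_cum = observed_cumulative_curve(weekly[weekly["group"] == group])
        return compare_parameterizations(inputs.model_runs, obs_cum)
    report = stage("evaluation")(_evaluation)
    if report is not None:
        nio.write_table(report, out / "evaluation.csv")
        results["evaluation"] = report

    if inputs.weather is not None and inputs.weather_second_year is not None:
        welch = pd.concat(
            [welch_monthly_weather(inputs.weather, inputs.weather_second_year,
                                   var).assign(variable=var)
             for var in ("tmin_c", "tmax_c", "precip_mm")],
            ignore_index=True)
        nio.write_table(welch, out / "weather_welch.csv")
        results["weather_welch"] = welch

    manifest = dict(config_hash=config.config_hash(), seed=config.seed,
                    n_events=len(events),
                    n_accepted_fluxes=int(flux_table["accepted"].sum()),
                    n_signatures=len(signatures),
                    n_partitions=len(part_df))
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    results["manifest"] = manifest
    return results
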