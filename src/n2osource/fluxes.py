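"""Areal N₂O fluxes from automatic-chamber closure events.

A closure yields four sequential headspace bag samples; the mole-fraction
increase over time, fit by ordinary least squares, gives the emission
rate.  The ppb h⁻¹ slope is converted to an areal mass flux with the
ideal-gas molar volume at ambient temperature and pressure:

    flux = slope · 1e-9 · p / (R·T) · M · h     [µg N₂O-N m⁻² h⁻¹]

with M = 28 g N per mol N₂O and h the chamber headspace height.  Fits
with R² below the acceptance gate are flagged rejected; they stay in the
table so that gate bookkeeping is auditable downstream.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from datetime import datetime, timedelta
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import M_N2O_N, R_GAS

logger = logging.getLogger(__name__)


class DegenerateFitError(ValueError):
    """Regression impossible: no variance on the predictor."""


@dataclass
class BagSample:
    """One gas bag: fill time after chamber closure plus what the CRDS read."""

    t_fill: float                 # minutes after closure
    conc_n2o: float               # ppb
    d15a: Optional[float] = None  # ‰ vs AIR-N2
    d15b: Optional[float] = None  # ‰ vs AIR-N2
    d18o: Optional[float] = None  # ‰ vs VSMOW
    analyzer_id: str = "A1"

    def __post_init__(self) -> None:
        if self.t_fill <= 0:
            raise ValueError("bag fill time must be positive")
        if self.conc_n2o <= 0:
            raise ValueError("N2O concentration must be positive")


@dataclass
class ClosureEvent:
    """A 15-minute chamber closure with its ordered bag sequence."""

    chamber_id: str
    treatment: str
    timestamp: datetime
    bags: list[BagSample]
    air_temp: float               # °C
    pressure: float               # Pa
    chamber_height: float         # m

    def __post_init__(self) -> None:
        if len(self.bags) < 2:
            raise ValueError("closure needs at least two bag samples")
        times = self.bag_times_by_analyzer()
        for ts in times.values():
            if not all(b < a for b, a in zip(ts, ts[1:])):
                raise ValueError("bag fill times must be strictly increasing")
        if self.air_temp <= -100.0:
            raise ValueError("implausible air temperature")

    def bag_times_by_analyzer(self) -> dict[str, list[float]]:
        out: dict[str, list[float]] = {}
        for bag in self.bags:
            out.setdefault(bag.analyzer_id, []).append(bag.t_fill)
        return out

    @property
    def analyzers(self) -> list[str]:
        seen: list[str] = []
        for bag in self.bags:
            if bag.analyzer_id not in seen:
                seen.append(bag.analyzer_id)
        return seen


@dataclass
class FluxEstimate:
    """Slope-derived areal flux with its regression diagnostics."""

    flux: float                   # µg N2O-N m-2 h-1
    slope: float                  # ppb h-1
    r2: Optional[float]           # None when undefined (zero conc variance)
    se_flux: float
    accepted: bool
    n_bags: int
    chamber_id: str = ""
    treatment: str = ""
    timestamp: Optional[datetime] = None


def slope_to_flux(slope_ppb_h: float, air_temp: float, pressure: float,
                  chamber_height: float) -> float:
    """Ideal-gas conversion of a mole-fraction slope to an areal mass flux."""
    molar_density = pressure / (R_GAS * (air_temp + 273.15))   # mol m-3
    return slope_ppb_h * 1e-9 * molar_density * M_N2O_N * 1e6 * chamber_height


def flux_to_slope(flux: float, air_temp: float, pressure: float,
                  chamber_height: float) -> float:
    """Inverse of :func:`slope_to_flux`; used by the synthetic generator."""
    molar_density = pressure / (R_GAS * (air_temp + 273.15))
    return flux / (1e-9 * molar_density * M_N2O_N * 1e6 * chamber_height)


def compute_flux(event: ClosureEvent, r2_min: float = 0.7) -> FluxEstimate:
    """OLS of concentration against time, converted to µg N₂O-N m⁻² h⁻¹.

    Duplicate-analyzer bag sequences are pooled into one regression (both
    analyzers observe the same headspace).  A fit with undefined R² (all
    concentrations equal) is recorded as a rejected zero flux rather than
    raised: it is a real observation of no accumulation, just one the
    acceptance gate cannot vouch for.
    """
    t_h = np.array([b.t_fill for b in event.bags]) / 60.0
    conc = np.array([b.conc_n2o for b in event.bags])
    if np.ptp(t_h) == 0:
        raise DegenerateFitError("no variance in bag fill times")
    n = len(conc)
    meta = dict(chamber_id=event.chamber_id, treatment=event.treatment,
                timestamp=event.timestamp, n_bags=n)
    if np.ptp(conc) == 0:
        return FluxEstimate(flux=0.0, slope=0.0, r2=None, se_flux=0.0,
                            accepted=False, **meta)
    fit = stats.linregress(t_h, conc)
    flux = slope_to_flux(fit.slope, event.air_temp, event.pressure,
                         event.chamber_height)
    se_flux = abs(slope_to_flux(fit.stderr, event.air_temp, event.pressure,
                                event.chamber_height))
    r2 = fit.rvalue ** 2
    return FluxEstimate(flux=flux, slope=fit.slope, r2=r2, se_flux=se_flux,
                        accepted=bool(r2 >= r2_min), **meta)


def weekly_mean_flux(estimates: Sequence[FluxEstimate],
                     grouping: Literal["chamber", "treatment"] = "treatment",
                     ) -> pd.DataFrame:
    """Weekly means of accepted fluxes with a combined standard error.

    Estimates are grouped into ISO weeks.  Within each (group, week) cell
    chamber means are formed first; the reported SE is

        sqrt( var(chamber means)/n_chambers + mean(se_i²) )

    i.e. the among-chamber sampling variance of the mean plus the average
    regression variance.  With a single chamber only the regression term
    remains.  Weeks with no accepted estimate are omitted (logged).
    """
    rows = []
    for est in estimates:
        if not est.accepted or est.timestamp is None:
            continue
        iso = est.timestamp.isocalendar()
        rows.append(dict(
            group=est.chamber_id if grouping == "chamber" else est.treatment,
            chamber_id=est.chamber_id,
            iso_year=iso[0], iso_week=iso[1],
            flux=est.flux, se_flux=est.se_flux,
        ))
    if not rows:
        logger.warning("no accepted flux estimates; weekly table empty")
        return pd.DataFrame(columns=["group", "iso_year", "iso_week",
                                     "week_start", "mean_flux", "se_flux", "n"])
    df = pd.DataFrame(rows)
    out = []
    for (group, year, week), sub in df.groupby(["group", "iso_year", "iso_week"]):
        chamber_means = sub.groupby("chamber_id")["flux"].mean()
        n_ch = len(chamber_means)
        between_var = chamber_means.var(ddof=1) if n_ch > 1 else 0.0
        within_var = float(np.mean(sub["se_flux"] ** 2))
        se = math.sqrt(between_var / max(n_ch, 1) + within_var)
        out.append(dict(
            group=group, iso_year=int(year), iso_week=int(week),
            week_start=datetime.fromisocalendar(int(year), int(week), 1),
            mean_flux=float(chamber_means.mean()), se_flux=se, n=len(sub),
        ))
    return (pd.DataFrame(out)
            .sort_values(["group", "week_start"])
            .reset_index(drop=True))


def cumulative_flux(weekly: pd.DataFrame,
                    period: Optional[tuple[datetime, datetime]] = None,
                    ) -> float:
    """Time-integrate a weekly mean flux series to kg N ha⁻¹.

    Each weekly mean is applied as a constant over its own week; gaps
    between reported weeks are bridged by linear interpolation between
    the flanking weekly values, and the edges of the period hold the
    nearest weekly mean.  The piecewise-linear series is integrated in
    hours and converted µg m⁻² → kg ha⁻¹ (× 1e-5).
    """
    if weekly.empty:
        raise ValueError("cannot integrate an empty weekly series")
    if weekly["group"].nunique() > 1:
        raise ValueError("pass a single group's weekly series")
    wk = weekly.sort_values("week_start")
    t_nodes: list[datetime] = []
    v_nodes: list[float] = []
    for _, row in wk.iterrows():
        start = row["week_start"]
        end = start + timedelta(days=7)
        t_nodes += [start, end]
        v_nodes += [row["mean_flux"], row["mean_flux"]]
    if period is not None:
        p0, p1 = period
        if p0 < t_nodes[0]:
            t_nodes.insert(0, p0); v_nodes.insert(0, v_nodes[0])
        if p1 > t_nodes[-1]:
            t_nodes.append(p1); v_nodes.append(v_nodes[-1])
    t_h = np.array([(t - t_nodes[0]).total_seconds() / 3600.0 for t in t_nodes])
    v = np.array(v_nodes)
    if period is not None:
        lo = (period[0] - t_nodes[0]).total_seconds() / 3600.0
        hi = (period[1] - t_nodes[0]).total_seconds() / 3600.0
        grid = np.unique(np.clip(np.append(t_h, [lo, hi]), lo, hi))
        v = np.interp(grid, t_h, v)
        t_h = grid
    integral_ug_m2 = float(np.trapezoid(v, t_h))
    return integral_ug_m2 * 1e-5
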