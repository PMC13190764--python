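"""Soil-water diagnostics: VWC → WFPS, gap filling, obs-vs-sim comparison.

Water-filled pore space expresses the sensor's volumetric water content
as a percentage of total pore volume,

    WFPS = 100 · VWC / (1 − BD/PD),

with bulk density BD and particle density PD (default 2.65 g cm⁻³).
Daily means of the 15-minute sensor record are compared against a
simulated daily WFPS series via squared Pearson correlation and by
counting days at/above field capacity and at/below wilting point —
the two threshold exceedances that flag where a soil model wets up or
dries out more often than the field does.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class WfpsDiagnostics:
    """Observed-vs-simulated WFPS comparison over a common period."""

    r2_obs_sim: Optional[float]       # None when degenerate (constant series)
    days_at_or_above_fc_obs: int
    days_at_or_above_fc_sim: int
    days_at_or_below_wp_obs: int
    days_at_or_below_wp_sim: int
    range_obs: float                  # max - min, % WFPS
    range_sim: float
    n_days: int


def wfps_from_vwc(vwc, bd: float, pd_: float = 2.65):
    """Water-filled pore space (%) from volumetric water content.

    Accepts scalars or arrays.  Values above 100 % (sensor/BD mismatch)
    are returned as-is; clipping would hide a diagnostic signal.
    """
    if not 0 < bd < pd_:
        raise ValueError("need 0 < bulk density < particle density")
    vwc = np.asarray(vwc, dtype=float)
    if np.any(vwc < 0):
        raise ValueError("volumetric water content cannot be negative")
    porosity = 1.0 - bd / pd_
    out = 100.0 * vwc / porosity
    return float(out) if out.ndim == 0 else out


def daily_average_and_gapfill(primary: pd.DataFrame,
                              neighbor: Optional[pd.DataFrame] = None,
                              ) -> pd.DataFrame:
    """Daily VWC means, with missing days substituted from a neighbor plot.

    Input frames carry 15-minute records with columns ``timestamp`` and
    ``vwc``.  Output has one row per calendar day with ``date``, ``vwc``
    and ``source_plot`` ∈ {primary, neighbor}.  Days missing in both
    series stay absent (logged).
    """
    def _daily(df: pd.DataFrame) -> pd.Series:
        ts = pd.to_datetime(df["timestamp"])
        return df.groupby(ts.dt.normalize())["vwc"].mean()

    daily_primary = _daily(primary)
    out = pd.DataFrame({"date": daily_primary.index,
                        "vwc": daily_primary.values,
                        "source_plot": "primary"})
    if neighbor is not None and len(neighbor):
        daily_neighbor = _daily(neighbor)
        missing = daily_neighbor.index.difference(daily_primary.index)
        if len(missing):
            fill = pd.DataFrame({"date": missing,
                                 "vwc": daily_neighbor.loc[missing].values,
                                 "source_plot": "neighbor"})
            out = pd.concat([out, fill], ignore_index=True)
    out = out.sort_values("date").reset_index(drop=True)
    full = pd.date_range(out["date"].min(), out["date"].max(), freq="D")
    gaps = full.difference(pd.DatetimeIndex(out["date"]))
    if len(gaps):
        logger.warning("%d days missing in both primary and neighbor series",
                       len(gaps))
    return out


def wfps_diagnostics(obs_daily: pd.DataFrame, sim_daily: pd.DataFrame,
                     fc: float = 78.87, wp: float = 39.33) -> WfpsDiagnostics:
    """Compare daily observed and simulated WFPS series.

    Both frames need ``date`` and ``wfps`` columns.  r² is the squared
    Pearson correlation on common dates; threshold day counts use
    inclusive comparisons (≥ fc, ≤ wp) per series over its full common
    coverage.  A constant series makes r² undefined; it is reported as
    ``None`` with a warning rather than raised.
    """
    obs = obs_daily.set_index(pd.to_datetime(obs_daily["date"]))["wfps"]
    sim = sim_daily.set_index(pd.to_datetime(sim_daily["date"]))["wfps"]
    common = obs.index.intersection(sim.index)
    if len(common) < 3:
        raise ValueError("fewer than 3 common dates between obs and sim")
    o, s = obs.loc[common].to_numpy(float), sim.loc[common].to_numpy(float)
    if np.std(o) == 0 or np.std(s) == 0:
        logger.warning("constant WFPS series; r^2 undefined")
        r2 = None
    else:
        r2 = float(np.corrcoef(o, s)[0, 1] ** 2)
    return WfpsDiagnostics(
        r2_obs_sim=r2,
        days_at_or_above_fc_obs=int(np.sum(o >= fc)),
        days_at_or_above_fc_sim=int(np.sum(s >= fc)),
        days_at_or_below_wp_obs=int(np.sum(o <= wp)),
        days_at_or_below_wp_sim=int(np.sum(s <= wp)),
        range_obs=float(o.max() - o.min()),
        range_sim=float(s.max() - s.min()),
        n_days=len(common))
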