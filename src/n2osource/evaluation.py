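"""Model-evaluation statistics: RMSE, parameter-set comparison, Welch tests.

A biogeochemical model run is consumed as a daily table of total N₂O,
its nitrification and denitrification components, N₂ and simulated WFPS
per parameter set.  Cumulative simulated curves are compared against
observed cumulative flux at the observation dates by root mean squared
error, RMSE = sqrt(Σ(Sᵢ−Oᵢ)²/n).  The weather comparison between two
years uses the Welch two-sample t-test per calendar month.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class DayCentParamSet:
    """Bookkeeping for one nitrogen-cycling parameterization.

    Holds the seven N-cycle parameters that matter for pathway-resolved
    N₂O: minimum water/temperature reduction on nitrification (ncoeff),
    the proportions of nitrified N lost as N₂O at field capacity and
    wilting point, maximum daily nitrification amount, the net
    mineralization → NO₃ fraction, the WFPS-denitrification inflection
    adjustment, and the N₂/N₂O ratio adjustment.
    """

    name: str
    ncoeff: float
    n2oadjust_fc: float
    n2oadjust_wp: float
    maxnitamt: float
    netmn_to_no3: float
    wfpsdnitadj: float
    n2n2oadj: float

    def __post_init__(self) -> None:
        for f in ("ncoeff", "n2oadjust_fc", "n2oadjust_wp", "maxnitamt",
                  "netmn_to_no3", "wfpsdnitadj", "n2n2oadj"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be nonnegative")


# Published parameter triplet: model defaults, a traditional total-flux
# calibration, and an expert-informed set guided by WFPS + isotope data.
PARAM_SETS = {
    "default": DayCentParamSet("default", 0.030, 0.025, 0.020, 1.500,
                               0.200, 1.000, 1.000),
    "traditional": DayCentParamSet("traditional", 0.027, 0.000, 0.004, 3.690,
                                   0.359, 1.400, 1.159),
    "expert": DayCentParamSet("expert", 0.027, 0.001, 0.001, 3.690,
                              0.359, 1.000, 1.000),
}


def rmse(observed, simulated) -> float:
    """Root mean squared error between paired series, in O's units."""
    o = np.asarray(observed, dtype=float)
    s = np.asarray(simulated, dtype=float)
    if o.shape != s.shape:
        raise ValueError("observed and simulated lengths differ")
    if o.size == 0:
        raise ValueError("empty evaluation pair")
    return float(np.sqrt(np.mean((s - o) ** 2)))


def validate_simulated_daily(df: pd.DataFrame, tol: float = 1e-6) -> pd.DataFrame:
    """Check the pathway-split consistency of a daily model-output table."""
    required = {"date", "n2o_total", "n2o_nit", "n2o_denit", "n2"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"model daily table missing columns: {sorted(missing)}")
    gap = (df["n2o_total"] - df["n2o_nit"] - df["n2o_denit"]).abs()
    if (gap > tol * np.maximum(1.0, df["n2o_total"].abs())).any():
        raise ValueError("n2o_total != n2o_nit + n2o_denit beyond tolerance")
    return df


def compare_parameterizations(runs: dict[str, pd.DataFrame],
                              observed_cumulative: pd.DataFrame,
                              ) -> pd.DataFrame:
    """Evaluate each model run against the observed cumulative flux curve.

    ``runs`` maps a parameter-set name to a daily table with columns
    ``date``, ``n2o_total``, ``n2o_nit``, ``n2o_denit``, ``n2``
    (g N ha⁻¹ d⁻¹).  ``observed_cumulative`` has ``date`` and
    ``cum_kg_n_ha``.  Per run the report carries cumulative totals
    (kg N ha⁻¹), pathway shares, cumulative N₂, and the RMSE of the
    simulated cumulative curve interpolated to the observation dates.
    """
    if observed_cumulative.empty:
        raise ValueError("observed cumulative series is empty")
    obs_dates = pd.to_datetime(observed_cumulative["date"])
    obs_vals = observed_cumulative["cum_kg_n_ha"].to_numpy(float)
    rows = []
    for name, run in runs.items():
        run = validate_simulated_daily(run)
        dates = pd.to_datetime(run["date"])
        if obs_dates.min() < dates.min() or obs_dates.max() > dates.max():
            raise ValueError(f"run {name!r} does not cover the observation period")
        cum_total = run["n2o_total"].cumsum() * 1e-3   # g -> kg N/ha
        cum_nit = float(run["n2o_nit"].sum()) * 1e-3
        cum_den = float(run["n2o_denit"].sum()) * 1e-3
        cum_n2 = float(run["n2"].sum()) * 1e-3
        t = dates.astype("int64").to_numpy(float)
        t_obs = obs_dates.astype("int64").to_numpy(float)
        sim_at_obs = np.interp(t_obs, t, cum_total.to_numpy(float))
        total = cum_nit + cum_den
        rows.append(dict(
            param_set=name,
            cum_n2o_total=float(cum_total.iloc[-1]),
            cum_n2o_nit=cum_nit, cum_n2o_denit=cum_den, cum_n2=cum_n2,
            share_nit=cum_nit / total if total > 0 else np.nan,
            share_denit=cum_den / total if total > 0 else np.nan,
            rmse_cum=rmse(obs_vals, sim_at_obs)))
    return pd.DataFrame(rows)


def welch_monthly_weather(year1_daily: pd.DataFrame, year2_daily: pd.DataFrame,
                          variable: str, alpha: float = 0.05) -> pd.DataFrame:
    """Welch two-sample t-test on monthly samples of a daily weather variable.

    Input frames carry ``date`` plus the named variable.  For each
    calendar month present in both years the table reports t, the
    Welch–Satterthwaite degrees of freedom, the two-sided p, and a
    significance flag at ``alpha``.  Two zero-variance samples with
    equal means yield t=0, p=1 instead of NaN.
    """
    def _by_month(df: pd.DataFrame) -> dict[int, np.ndarray]:
        months = pd.to_datetime(df["date"]).dt.month
        return {m: sub[variable].to_numpy(float)
                for m, sub in df.groupby(months)}

    g1, g2 = _by_month(year1_daily), _by_month(year2_daily)
    rows = []
    for month in sorted(set(g1) & set(g2)):
        a, b = g1[month], g2[month]
        if len(a) < 2 or len(b) < 2:
            continue
        if np.var(a) == 0 and np.var(b) == 0:
            t, df_w, p = (0.0, float(len(a) + len(b) - 2), 1.0) \
                if np.mean(a) == np.mean(b) else (np.inf, np.nan, 0.0)
        else:
            res = stats.ttest_ind(a, b, equal_var=False)
            t, p = float(res.statistic), float(res.pvalue)
            df_w = float(res.df)
        rows.append(dict(month=month, t=t, df=df_w, p=p,
                         significant=bool(p < alpha)))
    return pd.DataFrame(rows)
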