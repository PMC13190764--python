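"""Synthetic field data with the statistical structure the pipeline assumes.

Generates the four inputs the analysis consumes — chamber bag-sample
records, 15-minute soil-moisture series, daily weather, and daily
pathway-split model output — from known ground truth, so every
downstream estimator can be tested as the inverse of a generator.

Chamber headspace concentrations accumulate linearly over ambient
background at the rate implied by the true flux through the ideal-gas
conversion; bag δ values follow exact conservative two-endmember mixing

    δ_mix = (C_amb·δ_amb + ΔC·δ_src) / (C_amb + ΔC)

between ambient air and the microbial source, with independent Gaussian
noise per channel on top.  Source signatures come from a pathway mix
(denitrification-group fraction f_den) with optional closed-system
Rayleigh enrichment of the residual pool when part of the produced N₂O
is reduced to N₂.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from datetime import datetime, timedelta
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .fluxes import BagSample, ClosureEvent, flux_to_slope

#: Bag fill times (minutes after closure) of the automatic chamber system.
DEFAULT_BAG_TIMES = (3.50, 7.25, 11.50, 14.25)

#: Chambers close for 15 minutes every 4 hours.
CLOSURE_MINUTES = 15.0
CLOSURE_INTERVAL_H = 4.0


@dataclass(frozen=True)
class TrueScenario:
    """Ground truth for one chamber closure."""

    flux_true: float = 103.0        # µg N2O-N m-2 h-1
    source_d15a: float = 0.0        # ‰
    source_d15b: float = 0.0
    source_d18o: float = 30.0
    ambient_conc: float = 330.0     # ppb
    ambient_d15a: float = 16.05     # bulk 6.7 + SP 18.7 / 2
    ambient_d15b: float = -2.65
    ambient_d18o: float = 44.6
    chamber_height: float = 0.3     # m
    air_temp: float = 15.0          # °C
    pressure: float = 96600.0       # Pa
    noise_conc: float = 1.0         # ppb sd
    noise_delta: float = 0.3        # ‰ sd per channel
    seed: int = 0

    def __post_init__(self) -> None:
        if self.flux_true < 0:
            raise ValueError("true flux cannot be negative")
        if self.ambient_conc <= 0 or self.chamber_height <= 0:
            raise ValueError("ambient concentration and chamber height must be positive")
        if self.noise_conc < 0 or self.noise_delta < 0:
            raise ValueError("noise standard deviations cannot be negative")


@dataclass(frozen=True)
class PathwayMixSpec:
    """Pathway mixture and reduction extent behind an emitted signature."""

    f_den: float = 0.85             # fraction of gross N2O from bD+nD
    endmember_sp_den: float = 0.0   # ‰
    endmember_sp_nit: float = 35.0
    endmember_bulk_den: float = -20.0
    endmember_bulk_nit: float = -35.0
    reduction_r: float = 0.0        # fraction of produced N2O reduced to N2
    eps_sp_red: float = -5.0        # ‰, net isotope effects of reduction
    eps_bulk_red: float = -7.0
    eps_d18o_red: float = -15.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.f_den <= 1.0:
            raise ValueError("f_den must lie in [0, 1]")
        if not 0.0 <= self.reduction_r < 1.0:
            raise ValueError("reduction_r must lie in [0, 1); a fully "
                             "consumed pool emits nothing")


def mix_and_reduce(mix: PathwayMixSpec) -> tuple[float, float]:
    """Emitted (SP, bulk) from the pathway mixture after partial reduction.

    Production mixing is linear per axis; reduction enriches the residual
    emitted pool by ε·ln(1−r) with ε < 0, so the shift is positive.
    """
    sp_prod = mix.f_den * mix.endmember_sp_den + (1 - mix.f_den) * mix.endmember_sp_nit
    bulk_prod = (mix.f_den * mix.endmember_bulk_den
                 + (1 - mix.f_den) * mix.endmember_bulk_nit)
    shift = math.log1p(-mix.reduction_r)
    return sp_prod + mix.eps_sp_red * shift, bulk_prod + mix.eps_bulk_red * shift


def generate_closure(scenario: TrueScenario,
                     bag_times: Sequence[float] = DEFAULT_BAG_TIMES,
                     timestamp: Optional[datetime] = None,
                     chamber_id: str = "CH1",
                     treatment: str = "NPK",
                     analyzers: Sequence[str] = ("A1",),
                     rng: Optional[np.random.Generator] = None,
                     ) -> ClosureEvent:
    """One chamber closure's bag sequence from ground truth.

    With several ``analyzers`` the same headspace is sampled once per
    analyzer with independent measurement noise (duplicate analysis).
    Noiseless output inverts exactly through the flux and Keeling
    estimators.
    """
    times = list(bag_times)
    if not all(b < a for b, a in zip(times, times[1:])):
        raise ValueError("bag times must be strictly increasing")
    if times[0] <= 0 or times[-1] > CLOSURE_MINUTES:
        raise ValueError(f"bag times must lie in (0, {CLOSURE_MINUTES}] min")
    if rng is None:
        rng = np.random.default_rng(scenario.seed)

    slope = flux_to_slope(scenario.flux_true, scenario.air_temp,
                          scenario.pressure, scenario.chamber_height)
    source = {"d15a": scenario.source_d15a, "d15b": scenario.source_d15b,
              "d18o": scenario.source_d18o}
    ambient = {"d15a": scenario.ambient_d15a, "d15b": scenario.ambient_d15b,
               "d18o": scenario.ambient_d18o}
    bags: list[BagSample] = []
    for analyzer in analyzers:
        for t_min in times:
            conc_clean = scenario.ambient_conc + slope * t_min / 60.0
            added = conc_clean - scenario.ambient_conc
            deltas = {}
            for ch in ("d15a", "d15b", "d18o"):
                mixed = ((scenario.ambient_conc * ambient[ch] + added * source[ch])
                         / conc_clean)
                deltas[ch] = mixed + rng.normal(0.0, scenario.noise_delta)
            conc = conc_clean + rng.normal(0.0, scenario.noise_conc)
            bags.append(BagSample(t_fill=t_min, conc_n2o=conc,
                                  analyzer_id=analyzer, **deltas))
    return ClosureEvent(chamber_id=chamber_id, treatment=treatment,
                        timestamp=timestamp or datetime(2024, 5, 14, 8, 0),
                        bags=bags, air_temp=scenario.air_temp,
                        pressure=scenario.pressure,
                        chamber_height=scenario.chamber_height)


def source_from_mix(mix: PathwayMixSpec, base_d18o: float = 30.0,
                    ) -> tuple[float, float, float]:
    """(δ¹⁵Nα, δ¹⁵Nβ, δ¹⁸O) of the emitted source implied by a pathway mix."""
    sp, bulk = mix_and_reduce(mix)
    d18o = base_d18o + mix.eps_d18o_red * math.log1p(-mix.reduction_r)
    return bulk + sp / 2.0, bulk - sp / 2.0, d18o


def generate_campaign(n_closures: int,
                      flux_series: Sequence[float],
                      mix: PathwayMixSpec,
                      template: TrueScenario = TrueScenario(),
                      seed: int = 0,
                      start: datetime = datetime(2024, 5, 1, 0, 0),
                      chamber_ids: Sequence[str] = ("CH1", "CH2", "CH3"),
                      treatment: str = "NPK",
                      analyzers: Sequence[str] = ("A1",),
                      bag_times: Sequence[float] = DEFAULT_BAG_TIMES,
                      ) -> list[ClosureEvent]:
    """A campaign of closures on the 4-hour chamber schedule.

    Every closure's true source signature derives from ``mix`` through
    :func:`mix_and_reduce`; fluxes follow ``flux_series``.  Chambers
    rotate through ``chamber_ids``.  Deterministic under ``seed``.
    """
    if n_closures <= 0:
        raise ValueError("n_closures must be positive")
    if len(flux_series) != n_closures:
        raise ValueError("flux_series length must equal n_closures")
    rng = np.random.default_rng(seed)
    d15a, d15b, d18o = source_from_mix(mix, base_d18o=template.source_d18o)
    events = []
    for i in range(n_closures):
        scenario = replace(template, flux_true=float(flux_series[i]),
                           source_d15a=d15a, source_d15b=d15b, source_d18o=d18o)
        events.append(generate_closure(
            scenario, bag_times=bag_times,
            timestamp=start + timedelta(hours=CLOSURE_INTERVAL_H * i),
            chamber_id=chamber_ids[i % len(chamber_ids)],
            treatment=treatment, analyzers=analyzers, rng=rng))
    return events


def generate_vwc_series(days: int,
                        porosity: float = 0.47547,
                        fc_wfps: float = 78.87,
                        wp_wfps: float = 39.33,
                        wet_days: Iterable[int] = (),
                        dry_days: Iterable[int] = (),
                        noise: float = 0.0,
                        seed: int = 0,
                        start: datetime = datetime(2023, 1, 1),
                        plot_id: str = "NPK-sugarbeet",
                        ) -> pd.DataFrame:
    """A 15-minute VWC sensor record with prescribed threshold exceedances.

    Baseline WFPS sits midway between wilting point and field capacity;
    days listed in ``wet_days`` are pushed above ``fc_wfps`` and
    ``dry_days`` below ``wp_wfps``, so that with ``noise=0`` the daily
    day-count diagnostics recover exactly the requested counts.
    """
    if not 0 < wp_wfps < fc_wfps <= 100:
        raise ValueError("need 0 < wilting point < field capacity <= 100 % WFPS")
    wet = set(int(d) for d in wet_days)
    dry = set(int(d) for d in dry_days)
    if wet & dry:
        raise ValueError(f"days {sorted(wet & dry)} listed as both wet and dry")
    if wet and (min(wet) < 0 or max(wet) >= days):
        raise ValueError("wet day index out of range")
    if dry and (min(dry) < 0 or max(dry) >= days):
        raise ValueError("dry day index out of range")
    rng = np.random.default_rng(seed)
    baseline = 0.5 * (wp_wfps + fc_wfps)
    wet_level = fc_wfps + 0.5 * (100.0 - fc_wfps)
    dry_level = 0.5 * wp_wfps
    per_day = 96  # 15-min cadence
    wfps = np.full(days * per_day, baseline)
    for d in wet:
        wfps[d * per_day:(d + 1) * per_day] = wet_level
    for d in dry:
        wfps[d * per_day:(d + 1) * per_day] = dry_level
    vwc = wfps / 100.0 * porosity + rng.normal(0.0, noise, days * per_day)
    timestamps = [start + timedelta(minutes=15 * i) for i in range(days * per_day)]
    return pd.DataFrame({"timestamp": timestamps, "plot_id": plot_id,
                         "vwc": np.clip(vwc, 0.0, None)})


def generate_weather_series(days: int, seed: int = 0,
                            start: datetime = datetime(2023, 1, 1),
                            mean_temp: float = 9.4,
                            annual_amplitude: float = 9.0,
                            diurnal_range: float = 8.0,
                            annual_precip: float = 1031.0,
                            wet_day_prob: float = 0.45,
                            ) -> pd.DataFrame:
    """Daily tmin/tmax (°C) and precipitation (mm) for a temperate site.

    Temperature follows a seasonal sinusoid with Gaussian weather noise;
    precipitation is Bernoulli-gamma with the annual total set by
    ``annual_precip`` in expectation.
    """
    rng = np.random.default_rng(seed)
    doy = np.arange(days)
    seasonal = mean_temp + annual_amplitude * np.sin(
        2 * np.pi * (doy - 105 + start.timetuple().tm_yday) / 365.25)
    tmean = seasonal + rng.normal(0.0, 2.5, days)
    tmin = tmean - diurnal_range / 2 + rng.normal(0.0, 0.8, days)
    tmax = tmean + diurnal_range / 2 + rng.normal(0.0, 0.8, days)
    wet = rng.random(days) < wet_day_prob
    mean_wet_amount = annual_precip / (365.25 * wet_day_prob)
    precip = np.where(wet, rng.gamma(1.2, mean_wet_amount / 1.2, days), 0.0)
    dates = [start + timedelta(days=int(d)) for d in doy]
    return pd.DataFrame({"date": dates, "tmin_c": tmin, "tmax_c": tmax,
                         "precip_mm": precip})


def generate_model_daily(days: int,
                         start: datetime = datetime(2024, 1, 1),
                         annual_total_kg: float = 0.63,
                         f_den: float = 0.85,
                         n2_to_n2o_denit: float = 5.0,
                         pulse_days: Sequence[int] = (128, 142),
                         pulse_share: float = 0.6,
                         wfps_series: Optional[Sequence[float]] = None,
                         seed: int = 0,
                         ) -> pd.DataFrame:
    """Pathway-split daily N₂O/N₂ emission series shaped like model output.

    A low baseline with exponential pulses after the ``pulse_days``
    (fertilization events), scaled so the annual total N₂O is
    ``annual_total_kg`` kg N ha⁻¹ and split ``f_den`` : 1−``f_den``
    between denitrification and nitrification.  Units g N ha⁻¹ d⁻¹.
    """
    rng = np.random.default_rng(seed)
    doy = np.arange(days)
    shape = np.full(days, 1.0)
    for p in pulse_days:
        shape += (pulse_share * days / (len(pulse_days) * 10.0)
                  * np.exp(-np.clip(doy - p, 0, None) / 10.0) * (doy >= p))
    shape *= rng.lognormal(0.0, 0.3, days)
    total = shape / shape.sum() * annual_total_kg * 1e3   # g N/ha per day
    n2o_denit = total * f_den
    n2o_nit = total * (1 - f_den)
    n2 = n2o_denit * n2_to_n2o_denit
    if wfps_series is None:
        wfps = 60.0 + 15.0 * np.sin(2 * np.pi * (doy - 30) / 365.25) \
            + rng.normal(0.0, 4.0, days)
    else:
        wfps = np.asarray(wfps_series, dtype=float)
    dates = [start + timedelta(days=int(d)) for d in doy]
    return pd.DataFrame({"date": dates, "n2o_total": total, "n2o_nit": n2o_nit,
                         "n2o_denit": n2o_denit, "n2": n2,
                         "wfps_sim": wfps})
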