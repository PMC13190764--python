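"""Flux estimation: ideal-gas conversion, gates, weekly and cumulative math."""

from datetime import datetime, timedelta

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from n2osource import TrueScenario, generate_closure
from n2osource.fluxes import (BagSample, ClosureEvent, DegenerateFitError,
                              FluxEstimate, compute_flux, cumulative_flux,
                              flux_to_slope, slope_to_flux, weekly_mean_flux)


def _event(concs, times=(3.5, 7.25, 11.5, 14.25), temp=25.0, p=101325.0,
           h=0.3, chamber="CH1", ts=None):
    bags = [BagSample(t_fill=t, conc_n2o=c) for t, c in zip(times, concs)]
    return ClosureEvent(chamber_id=chamber, treatment="NPK",
                        timestamp=ts or datetime(2024, 5, 14, 8),
                        bags=bags, air_temp=temp, pressure=p, chamber_height=h)


class TestComputeFlux:
    def test_ideal_gas_conversion_hand_value(self):
        """100 ppb/h at 25 °C, 101325 Pa, 0.3 m headspace → 34.33 µg m⁻² h⁻¹."""
        assert slope_to_flux(100.0, 25.0, 101325.0, 0.3) == pytest.approx(
            34.33, abs=0.01)

    def test_slope_flux_inverse_pair(self):
        f = 220.0
        s = flux_to_slope(f, 15.0, 96600.0, 0.3)
        assert slope_to_flux(s, 15.0, 96600.0, 0.3) == pytest.approx(f, rel=1e-12)

    def test_flat_concentrations_rejected_zero_flux(self):
        est = compute_flux(_event([330.0] * 4))
        assert est.flux == 0.0 and est.r2 is None and not est.accepted

    def test_noiseless_synthetic_recovery(self, noiseless_event):
        est = compute_flux(noiseless_event)
        assert est.flux == pytest.approx(103.0, rel=1e-9)
        assert est.accepted

    def test_exact_line_has_zero_se(self):
        slope = 120.0  # ppb/h
        concs = [330.0 + slope * t / 60.0 for t in (3.5, 7.25, 11.5, 14.25)]
        est = compute_flux(_event(concs))
        assert est.r2 == pytest.approx(1.0)
        assert est.se_flux == pytest.approx(0.0, abs=1e-6)

    def test_two_bags_minimum(self):
        bags = [BagSample(t_fill=3.5, conc_n2o=330.0)]
        with pytest.raises(ValueError):
            ClosureEvent("CH1", "NPK", datetime(2024, 5, 1), bags,
                         15.0, 96600.0, 0.3)

    def test_r2_gate_controls_acceptance(self):
        concs = [330.0, 345.0, 331.0, 360.0]  # scattered
        est = compute_flux(_event(concs), r2_min=0.99)
        assert not est.accepted
        est2 = compute_flux(_event(concs), r2_min=0.1)
        assert est2.accepted

    @settings(max_examples=40, deadline=None)
    @given(scale=st.floats(0.1, 10.0))
    def test_flux_linear_in_slope_and_height(self, scale):
        base = slope_to_flux(100.0, 15.0, 96600.0, 0.3)
        assert slope_to_flux(100.0 * scale, 15.0, 96600.0, 0.3) == pytest.approx(
            base * scale, rel=1e-12)
        assert slope_to_flux(100.0, 15.0, 96600.0, 0.3 * scale) == pytest.approx(
            base * scale, rel=1e-12)


class TestWeeklyMeanFlux:
    def _estimate(self, flux, se=0.0, chamber="CH1", ts=None):
        return FluxEstimate(flux=flux, slope=0.0, r2=0.95, se_flux=se,
                            accepted=True, n_bags=4, chamber_id=chamber,
                            treatment="NPK",
                            timestamp=ts or datetime(2024, 5, 14, 8))

    def test_single_chamber_regression_se_only(self):
        ests = [self._estimate(100.0, se=2.5) for _ in range(3)]
        wk = weekly_mean_flux(ests, grouping="chamber")
        assert len(wk) == 1
        assert wk["mean_flux"].iloc[0] == pytest.approx(100.0)
        assert wk["se_flux"].iloc[0] == pytest.approx(2.5)

    def test_three_chambers_between_chamber_se(self):
        """Chambers at 100/103/106 with zero fit SE → SE = 3/√3 = 1.732."""
        ests = [self._estimate(f, se=0.0, chamber=c)
                for f, c in zip((100.0, 103.0, 106.0), ("C1", "C2", "C3"))]
        wk = weekly_mean_flux(ests, grouping="treatment")
        assert wk["mean_flux"].iloc[0] == pytest.approx(103.0)
        assert wk["se_flux"].iloc[0] == pytest.approx(3.0 / np.sqrt(3), rel=1e-9)

    def test_rejected_estimates_drop_out(self):
        ests = [self._estimate(100.0)]
        rejected = FluxEstimate(flux=500.0, slope=0.0, r2=0.2, se_flux=0.0,
                                accepted=False, n_bags=4, chamber_id="CH1",
                                treatment="NPK",
                                timestamp=datetime(2024, 5, 14, 8))
        wk = weekly_mean_flux(ests + [rejected])
        assert wk["mean_flux"].iloc[0] == pytest.approx(100.0)

    def test_all_rejected_week_absent(self):
        rejected = FluxEstimate(flux=500.0, slope=0.0, r2=0.2, se_flux=0.0,
                                accepted=False, n_bags=4, chamber_id="CH1",
                                treatment="NPK",
                                timestamp=datetime(2024, 5, 14, 8))
        assert weekly_mean_flux([rejected]).empty


def _weekly_frame(values, start=datetime(2024, 1, 1)):
    rows = []
    for i, v in enumerate(values):
        ws = start + timedelta(days=7 * i)
        rows.append(dict(group="NPK", iso_year=ws.isocalendar()[0],
                         iso_week=ws.isocalendar()[1], week_start=ws,
                         mean_flux=v, se_flux=0.0, n=1))
    return pd.DataFrame(rows)


class TestCumulativeFlux:
    def test_constant_year_hand_value(self):
        """100 µg m⁻² h⁻¹ held for 365 d integrates to 8.76 kg N ha⁻¹."""
        wk = _weekly_frame([100.0] * 52)
        start = wk["week_start"].iloc[0]
        total = cumulative_flux(wk, period=(start, start + timedelta(days=365)))
        assert total == pytest.approx(100.0 * 8760 * 1e-5, rel=1e-9)

    def test_zero_flux_integrates_to_zero(self):
        wk = _weekly_frame([0.0] * 10)
        assert cumulative_flux(wk) == 0.0

    def test_gap_interpolation_matches_numeric_oracle(self):
        """Triangular decline across a 3-week gap equals brute-force quadrature."""
        rows = _weekly_frame([200.0]).iloc[:1]
        later = _weekly_frame([0.0], start=datetime(2024, 1, 29))
        wk = pd.concat([rows, later], ignore_index=True)
        got = cumulative_flux(wk)
        # oracle: dense hourly sampling of the documented step+linear rule
        t0 = wk["week_start"].iloc[0]
        hours = np.arange(0, 35 * 24 + 1)
        nodes_t = np.array([0, 7 * 24, 28 * 24, 35 * 24], dtype=float)
        nodes_v = np.array([200.0, 200.0, 0.0, 0.0])
        dense = np.interp(hours, nodes_t, nodes_v)
        oracle = np.trapezoid(dense, hours) * 1e-5
        assert got == pytest.approx(oracle, rel=1e-6)

    def test_cumulative_nondecreasing_in_period(self):
        wk = _weekly_frame([50.0, 120.0, 80.0, 0.0, 30.0])
        start = wk["week_start"].iloc[0]
        totals = [cumulative_flux(wk, period=(start, start + timedelta(days=d)))
                  for d in (7, 14, 21, 28, 35)]
        assert all(b >= a for a, b in zip(totals, totals[1:]))

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            cumulative_flux(_weekly_frame([]))


class TestEstimatorCalibration:
    def test_unbiased_at_reference_noise(self):
        """1000 noisy closures at 1 ppb: |bias| < 2%, SE tracks empirical sd."""
        rng = np.random.default_rng(2024)
        ests, ses = [], []
        for _ in range(1000):
            sc = TrueScenario(flux_true=103.0, noise_conc=1.0, noise_delta=0.0)
            ev = generate_closure(sc, rng=np.random.default_rng(
                int(rng.integers(2**31))))
            est = compute_flux(ev)
            ests.append(est.flux)
            ses.append(est.se_flux)
        ests = np.asarray(ests)
        assert abs(ests.mean() - 103.0) / 103.0 < 0.02
        assert abs(np.mean(ses) - ests.std()) / ests.std() < 0.2
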