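"""Generator correctness: mixing identities, Rayleigh math, VWC structure."""

import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from n2osource import (PathwayMixSpec, TrueScenario, generate_campaign,
                       generate_closure, generate_model_daily,
                       generate_vwc_series, generate_weather_series,
                       mix_and_reduce)
from n2osource.fluxes import compute_flux
from n2osource.keeling import fit_keeling
from n2osource.soil_water import wfps_from_vwc


class TestGenerateClosure:
    def test_zero_flux_keeps_bags_at_ambient(self):
        sc = TrueScenario(flux_true=0.0, noise_conc=0.0, noise_delta=0.0)
        ev = generate_closure(sc)
        for bag in ev.bags:
            assert bag.conc_n2o == pytest.approx(sc.ambient_conc, abs=1e-12)
            assert bag.d15a == pytest.approx(sc.ambient_d15a, abs=1e-12)
            assert bag.d15b == pytest.approx(sc.ambient_d15b, abs=1e-12)
            assert bag.d18o == pytest.approx(sc.ambient_d18o, abs=1e-12)

    def test_noiseless_bags_lie_on_keeling_line(self, noiseless_event,
                                                noiseless_scenario):
        """Exact conservative mixing puts (1/C, δ) on a line through the source."""
        for channel, truth in (("d15a", 5.0), ("d15b", -12.0), ("d18o", 28.0)):
            fit = fit_keeling(noiseless_event, channel)
            assert fit.intercept == pytest.approx(truth, abs=1e-9)
            assert fit.r2 == pytest.approx(1.0, abs=1e-9)

    def test_noiseless_flux_round_trip(self, noiseless_event):
        est = compute_flux(noiseless_event)
        assert est.flux == pytest.approx(103.0, rel=1e-9)

    def test_same_seed_reproduces_bags_exactly(self):
        sc = TrueScenario(seed=7)
        a, b = generate_closure(sc), generate_closure(sc)
        assert [v.conc_n2o for v in a.bags] == [v.conc_n2o for v in b.bags]
        assert [v.d15a for v in a.bags] == [v.d15a for v in b.bags]

    def test_invalid_bag_times_rejected(self):
        sc = TrueScenario()
        with pytest.raises(ValueError):
            generate_closure(sc, bag_times=[5.0, 3.0, 8.0])
        with pytest.raises(ValueError):
            generate_closure(sc, bag_times=[3.0, 8.0, 20.0])

    def test_negative_scenario_fields_rejected(self):
        with pytest.raises(ValueError):
            TrueScenario(flux_true=-1.0)
        with pytest.raises(ValueError):
            TrueScenario(noise_conc=-0.5)


class TestMixAndReduce:
    def test_pure_denitrification_returns_den_endmember(self):
        mix = PathwayMixSpec(f_den=1.0, reduction_r=0.0)
        sp, bulk = mix_and_reduce(mix)
        assert sp == mix.endmember_sp_den
        assert bulk == mix.endmember_bulk_den

    def test_even_mixture_is_midpoint(self):
        mix = PathwayMixSpec(f_den=0.5, endmember_sp_den=-5.0,
                             endmember_sp_nit=35.0, reduction_r=0.0)
        sp, _ = mix_and_reduce(mix)
        assert sp == pytest.approx(15.0)

    def test_rayleigh_shift_hand_value(self):
        """ε=-5 ‰ at half the pool reduced shifts SP by -5·ln(0.5)=3.466 ‰."""
        mix = PathwayMixSpec(f_den=1.0, endmember_sp_den=0.0,
                             reduction_r=0.5, eps_sp_red=-5.0)
        sp, _ = mix_and_reduce(mix)
        assert sp == pytest.approx(-5.0 * math.log(0.5), abs=1e-9)

    def test_full_reduction_rejected(self):
        with pytest.raises(ValueError):
            PathwayMixSpec(reduction_r=1.0)

    @settings(max_examples=50, deadline=None)
    @given(r1=st.floats(0.0, 0.9), r2=st.floats(0.0, 0.9))
    def test_emitted_sp_monotone_in_reduction(self, r1, r2):
        lo, hi = sorted((r1, r2))
        if hi - lo < 1e-9:
            return
        sp_lo, _ = mix_and_reduce(PathwayMixSpec(reduction_r=lo))
        sp_hi, _ = mix_and_reduce(PathwayMixSpec(reduction_r=hi))
        assert sp_hi > sp_lo

    @settings(max_examples=50, deadline=None)
    @given(f1=st.floats(0.0, 1.0), f2=st.floats(0.0, 1.0))
    def test_emitted_sp_monotone_in_nitrification_share(self, f1, f2):
        lo, hi = sorted((f1, f2))
        if hi - lo < 1e-9:
            return
        sp_more_den, _ = mix_and_reduce(PathwayMixSpec(f_den=hi))
        sp_less_den, _ = mix_and_reduce(PathwayMixSpec(f_den=lo))
        assert sp_less_den > sp_more_den   # sp_nit > sp_den


class TestGenerateCampaign:
    def test_constant_flux_campaign_shares_true_source(self):
        events = generate_campaign(6, [150.0] * 6, PathwayMixSpec(), seed=1)
        assert len(events) == 6
        hours = {(b - a).total_seconds() / 3600
                 for a, b in zip([e.timestamp for e in events],
                                 [e.timestamp for e in events][1:])}
        assert hours == {4.0}

    def test_pure_den_campaign_sp_equals_endmember(self):
        mix = PathwayMixSpec(f_den=1.0, reduction_r=0.0)
        events = generate_campaign(3, [200.0] * 3, mix,
                                   template=TrueScenario(noise_conc=0.0,
                                                         noise_delta=0.0),
                                   seed=2)
        for ev in events:
            a = fit_keeling(ev, "d15a").intercept
            b = fit_keeling(ev, "d15b").intercept
            assert (a - b) == pytest.approx(mix.endmember_sp_den, abs=1e-9)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            generate_campaign(3, [100.0] * 4, PathwayMixSpec())


class TestGenerateVwcSeries:
    def test_no_excursions_no_threshold_days(self, config):
        df = generate_vwc_series(days=5, noise=0.0)
        wfps = wfps_from_vwc(df["vwc"].to_numpy(), config.bulk_density)
        assert np.all(wfps < config.fc_wfps)
        assert np.all(wfps > config.wp_wfps)

    def test_requested_day_counts_exact(self, config):
        wet = range(3, 20)   # 17 wet days
        dry = range(40, 50)  # 10 dry days
        df = generate_vwc_series(days=60, wet_days=wet, dry_days=dry, noise=0.0)
        daily = df.groupby(df["timestamp"].dt.normalize())["vwc"].mean()
        wfps = wfps_from_vwc(daily.to_numpy(), config.bulk_density)
        assert int(np.sum(wfps >= config.fc_wfps)) == 17
        assert int(np.sum(wfps <= config.wp_wfps)) == 10

    def test_vwc_at_field_capacity_boundary_counts(self, config):
        porosity = 1 - config.bulk_density / config.particle_density
        df = generate_vwc_series(days=4, wet_days=range(4), noise=0.0)
        wfps = wfps_from_vwc(df["vwc"].to_numpy(), config.bulk_density)
        assert np.all(wfps >= config.fc_wfps)

    def test_overlapping_wet_dry_rejected(self):
        with pytest.raises(ValueError):
            generate_vwc_series(days=10, wet_days=[2, 3], dry_days=[3, 4])

    def test_cadence_is_15_minutes(self):
        df = generate_vwc_series(days=1)
        assert len(df) == 96
        step = df["timestamp"].diff().dropna().unique()
        assert len(step) == 1 and step[0] == np.timedelta64(15, "m")


class TestAuxGenerators:
    def test_weather_series_deterministic_and_plausible(self):
        a = generate_weather_series(days=365, seed=3)
        b = generate_weather_series(days=365, seed=3)
        assert a.equals(b)
        assert (a["tmax_c"] >= a["tmin_c"]).all()
        assert (a["precip_mm"] >= 0).all()

    def test_model_daily_pathway_split_consistent(self):
        df = generate_model_daily(days=365, f_den=0.85, seed=4)
        np.testing.assert_allclose(df["n2o_total"],
                                   df["n2o_nit"] + df["n2o_denit"], rtol=1e-12)
        assert df["n2o_total"].sum() * 1e-3 == pytest.approx(0.63, rel=1e-9)
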