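"""Monte-Carlo source partition, dual-isotope coordinates, reduction line."""

import math
from datetime import datetime

import numpy as np
import pandas as pd
import pytest

from n2osource.config import EndmemberBox, ReductionModel
from n2osource.keeling import SourceSignature
from n2osource.partition import (PartitionResult, UnidentifiableError,
                                 dual_isotope_coordinates,
                                 monte_carlo_partition, partition_table,
                                 reduction_line)

POINT_DEN = EndmemberBox("bD+nD", sp_range=(-5.0, -5.0),
                         bulk_range=(-20.0, -20.0))
POINT_NIT = EndmemberBox("Ni", sp_range=(35.0, 35.0),
                         bulk_range=(-35.0, -35.0))
NO_REDUCTION = ReductionModel(r_max=0.0)


def _sig(sp: float, bulk: float, ts=None) -> SourceSignature:
    return SourceSignature(chamber_id="CH1", timestamp=ts,
                           d15a_src=bulk + sp / 2, d15b_src=bulk - sp / 2,
                           d18o_src=None, quality="Q1", flux=150.0)


class TestMonteCarloPartition:
    def test_midpoint_sp_gives_even_split(self):
        """SP 15 ‰ between point endmembers −5 and +35 → f_den = 0.5."""
        res = monte_carlo_partition(_sig(15.0, -27.5), (POINT_DEN, POINT_NIT),
                                    NO_REDUCTION, n_draws=100_000, seed=1,
                                    obs_sd_sp=0.5, obs_sd_bulk=0.5)
        assert res.f_den_mean == pytest.approx(0.5, abs=0.01)
        assert res.f_den_mean + res.f_nit_mean == pytest.approx(1.0, abs=1e-12)

    def test_signature_inside_den_box_attributed_to_denitrification(self):
        den = EndmemberBox("bD+nD", (-5.0, 5.0), (-45.0, 5.0))
        nit = EndmemberBox("Ni", (33.0, 38.0), (-60.0, -10.0))
        res = monte_carlo_partition(_sig(0.0, -20.0), (den, nit),
                                    NO_REDUCTION, n_draws=20_000, seed=2)
        assert res.f_den_mean > 0.9

    def test_identical_sp_ranges_unidentifiable(self):
        box = EndmemberBox("x", (0.0, 5.0), (-30.0, 0.0))
        with pytest.raises(UnidentifiableError):
            monte_carlo_partition(_sig(2.0, -15.0), (box, box), NO_REDUCTION)

    def test_too_few_draws_rejected(self):
        with pytest.raises(ValueError):
            monte_carlo_partition(_sig(15.0, -27.5), (POINT_DEN, POINT_NIT),
                                  NO_REDUCTION, n_draws=100)

    def test_fixed_seed_bit_identical(self):
        a = monte_carlo_partition(_sig(10.0, -25.0), (POINT_DEN, POINT_NIT),
                                  NO_REDUCTION, n_draws=5000, seed=7)
        b = monte_carlo_partition(_sig(10.0, -25.0), (POINT_DEN, POINT_NIT),
                                  NO_REDUCTION, n_draws=5000, seed=7)
        assert a == b

    def test_f_den_monotone_nonincreasing_in_sp(self):
        """More nitrification-like SP ⇒ smaller denitrification fraction."""
        means = [monte_carlo_partition(_sig(sp, -25.0),
                                       (POINT_DEN, POINT_NIT), NO_REDUCTION,
                                       n_draws=20_000, seed=3).f_den_mean
                 for sp in (0.0, 10.0, 20.0, 30.0)]
        assert all(b < a for a, b in zip(means, means[1:]))

    def test_reduction_prior_widens_interval(self):
        no_red = monte_carlo_partition(_sig(10.0, -25.0),
                                       (POINT_DEN, POINT_NIT), NO_REDUCTION,
                                       n_draws=20_000, seed=4)
        with_red = monte_carlo_partition(_sig(10.0, -25.0),
                                         (POINT_DEN, POINT_NIT),
                                         ReductionModel(r_max=0.8),
                                         n_draws=20_000, seed=4)
        assert (with_red.ci95_den[1] - with_red.ci95_den[0]
                > no_red.ci95_den[1] - no_red.ci95_den[0])

    def test_percentiles_retained_unclipped(self):
        """A signature beyond the den endmember yields CI bounds above 1."""
        res = monte_carlo_partition(_sig(-8.0, -20.0), (POINT_DEN, POINT_NIT),
                                    NO_REDUCTION, n_draws=20_000, seed=5)
        assert res.ci95_den[1] > 1.0
        assert res.f_den_mean <= 1.0


class TestDualIsotopeCoordinates:
    def _weather(self, dates, rain):
        return pd.DataFrame({"date": dates, "precip_mm": rain})

    def test_zero_rain_everywhere(self):
        dates = pd.date_range("2024-05-01", periods=30)
        sig = _sig(10.0, -25.0, ts=datetime(2024, 5, 20))
        out = dual_isotope_coordinates([sig], self._weather(dates, 0.0))
        assert out["rain7d"].iloc[0] == 0.0
        assert out["sp"].iloc[0] == pytest.approx(10.0)

    def test_week_of_daily_millimetres_sums_to_seven(self):
        dates = pd.date_range("2024-05-01", periods=30)
        sig = _sig(10.0, -25.0, ts=datetime(2024, 5, 20))
        out = dual_isotope_coordinates([sig], self._weather(dates, 1.0))
        assert out["rain7d"].iloc[0] == pytest.approx(7.0)

    def test_window_is_half_open_seven_days(self):
        """Rain exactly 8 days before sampling is outside (t−7d, t]."""
        dates = pd.date_range("2024-05-01", periods=30)
        rain = np.zeros(30)
        t = datetime(2024, 5, 20)
        rain[list(dates).index(pd.Timestamp("2024-05-12"))] = 5.0  # day -8
        out = dual_isotope_coordinates([_sig(1.0, -20.0, ts=t)],
                                       self._weather(dates, rain))
        assert out["rain7d"].iloc[0] == 0.0
        # brute-force oracle over the stated window
        rain[list(dates).index(pd.Timestamp("2024-05-13"))] = 2.0  # day -7: out
        rain[list(dates).index(pd.Timestamp("2024-05-14"))] = 4.0  # day -6: in
        rain[list(dates).index(pd.Timestamp("2024-05-20"))] = 3.0  # day 0: in
        out2 = dual_isotope_coordinates([_sig(1.0, -20.0, ts=t)],
                                        self._weather(dates, rain))
        brute = sum(r for d, r in zip(dates, rain)
                    if pd.Timestamp(t) - pd.Timedelta(days=7) < d <= pd.Timestamp(t))
        assert out2["rain7d"].iloc[0] == pytest.approx(brute) == pytest.approx(7.0)

    def test_missing_weather_yields_nan(self):
        out = dual_isotope_coordinates([_sig(1.0, -20.0,
                                             ts=datetime(2024, 5, 20))], None)
        assert np.isnan(out["rain7d"].iloc[0])


class TestReductionLine:
    RED = ReductionModel(eps_sp=-5.0, eps_bulk=-7.0, r_max=0.9)

    def test_r_zero_is_start_point(self):
        line = reduction_line((10.0, -25.0), self.RED, [0.0])
        assert line["sp"].iloc[0] == 10.0
        assert line["bulk"].iloc[0] == -25.0

    def test_sp_shift_hand_value(self):
        line = reduction_line((0.0, 0.0), self.RED, [0.5])
        assert line["sp"].iloc[0] == pytest.approx(-5.0 * math.log(0.5))

    def test_slope_is_eps_ratio_everywhere(self):
        line = reduction_line((10.0, -25.0), self.RED,
                              np.linspace(0.0, 0.8, 9))
        dsp = np.diff(line["sp"])
        dbulk = np.diff(line["bulk"])
        np.testing.assert_allclose(dsp / dbulk, 5.0 / 7.0, rtol=1e-12)

    def test_r_of_one_rejected(self):
        with pytest.raises(ValueError):
            reduction_line((0.0, 0.0), self.RED, [0.5, 1.0])


def test_partition_table_shape():
    res = PartitionResult(date=datetime(2024, 5, 14), f_den_mean=0.9,
                          f_nit_mean=0.1, ci95_den=(0.3, 1.6),
                          ci95_nit=(-0.6, 0.7), n_draws=1000, seed=1)
    df = partition_table([res])
    assert list(df.columns)[:4] == ["date", "f_den_mean", "f_den_lo", "f_den_hi"]
    assert df["f_den_mean"].iloc[0] + df["f_nit_mean"].iloc[0] == pytest.approx(1.0)
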