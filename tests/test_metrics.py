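"""Exposure indices, efficiency statistic, wind-rose binning."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from facesim.metrics import (
    DEFAULT_THRESHOLDS,
    IndexThresholds,
    aot40,
    exposure_summary,
    load_efficiency_archive,
    sum06,
    target_percentages,
    w126,
    w126_weight,
    wind_rose,
)
from facesim.species import UnitError

from conftest import make_minutes


def hourly_o3(values, start="2009-07-01 09:00"):
    ts = pd.Timestamp(start) + pd.to_timedelta(np.arange(len(values)), unit="h")
    return pd.DataFrame(
        {"hour": ts, "plot_id": 2, "species": "O3", "mean": values,
         "median": values, "n_valid": 60}
    )


class TestExposureIndices:
    def test_aot40_all_below_threshold(self):
        assert aot40(hourly_o3([35.0, 40.0, 28.0])) == 0.0  # 40 itself: strict >

    def test_aot40_hand_sum(self):
        # (45-40) + (80-40) = 45 ppb.h = 0.045 ppm.h
        assert aot40(hourly_o3([35.0, 45.0, 80.0])) == pytest.approx(0.045, rel=1e-9)

    def test_aot40_below_threshold_invariance(self):
        base = hourly_o3([35.0, 45.0, 80.0])
        extended = hourly_o3([35.0, 45.0, 80.0, 39.0])
        assert aot40(extended) == aot40(base)

    def test_sum06_strict_threshold(self):
        assert sum06(hourly_o3([55.0, 60.0, 59.0])) == 0.0

    def test_sum06_sums_full_concentrations(self):
        # 61 + 70 = 131 ppb.h = 0.131 ppm.h (full values, not the excess)
        assert sum06(hourly_o3([55.0, 61.0, 70.0])) == pytest.approx(0.131, rel=1e-9)
        assert sum06(hourly_o3([100.0])) == pytest.approx(0.100, rel=1e-9)

    def test_sum06_inclusive_variant(self):
        inclusive = IndexThresholds(sum06_inclusive=True)
        assert sum06(hourly_o3([60.0]), inclusive) == pytest.approx(0.060, rel=1e-9)

    def test_w126_weight_limits(self):
        assert w126_weight(0.0) == pytest.approx(1.0 / 4404.0, rel=1e-9)
        assert w126_weight(10.0) == pytest.approx(1.0, abs=1e-12)

    def test_w126_single_hour(self):
        # 0.1 * 1/(1 + 4403*e^(-12.6)), evaluated independently
        assert w126(hourly_o3([100.0])) == pytest.approx(0.098537022495, rel=1e-9)

    def test_daylight_window_is_8_to_19_inclusive(self):
        hours = hourly_o3([100.0] * 24, start="2009-07-01 00:00")
        # only hours labelled 08..19 contribute: 12 of 24
        assert sum06(hours) == pytest.approx(1.2, rel=1e-9)
        assert exposure_summary(hours, "x").n_hours_used == 12

    def test_missing_hours_skipped(self):
        h = hourly_o3([100.0, np.nan, 100.0])
        assert sum06(h) == pytest.approx(0.200, rel=1e-9)

    def test_co2_input_rejected(self):
        h = hourly_o3([100.0]).assign(species="CO2")
        with pytest.raises(UnitError):
            aot40(h)

    @given(
        values=st.lists(st.floats(0, 300), min_size=1, max_size=40),
        bump=st.floats(0, 50),
        index=st.sampled_from([aot40, sum06, w126]),
    )
    def test_indices_nonnegative_and_monotone(self, values, bump, index):
        base = hourly_o3(values)
        raised = hourly_o3([v + bump for v in values])
        lo, hi = index(base), index(raised)
        assert lo >= 0.0
        assert hi >= lo - 1e-12

    @given(c=st.floats(0.001, 0.12))
    def test_w126_weight_increasing_and_bounded(self, c):
        # restricted to concentrations where the strict bound is resolvable
        # in double precision (the weight rounds to 1.0 above ~0.2 ppm)
        w_lo, w_hi = w126_weight(c), w126_weight(c * 1.01)
        assert 0.0 < w_lo < w_hi < 1.0


class TestTargetPercentages:
    def test_worked_ten_minute_example(self):
        conc = [550, 560, 540, 600, 660, 661, 439, 441, 550, 550]
        rep = target_percentages(make_minutes(conc, setpoint=550.0))
        # inclusive bounds 495-605 and 440-660
        assert rep.minutes_on == 10
        assert rep.pct_within_10 == pytest.approx(60.0)
        assert rep.pct_within_20 == pytest.approx(80.0)

    def test_perfect_tracking_is_100pct(self):
        rep = target_percentages(make_minutes([550.0] * 20, setpoint=550.0))
        assert rep.pct_within_10 == 100.0 and rep.pct_within_20 == 100.0

    def test_off_minutes_excluded(self):
        on = make_minutes([550.0] * 5, system_on=True)
        off = make_minutes([9999.0] * 5, system_on=False, start="2009-07-01 09:00")
        rep = target_percentages(pd.concat([on, off], ignore_index=True))
        assert rep.minutes_on == 5
        assert rep.pct_within_10 == 100.0

    def test_zero_on_minutes_is_undefined_not_an_error(self):
        rep = target_percentages(make_minutes([550.0] * 5, system_on=False))
        assert rep.minutes_on == 0
        assert rep.pct_within_10 is None and rep.pct_within_20 is None

    @given(
        conc=st.lists(st.floats(300, 900), min_size=1, max_size=60),
        setpoint=st.floats(400, 700),
    )
    def test_nested_tolerances(self, conc, setpoint):
        rep = target_percentages(make_minutes(conc, setpoint=setpoint))
        assert 0.0 <= rep.pct_within_10 <= rep.pct_within_20 <= 100.0


class TestEfficiencyArchive:
    def test_covers_2001_to_2021(self):
        arch = load_efficiency_archive()
        assert list(arch["year"]) == list(range(2001, 2022))
        assert arch.loc[arch["year"] == 2001, "pct10_o3"].isna().all()
        row_2009 = arch.loc[arch["year"] == 2009].iloc[0]
        assert (row_2009["pct10_co2"], row_2009["pct20_co2"]) == (75.7, 89.8)

    def test_published_rows_satisfy_nested_tolerance(self):
        arch = load_efficiency_archive()
        assert (arch["pct10_co2"] <= arch["pct20_co2"]).all()
        o3 = arch.dropna(subset=["pct10_o3"])
        assert (o3["pct10_o3"] <= o3["pct20_o3"]).all()


class TestWindRose:
    def test_single_cell(self):
        wind = pd.DataFrame({"speed": [3.0] * 8, "direction": [90.0] * 8})
        rose = wind_rose(wind)
        assert rose.frequencies.loc[90, "2-4"] == 100.0
        assert rose.frequencies.to_numpy().sum() == pytest.approx(100.0)
        assert rose.calm_pct == 0.0
        assert rose.mean_speed == pytest.approx(3.0)

    def test_all_calm(self):
        wind = pd.DataFrame({"speed": [0.1] * 5, "direction": [0.0] * 5})
        rose = wind_rose(wind)
        assert rose.calm_pct == 100.0
        assert (rose.frequencies.to_numpy() == 0).all()

    def test_one_sample_per_sector(self):
        dirs = [i * 30.0 for i in range(12)]
        dirs[0] = 360.0  # north encoded as 360
        wind = pd.DataFrame({"speed": [1.0] * 12, "direction": dirs})
        rose = wind_rose(wind)
        per_sector = rose.frequencies.sum(axis=1)
        assert np.allclose(per_sector, 100.0 / 12)

    def test_sector_edges_plus_minus_15_degrees(self):
        wind = pd.DataFrame({"speed": [1.0, 1.0], "direction": [14.9, 15.1]})
        rose = wind_rose(wind)
        assert rose.frequencies.loc[0].sum() == 50.0
        assert rose.frequencies.loc[30].sum() == 50.0

    def test_speed_classes(self):
        wind = pd.DataFrame(
            {"speed": [1.0, 2.0, 4.0, 6.0, 9.0], "direction": [180.0] * 5}
        )
        rose = wind_rose(wind)
        row = rose.frequencies.loc[180]
        assert row["0-2"] == 20.0 and row["2-4"] == 20.0
        assert row["4-6"] == 20.0 and row[">6"] == 40.0

    def test_frequencies_plus_calm_sum_to_100(self):
        rng = np.random.default_rng(4)
        speed = rng.uniform(0, 8, 500)
        direction = rng.uniform(0.01, 360, 500)
        direction[speed < 0.5] = 0.0
        rose = wind_rose(pd.DataFrame({"speed": speed, "direction": direction}))
        assert rose.frequencies.to_numpy().sum() + rose.calm_pct == pytest.approx(100.0)
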