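"""Plot simulator: sector geometry, compartment dynamics, closed-loop runs."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest

from facesim.controller import DEFAULT_COEFFICIENTS, ControllerState, integral_limit_for, pid_step
from facesim.environment import AmbientParams, WindParams
from facesim.qc import DEFAULT_FILTER_WINDOWS, apply_filter
from facesim.registry import ExperimentConfig, SetpointSpec
from facesim.simulate import (
    CONTROL_DT,
    DEFAULT_PLOT_PARAMS,
    DEFAULT_VALVE_SCALE,
    CoverageError,
    FumigationSchedule,
    PlotParams,
    PlotState,
    concat_minutes,
    generate_environment,
    select_sector,
    simulate_experiment,
    steady_state_concentration,
    step_concentration,
)
from facesim.species import GasSpecies

CO2 = GasSpecies.CO2


def co2_config(days=1, setpoint=550.0, plots=(3,), year=2009):
    start = dt.date(year, 6, 19)
    return ExperimentConfig(
        year=year,
        treatment=frozenset({CO2}),
        crop="soybean",
        plot_setpoints={p: {CO2: SetpointSpec("constant", setpoint)} for p in plots},
        planting_date=start,
        treating_date=start,
        harvest_date=start + dt.timedelta(days=days),
    )


class TestSelectSector:
    def test_north_is_sector_zero_with_wrap_around_neighbors(self):
        main, w = select_sector(360.0)
        assert main == 0
        assert w[0] == 1.0 and w[1] == 0.5 and w[7] == 0.5
        assert w.sum() == pytest.approx(2.0)

    def test_east_is_sector_two(self):
        main, _ = select_sector(90.0)
        assert main == 2

    def test_calm_retains_previous_sector(self):
        main, w = select_sector(0.0, previous=5)
        assert main == 5 and w[5] == 1.0
        assert select_sector(0.0)[0] == 0  # no previous -> sector 0

    def test_out_of_range_direction_rejected(self):
        with pytest.raises(ValueError):
            select_sector(361.0)

    @pytest.mark.parametrize("direction", np.linspace(0.5, 360, 24))
    def test_weights_sum_and_support(self, direction):
        _, w = select_sector(direction, neighbor_weight=0.3)
        assert w.sum() == pytest.approx(1.0 + 2 * 0.3)
        assert (w > 0).sum() == 3


class TestStepConcentration:
    PARAMS = DEFAULT_PLOT_PARAMS[CO2]

    def test_equilibrium_at_ambient_with_valve_closed(self):
        state = PlotState(concentration=400.0)
        out = step_concentration(state, 0.0, 2.0, 400.0, self.PARAMS)
        assert out.concentration == 400.0

    def test_monotone_decay_toward_ambient(self):
        state = PlotState(concentration=700.0)
        prev = state.concentration
        for _ in range(200):
            state = step_concentration(state, 0.0, 2.0, 400.0, self.PARAMS)
            assert 400.0 <= state.concentration <= prev
            prev = state.concentration
        assert state.concentration == pytest.approx(400.0, abs=0.5)

    @pytest.mark.parametrize("valve,wind", [(2.0, 1.0), (5.0, 3.0), (1.0, 0.1)])
    def test_converges_to_closed_form_fixed_point(self, valve, wind):
        # oracle: C* = ambient + injection_gain*valve/d(ws), incl. low-wind rule
        target = steady_state_concentration(self.PARAMS, valve, wind, 400.0)
        state = PlotState(concentration=400.0)
        for _ in range(3000):
            state = step_concentration(state, valve, wind, 400.0, self.PARAMS)
        assert state.concentration == pytest.approx(target, rel=1e-6)

    def test_low_wind_rule_slows_dilution(self):
        slow = steady_state_concentration(self.PARAMS, 2.0, 0.1, 400.0)
        fast = steady_state_concentration(self.PARAMS, 2.0, 0.3, 400.0)
        assert slow > fast  # recirculation keeps more gas in the plot

    def test_concentration_floor_and_dt_validation(self):
        with pytest.raises(ValueError):
            step_concentration(PlotState(400.0), 0.0, 1.0, 400.0, self.PARAMS, dt=0.0)
        with pytest.raises(ValueError):
            PlotState(concentration=-1.0)


class TestClosedLoop:
    def test_always_off_schedule_tracks_ambient(self):
        cfg = co2_config()
        env = generate_environment(cfg, seed=1)
        res = simulate_experiment(cfg, env, schedule=FumigationSchedule(enabled=False))
        m = res[(3, CO2)]
        assert (m["valve_setting"] == 0).all()
        assert not m["system_on"].any()
        amb = env.ambient["co2"].to_numpy()
        assert np.allclose(m["concentration"], amb)

    def test_one_day_run_within_20pct_after_burn_in(self):
        cfg = co2_config()
        env = generate_environment(cfg, seed=1)
        m = res = simulate_experiment(cfg, env)[(3, CO2)]
        on = m[m["system_on"]].reset_index(drop=True).iloc[10:]  # 10-min burn-in
        frac = ((on["concentration"] - 550.0).abs() <= 0.2 * 550.0).mean()
        assert frac >= 0.90

    def test_steady_conditions_drive_tracking_error_to_zero(self):
        # constant wind and ambient: integral action removes the offset
        cfg = co2_config()
        env = generate_environment(
            cfg,
            seed=1,
            wind_params=WindParams(volatility=0.0),
            ambient_params=AmbientParams(co2_diurnal_amp=0.0, noise_sd=0.0),
        )
        m = simulate_experiment(cfg, env)[(3, CO2)]
        last_on = m[m["system_on"]].iloc[-30:]
        assert (last_on["concentration"] - 550.0).abs().max() < 2.0

    def test_combined_treatment_emits_two_streams_per_plot(self):
        start = dt.date(2003, 6, 17)
        cfg = ExperimentConfig(
            year=2003,
            treatment=frozenset({CO2, GasSpecies.O3}),
            crop="soybean",
            plot_setpoints={
                6: {
                    CO2: SetpointSpec("constant", 550.0),
                    GasSpecies.O3: SetpointSpec("ambient_multiple", 1.5),
                }
            },
            planting_date=start,
            treating_date=start,
            harvest_date=start + dt.timedelta(days=1),
        )
        env = generate_environment(cfg, seed=2)
        res = simulate_experiment(cfg, env)
        assert set(res) == {(6, CO2), (6, GasSpecies.O3)}
        o3 = res[(6, GasSpecies.O3)]
        on = o3[o3["system_on"]]
        # ambient-multiple setpoint: resolved against rolling ambient, not constant
        assert on["setpoint"].nunique() > 1
        roll = env.ambient["o3"].rolling(15, min_periods=1).mean()
        expected = 1.5 * roll[on.index]
        assert np.allclose(on["setpoint"], expected)

    def test_simulated_minutes_pass_filter_window(self):
        cfg = co2_config(days=2)
        env = generate_environment(cfg, seed=3)
        m = concat_minutes(simulate_experiment(cfg, env))
        mask = apply_filter(m, DEFAULT_FILTER_WINDOWS[CO2])
        assert mask.all()

    def test_off_minutes_have_closed_valve(self):
        cfg = co2_config()
        env = generate_environment(cfg, seed=1)
        m = simulate_experiment(cfg, env)[(3, CO2)]
        assert (m.loc[~m["system_on"], "valve_setting"] == 0).all()

    def test_env_gap_raises_coverage_error(self):
        cfg = co2_config(days=2)
        env = generate_environment(co2_config(days=1), seed=1)  # too short
        with pytest.raises(CoverageError, match="wind|ambient"):
            simulate_experiment(cfg, env)


def test_inlined_loop_matches_public_operation_chain():
    """The fast inner loop must agree step-for-step with chaining the public
    pid_step / select_sector / step_concentration operations."""
    cfg = co2_config()
    env = generate_environment(cfg, seed=11)
    schedule = FumigationSchedule(start_hour=8, end_hour=9)
    m = simulate_experiment(cfg, env, schedule=schedule)[(3, CO2)]

    params = DEFAULT_PLOT_PARAMS[CO2]
    coeffs = DEFAULT_COEFFICIENTS[CO2]
    scale = DEFAULT_VALVE_SCALE[CO2]
    ilim = integral_limit_for(scale, coeffs.ki)
    speed = env.wind[3]["speed"].to_numpy()
    direction = env.wind[3]["direction"].to_numpy()
    amb = env.ambient["co2"].to_numpy()

    w_start, w_end, tail = 8 * 60, 9 * 60, 15
    conc = amb[w_start]
    ctrl = ControllerState()
    sector = None
    ref_conc, ref_valve = [], []
    for minute in range(w_start, w_end + tail):
        on = minute < w_end
        c_sum = v_sum = 0.0
        for k in range(15):
            i4 = minute * 15 + k
            if on:
                cmd, ctrl = pid_step(
                    coeffs, ctrl, 550.0, conc, speed[i4], CONTROL_DT,
                    scale=scale, integral_limit=ilim,
                )
                valve = cmd.valve_setting
            else:
                valve = 0.0
            sector, _ = select_sector(direction[i4], previous=sector)
            state = step_concentration(
                PlotState(conc), valve, speed[i4], amb[minute], params, CONTROL_DT
            )
            conc = state.concentration
            c_sum += conc
            v_sum += valve
        ref_conc.append(c_sum / 15)
        ref_valve.append(v_sum / 15)

    got = m.iloc[w_start:w_end + tail]
    assert np.allclose(got["concentration"].to_numpy(), ref_conc, rtol=0, atol=1e-9)
    assert np.allclose(got["valve_setting"].to_numpy(), ref_valve, rtol=0, atol=1e-9)
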