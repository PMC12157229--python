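"""Closed-loop dynamics: recruitment curve, geometric loop recursion,
watchdog contract, stability dichotomy and reproducibility."""

import numpy as np
import pytest

from mecfes.closed_loop import (
    LoopState,
    PlantModel,
    SimResult,
    WatchdogConfig,
    find_critical_gain,
    loop_gain,
    recruitment_response,
    run_from_snapshot,
    run_sample_level_simulation,
    run_simulation,
    step_loop,
    watchdog_update,
)
from mecfes.dsp_chain import ControlParams, run_chain
from mecfes.errors import SweepNotFoundError
from mecfes.signal_model import ActivationProfile, ArtifactModel, NoiseModel, generate_volitional_mes
from mecfes.stim_engine import PulseSchedule, StimParams


def _plant(product, gain=60.0, noise=0.0):
    return PlantModel(residual_artifact_per_ma=product / gain, noise_floor_mv=noise)


def _control(gain=60.0):
    return ControlParams(off_mv=(0.0, 0.0),
                         gain_ma_per_mv=((gain, 0.0), (0.0, gain)))


class TestRecruitment:
    def test_zero_current_zero_activation(self):
        assert recruitment_response(0.0, PlantModel()) == 0.0

    def test_saturates_at_one(self):
        assert recruitment_response(1000.0, PlantModel()) == pytest.approx(1.0, abs=1e-9)

    def test_midpoint_matches_closed_form(self):
        p = PlantModel(recruitment_i50_ma=15.0, recruitment_slope_ma=2.0)
        s0 = 1 / (1 + np.exp(15.0 / 2.0))
        expected = (0.5 - s0) / (1 - s0)
        assert recruitment_response(15.0, p) == pytest.approx(expected, rel=1e-12)

    def test_monotone_nondecreasing(self):
        r = recruitment_response(np.linspace(0, 60, 200), PlantModel())
        assert np.all(np.diff(r) >= 0)

    def test_negative_current_rejected(self):
        with pytest.raises(ValueError):
            recruitment_response(-1.0, PlantModel())


class TestStepLoop:
    def test_origin_is_fixed_point(self, stim_params):
        state = LoopState.initial(2)
        for _ in range(10):
            state = step_loop(state, np.zeros(2), _control(), stim_params,
                              _plant(0.5))
        assert np.all(state.i_ma == 0.0)

    def test_subunity_product_decays_geometrically(self, stim_params):
        state = step_loop(LoopState.initial(2), np.array([0.1, 0.0]),
                          _control(), stim_params, _plant(0.5),
                          quantize=False, smooth=False)
        prev = state.i_ma[0]
        for _ in range(6):
            state = step_loop(state, np.zeros(2), _control(), stim_params,
                              _plant(0.5), quantize=False, smooth=False)
            assert state.i_ma[0] == pytest.approx(0.5 * prev, rel=1e-12)
            prev = state.i_ma[0]

    def test_superunity_product_grows_to_clamp(self, stim_params):
        state = step_loop(LoopState.initial(2), np.array([0.1, 0.0]),
                          _control(), stim_params, _plant(1.5),
                          quantize=False, smooth=False)
        for _ in range(20):
            state = step_loop(state, np.zeros(2), _control(), stim_params,
                              _plant(1.5), quantize=False, smooth=False)
        assert state.i_ma[0] == stim_params.current_limit_ma


class TestWatchdog:
    def test_below_threshold_never_trips(self, stim_params):
        cfg = WatchdogConfig(max_duration_s=0.3)
        state = LoopState.initial(1)
        state.i_ma = np.array([0.9 * cfg.max_fraction * stim_params.current_limit_ma])
        for _ in range(50):
            state = watchdog_update(state, cfg, stim_params, 0.06)
        assert not state.tripped.any() and state.trip_count == 0

    def test_trips_after_exact_duration(self, stim_params):
        cfg = WatchdogConfig(max_duration_s=0.3)
        state = LoopState.initial(1)
        state.v_meas_mv = np.array([1.0])  # drive stays high: no re-arm
        n_to_trip = int(np.ceil(0.3 / 0.06))
        for k in range(n_to_trip):
            state.i_ma = np.array([stim_params.current_limit_ma])
            state = watchdog_update(state, cfg, stim_params, 0.06)
        assert state.tripped.all()
        assert state.i_ma[0] == 0.0

    def test_latched_while_drive_high(self, stim_params):
        cfg = WatchdogConfig(max_duration_s=0.12)
        state = LoopState.initial(1)
        state.v_meas_mv = np.array([1.0])
        for _ in range(10):
            state.i_ma = np.where(state.tripped, 0.0,
                                  np.array([stim_params.current_limit_ma]))
            state = watchdog_update(state, cfg, stim_params, 0.06)
        assert state.tripped.all()
        assert state.trip_count == 1  # no chatter


class TestLoopGain:
    def test_product_formula(self):
        g = loop_gain(_control(2.0), PlantModel(residual_artifact_per_ma=0.5))
        assert np.allclose(g, 1.0)

    def test_no_feedback_path(self):
        assert np.all(loop_gain(_control(), _plant(0.0)) == 0.0)

    def test_dichotomy_matches_simulation(self, stim_params):
        for product, stable in [(0.8, True), (1.25, False)]:
            plant = _plant(product)
            assert (loop_gain(_control(), plant)[0] < 1) == stable
            state = step_loop(LoopState.initial(2), np.array([0.05, 0.0]),
                              _control(), stim_params, plant,
                              quantize=False, smooth=False)
            for _ in range(200):
                state = step_loop(state, np.zeros(2), _control(), stim_params,
                                  plant, quantize=False, smooth=False)
            if stable:
                assert state.i_ma[0] < 1e-6
            else:
                assert state.i_ma[0] == stim_params.current_limit_ma


class TestCriticalGain:
    def test_boundary_at_unity(self, stim_params):
        crit = find_critical_gain(_control(), stim_params, _plant(0.5),
                                  sweep=(0.5, 1.5), resolution=0.01)
        assert crit == pytest.approx(1.0, abs=0.01)

    def test_sweep_excluding_transition_raises(self, stim_params):
        with pytest.raises(SweepNotFoundError):
            find_critical_gain(_control(), stim_params, _plant(0.5),
                               sweep=(0.3, 0.9), duration_s=20.0)


class TestSimulation:
    def test_zero_profile_zero_output(self, stim_params):
        res = run_simulation(3.0, ActivationProfile.constant(0.0), _control(),
                             stim_params, _plant(0.0), noise=False)
        assert np.all(res.i_ma == 0.0) and np.all(res.force_n == 0.0)

    def test_stable_boxcar_tracks_profile(self, stim_params):
        prof = ActivationProfile.boxcar(2.0, 6.0, 0.5)
        res = run_simulation(10.0, prof, _control(), stim_params, _plant(0.0),
                             emg_rms_mv=0.5, noise=False)
        mid = res.i_ma[(res.times_s > 4) & (res.times_s < 6), 0]
        assert np.allclose(mid, 0.5 * 0.5 * 60.0, rtol=0.01)

    def test_unstable_run_trips_once_then_silent(self, stim_params):
        prof = ActivationProfile.boxcar(0.0, 0.12, 0.2, n_channels=1)
        control = ControlParams(off_mv=(0.0,), gain_ma_per_mv=((60.0,),))
        res = run_simulation(20.0, prof, control, stim_params, _plant(1.5),
                             WatchdogConfig(), emg_rms_mv=0.5, noise=False)
        assert len(res.trip_events) == 1
        t_trip = res.trip_events[0][0]
        assert np.all(res.i_ma[res.times_s > t_trip] == 0.0)

    def test_current_never_exceeds_limit(self, stim_params):
        prof = ActivationProfile.constant(1.0)
        res = run_simulation(10.0, prof, _control(100.0), stim_params,
                             _plant(1.5, gain=100.0), WatchdogConfig(), seed=5)
        assert np.all(res.i_ma <= stim_params.current_limit_ma + 1e-12)

    def test_bit_exact_reproduction_from_snapshot(self, stim_params):
        prof = ActivationProfile.boxcar(1.0, 3.0, 0.6)
        res = run_simulation(5.0, prof, _control(), stim_params,
                             _plant(0.5, noise=0.01), WatchdogConfig(), seed=42)
        res2 = run_from_snapshot(res.config, prof)
        assert np.array_equal(res.i_ma, res2.i_ma)
        assert np.array_equal(res.v_meas_mv, res2.v_meas_mv)


class TestSampleLevelLoop:
    def test_zero_coupling_matches_open_loop(self, quiet_noise, stim_params):
        """With no artifact coupling the closed loop must equal the open-loop
        chain run on the same volitional trace."""
        art = ArtifactModel(direct_artifact_amp_per_ma=0.0, mwave_amp_max_mv=0.0)
        cp = ControlParams(off_mv=(0.05, 0.05))
        prof = ActivationProfile.boxcar(1.0, 3.0, 0.8)
        res = run_sample_level_simulation(
            4.0, prof, quiet_noise, art, cp, stim_params, PlantModel(),
            fs=1000.0, include_mains=False)
        trace = generate_volitional_mes(prof, quiet_noise, 4.0, 1000.0)
        # open loop: same pulse grid (timing only; amplitudes are irrelevant
        # because coupling is zero), same params
        from mecfes.stim_engine import periodic_commands, schedule_pulses
        sched = schedule_pulses(periodic_commands(0.0, 4.0, stim_params), stim_params)
        open_res = run_chain(trace, sched, cp, stim_params)
        assert np.allclose(res.i_ma, open_res.commands_ma, atol=1e-12)

    def test_oscillation_flag_on_onoff_cycling(self, stim_params):
        fake = SimResult(
            times_s=np.arange(40) * 0.06,
            v_meas_mv=np.zeros((40, 1)), v_smooth_mv=np.zeros((40, 1)),
            i_ma=np.tile([30.0, 30.0, 0.0, 0.0], 10)[:, None],
            force_n=np.zeros((40, 1)))
        from mecfes.closed_loop import _detect_oscillation
        assert _detect_oscillation(fake.i_ma, 30.0)[0]
        assert not _detect_oscillation(np.full((40, 1), 30.0), 30.0)[0]
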