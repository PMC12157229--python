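"""Firmware chain stages against their closed forms: blanking sample
counts, comb nulls, RMS windows, smoother recursion and the control law."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from mecfes.dsp_chain import (
    ControlParams,
    Envelope,
    FirmwarePipeline,
    apply_blanking,
    comb_filter,
    control_drive,
    control_law,
    run_chain,
    smooth_envelope,
    windowed_rms,
)
from mecfes.signal_model import ActivationProfile, MesTrace, NoiseModel, add_mains_interference, generate_volitional_mes
from mecfes.stim_engine import PulseEvent, PulseSchedule, StimParams, periodic_commands, schedule_pulses

FS = 1000.0


def _ones_trace(n=60, n_ch=2):
    return MesTrace(np.ones((n_ch, n)), fs=FS)


class TestBlanking:
    def test_no_events_identity(self):
        tr = _ones_trace()
        out = apply_blanking(tr, PulseSchedule([]), 20.0)
        assert np.array_equal(out.samples, tr.samples)

    def test_zero_duration_identity(self):
        tr = _ones_trace()
        sched = PulseSchedule([PulseEvent(0.0, 0, 10.0, 300.0)])
        out = apply_blanking(tr, sched, 0.0)
        assert np.array_equal(out.samples, tr.samples)

    def test_exact_sample_count(self):
        # one event at the window start, 20 ms blank at 1 kHz -> 20 zeros
        tr = _ones_trace(60)
        sched = PulseSchedule([PulseEvent(0.0, 0, 10.0, 300.0)])
        out = apply_blanking(tr, sched, 20.0)
        assert int((out.samples[0] == 0).sum()) == 20
        assert np.all(out.samples[:, 20:] == 1.0)


class TestComb:
    def test_removes_dc(self):
        tr = MesTrace(np.full((1, 300), 3.7), fs=FS)
        out = comb_filter(tr, 60.0)
        assert np.all(out.samples[:, 60:] == 0.0)
        assert np.all(out.samples[:, :60] == 0.0)  # zero-padded head

    def test_nulls_mains_exactly(self):
        t = np.arange(1000) / FS
        tr = MesTrace(np.sin(2 * np.pi * 50.0 * t)[None, :], fs=FS)
        out = comb_filter(tr, 60.0)
        assert np.allclose(out.samples[:, 60:], 0.0, atol=1e-12)

    def test_nulls_any_period_synchronous_signal(self, rng):
        one_period = rng.standard_normal(60)
        tr = MesTrace(np.tile(one_period, 10)[None, :], fs=FS)
        out = comb_filter(tr, 60.0)
        assert np.allclose(out.samples[:, 60:], 0.0, atol=1e-12)

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            comb_filter(MesTrace(np.zeros((1, 30)), fs=FS), 60.0)


class TestWindowedRms:
    def test_zero_signal(self):
        env = windowed_rms(MesTrace(np.zeros((2, 600)), fs=FS), PulseSchedule([]), 20.0)
        assert np.all(env.values == 0.0)
        assert env.values.shape == (2, 10)

    def test_constant_over_nonblanked(self):
        tr = _ones_trace(120)
        tr.samples *= 2.5
        sched = PulseSchedule([PulseEvent(0.0, 0, 1.0, 300.0), PulseEvent(0.060, 0, 1.0, 300.0)])
        env = windowed_rms(apply_blanking(tr, sched, 20.0), sched, 20.0)
        assert np.allclose(env.values, 2.5)  # blanked samples excluded from count

    def test_sinusoid_integer_cycles(self):
        t = np.arange(60) / FS
        x = np.sin(2 * np.pi * 100.0 * t)  # 4 cycles in the 40 ms kept span
        tr = MesTrace(x[None, :], fs=FS)
        sched = PulseSchedule([PulseEvent(0.0, 0, 1.0, 300.0)])
        env = windowed_rms(apply_blanking(tr, sched, 20.0), sched, 20.0)
        assert env.values[0, 0] == pytest.approx(1 / np.sqrt(2), rel=1e-9)

    def test_fully_blanked_window_warns(self):
        tr = _ones_trace(60)
        sched = PulseSchedule([PulseEvent(0.0, 0, 1.0, 300.0),
                               PulseEvent(0.030, 0, 1.0, 300.0)])
        with pytest.warns(UserWarning):
            env = windowed_rms(tr, sched, 30.0)
        assert env.values[0, 0] == 0.0


class TestSmoothing:
    def test_constant_is_fixed_point(self):
        env = Envelope(np.full((1, 20), 0.4), np.arange(20) * 0.06, 0.06)
        out = smooth_envelope(env, 0.2)
        assert np.allclose(out.values, 0.4)

    def test_unit_step_closed_form(self):
        x = np.concatenate([[0.0], np.ones(30)])
        env = Envelope(x[None, :], np.arange(31) * 0.06, 0.06)
        out = smooth_envelope(env, 0.2)
        a = np.exp(-0.06 / 0.2)
        for k in (1, 5, 15, 30):
            assert out.values[0, k] == pytest.approx(1 - a**k, rel=1e-12)

    def test_tiny_tau_tends_to_identity(self):
        env = Envelope(np.array([[0.1, 0.9, 0.2, 0.7]]), np.arange(4) * 0.06, 0.06)
        out = smooth_envelope(env, 1e-6)
        assert np.allclose(out.values, env.values, atol=1e-9)


class TestControlLaw:
    def test_single_channel_arithmetic(self, stim_params):
        p = ControlParams(off_mv=(2.0, 0.0), gain_ma_per_mv=((3.0, 0.0), (0.0, 0.0)))
        drive = control_drive(np.array([10.0, 0.0]), p)
        assert drive[0] == pytest.approx(24.0)  # (10 - 2) * 3

    def test_flexor_inhibition_configuration(self, stim_params):
        p = ControlParams(off_mv=(0.0, 0.0), gain_ma_per_mv=((2.0, 0.0), (-2.0, 0.0)))
        drive = control_drive(np.array([5.0, 3.0]), p)
        assert drive[0] == pytest.approx(4.0)  # 5*2 + 3*(-2)

    def test_below_offset_rectified_to_zero(self, stim_params):
        p = ControlParams(off_mv=(2.0, 0.0), gain_ma_per_mv=((3.0, 0.0), (0.0, 0.0)))
        cmd = control_law(np.array([1.0, 0.0]), p, stim_params)
        assert cmd.currents_ma[0] == 0.0

    def test_clamped_and_quantized(self, stim_params):
        p = ControlParams(off_mv=(0.0, 0.0), gain_ma_per_mv=((100.0, 0.0), (0.0, 0.0)))
        cmd = control_law(np.array([5.0, 0.0]), p, stim_params)
        step = stim_params.dac_step_ma
        assert cmd.currents_ma[0] == pytest.approx(np.floor(30.0 / step) * step)

    @given(v=st.floats(0.0, 2.0), scale=st.floats(0.1, 5.0))
    def test_linearity_above_offset(self, v, scale):
        p = ControlParams(off_mv=(0.0, 0.0), gain_ma_per_mv=((3.0, 0.0), (0.0, 3.0)))
        d1 = control_drive(np.array([v, 0.0]), p)
        d2 = control_drive(np.array([scale * v, 0.0]), p)
        assert d2[0] == pytest.approx(scale * d1[0], rel=1e-9, abs=1e-12)

    @given(v1=st.floats(0.0, 2.0), dv=st.floats(0.0, 1.0))
    def test_monotone_in_inputs_for_nonnegative_gains(self, v1, dv):
        p = ControlParams()
        lo = control_drive(np.array([v1, 0.3]), p)
        hi = control_drive(np.array([v1 + dv, 0.3]), p)
        assert np.all(hi >= lo - 1e-12)


class TestPipeline:
    def test_silent_input_zero_command(self, stim_params):
        cp = ControlParams()
        pipe = FirmwarePipeline(cp, stim_params, FS)
        for _ in range(5):
            out = pipe.process_period(np.zeros((2, 60)), [(0.0, 0)])
            assert np.all(out.command.currents_ma == 0.0)

    def test_mains_only_zero_command(self, stim_params):
        cp = ControlParams(off_mv=(0.0, 0.0))
        noise = NoiseModel(mains_amp_mv=1.0, emg_rms_at_full_activation_mv=0.0)
        zero = MesTrace(np.zeros((2, 2000)), fs=FS)
        tr = add_mains_interference(zero, noise)
        res = run_chain(tr, PulseSchedule([]), cp, stim_params)
        assert np.all(res.commands_ma == 0.0)

    def test_blank_then_comb_order_pinned(self, stim_params, rng):
        # the pipeline's comb input is the blanked signal: reproduce its
        # output from the standalone stages applied in that order
        cp = ControlParams(off_mv=(0.0, 0.0))
        x = rng.standard_normal((2, 300))
        tr = MesTrace(x, fs=FS)
        sched = schedule_pulses(periodic_commands(10.0, 0.3, stim_params), stim_params)
        blanked = apply_blanking(tr, sched, cp.blank_ms)
        combed = comb_filter(blanked, stim_params.period_ms)
        env_expected = windowed_rms(combed, sched, cp.blank_ms, stim_params.period_ms)
        res = run_chain(tr, sched, cp, stim_params)
        assert np.allclose(res.envelope_raw.values, env_expected.values, atol=1e-12)

    def test_volitional_rms_recovered(self, quiet_noise, stim_params):
        # oracle: direct RMS of the generated volitional component
        cp = ControlParams(off_mv=(0.0, 0.0), gain_ma_per_mv=((2.0, 0.0), (0.0, 2.0)),
                           smooth_tau_s=1e-6)
        tr = generate_volitional_mes(ActivationProfile.constant(1.0), quiet_noise, 12.0, FS)
        res = run_chain(tr, PulseSchedule([]), cp, stim_params)
        target = quiet_noise.emg_rms_at_full_activation_mv
        # comb filtering of white-ish noise raises RMS by sqrt(2); skip the
    # first window (zero-history convention) and average the rest
        mean_v = res.envelope_raw.values[:, 1:].mean(axis=1)
        assert np.allclose(mean_v / np.sqrt(2), target, rtol=0.1)
        mean_cmd = res.commands_ma[1:].mean(axis=0)
        assert np.allclose(mean_cmd, 2.0 * mean_v, rtol=0.05)
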