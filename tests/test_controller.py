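import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from colligaze.config import ConfigError, ControllerParams
from colligaze.controller import (head_gain_and_delay, omr_soft_limit,
                                  plant_filter, plant_impulse_response,
                                  run_gaze_loop, vor_gain)
from colligaze.decoder import GazeTrace


@pytest.fixture(scope="module")
def params():
    return ControllerParams()


class TestOmrLimiter:
    def test_odd_and_zero_at_origin(self, params):
        assert omr_soft_limit(0.0, params) == 0.0
        assert omr_soft_limit(12.0, params) == -omr_soft_limit(-12.0, params)

    def test_closed_form_value(self, params):
        assert omr_soft_limit(10.0, params) == pytest.approx(30 * math.tanh(0.3))
        assert omr_soft_limit(10.0, params) == pytest.approx(8.7394, abs=1e-3)

    def test_saturates_at_the_oculomotor_range(self, params):
        assert omr_soft_limit(1e6, params) == pytest.approx(30.0)
        assert omr_soft_limit(-1e6, params) == pytest.approx(-30.0)

    @given(st.floats(min_value=-200, max_value=200), st.floats(min_value=-200, max_value=200))
    def test_monotone(self, a, b):
        params = ControllerParams()
        if a < b:
            assert omr_soft_limit(a, params) <= omr_soft_limit(b, params)


class TestVorGain:
    def test_fully_engaged_on_target(self, params):
        assert vor_gain(0.0, params) == pytest.approx(1.0)

    def test_suppressed_for_large_errors(self, params):
        assert vor_gain(1e4, params) == pytest.approx(0.0, abs=1e-12)

    def test_closed_form_value(self, params):
        assert vor_gain(23.105, params) == pytest.approx(0.4, abs=1e-4)

    def test_clipped_to_unit_interval(self, params):
        g = vor_gain(np.linspace(-100, 100, 201), params)
        assert g.min() >= 0.0 and g.max() <= 1.0


class TestHeadGainAndDelay:
    def test_straight_ahead_gain_half(self, params):
        g_H, _ = head_gain_and_delay(20.0, 0.0, params)
        assert g_H == pytest.approx(0.5)

    def test_base_delay(self, params):
        _, dT = head_gain_and_delay(0.0, 0.0, params)
        assert dT == pytest.approx(70.0)

    def test_bilinear_delay(self, params):
        _, dT = head_gain_and_delay(40.0, -10.0, params)
        assert dT == pytest.approx(51.2)

    def test_delay_floored_at_zero(self, params):
        _, dT = head_gain_and_delay(60.0, 35.0, params)
        assert dT == 0.0

    def test_negative_amplitude_rejected(self, params):
        with pytest.raises(ConfigError):
            head_gain_and_delay(-1.0, 0.0, params)


class TestPlant:
    def test_impulse_response_integrates_to_one(self):
        tau = np.arange(0, 5000.0, 0.1)
        h = plant_impulse_response(tau, 250.0, 150.0)
        assert np.trapezoid(h, tau) == pytest.approx(1.0, rel=1e-4)

    def test_impulse_peak_time_closed_form(self):
        T1, T2 = 250.0, 150.0
        tau = np.arange(0, 2000.0, 0.01)
        h = plant_impulse_response(tau, T1, T2)
        t_peak = T1 * T2 / (T1 - T2) * math.log(T1 / T2)
        assert tau[np.argmax(h)] == pytest.approx(t_peak, abs=0.02)

    def test_step_converges_to_unit_dc_gain(self):
        dt = 0.1
        step = np.full(int(5000 / dt), 100.0)
        out = plant_filter(step, 250.0, 150.0, dt)
        assert out[-1] == pytest.approx(100.0, rel=1e-3)

    def test_degenerate_kernel_rejected(self):
        with pytest.raises(ConfigError):
            plant_filter(np.ones(10), 100.0, 100.0, 0.1)
        with pytest.raises(ConfigError):
            plant_impulse_response(np.arange(3.0), 50.0, 50.0)


def _synthetic_trace(amplitude=20.0, t_on=20.0, dur=40.0, dt=1.0):
    """Raised-cosine desired velocity pulse decoding to ``amplitude``."""
    t = np.arange(0, 400.0, dt)
    v = np.zeros_like(t)
    inside = (t >= t_on) & (t <= t_on + dur)
    v[inside] = (1 - np.cos(2 * np.pi * (t[inside] - t_on) / dur)) / 2
    v *= amplitude / (np.trapezoid(v, t) / 1000.0)
    dG = np.cumsum(v) * dt / 1000.0
    return GazeTrace(t=t, delta_G=dG, g_dot_des=v, window=21, order=3)


class TestGazeLoop:
    def test_gaze_is_sum_of_eye_and_head(self, cond40):
        b = cond40.bundle
        assert np.allclose(b.G, b.E + b.H, atol=1e-12)
        assert np.allclose(b.Gdot, b.Edot + b.Hdot, atol=1e-12)

    def test_loop_identity(self, cond40):
        """Burst output equals eye velocity plus VOR-weighted head velocity."""
        b = cond40.bundle
        free = ~b.omr_clamped  # the identity holds while the eye is off its stop
        residual = b.edot_des - (b.Edot + b.g_v * b.Hdot)
        assert np.abs(residual[free]).max() < 1e-9
        assert free.mean() > 0.5

    def test_head_disabled_pins_head(self, config):
        from colligaze.experiment import simulate_condition
        res = simulate_condition(config, 20.0, 0.0, 0.0, head_enabled=False)
        b = res.bundle
        assert np.allclose(b.H, b.H[0])
        assert np.allclose(b.G - b.G[0], b.E - b.E[0])

    def test_oculomotor_range_respected(self, config):
        from colligaze.experiment import simulate_condition
        for amp, E0 in ((60.0, 0.0), (40.0, 20.0), (40.0, -20.0)):
            b = simulate_condition(config, amp, E0, 0.0).bundle
            assert np.abs(b.E).max() <= config.controller.omr_bound + 0.5

    def test_terminal_accuracy_synthetic_pulse(self):
        tr = _synthetic_trace(amplitude=20.0)
        b = run_gaze_loop(tr, 0.0, 0.0)
        assert b.G[-1] - b.G[0] == pytest.approx(20.0, rel=0.05)

    def test_head_delay_larger_for_contra_smaller_for_big_shifts(self):
        tr_small = _synthetic_trace(amplitude=10.0)
        tr_big = _synthetic_trace(amplitude=50.0)
        b_contra = run_gaze_loop(tr_small, -10.0, 0.0)
        b_ipsi = run_gaze_loop(tr_small, 10.0, 0.0)
        b_big = run_gaze_loop(tr_big, 0.0, 0.0)
        b_mid = run_gaze_loop(tr_small, 0.0, 0.0)
        assert b_contra.delta_T_H > b_ipsi.delta_T_H
        assert b_big.delta_T_H < b_mid.delta_T_H

    def test_eye_position_outside_range_rejected(self):
        tr = _synthetic_trace()
        with pytest.raises(ConfigError):
            run_gaze_loop(tr, 40.0, 0.0)

    def test_head_constant_before_gate(self, cond40):
        b = cond40.bundle
        before = b.t < b.t_head_gate
        assert np.allclose(b.H[before], b.H0)

    def test_contra_start_yields_faster_gaze_and_later_smaller_head(self, config):
        from colligaze.analysis import detect_movement
        from colligaze.experiment import simulate_condition
        out = {}
        for E0 in (-10.0, 10.0):
            b = simulate_condition(config, 40.0, E0, 0.0).bundle
            ev = detect_movement(b.t, b.G, b.Gdot, 20.0, 5.0)
            i_off = int(np.searchsorted(b.t, ev.offset))
            out[E0] = (ev.peak_velocity, b.delta_T_H, b.H[i_off] - b.H[0],
                       np.abs(b.E[:i_off] - b.E[0]).max())
        pk_c, dT_c, dH_c, dE_c = out[-10.0]
        pk_i, dT_i, dH_i, dE_i = out[10.0]
        assert pk_c > pk_i       # contralateral start is fastest
        assert dT_c > dT_i       # head starts later
        assert dH_c < dH_i       # and contributes less during the shift
        assert dE_c > dE_i       # while the eye contributes more
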