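import numpy as np
import pytest

from colligaze.analysis import (AnalysisError, NO_MOVEMENT, cumulative_count,
                                detect_movement, firing_rate,
                                fit_static_movement_field, main_sequence,
                                phase_trajectory, predict_dynamic_movement_field,
                                rate_velocity_correlation)
from colligaze.config import EfferentMap
from colligaze.decoder import afferent_coordinate


@pytest.fixture(scope="module")
def eff():
    return EfferentMap()


def _synthetic_counts(eff, N0=20.0, u0=2.85, sigma_p=0.47, eps=0.002,
                      amplitudes=np.arange(5.0, 56.0, 2.0),
                      E0s=(-20.0, 0.0, 20.0)):
    amps, e0s = np.meshgrid(amplitudes, E0s)
    amps, e0s = amps.ravel(), e0s.ravel()
    u = afferent_coordinate(amps, eff)
    counts = N0 * (1 + eps * e0s) * np.exp(-(u - u0) ** 2 / (2 * sigma_p ** 2))
    return counts, amps, e0s


class TestStaticMovementField:
    def test_noiseless_parameter_recovery(self, eff):
        counts, amps, e0s = _synthetic_counts(eff)
        mf = fit_static_movement_field(counts, amps, e0s, eff)
        assert mf.N0 == pytest.approx(20.0, rel=1e-6)
        assert mf.u0 == pytest.approx(2.85, rel=1e-6)
        assert mf.sigma_p == pytest.approx(0.47, rel=1e-6)
        assert mf.epsilon == pytest.approx(0.002, rel=1e-6)
        assert mf.r == pytest.approx(1.0, abs=1e-9)

    def test_eye_position_insensitive_counts_give_zero_eps(self, eff):
        counts, amps, e0s = _synthetic_counts(eff, eps=0.0)
        mf = fit_static_movement_field(counts, amps, e0s, eff)
        assert abs(mf.epsilon) < 1e-8

    def test_all_zero_counts_rejected(self, eff):
        _, amps, e0s = _synthetic_counts(eff)
        with pytest.raises(AnalysisError):
            fit_static_movement_field(np.zeros_like(amps), amps, e0s, eff)

    def test_too_few_trials_rejected(self, eff):
        with pytest.raises(AnalysisError):
            fit_static_movement_field([1.0, 2.0], [10.0, 20.0], [0.0, 0.0], eff)

    def test_recovery_with_distant_optimum(self, eff):
        # multi-start must find an optimum far from the count-weighted centre
        counts, amps, e0s = _synthetic_counts(eff, u0=1.2, sigma_p=0.3)
        mf = fit_static_movement_field(counts, amps, e0s, eff)
        assert mf.u0 == pytest.approx(1.2, rel=1e-4)


class TestDynamicMovementField:
    def test_prediction_reaches_static_count_at_movement_end(self, eff):
        counts, amps, e0s = _synthetic_counts(eff)
        mf = fit_static_movement_field(counts, amps, e0s, eff)
        t = np.arange(0, 200.0, 1.0)
        dG = 20.0 * np.clip(t / 100.0, 0, 1)  # ramp then plateau at 20 deg
        pred = predict_dynamic_movement_field(mf, t, dG, 20.0, 0.0, eff, lead=10.0)
        assert pred[-1] == pytest.approx(mf.predict([20.0], [0.0], eff)[0])

    def test_half_displacement_gives_half_count(self, eff):
        counts, amps, e0s = _synthetic_counts(eff)
        mf = fit_static_movement_field(counts, amps, e0s, eff)
        t = np.arange(0, 200.0, 1.0)
        dG = 20.0 * np.clip(t / 100.0, 0, 1)
        pred = predict_dynamic_movement_field(mf, t, dG, 20.0, 0.0, eff, lead=0.0)
        N = mf.predict([20.0], [0.0], eff)[0]
        assert pred[t == 50.0][0] == pytest.approx(N / 2)

    def test_zero_amplitude_rejected(self, eff):
        counts, amps, e0s = _synthetic_counts(eff)
        mf = fit_static_movement_field(counts, amps, e0s, eff)
        with pytest.raises(AnalysisError):
            predict_dynamic_movement_field(mf, np.arange(10.0), np.zeros(10),
                                           0.0, 0.0, eff)


class TestPhaseTrajectory:
    def test_empty_spike_train_gives_empty_trajectory(self):
        tr = phase_trajectory([], np.arange(0, 100.0), np.zeros(100), lead=10.0)
        assert tr.cs.size == 0
        assert tr.n_spikes == 0

    def test_slope_approximates_count_over_amplitude(self):
        t = np.arange(0, 100.0, 1.0)
        dG = 10.0 * np.clip(t / 50.0, 0, 1)
        spikes = np.linspace(1.0, 49.0, 20)  # uniform burst over the ramp
        tr = phase_trajectory(spikes, t, dG, lead=0.0)
        assert tr.slope() == pytest.approx(20.0 / 10.0, rel=0.15)

    def test_cumulative_count_endpoint(self):
        t = np.arange(0, 100.0, 1.0)
        cs = cumulative_count([5.0, 10.0, 30.0], t)
        assert cs[-1] == 3
        assert np.all(np.diff(cs) >= 0)


class TestRateVelocityCorrelation:
    def test_identical_profiles_up_to_scale(self):
        t = np.arange(0, 200.0, 1.0)
        pulse = np.exp(-(t - 80) ** 2 / (2 * 15.0 ** 2))
        r = rate_velocity_correlation(t, 5 * pulse, t, 300 * pulse,
                                      (40.0, 120.0), lead=0.0)
        assert r == pytest.approx(1.0, abs=1e-9)

    def test_time_reversed_skewed_pulse_correlates_worse(self):
        t = np.arange(0, 200.0, 1.0)
        x = np.clip((t - 50) / 1000.0, 0, None)
        skewed = x ** 2 * np.exp(-x * 80)   # fast rise, slow decay
        r_fwd = rate_velocity_correlation(t, skewed, t, skewed, (50.0, 150.0), lead=0.0)
        r_rev = rate_velocity_correlation(t, skewed, t, skewed[::-1],
                                          (50.0, 150.0), lead=0.0)
        assert r_rev < r_fwd

    def test_constant_profile_rejected(self):
        t = np.arange(0, 100.0, 1.0)
        with pytest.raises(AnalysisError):
            rate_velocity_correlation(t, np.ones_like(t) * 0.0, t, np.sin(t / 5),
                                      (10.0, 90.0), lead=0.0)


class TestFiringRate:
    def test_integrates_to_spike_count(self):
        t = np.arange(-50, 250.0, 0.5)
        spikes = [20.0, 25.0, 60.0, 61.0, 100.0]
        r = firing_rate(spikes, t, sigma=4.0)
        assert np.trapezoid(r, t) / 1000.0 == pytest.approx(len(spikes), rel=1e-6)

    def test_empty_train_is_zero(self):
        assert np.all(firing_rate([], np.arange(10.0)) == 0)


class TestDetectMovement:
    def test_constant_position_reports_no_movement(self):
        t = np.arange(0, 500.0, 0.5)
        ev = detect_movement(t, np.full_like(t, 3.0), np.zeros_like(t))
        assert ev is NO_MOVEMENT
        assert not ev.detected

    def test_raised_cosine_pulse_recovered(self):
        dt = 0.5
        t = np.arange(0, 500.0, dt)
        amp, t_on, dur = 25.0, 100.0, 80.0
        v = np.zeros_like(t)
        inside = (t >= t_on) & (t <= t_on + dur)
        v[inside] = (1 - np.cos(2 * np.pi * (t[inside] - t_on) / dur)) / 2
        v *= amp / (np.trapezoid(v, t) / 1000.0)
        pos = np.cumsum(v) * dt / 1000.0
        ev = detect_movement(t, pos, v, threshold=20.0, hysteresis=5.0)
        assert ev.detected
        assert ev.amplitude == pytest.approx(amp, rel=0.02)
        assert ev.peak_velocity == pytest.approx(v.max(), rel=1e-9)
        assert t_on < ev.onset < t_on + dur / 4

    def test_brief_glitch_below_hysteresis_ignored(self):
        t = np.arange(0, 100.0, 0.5)
        v = np.zeros_like(t)
        v[40:43] = 50.0  # 1.5 ms blip < 5 ms hysteresis
        ev = detect_movement(t, np.cumsum(v) * 0.0005, v)
        assert not ev.detected


class TestMainSequence:
    def test_single_bundle_single_row(self, cond40, config):
        table = main_sequence([cond40.bundle], config.analysis)
        assert len(table) == 1
        row = table.iloc[0]
        assert row.amplitude_deg == pytest.approx(
            detect_movement(cond40.bundle.t, cond40.bundle.G, cond40.bundle.Gdot,
                            config.analysis.vel_threshold,
                            config.analysis.hysteresis).amplitude)

    def test_empty_input_rejected(self):
        with pytest.raises(AnalysisError):
            main_sequence([])
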