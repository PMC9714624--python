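"""Standard measurement protocols for characterising a tuned model.

These functions run the published experiment designs end to end: the
spike-count invariance sweep (three amplitudes, nine initial eye positions),
the movement-field protocol (amplitudes 5-55 deg in 2-deg steps at three eye
positions), head-contribution measurements, the main-sequence sweep and the
rate-velocity correlation.  They are used by the test suite and by the
reproduction script, and cache nothing: every number is recomputed from a
fresh simulation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .analysis import (StaticMF, burst_metrics, cumulative_count, detect_movement,
                       firing_rate, fit_static_movement_field, main_sequence,
                       rate_velocity_correlation)
from .config import ModelConfig
from .decoder import afferent_coordinate
from .experiment import simulate_condition

SWEEP_AMPLITUDES = (15.0, 30.0, 45.0)
SWEEP_E0 = (-40.0, -30.0, -20.0, -10.0, 0.0, 10.0, 20.0, 30.0, 40.0)
MF_AMPLITUDES = tuple(np.arange(5.0, 56.0, 2.0))
MF_E0 = (-20.0, 0.0, 20.0)
MAIN_SEQ_AMPLITUDES = tuple(np.arange(5.0, 61.0, 5.0))
MAIN_SEQ_E0 = (-30.0, -10.0, 0.0, 10.0, 30.0)


def spike_count_sweep(config: ModelConfig,
                      amplitudes=SWEEP_AMPLITUDES,
                      E0s=SWEEP_E0,
                      duration: float = 300.0) -> pd.DataFrame:
    """Central-unit and population spike counts over amplitude x eye position.

    One network simulation per condition; also reports the central unit's
    kernel-smoothed peak firing rate, burst onset and duration.
    """
    rows = []
    for amp in amplitudes:
        for E0 in E0s:
            res = simulate_condition(config, amp, E0, duration=duration,
                                     run_controller=False)
            counts = res.sc_raster.counts()
            m = burst_metrics(res.sc_raster.spike_times[res.central_index],
                              sigma=config.analysis.rate_sigma)
            rows.append({"amplitude": amp, "E0": E0,
                         "central_count": int(counts[res.central_index]),
                         "population_count": int(counts.sum()),
                         "peak_rate": m["peak_rate"], "onset": m["onset"],
                         "duration": m["duration"]})
    return pd.DataFrame(rows)


def optimal_counts(config: ModelConfig, amplitudes=(10.0, 20.0, 40.0),
                   duration: float = 300.0) -> list[int]:
    """Spike count of each unit for the gaze shift of its own optimal amplitude."""
    out = []
    for amp in amplitudes:
        res = simulate_condition(config, amp, 0.0, duration=duration,
                                 run_controller=False)
        out.append(int(res.sc_raster.counts()[res.central_index]))
    return out


def peak_rate_modulation(config: ModelConfig, amplitude: float = 15.0,
                         duration: float = 300.0) -> float:
    """Percent decrease of the central unit's peak rate, far-contra to far-ipsi."""
    rates = {}
    for E0 in (config.motor_map.e0_min, config.motor_map.e0_max):
        res = simulate_condition(config, amplitude, E0, duration=duration,
                                 run_controller=False)
        m = burst_metrics(res.sc_raster.spike_times[res.central_index],
                          sigma=config.analysis.rate_sigma)
        rates[E0] = m["peak_rate"]
    contra = rates[config.motor_map.e0_min]
    ipsi = rates[config.motor_map.e0_max]
    return 100.0 * (contra - ipsi) / contra


def head_contribution(config: ModelConfig, amplitude: float,
                      E0: float = 0.0, H0: float = 0.0) -> dict:
    """Head displacement accumulated at the detected gaze offset (deg)."""
    res = simulate_condition(config, amplitude, E0, H0)
    b = res.bundle
    ev = detect_movement(b.t, b.G, b.Gdot, config.analysis.vel_threshold,
                         config.analysis.hysteresis, E0=E0)
    if not ev.detected:
        return {"head_at_offset": 0.0, "gaze_amplitude": 0.0,
                "offset": np.nan, "peak_gaze_velocity": 0.0}
    i_end = int(np.searchsorted(b.t, ev.offset))
    return {"head_at_offset": float(b.H[i_end] - b.H[0]),
            "gaze_amplitude": ev.amplitude, "offset": ev.offset,
            "peak_gaze_velocity": ev.peak_velocity}


@dataclass(frozen=True)
class MovementFieldStudy:
    """Movement-field protocol output for one unit."""

    mf: StaticMF
    counts: np.ndarray
    amplitudes: np.ndarray
    E0s: np.ndarray
    dynamic_r: float
    n_dynamic_points: int


def movement_field_study(config: ModelConfig, optimal_amplitude: float = 20.0,
                         amplitudes=MF_AMPLITUDES, E0s=MF_E0,
                         sample_step: float = 10.0) -> MovementFieldStudy:
    """Run the full movement-field protocol for one unit and fit both models.

    Simulates every (amplitude, E0) condition with the complete model, counts
    the unit's burst spikes, fits the static movement field, and pools the
    dynamic movement-field prediction (static count scaled by the 10 ms
    back-shifted fractional desired displacement) against the simulated
    cumulative counts, sampled every ``sample_step`` ms from burst/gaze onset
    to gaze offset.
    """
    u_unit = afferent_coordinate(optimal_amplitude, config.efferent)
    lead = config.analysis.lead_time
    trials = []
    for E0 in E0s:
        for amp in amplitudes:
            trials.append((amp, E0, simulate_condition(config, amp, E0)))
    counts = np.array([
        len(res.sc_raster.spike_times[res.motor_map.central_unit(u_unit)])
        for _, _, res in trials], float)
    amp_arr = np.array([tr[0] for tr in trials])
    e0_arr = np.array([tr[1] for tr in trials])
    mf = fit_static_movement_field(counts, amp_arr, e0_arr, config.efferent,
                                   map_length=config.motor_map.map_length)

    pred_all, obs_all = [], []
    for (amp, E0, res) in trials:
        unit = res.motor_map.central_unit(u_unit)
        ts = res.sc_raster.spike_times[unit]
        if ts.size == 0:
            continue
        b = res.bundle
        ev = detect_movement(b.t, b.G, b.Gdot, config.analysis.vel_threshold,
                             config.analysis.hysteresis)
        if not ev.detected:
            continue
        A = res.trace.amplitude
        t_grid = np.arange(min(ts[0], ev.onset), ev.offset, sample_step)
        cs = cumulative_count(ts, t_grid)
        n_pred = float(mf.predict([A], [E0], config.efferent)[0])
        shifted = np.interp(t_grid + lead, res.trace.t, res.trace.delta_G)
        pred_all.append(n_pred / A * shifted)
        obs_all.append(cs)
    pred = np.concatenate(pred_all)
    obs = np.concatenate(obs_all)
    r = float(np.corrcoef(pred, obs)[0, 1])
    return MovementFieldStudy(mf=mf, counts=counts, amplitudes=amp_arr,
                              E0s=e0_arr, dynamic_r=r,
                              n_dynamic_points=int(pred.size))


def rate_velocity_study(config: ModelConfig, amplitude: float = 20.0,
                        E0: float = -20.0) -> float:
    """Rate vs gaze-velocity correlation for one full-model gaze shift."""
    res = simulate_condition(config, amplitude, E0)
    u_unit = afferent_coordinate(amplitude, config.efferent)
    unit = res.motor_map.central_unit(u_unit)
    ts = res.sc_raster.spike_times[unit]
    b = res.bundle
    ev = detect_movement(b.t, b.G, b.Gdot, config.analysis.vel_threshold,
                         config.analysis.hysteresis)
    t_grid = np.arange(0.0, b.t[-1], config.analysis.analysis_dt)
    rate = firing_rate(ts, t_grid, config.analysis.rate_sigma)
    return rate_velocity_correlation(t_grid, rate, b.t, b.Gdot,
                                     (ev.onset, ev.offset),
                                     lead=config.analysis.lead_time)


def main_sequence_study(config: ModelConfig,
                        amplitudes=MAIN_SEQ_AMPLITUDES,
                        E0s=MAIN_SEQ_E0) -> pd.DataFrame:
    """Peak gaze velocity vs amplitude for several initial eye positions."""
    bundles = []
    nominal = []
    for E0 in E0s:
        for amp in amplitudes:
            bundles.append(simulate_condition(config, amp, E0).bundle)
            nominal.append(amp)
    table = main_sequence(bundles, config.analysis)
    table["nominal_deg"] = nominal
    return table
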