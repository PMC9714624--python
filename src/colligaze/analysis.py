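"""Movement-field and kinematics analyses of simulated gaze shifts.

Quantifies model units the way collicular recordings are analysed: the static
movement field (total burst spike count vs gaze amplitude and initial eye
position, a Gaussian in map coordinates with a planar eye-position gain), the
dynamic movement field (cumulative spike count tracking the back-shifted
fractional gaze displacement), phase trajectories, firing-rate/gaze-velocity
correlations, and main-sequence tables built from detected movements.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .config import AnalysisParams, ConfigError, EfferentMap
from .decoder import afferent_coordinate


class AnalysisError(ValueError):
    """Raised when an analysis is undefined for the given data."""


def firing_rate(spike_times: np.ndarray, t_grid: np.ndarray,
                sigma: float = 4.0) -> np.ndarray:
    """Gaussian-kernel instantaneous firing rate (spikes/s)."""
    t_grid = np.asarray(t_grid, float)
    spike_times = np.asarray(spike_times, float)
    if spike_times.size == 0:
        return np.zeros_like(t_grid)
    d = t_grid[:, None] - spike_times[None, :]
    r = np.exp(-d**2 / (2.0 * sigma**2)).sum(axis=1)
    return r / (sigma * np.sqrt(2.0 * np.pi)) * 1000.0


def cumulative_count(spike_times: np.ndarray, t_grid: np.ndarray) -> np.ndarray:
    """Number of spikes at or before each grid time."""
    return np.searchsorted(np.sort(np.asarray(spike_times, float)),
                           np.asarray(t_grid, float), side="right").astype(float)


def burst_metrics(spike_times: np.ndarray, sigma: float = 4.0,
                  dt: float = 1.0) -> dict:
    """Onset, offset, duration, spike count and kernel-smoothed peak rate."""
    ts = np.asarray(spike_times, float)
    if ts.size == 0:
        return {"count": 0, "onset": np.nan, "offset": np.nan,
                "duration": np.nan, "peak_rate": 0.0}
    grid = np.arange(max(ts[0] - 5 * sigma, 0.0), ts[-1] + 5 * sigma, dt)
    r = firing_rate(ts, grid, sigma)
    return {"count": int(ts.size), "onset": float(ts[0]), "offset": float(ts[-1]),
            "duration": float(ts[-1] - ts[0]), "peak_rate": float(r.max())}


@dataclass(frozen=True)
class StaticMF:
    """Static movement-field parameters of one unit.

    ``N = N0 * (1 + epsilon*E0) * exp(-(u(dG) - u0)**2 / (2*sigma_p**2))``
    with ``u(dG)`` the afferent map coordinate of the gaze amplitude.
    """

    N0: float        # spikes at the optimal amplitude, straight-ahead eye
    u0: float        # mm, optimal coordinate
    sigma_p: float   # mm, tuning width on the map
    epsilon: float   # spikes/deg, eye-position sensitivity
    r: float         # Pearson correlation, fitted vs observed counts

    def predict(self, amplitudes, E0s, efferent: EfferentMap) -> np.ndarray:
        u = afferent_coordinate(np.asarray(amplitudes, float), efferent)
        return (self.N0 * (1.0 + self.epsilon * np.asarray(E0s, float))
                * np.exp(-(u - self.u0)**2 / (2.0 * self.sigma_p**2)))


def fit_static_movement_field(counts, amplitudes, E0s, efferent: EfferentMap,
                              map_length: float = 5.0,
                              n_starts: int = 5) -> StaticMF:
    """Nonlinear least-squares fit of the static movement field.

    Parameters
    ----------
    counts, amplitudes, E0s
        Per-trial burst spike counts with the gaze amplitude (deg) and
        initial eye position (deg) of each trial.
    efferent
        Afferent mapping constants used to place amplitudes on the map.
    n_starts
        Trust-region fits are started from this many initial ``u0`` values
        spread across the map; the lowest-residual solution wins (ties broken
        by the earlier start).

    Raises
    ------
    AnalysisError
        For all-zero counts, fewer than 4 usable trials, or a singular fit.
    """
    counts = np.asarray(counts, float)
    amplitudes = np.asarray(amplitudes, float)
    E0s = np.asarray(E0s, float)
    if counts.size != amplitudes.size or counts.size != E0s.size:
        raise AnalysisError("counts, amplitudes and E0s must have equal length")
    if not np.any(counts > 0):
        raise AnalysisError("all spike counts are zero; movement field undefined")
    if counts.size < 4:
        raise AnalysisError("need at least 4 trials to fit 4 parameters")

    u_trial = afferent_coordinate(amplitudes, efferent)

    def residuals(p):
        N0, u0, sig, eps = p
        pred = N0 * (1.0 + eps * E0s) * np.exp(-(u_trial - u0)**2 / (2.0 * sig**2))
        return pred - counts

    n0_init = float(counts.max())
    u0_guess = float(u_trial[np.argmax(counts)])
    starts = np.linspace(0.1 * map_length, 0.9 * map_length, n_starts)
    # seed closest start from the empirical peak for robustness
    starts[np.argmin(np.abs(starts - u0_guess))] = u0_guess

    best = None
    for u0_start in starts:
        try:
            sol = optimize.least_squares(
                residuals, x0=[n0_init, u0_start, 0.5, 0.0],
                bounds=([1e-6, 0.0, 1e-3, -1.0], [np.inf, map_length, map_length, 1.0]),
                method="trf")
        except Exception:
            continue
        if not np.all(np.isfinite(sol.x)):
            continue
        if best is None or sol.cost < best.cost - 1e-12:
            best = sol
    if best is None:
        raise AnalysisError("movement-field fit failed from every start")

    N0, u0, sig, eps = best.x
    pred = N0 * (1.0 + eps * E0s) * np.exp(-(u_trial - u0)**2 / (2.0 * sig**2))
    if np.std(pred) == 0 or np.std(counts) == 0:
        raise AnalysisError("singular fit: predictions or counts are constant")
    r = float(np.corrcoef(pred, counts)[0, 1])
    return StaticMF(N0=float(N0), u0=float(u0), sigma_p=float(sig),
                    epsilon=float(eps), r=r)


def predict_dynamic_movement_field(mf: StaticMF, t_grid, delta_G_t, amplitude: float,
                                   E0: float, efferent: EfferentMap,
                                   lead: float = 10.0) -> np.ndarray:
    """Predicted cumulative spike count over time (dynamic movement field).

    The static count for the trial, scaled by the back-shifted fractional
    gaze displacement: ``CS(t) = N(dG, E0)/dG * dG(t + lead)``.
    """
    if amplitude <= 0:
        raise AnalysisError("dynamic movement field undefined for zero amplitude")
    t_grid = np.asarray(t_grid, float)
    delta_G_t = np.asarray(delta_G_t, float)
    N = float(mf.predict([amplitude], [E0], efferent)[0])
    shifted = np.interp(t_grid + lead, t_grid, delta_G_t,
                        left=0.0, right=delta_G_t[-1])
    return N / amplitude * shifted


@dataclass(frozen=True)
class PhaseTrajectory:
    """Cumulative spike count vs back-shifted gaze displacement."""

    delta_G_shifted: np.ndarray  # deg
    cs: np.ndarray               # spikes
    lead: float                  # ms

    @property
    def n_spikes(self) -> int:
        return int(self.cs[-1]) if self.cs.size else 0

    def slope(self) -> float:
        """Least-squares slope through the origin (spikes/deg)."""
        x, y = self.delta_G_shifted, self.cs
        denom = float(np.dot(x, x))
        if denom == 0:
            raise AnalysisError("degenerate phase trajectory (no displacement)")
        return float(np.dot(x, y) / denom)


def phase_trajectory(spike_times, t_grid, delta_G_t, lead: float = 10.0,
                     pad: float = 5.0) -> PhaseTrajectory:
    """Pair the unit's running spike count with the back-shifted displacement.

    Sampled on the analysis grid from burst onset to shortly after burst end
    (``pad`` ms); empty spike trains give an empty trajectory.
    """
    if lead < 0:
        raise ConfigError("lead must be >= 0")
    ts = np.asarray(spike_times, float)
    t_grid = np.asarray(t_grid, float)
    if ts.size == 0:
        return PhaseTrajectory(np.empty(0), np.empty(0), lead)
    mask = (t_grid >= ts[0]) & (t_grid <= ts[-1] + pad)
    cs = cumulative_count(ts, t_grid[mask])
    shifted = np.interp(t_grid[mask] + lead, t_grid, np.asarray(delta_G_t, float),
                        left=0.0, right=float(np.asarray(delta_G_t)[-1]))
    return PhaseTrajectory(delta_G_shifted=shifted, cs=cs, lead=lead)


def _normalize_profile(t, y, t0, t1, n: int = 101):
    """Resample a profile onto normalised time [0, 1] and scale peak to 1."""
    tt = np.linspace(t0, t1, n)
    yy = np.interp(tt, t, y)
    peak = np.abs(yy).max()
    if peak == 0:
        raise AnalysisError("constant profile: correlation undefined")
    return yy / peak


def rate_velocity_correlation(t_rate, rate, t_vel, velocity, window: tuple,
                              lead: float = 10.0, normalize: bool = True) -> float:
    """Pearson correlation between a firing-rate and a velocity profile.

    The rate profile is shifted forward by the neural ``lead`` (ms) before
    comparison; with ``normalize`` both profiles are resampled to the movement
    window (normalised duration) and scaled to their maxima, mirroring how
    burst/velocity overlays are usually displayed.
    """
    t0, t1 = window
    if not t1 > t0:
        raise AnalysisError("empty analysis window")
    rate_shift = np.asarray(t_rate, float) + lead
    if normalize:
        a = _normalize_profile(rate_shift, rate, t0, t1)
        b = _normalize_profile(np.asarray(t_vel, float), velocity, t0, t1)
    else:
        tt = np.linspace(t0, t1, 101)
        a = np.interp(tt, rate_shift, rate)
        b = np.interp(tt, np.asarray(t_vel, float), velocity)
    if np.std(a) == 0 or np.std(b) == 0:
        raise AnalysisError("constant profile: correlation undefined")
    return float(stats.pearsonr(a, b)[0])


@dataclass(frozen=True)
class MovementEvent:
    """A detected movement: onset/offset (ms), amplitude (deg), peak velocity."""

    onset: float
    offset: float
    amplitude: float
    peak_velocity: float
    E0: float = np.nan

    @property
    def detected(self) -> bool:
        return np.isfinite(self.onset)

    @property
    def duration(self) -> float:
        return self.offset - self.onset


NO_MOVEMENT = MovementEvent(np.nan, np.nan, 0.0, 0.0)


def detect_movement(t, position, velocity, threshold: float = 20.0,
                    hysteresis: float = 5.0, E0: float = np.nan) -> MovementEvent:
    """Velocity-criterion movement detection.

    Onset is the first sample where |velocity| exceeds ``threshold`` and stays
    above it for at least ``hysteresis`` ms; offset is the last sample of the
    final such epoch.  Returns :data:`NO_MOVEMENT` (not an exception) when the
    threshold is never crossed.
    """
    t = np.asarray(t, float)
    position = np.asarray(position, float)
    velocity = np.asarray(velocity, float)
    dt = t[1] - t[0]
    above = np.abs(velocity) >= threshold
    if not above.any():
        return NO_MOVEMENT
    min_run = max(int(round(hysteresis / dt)), 1)
    padded = np.concatenate([[False], above, [False]]).astype(int)
    edges = np.diff(padded)
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1) - 1
    keep = (ends - starts + 1) >= min_run
    if not keep.any():
        return NO_MOVEMENT
    i0 = starts[keep][0]
    i1 = ends[keep][-1]
    inside = slice(i0, i1 + 1)
    return MovementEvent(
        onset=float(t[i0]), offset=float(t[i1]),
        amplitude=float(position[i1] - position[i0]),
        peak_velocity=float(np.abs(velocity[inside]).max()),
        E0=E0,
    )


def main_sequence(bundles, analysis: AnalysisParams | None = None) -> pd.DataFrame:
    """Amplitude / peak gaze velocity / initial eye position table.

    One row per trajectory bundle, with gaze movement detected on G(t) by the
    velocity criterion.
    """
    analysis = analysis or AnalysisParams()
    if len(bundles) == 0:
        raise AnalysisError("need at least one trajectory bundle")
    rows = []
    for b in bundles:
        ev = detect_movement(b.t, b.G, b.Gdot, analysis.vel_threshold,
                             analysis.hysteresis, E0=b.E0)
        rows.append({"amplitude_deg": ev.amplitude,
                     "peak_gaze_velocity_deg_s": ev.peak_velocity,
                     "E0_deg": b.E0, "planned_deg": b.planned_amplitude,
                     "onset_ms": ev.onset, "offset_ms": ev.offset})
    return pd.DataFrame(rows)
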