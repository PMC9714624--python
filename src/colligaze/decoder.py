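"""Dynamic linear ensemble decoding of the collicular population output.

Every spike of every recruited unit contributes a fixed, site-dependent gaze
increment (its "spike gaze vector"); the running sum over the population is
the desired gaze displacement dG(t), and its Savitzky-Golay smoothed
derivative is the desired gaze-velocity command handed to the downstream
feedback controller.

The site dependence follows the exponential efferent magnification of the
motor map: a unit at coordinate u contributes ``kappa * A * (exp(u/B_u) - 1)``
degrees per spike, the inverse of the logarithmic afferent mapping
``u = B_u * ln((dG + A)/A)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.signal import savgol_filter

from .config import AnalysisParams, ConfigError, EfferentMap
from .motor_map import SpikeRaster


def afferent_coordinate(delta_G, efferent: EfferentMap):
    """Map a gaze amplitude (deg) to its anatomical coordinate u (mm).

    Logarithmic afferent magnification ``u = B_u * ln((dG + A)/A)``; the
    inverse of the amplitude carried by the efferent map.
    """
    dG = np.asarray(delta_G, dtype=float)
    if np.any(dG < 0):
        raise ConfigError("gaze amplitude must be non-negative")
    out = efferent.B_u * np.log((dG + efferent.A) / efferent.A)
    return float(out) if np.isscalar(delta_G) else out


def efferent_amplitude(u, efferent: EfferentMap):
    """Inverse of :func:`afferent_coordinate`: amplitude (deg) at coordinate u."""
    u = np.asarray(u, dtype=float)
    out = efferent.A * (np.exp(u / efferent.B_u) - 1.0)
    return float(out) if out.ndim == 0 else out


def spike_gaze_vector(u, efferent: EfferentMap):
    """Gaze displacement (deg) contributed by one spike of a unit at u (mm)."""
    u_arr = np.asarray(u, dtype=float)
    if np.any(u_arr < 0):
        raise ConfigError("map coordinate must be non-negative")
    out = efferent.kappa * efferent.A * (np.exp(u_arr / efferent.B_u) - 1.0)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class GazeTrace:
    """Decoded desired gaze displacement and velocity on a uniform grid."""

    t: np.ndarray          # ms
    delta_G: np.ndarray    # deg, cumulative decoded displacement
    g_dot_des: np.ndarray  # deg/s, smoothed desired gaze velocity
    window: int            # Savitzky-Golay window (samples)
    order: int             # Savitzky-Golay polynomial order

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    @property
    def amplitude(self) -> float:
        """Final decoded gaze displacement (deg)."""
        return float(self.delta_G[-1])

    def to_csv(self, path: str | Path) -> None:
        header = "t_ms,delta_G_deg,g_dot_des_deg_s"
        data = np.column_stack([self.t, self.delta_G, self.g_dot_des])
        np.savetxt(path, data, delimiter=",", header=header, comments="")


def decode_displacement(raster: SpikeRaster, efferent: EfferentMap,
                        t_grid: np.ndarray) -> np.ndarray:
    """Cumulative decoded gaze displacement dG(t) sampled on ``t_grid``.

    A step function accumulating one spike gaze vector per spike; exact
    (resolution independent) because spikes are binned by time, not smoothed.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.size == 0:
        raise ConfigError("empty time grid")
    m = spike_gaze_vector(raster.u, efferent)
    idx, times = raster.flat()
    if times.size and (times.min() < t_grid[0] or times.max() > t_grid[-1]):
        raise ConfigError("spike times fall outside the requested grid")
    if times.size == 0:
        return np.zeros_like(t_grid)
    # each spike contributes from the first grid point at/after its time
    weights = m[idx]
    order = np.searchsorted(t_grid, times, side="left")
    steps = np.zeros(t_grid.size + 1)
    np.add.at(steps, order, weights)
    return np.cumsum(steps[:-1])


def desired_gaze_velocity(t_grid: np.ndarray, delta_G: np.ndarray,
                          window: int = 21, order: int = 3) -> np.ndarray:
    """Savitzky-Golay smoothed first derivative of dG(t), in deg/s."""
    t_grid = np.asarray(t_grid, dtype=float)
    delta_G = np.asarray(delta_G, dtype=float)
    if t_grid.size < window:
        raise ConfigError(f"grid of {t_grid.size} samples shorter than window {window}")
    dt_s = (t_grid[1] - t_grid[0]) / 1000.0
    return savgol_filter(delta_G, window_length=window, polyorder=order,
                         deriv=1, delta=dt_s)


def decode_gaze_trajectory(raster: SpikeRaster, efferent: EfferentMap,
                           t_grid: np.ndarray | None = None,
                           analysis: AnalysisParams | None = None) -> GazeTrace:
    """Full decode: spike raster -> (dG(t), desired gaze velocity).

    Parameters
    ----------
    raster
        SC-layer spike raster.
    efferent
        Efferent map with calibrated ``kappa``.
    t_grid
        Uniform analysis grid (ms).  Defaults to the analysis resolution over
        the full raster duration.
    analysis
        Smoothing parameters (window length and polynomial order).
    """
    analysis = analysis or AnalysisParams()
    if t_grid is None:
        t_grid = np.arange(0.0, raster.duration + analysis.analysis_dt / 2,
                           analysis.analysis_dt)
    dG = decode_displacement(raster, efferent, t_grid)
    v = desired_gaze_velocity(t_grid, dG, analysis.savgol_window, analysis.savgol_order)
    return GazeTrace(t=np.asarray(t_grid, float), delta_G=dG, g_dot_des=v,
                     window=analysis.savgol_window, order=analysis.savgol_order)
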