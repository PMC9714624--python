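"""The one-dimensional collicular motor map and its spiking simulation.

Two layers of adaptive exponential integrate-and-fire (AdEx) units, 200 per
layer, span 0-5 mm of the rostral-caudal axis.  Input-layer units are
non-interacting and transform a separable Gaussian-in-space, gamma-in-time
current pulse into a localised population of spike trains.  Each input unit
projects one-to-one onto the output (SC) unit at the same coordinate through a
feedforward weight that decreases linearly toward the caudal pole, as does the
adaptation time constant; SC units additionally interact through a soft
winner-take-all Mexican-hat scheme (narrow Gaussian excitation, broad
inhibition) whose strength falls off with the site gain ``1 - 0.04*u**2``.
An initial eye-in-head position ``E0`` multiplies both the adaptation time
constant and the lateral weights through the affine gain
``alpha(E0) = gain_slope*E0 + gain_offset``, identical for all units.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from . import _kernel
from .config import AdExParams, ConfigError, InputProfile, MotorMapSpec


class SimulationError(RuntimeError):
    """Numerical failure of the network integration (non-finite state)."""


def unit_positions(spec: MotorMapSpec) -> np.ndarray:
    """Anatomical coordinates u_n (mm), uniform over [0, map_length]."""
    return np.linspace(0.0, spec.map_length, spec.n_units)


def eye_position_gain(spec: MotorMapSpec, E0: float) -> float:
    """Affine eye-position gain alpha(E0) applied to tau_q and lateral weights."""
    if not np.isfinite(E0):
        raise ConfigError("E0 must be finite")
    if not (spec.e0_min <= E0 <= spec.e0_max):
        raise ConfigError(
            f"E0 = {E0} deg outside configured range [{spec.e0_min}, {spec.e0_max}]")
    return spec.gain_slope * E0 + spec.gain_offset


def site_gain(spec: MotorMapSpec, u: np.ndarray) -> np.ndarray:
    """Location-dependent lateral gain S = 1 - s_coeff * u**2, clamped at 0."""
    return np.maximum(1.0 - spec.s_coeff * np.asarray(u) ** 2, 0.0)


@dataclass(frozen=True)
class MotorMap:
    """A built motor map: per-unit parameters and lateral weight matrices.

    ``tau_base`` and ``w_ff`` are the rostral-to-caudal linear ramps before any
    eye-position modulation; ``tau_q`` includes the ``(1 + alpha)`` gain.
    ``W_exc[i, j]`` / ``W_inh[i, j]`` are the lateral weights from unit i onto
    unit j (diagonal zero, all entries non-negative).
    """

    u: np.ndarray          # (n,) mm
    tau_base: np.ndarray   # (n,) ms
    tau_q: np.ndarray      # (n,) ms, eye-position modulated
    w_ff: np.ndarray       # (n,) nS
    W_exc: np.ndarray      # (n, n) nS
    W_inh: np.ndarray      # (n, n) nS
    alpha: float
    E0: float

    @property
    def n_units(self) -> int:
        return self.u.size

    def central_unit(self, u_target: float) -> int:
        """Index of the unit closest to coordinate ``u_target`` (mm)."""
        return int(np.argmin(np.abs(self.u - u_target)))


def build_motor_map(spec: MotorMapSpec, adex: AdExParams, E0: float = 0.0) -> MotorMap:
    """Construct the motor map for one initial eye position.

    Parameters
    ----------
    spec
        Map layout and connectivity parameters.
    adex
        Intrinsic unit parameters (validated but not stored in the map).
    E0
        Initial eye-in-head position in degrees; must lie within the
        configured admissible range.

    Returns
    -------
    MotorMap
        Per-unit adaptation time constants and feedforward weights (linear
        rostral-to-caudal ramps) and the lateral weight matrices, all scaled
        by the eye-position gain where applicable.
    """
    del adex  # intrinsic parameters are location-independent; validated upstream
    u = unit_positions(spec)
    n = spec.n_units
    ramp = np.arange(n) / (n - 1)          # 0 at the rostral pole, 1 caudal
    tau_base = spec.tau_max + ramp * (spec.tau_min - spec.tau_max)
    w_ff = spec.w_ff_max + ramp * (spec.w_ff_min - spec.w_ff_max)
    alpha = eye_position_gain(spec, E0)
    tau_q = (1.0 + alpha) * tau_base

    du2 = (u[:, None] - u[None, :]) ** 2
    # The site gain scales a unit's *outgoing* lateral synapses, so the
    # whole population recruited for one target feels a lateral interaction
    # strength set by the target's map location.  This is what makes the
    # recruited population emit a near-constant number of spikes at every
    # amplitude despite the rostrally increasing feedforward drive.
    S = site_gain(spec, u)[:, None]
    W_exc = S * (1.0 + alpha) * spec.w_exc_bar * np.exp(-du2 / (2.0 * spec.sigma_exc**2))
    W_inh = S * (1.0 + alpha) * (1.0 - spec.w_inh_bar * np.exp(-du2 / (2.0 * spec.sigma_inh**2)))
    # negative lobe of the inhibitory difference term would act as excitation
    W_inh = np.maximum(W_inh, 0.0)
    np.fill_diagonal(W_exc, 0.0)
    np.fill_diagonal(W_inh, 0.0)
    return MotorMap(u=u, tau_base=tau_base, tau_q=tau_q, w_ff=w_ff,
                    W_exc=W_exc, W_inh=W_inh, alpha=alpha, E0=float(E0))


def temporal_profile(profile: InputProfile, t_ms: np.ndarray) -> np.ndarray:
    """Gamma-shaped temporal input factor, normalised to a peak value of 1.

    The pulse is ``t**gamma * exp(-beta*t)`` with t in seconds, zero for
    t <= 0, and attains its maximum at ``t = gamma/beta``.
    """
    t = np.asarray(t_ms, dtype=float) / 1000.0
    g, b = profile.gamma_shape, profile.beta_rate
    t_pk = g / b
    out = np.zeros_like(t)
    pos = t > 0
    # evaluated in log space relative to the peak so large gamma stays stable
    out[pos] = np.exp(g * np.log(t[pos] / t_pk) - b * t[pos] + g)
    return out


def spatial_profile(profile: InputProfile, u: np.ndarray) -> np.ndarray:
    """Gaussian spatial input factor centred on the target image point."""
    d = np.asarray(u, dtype=float) - profile.u_T
    return np.exp(-d**2 / (2.0 * profile.sigma_pop**2))


def external_input_current(profile: InputProfile, t_ms: np.ndarray,
                           u: np.ndarray) -> np.ndarray:
    """External current (pA) on the input layer: units x time.

    Separable product of the spatial Gaussian and the normalised temporal
    gamma pulse, scaled by the peak current ``I0``; non-negative everywhere
    and zero for t <= 0.
    """
    t_ms = np.asarray(t_ms, dtype=float)
    if t_ms.size == 0:
        raise ConfigError("empty time grid")
    return profile.I0 * np.outer(spatial_profile(profile, u), temporal_profile(profile, t_ms))


@dataclass(frozen=True)
class SpikeRaster:
    """Spike times of one network layer.

    ``spike_times[n]`` is the strictly increasing array of spike times (ms) of
    unit n; ``u`` holds the anatomical coordinates.
    """

    layer: str
    u: np.ndarray
    spike_times: tuple[np.ndarray, ...]
    duration: float

    @property
    def n_units(self) -> int:
        return self.u.size

    def counts(self) -> np.ndarray:
        """Number of spikes per unit."""
        return np.array([ts.size for ts in self.spike_times])

    def total_spikes(self) -> int:
        return int(self.counts().sum())

    def flat(self) -> tuple[np.ndarray, np.ndarray]:
        """(unit_index, time) pairs for all spikes, ordered by time then unit."""
        idx = np.concatenate([np.full(ts.size, n, dtype=int)
                              for n, ts in enumerate(self.spike_times)] or [np.empty(0, int)])
        t = np.concatenate(list(self.spike_times) or [np.empty(0)])
        order = np.lexsort((idx, t))
        return idx[order], t[order]


def raster_from_events(layer: str, u: np.ndarray, units: np.ndarray,
                       times: np.ndarray, duration: float) -> SpikeRaster:
    per_unit = []
    for n in range(u.size):
        ts = np.sort(times[units == n])
        per_unit.append(np.ascontiguousarray(ts))
    return SpikeRaster(layer=layer, u=np.asarray(u, float),
                       spike_times=tuple(per_unit), duration=float(duration))


def write_rasters_tsv(path: str | Path, rasters: Sequence[SpikeRaster],
                      config_hash: str = "") -> None:
    """Tab-separated spike table: unit_id, layer, u_mm, spike_time_ms."""
    lines = [f"# config_hash={config_hash}",
             "unit_id\tlayer\tu_mm\tspike_time_ms"]
    for raster in rasters:
        idx, t = raster.flat()
        for n, ts in zip(idx, t):
            lines.append(f"{n}\t{raster.layer}\t{raster.u[n]:.6f}\t{ts:.4f}")
    Path(path).write_text("\n".join(lines) + "\n")


def simulate_network(motor_map: MotorMap, adex: AdExParams, profile: InputProfile,
                     duration: float = 300.0,
                     max_spikes: int = 200_000) -> tuple[SpikeRaster, SpikeRaster]:
    """Integrate the two-layer network and return (input, SC) spike rasters.

    Fixed-step forward Euler at ``adex.dt`` with exact conductance decay; the
    run is fully deterministic given the configuration.  Raises
    ``SimulationError`` naming the unit and time if the state diverges.
    """
    n_steps = int(round(duration / adex.dt))
    t_grid = np.arange(n_steps) * adex.dt
    I_time = temporal_profile(profile, t_grid)
    I_space = profile.I0 * spatial_profile(profile, motor_map.u)

    out = _kernel.integrate_two_layer(
        adex.dt, n_steps,
        adex.C, adex.g_L, adex.E_L, adex.eta, adex.V_T, adex.a_sub,
        adex.b_spike, adex.V_r, adex.E_e, adex.E_i,
        adex.tau_exc, adex.tau_inh, adex.tau_q_input,
        np.ascontiguousarray(motor_map.tau_q),
        np.ascontiguousarray(I_space), np.ascontiguousarray(I_time),
        np.ascontiguousarray(motor_map.w_ff),
        np.ascontiguousarray(motor_map.W_exc),
        np.ascontiguousarray(motor_map.W_inh),
        max_spikes,
    )
    in_units, in_times, n_in, sc_units, sc_times, n_sc, status, bad_unit, bad_time = out
    if status == _kernel.STATUS_NONFINITE:
        raise SimulationError(
            f"non-finite state in unit {bad_unit} at t = {bad_time:.2f} ms")
    if status == _kernel.STATUS_OVERFLOW:
        raise SimulationError(
            f"spike buffer overflow (> {max_spikes} spikes) at t = {bad_time:.2f} ms; "
            "the network is likely runaway-excited")
    input_raster = raster_from_events("input", motor_map.u,
                                      in_units[:n_in], in_times[:n_in], duration)
    sc_raster = raster_from_events("sc", motor_map.u,
                                   sc_units[:n_sc], sc_times[:n_sc], duration)
    return input_raster, sc_raster
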