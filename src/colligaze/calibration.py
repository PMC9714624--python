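"""Brute-force network tuning against the population firing constraints.

The motor map must satisfy a set of population-level constraints for its
output to drive accurate gaze shifts: the central unit of the recruited
population emits close to 20 spikes at every amplitude and initial eye
position (18-21 band), the whole population emits close to 450 spikes, the
central unit's peak firing rate decreases from rostral to caudal target
sites, and the burst starts roughly 20 ms after input onset.  There is no
analytical solution for the spiking network, so tuning is an exhaustive grid
search: every parameter combination is simulated and scored, and the argmin
wins (deterministically, with lexicographic tie-breaking).

The decoder scale ``kappa`` is not searched: it is fixed afterwards by
requiring the decoded amplitude of a 15 deg gaze shift to be exactly 15 deg.
"""

from __future__ import annotations

import dataclasses
import itertools
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .analysis import burst_metrics
from .config import ConfigError, EfferentMap, ModelConfig
from .decoder import afferent_coordinate, spike_gaze_vector
from .motor_map import SpikeRaster, build_motor_map, simulate_network


@dataclass(frozen=True)
class GridSpec:
    """Axes of an exhaustive search: (name, lower, upper, steps) per parameter."""

    axes: tuple[tuple[str, float, float, int], ...]

    def __post_init__(self) -> None:
        for name, lo, hi, steps in self.axes:
            if not (math.isfinite(lo) and math.isfinite(hi)):
                raise ConfigError(f"bounds for {name!r} must be finite")
            if steps < 1:
                raise ConfigError(f"step count for {name!r} must be >= 1")

    def points(self) -> list[dict[str, float]]:
        grids = [np.linspace(lo, hi, steps) if steps > 1 else np.array([lo])
                 for _, lo, hi, steps in self.axes]
        names = [a[0] for a in self.axes]
        return [dict(zip(names, vals)) for vals in itertools.product(*grids)]

    @property
    def size(self) -> int:
        return int(np.prod([max(a[3], 1) for a in self.axes]))


@dataclass(frozen=True)
class TuningResult:
    best_params: dict[str, float]
    best_objective: float
    log: tuple[tuple[tuple[float, ...], float], ...]  # (param tuple, objective)

    @property
    def n_evaluations(self) -> int:
        return len(self.log)


def brute_force_tune(grid: GridSpec,
                     objective: Callable[[dict[str, float]], float]) -> TuningResult:
    """Exhaustively evaluate ``objective`` on the grid and return the argmin.

    Objective failures (exceptions, non-finite values) are recorded as +inf
    and do not abort the search.  With equal objective values the
    lexicographically smallest parameter tuple wins, so the result does not
    depend on evaluation order.
    """
    log = []
    best_val = math.inf
    best_key: tuple[float, ...] | None = None
    best_params: dict[str, float] | None = None
    for params in grid.points():
        key = tuple(params.values())
        try:
            val = float(objective(params))
        except Exception:
            val = math.inf
        if not math.isfinite(val):
            val = math.inf
        log.append((key, val))
        if val < best_val or (val == best_val and (best_key is None or key < best_key)):
            best_val = val
            best_key = key
            best_params = params
    if best_params is None:
        raise ConfigError("empty tuning grid")
    return TuningResult(best_params=best_params, best_objective=best_val,
                        log=tuple(log))


def calibrate_kappa(sc_raster: SpikeRaster, efferent: EfferentMap,
                    target_amplitude: float = 15.0) -> float:
    """Decoder scale such that the given burst decodes exactly to the target.

    Run the tuned network for the target amplitude (straight-ahead eye), sum
    the population's spike gaze vectors at unit scale, and divide: the result
    makes the decoded amplitude of this condition exact by construction and
    every other amplitude follows from the efferent magnification.
    """
    unit_eff = dataclasses.replace(efferent, kappa=1.0)
    m = spike_gaze_vector(sc_raster.u, unit_eff)
    total = float((m * sc_raster.counts()).sum())
    if total <= 0:
        raise ConfigError("no weighted spikes to calibrate against")
    return target_amplitude / total


def fit_eye_position_gain(E0s: Sequence[float],
                          alphas: Sequence[float]) -> tuple[float, float]:
    """Ordinary least-squares affine fit alpha(E0) = slope*E0 + offset."""
    E0s = np.asarray(E0s, float)
    alphas = np.asarray(alphas, float)
    if np.unique(E0s).size < 2:
        raise ConfigError("need at least two distinct E0 values for an affine fit")
    slope, offset = np.polyfit(E0s, alphas, 1)
    return float(slope), float(offset)


@dataclass(frozen=True)
class ObjectiveWeights:
    """Relative weights of the tuning-constraint terms."""

    central_count: float = 1.0      # (N_central - target)^2, per spike^2
    population_count: float = 0.01  # (N_pop - target)^2
    rate_monotonicity: float = 5.0  # penalty per Hz of non-monotone peak rate
    central_target: float = 20.0    # spikes
    population_target: float = 450.0


def constraint_objective(config: ModelConfig,
                         amplitudes: Sequence[float] = (15.0, 30.0, 45.0),
                         E0s: Sequence[float] = (-40.0, 0.0, 40.0),
                         weights: ObjectiveWeights | None = None,
                         duration: float = 300.0) -> float:
    """Score a configuration against the printed population constraints."""
    w = weights or ObjectiveWeights()
    loss = 0.0
    peak_at_mid_e0 = []
    for amp in amplitudes:
        u_T = afferent_coordinate(amp, config.efferent)
        profile = config.input.with_target(u_T)
        for E0 in E0s:
            mm = build_motor_map(config.motor_map, config.adex, E0)
            _, sc = simulate_network(mm, config.adex, profile, duration)
            counts = sc.counts()
            central = int(counts[mm.central_unit(u_T)])
            loss += w.central_count * (central - w.central_target) ** 2
            loss += w.population_count * (counts.sum() - w.population_target) ** 2
            if E0 == 0.0:
                m = burst_metrics(sc.spike_times[mm.central_unit(u_T)],
                                  sigma=config.analysis.rate_sigma)
                peak_at_mid_e0.append(m["peak_rate"])
    # peak rate must fall from rostral (small) to caudal (large) amplitudes
    for lo, hi in zip(peak_at_mid_e0, peak_at_mid_e0[1:]):
        loss += w.rate_monotonicity * max(hi - lo, 0.0)
    return loss


def tune_network(base: ModelConfig, grid: GridSpec,
                 setter: Callable[[ModelConfig, dict[str, float]], ModelConfig],
                 **objective_kwargs) -> tuple[ModelConfig, TuningResult]:
    """Grid-search free network scalars under the constraint objective.

    ``setter`` maps a parameter dict onto a new configuration; the best
    configuration (with ``kappa`` still uncalibrated) is returned with the
    full tuning log.
    """
    result = brute_force_tune(
        grid, lambda p: constraint_objective(setter(base, p), **objective_kwargs))
    return setter(base, result.best_params), result
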