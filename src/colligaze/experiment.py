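"""Experiment orchestration: full simulate -> decode -> control pipelines.

Ties the motor map, decoder and gaze controller into single-call conditions
and reproducible multi-condition experiment runs with manifests.  All
computations are deterministic: re-running an experiment produces
byte-identical output files.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import yaml

from .config import ConfigError, ModelConfig
from .controller import TrajectoryBundle, run_gaze_loop
from .decoder import GazeTrace, afferent_coordinate, decode_gaze_trajectory
from .motor_map import (MotorMap, SpikeRaster, build_motor_map,
                        simulate_network, write_rasters_tsv)


@dataclass(frozen=True)
class ConditionResult:
    """Everything produced for one (amplitude, E0, H0) condition."""

    amplitude: float
    E0: float
    H0: float
    motor_map: MotorMap
    input_raster: SpikeRaster
    sc_raster: SpikeRaster
    trace: GazeTrace
    bundle: TrajectoryBundle | None
    central_index: int


def simulate_condition(config: ModelConfig, amplitude: float, E0: float = 0.0,
                       H0: float = 0.0, duration: float = 300.0,
                       head_enabled: bool = True,
                       run_controller: bool = True) -> ConditionResult:
    """Run the full pipeline for one desired gaze shift.

    Builds the eye-position-modulated motor map, simulates the spiking
    network for the target's image point, decodes the desired gaze trace, and
    (optionally) runs the eye-head feedback loop.
    """
    u_T = afferent_coordinate(amplitude, config.efferent)
    if u_T > config.motor_map.map_length:
        raise ConfigError(f"amplitude {amplitude} deg maps outside the motor map")
    mm = build_motor_map(config.motor_map, config.adex, E0)
    inp, sc = simulate_network(mm, config.adex, config.input.with_target(u_T),
                               duration)
    trace = decode_gaze_trajectory(sc, config.efferent, analysis=config.analysis)
    bundle = None
    if run_controller:
        bundle = run_gaze_loop(trace, E0, H0, config.controller,
                               head_enabled=head_enabled)
    return ConditionResult(amplitude=float(amplitude), E0=float(E0), H0=float(H0),
                           motor_map=mm, input_raster=inp, sc_raster=sc,
                           trace=trace, bundle=bundle,
                           central_index=mm.central_unit(u_T))


@dataclass(frozen=True)
class ExperimentSpec:
    """A named list of gaze-shift conditions plus output location."""

    name: str
    conditions: tuple[tuple[float, float, float], ...]  # (amplitude, E0, H0)
    out_dir: str = "results"
    head_enabled: bool = True
    duration: float = 300.0
    seed: int = 0  # reserved; the pipeline is deterministic

    def __post_init__(self) -> None:
        if not self.name:
            raise ConfigError("experiment name must be non-empty")
        if len(self.conditions) == 0:
            raise ConfigError("experiment needs at least one condition")
        for amp, _e0, _h0 in self.conditions:
            if amp < 0:
                raise ConfigError(f"negative amplitude {amp} in conditions")

    def to_dict(self) -> dict:
        return {"name": self.name,
                "conditions": [list(c) for c in self.conditions],
                "out_dir": self.out_dir, "head_enabled": self.head_enabled,
                "duration": self.duration, "seed": self.seed}

    @classmethod
    def from_dict(cls, data: dict) -> "ExperimentSpec":
        if not isinstance(data, dict):
            raise ConfigError("experiment spec must be a mapping")
        known = {"name", "conditions", "out_dir", "head_enabled", "duration", "seed"}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown experiment keys: {sorted(unknown)}")
        if "name" not in data or "conditions" not in data:
            raise ConfigError("experiment spec requires 'name' and 'conditions'")
        conds = []
        for c in data["conditions"]:
            if len(c) != 3:
                raise ConfigError(f"condition {c!r} must be (amplitude, E0, H0)")
            conds.append(tuple(float(x) for x in c))
        return cls(name=str(data["name"]), conditions=tuple(conds),
                   out_dir=str(data.get("out_dir", "results")),
                   head_enabled=bool(data.get("head_enabled", True)),
                   duration=float(data.get("duration", 300.0)),
                   seed=int(data.get("seed", 0)))

    @classmethod
    def load(cls, path: str | Path) -> "ExperimentSpec":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


def _condition_dirname(amp: float, E0: float) -> str:
    sign = "+" if E0 >= 0 else "-"
    return f"{amp:g}deg_e0{sign}{abs(E0):g}"


def run_experiment(spec: ExperimentSpec, config: ModelConfig) -> dict:
    """Execute every condition and write the standard output bundle.

    Per condition: spike raster TSV, gaze-trace CSV, trajectory CSV with JSON
    sidecar.  A manifest records the config hash and per-condition status;
    a failing condition is recorded and does not abort the remaining ones.
    """
    out_root = Path(spec.out_dir) / spec.name
    out_root.mkdir(parents=True, exist_ok=True)
    chash = config.hash()
    manifest: dict = {"experiment": spec.name, "config_hash": chash,
                      "conditions": []}
    for amp, E0, H0 in spec.conditions:
        entry = {"amplitude": amp, "E0": E0, "H0": H0}
        cdir = out_root / _condition_dirname(amp, E0)
        try:
            res = simulate_condition(config, amp, E0, H0,
                                     duration=spec.duration,
                                     head_enabled=spec.head_enabled)
            cdir.mkdir(parents=True, exist_ok=True)
            write_rasters_tsv(cdir / "spikes.tsv",
                              [res.input_raster, res.sc_raster], chash)
            res.trace.to_csv(cdir / "gaze_trace.csv")
            if res.bundle is not None:
                res.bundle.to_csv(cdir / "trajectory.csv")
                res.bundle.save_sidecar(cdir / "trajectory.json", chash)
            entry.update(status="ok", dir=str(cdir),
                         files=["spikes.tsv", "gaze_trace.csv",
                                "trajectory.csv", "trajectory.json"])
        except Exception as exc:  # record partial completion
            entry.update(status="failed", error=f"{type(exc).__name__}: {exc}")
        manifest["conditions"].append(entry)
    (out_root / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
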