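"""Parameter containers and configuration I/O.

All quantities use the package-wide unit conventions: millivolts, nanosiemens,
picoamperes, picofarads, milliseconds, millimetres and degrees.  Every
container validates its invariants on construction, so a ``MotorMapSpec`` or
``ControllerParams`` instance that exists is safe to hand to the simulator.

Configurations round-trip through YAML with a versioned schema; unknown keys
are rejected so that a typo in a config file fails loudly instead of silently
falling back to a default.
"""

from __future__ import annotations

import dataclasses
import hashlib
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

SCHEMA_VERSION = 1


class ConfigError(ValueError):
    """Raised for malformed configuration input (bad keys, broken invariants)."""


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ConfigError(msg)


def _finite(obj: Any) -> None:
    for f in dataclasses.fields(obj):
        v = getattr(obj, f.name)
        if isinstance(v, (int, float)) and not math.isfinite(v):
            raise ConfigError(f"{type(obj).__name__}.{f.name} must be finite, got {v!r}")


@dataclass(frozen=True)
class MotorMapSpec:
    """Layout of the one-dimensional collicular motor map.

    The map holds ``n_units`` units spread uniformly over ``map_length`` mm of
    the rostral-caudal axis.  Feedforward weights and adaptation time
    constants decrease linearly from the rostral (small-saccade) to the caudal
    (large-saccade) pole; lateral connectivity is a Mexican-hat difference of
    Gaussians scaled by the site-dependent gain ``1 - s_coeff * u**2`` and by
    the eye-position gain ``gain_slope * E0 + gain_offset``.
    """

    n_units: int = 200
    map_length: float = 5.0          # mm
    w_ff_min: float = 4.0            # nS, caudal end of the feedforward ramp
    w_ff_max: float = 10.0           # nS, rostral end
    tau_min: float = 30.0            # ms, caudal adaptation time constant
    tau_max: float = 60.0            # ms, rostral
    w_exc_bar: float = 0.16          # nS, lateral excitatory amplitude
    w_inh_bar: float = 1.15          # nS, lateral inhibitory amplitude
    sigma_exc: float = 0.3           # mm, excitatory Gaussian width
    sigma_inh: float = 0.15          # mm, inhibitory Gaussian width
    s_coeff: float = 0.04            # mm^-2, site-dependent lateral gain
    gain_slope: float = -0.005       # deg^-1, eye-position gain slope
    gain_offset: float = 0.018       # eye-position gain at E0 = 0
    e0_min: float = -40.0            # deg, admissible initial eye positions
    e0_max: float = 40.0

    def __post_init__(self) -> None:
        _finite(self)
        _require(self.n_units >= 2, "n_units must be >= 2")
        _require(self.map_length > 0, "map_length must be > 0")
        _require(self.w_ff_min < self.w_ff_max, "w_ff_min must be < w_ff_max")
        _require(self.tau_min < self.tau_max, "tau_min must be < tau_max")
        _require(self.sigma_exc > 0 and self.sigma_inh > 0,
                 "lateral Gaussian widths must be positive")
        _require(self.e0_min < self.e0_max, "e0_min must be < e0_max")


@dataclass(frozen=True)
class AdExParams:
    """Intrinsic parameters of the adaptive exponential integrate-and-fire units.

    The membrane integrates leak, an exponential spike-initiation term, an
    adaptation current and conductance-based synaptic input; a spike is
    registered when the membrane reaches ``V_T``, after which the potential is
    reset to ``V_r`` and the adaptation current jumps by ``b_spike``.

    These constants are location-independent.  The shipped defaults were
    re-tuned in this package against the population constraints the model must
    satisfy (about 20 spikes for the central unit, about 450 spikes for the
    recruited population, a roughly 20 ms burst lag, and a rostral-to-caudal
    peak-rate gradient); they are not published values.
    """

    C: float = 150.0          # pF
    g_L: float = 10.0         # nS
    E_L: float = -70.0        # mV
    eta: float = 2.0          # mV, spike-initiation slope factor
    V_T: float = -50.0        # mV, spike threshold
    a_sub: float = 10.0       # nS, subthreshold adaptation
    b_spike: float = 132.0    # pA, spike-triggered adaptation increment
    V_r: float = -52.0        # mV, reset potential
    E_e: float = 0.0          # mV, excitatory reversal
    E_i: float = -85.0        # mV, inhibitory reversal
    tau_exc: float = 3.0      # ms
    tau_inh: float = 20.0     # ms
    tau_q_input: float = 60.0  # ms, adaptation time constant of input-layer units
    dt: float = 0.01          # ms, integration step

    def __post_init__(self) -> None:
        _finite(self)
        _require(self.C > 0 and self.g_L > 0 and self.eta > 0, "C, g_L, eta must be > 0")
        _require(self.tau_exc > 0 and self.tau_inh > 0, "synaptic taus must be > 0")
        _require(self.tau_q_input > 0, "tau_q_input must be > 0")
        _require(self.dt > 0, "dt must be > 0")
        _require(self.E_i < self.E_e, "E_i must be below E_e")
        _require(self.V_r <= self.V_T, "V_r must not exceed V_T")


@dataclass(frozen=True)
class InputProfile:
    """Separable spatial-temporal external input current.

    Space: a Gaussian of width ``sigma_pop`` centred on the target image point
    ``u_T``.  Time: a gamma-shaped pulse ``t**gamma_shape * exp(-beta_rate*t)``
    (t in seconds), normalised so its peak value is 1, which makes ``I0`` the
    realised maximum current on the central input unit.
    """

    I0: float = 14000.0          # pA, peak current
    sigma_pop: float = 0.64      # mm
    gamma_shape: float = 3.0     # dimensionless skewness
    beta_rate: float = 37.0      # s^-1, inverse duration
    u_T: float = 2.5             # mm, target image point

    def __post_init__(self) -> None:
        _finite(self)
        _require(self.I0 >= 0, "I0 must be >= 0")
        _require(self.sigma_pop > 0, "sigma_pop must be > 0")
        _require(self.gamma_shape > 0, "gamma_shape must be > 0")
        _require(self.beta_rate > 0, "beta_rate must be > 0")
        _require(self.u_T >= 0, "u_T must be >= 0")

    def with_target(self, u_T: float) -> "InputProfile":
        """Copy of this profile aimed at a different image point."""
        return dataclasses.replace(self, u_T=float(u_T))


@dataclass(frozen=True)
class EfferentMap:
    """Logarithmic afferent / exponential efferent magnification of the map.

    ``u = B_u * ln((dG + A)/A)`` maps a gaze amplitude (deg) onto its
    anatomical coordinate (mm); the inverse ``A*(exp(u/B_u) - 1)`` scaled by
    ``kappa`` is the gaze displacement contributed by one spike of a unit at
    coordinate ``u``.  ``kappa`` absorbs the assumed cell density and is fixed
    by calibrating the decoded amplitude of a 15 deg gaze shift.
    """

    A: float = 3.0          # deg
    B_u: float = 1.4        # mm
    kappa: float = 1.0      # dimensionless scaling, calibrated

    def __post_init__(self) -> None:
        _finite(self)
        _require(self.A > 0, "A must be > 0")
        _require(self.B_u > 0, "B_u must be > 0")
        _require(self.kappa > 0, "kappa must be > 0")


@dataclass(frozen=True)
class ControllerParams:
    """Parameters of the common gaze-feedback loop for eyes and head."""

    B_E: float = 60.0            # s^-1, linear ocular burst-generator gain
    B_H: float = 20.0            # s^-1, linear head burst-generator gain
    omr_bound: float = 30.0      # deg, soft oculomotor-range limit
    beta_omr: float = 0.03       # deg^-1, slope of the OMR soft limiter
    vor_slope: float = 0.03      # deg^-1, VOR gain suppression slope
    gh_slope: float = 0.05       # deg^-1, head-gain dependence on E0
    delay_base: float = 70.0     # ms, head-onset delay at dG = 0, E0 = 0
    delay_amp_slope: float = 0.72  # ms/deg, delay reduction per deg of amplitude
    T_E1: float = 200.0          # ms, ocular plant time constants
    T_E2: float = 20.0
    T_H1: float = 250.0          # ms, head plant time constants
    T_H2: float = 150.0
    efferent_delay: float = 10.0  # ms, common efferent motor delay
    dt_ctrl: float = 0.1         # ms, controller integration step
    onset_threshold: float = 1.0  # deg/s, desired-velocity level that opens the loop
    off_threshold: float = 0.2   # deg, residual gaze error that closes the burst latch
    fixation_tau: float = 200.0  # ms, decay of the fixation anchor on the OMR limiter
    head_damping: float = 5.0    # velocity-feedback gain stabilising the head loop
    horizon: float = 2000.0      # ms, simulated controller horizon

    def __post_init__(self) -> None:
        _finite(self)
        for name in ("T_E1", "T_E2", "T_H1", "T_H2"):
            _require(getattr(self, name) > 0, f"{name} must be > 0")
        _require(self.T_E1 != self.T_E2, "T_E1 and T_E2 must differ")
        _require(self.T_H1 != self.T_H2, "T_H1 and T_H2 must differ")
        _require(self.omr_bound > 0, "omr_bound must be > 0")
        _require(self.dt_ctrl > 0, "dt_ctrl must be > 0")
        _require(self.horizon > 0, "horizon must be > 0")


@dataclass(frozen=True)
class AnalysisParams:
    """Defaults for burst/movement analysis (grids, smoothing, detection)."""

    analysis_dt: float = 1.0      # ms, grid for decoded traces and rates
    savgol_window: int = 15       # samples, odd
    savgol_order: int = 2
    rate_sigma: float = 4.0       # ms, Gaussian kernel for firing-rate estimates
    vel_threshold: float = 20.0   # deg/s, movement-detection criterion
    hysteresis: float = 5.0       # ms, minimum supra-threshold duration
    lead_time: float = 10.0       # ms, neural lead of the collicular burst

    def __post_init__(self) -> None:
        _finite(self)
        _require(self.analysis_dt > 0, "analysis_dt must be > 0")
        _require(self.savgol_window % 2 == 1 and self.savgol_window > self.savgol_order,
                 "savgol_window must be odd and exceed savgol_order")
        _require(self.rate_sigma > 0, "rate_sigma must be > 0")
        _require(self.vel_threshold > 0, "vel_threshold must be > 0")
        _require(self.lead_time >= 0, "lead_time must be >= 0")


_SECTIONS = {
    "motor_map": MotorMapSpec,
    "adex": AdExParams,
    "input": InputProfile,
    "efferent": EfferentMap,
    "controller": ControllerParams,
    "analysis": AnalysisParams,
}


@dataclass(frozen=True)
class ModelConfig:
    """Complete model configuration: one block per subsystem."""

    motor_map: MotorMapSpec = field(default_factory=MotorMapSpec)
    adex: AdExParams = field(default_factory=AdExParams)
    input: InputProfile = field(default_factory=InputProfile)
    efferent: EfferentMap = field(default_factory=EfferentMap)
    controller: ControllerParams = field(default_factory=ControllerParams)
    analysis: AnalysisParams = field(default_factory=AnalysisParams)

    def to_dict(self) -> dict:
        d: dict[str, Any] = {"schema_version": SCHEMA_VERSION}
        for name in _SECTIONS:
            d[name] = dataclasses.asdict(getattr(self, name))
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "ModelConfig":
        if not isinstance(data, dict):
            raise ConfigError("config root must be a mapping")
        data = dict(data)
        version = data.pop("schema_version", SCHEMA_VERSION)
        if version != SCHEMA_VERSION:
            raise ConfigError(f"unsupported schema_version {version!r}")
        unknown = set(data) - set(_SECTIONS)
        if unknown:
            raise ConfigError(f"unknown config sections: {sorted(unknown)}")
        kwargs = {}
        for name, typ in _SECTIONS.items():
            block = data.get(name, {})
            if not isinstance(block, dict):
                raise ConfigError(f"section {name!r} must be a mapping")
            valid = {f.name for f in dataclasses.fields(typ)}
            bad = set(block) - valid
            if bad:
                raise ConfigError(f"unknown keys in section {name!r}: {sorted(bad)}")
            kwargs[name] = typ(**block)
        return cls(**kwargs)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "ModelConfig":
        return cls.from_dict(yaml.safe_load(text))

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_yaml())

    @classmethod
    def load(cls, path: str | Path) -> "ModelConfig":
        return cls.from_yaml(Path(path).read_text())

    def hash(self) -> str:
        """Short digest of the canonicalised config text, for output manifests."""
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:12]

    def replace(self, **sections: Any) -> "ModelConfig":
        return dataclasses.replace(self, **sections)


def default_config() -> ModelConfig:
    """The shipped tuned configuration (see ``colligaze/data/default_config.yaml``)."""
    from importlib import resources

    ref = resources.files("colligaze.data").joinpath("default_config.yaml")
    return ModelConfig.from_yaml(ref.read_text())
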