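"""Common gaze-feedback loop converting desired gaze velocity into eye and
head trajectories.

The comparator integrates the difference between the desired gaze velocity
(decoded from the collicular population) and the fed-back eye and head
velocities into a gaze motor error G_ERR.  Adding the eye-position estimate
from the oculomotor neural integrator turns this into a craniocentric error,
which a soft tanh limiter keeps within the oculomotor range before a linear
burst generator produces the desired eye velocity.  The actual eye velocity
command subtracts the gain-modulated vestibulo-ocular reflex (VOR) driven by
actual head velocity.  The head is driven in parallel by the same
craniocentric error, scaled by an eye-position-dependent gain and gated by an
onset delay that shrinks with planned gaze amplitude and ipsilateral initial
eye position; its command passes through a sluggish second-order plant.

Gaze is the sum of eye-in-head and head-on-neck at every sample, so the loop
drives gaze to the decoded amplitude even though the eye/head division of
labour varies with the initial conditions.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .config import ConfigError, ControllerParams
from .decoder import GazeTrace


class ControlError(RuntimeError):
    """Non-convergent feedback loop (gaze error growing without bound)."""


def omr_soft_limit(H_ERR, params: ControllerParams):
    """Soft oculomotor-range limiter: desired eye-in-head position (deg).

    Odd, monotone, bounded by +/- ``omr_bound``.
    """
    return params.omr_bound * np.tanh(params.beta_omr * np.asarray(H_ERR, float))


def vor_gain(G_ERR, params: ControllerParams):
    """VOR gain 1 - tanh(slope * G_ERR), clipped to [0, 1].

    Fully engaged (1) when gaze is on target, suppressed toward 0 for large
    gaze errors; the clip removes the unphysiological >1 branch for negative
    errors.
    """
    g = 1.0 - np.tanh(params.vor_slope * np.asarray(G_ERR, float))
    return np.clip(g, 0.0, 1.0)


def head_gain_and_delay(delta_G_planned: float, E0: float,
                        params: ControllerParams) -> tuple[float, float]:
    """Head recruitment gain g_H(E0) and head-onset delay dT_H (ms).

    ``g_H = 0.5*(1 + tanh(gh_slope * E0))`` and
    ``dT_H = delay_base - delay_amp_slope*|dG| - E0``, floored at 0 ms for
    causality.
    """
    if delta_G_planned < 0:
        raise ConfigError("planned amplitude must be non-negative")
    g_H = 0.5 * (1.0 + math.tanh(params.gh_slope * E0))
    dT_H = params.delay_base - params.delay_amp_slope * abs(delta_G_planned) - E0
    return g_H, max(dT_H, 0.0)


def plant_impulse_response(tau_ms, T1: float, T2: float) -> np.ndarray:
    """Two-exponential plant impulse response (1/ms), unit integral."""
    if T1 == T2:
        raise ConfigError("degenerate plant kernel: T1 must differ from T2")
    tau = np.asarray(tau_ms, dtype=float)
    out = (np.exp(-tau / T1) - np.exp(-tau / T2)) / (T1 - T2)
    return np.where(tau >= 0, out, 0.0)


def plant_filter(command: np.ndarray, T1: float, T2: float, dt: float) -> np.ndarray:
    """Filter a velocity command through the second-order plant.

    Implemented as two cascaded exact first-order stages (zero-order hold),
    equivalent to discrete convolution with the two-exponential impulse
    response; DC gain is exactly 1.
    """
    if T1 == T2:
        raise ConfigError("degenerate plant kernel: T1 must differ from T2")
    command = np.asarray(command, dtype=float)
    a1 = math.exp(-dt / T1)
    a2 = math.exp(-dt / T2)
    y1 = np.empty_like(command)
    y2 = np.empty_like(command)
    s1 = 0.0
    s2 = 0.0
    for k in range(command.size):
        s1 = a1 * s1 + (1.0 - a1) * command[k]
        s2 = a2 * s2 + (1.0 - a2) * s1
        y1[k] = s1
        y2[k] = s2
    return y2


@dataclass(frozen=True)
class TrajectoryBundle:
    """Eye, head and gaze traces plus loop internals from one gaze shift.

    Positions in deg, velocities in deg/s, time in ms.  ``G = E + H`` holds at
    every sample.  ``edot_des`` and ``g_v`` expose the burst-generator output
    and VOR gain so the loop identity ``Edot_des = Edot + g_V * Hdot`` can be
    verified externally.
    """

    t: np.ndarray
    E: np.ndarray
    H: np.ndarray
    G: np.ndarray
    Edot: np.ndarray
    Hdot: np.ndarray
    Gdot: np.ndarray
    edot_des: np.ndarray
    g_v: np.ndarray
    omr_clamped: np.ndarray  # samples where the eye sat on its mechanical stop
    E_mech: np.ndarray      # mechanically filtered eye trace (reporting only)
    delta_T_H: float        # ms
    g_H: float
    t_loop_on: float        # ms, comparator integration start
    t_eye_onset: float      # ms, eye-movement onset (velocity criterion)
    t_head_gate: float      # ms, head-command gate opening (inf if never)
    E0: float
    H0: float
    planned_amplitude: float

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    def gaze_displacement(self) -> np.ndarray:
        return self.G - (self.E0 + self.H0)

    def to_csv(self, path: str | Path) -> None:
        header = "t_ms,E_deg,H_deg,G_deg,Edot_deg_s,Hdot_deg_s,Gdot_deg_s"
        data = np.column_stack([self.t, self.E, self.H, self.G,
                                self.Edot, self.Hdot, self.Gdot])
        np.savetxt(path, data, delimiter=",", header=header, comments="",
                   fmt="%.6f")

    def sidecar(self, config_hash: str = "") -> dict:
        return {
            "delta_T_H_ms": self.delta_T_H,
            "g_H": self.g_H,
            "t_loop_on_ms": self.t_loop_on,
            "t_eye_onset_ms": self.t_eye_onset,
            "t_head_gate_ms": self.t_head_gate,
            "E0_deg": self.E0,
            "H0_deg": self.H0,
            "planned_amplitude_deg": self.planned_amplitude,
            "config_hash": config_hash,
        }

    def save_sidecar(self, path: str | Path, config_hash: str = "") -> None:
        Path(path).write_text(json.dumps(self.sidecar(config_hash), indent=2))


def run_gaze_loop(trace: GazeTrace, E0: float, H0: float,
                  params: ControllerParams | None = None,
                  head_enabled: bool = True,
                  error_bound: float = 500.0) -> TrajectoryBundle:
    """Run the eye-head feedback loop on a decoded desired-velocity trace.

    Parameters
    ----------
    trace
        Decoded gaze trace; its final displacement is the planned amplitude
        available feedforwardly (from the population spike count) for the
        head-onset delay.
    E0, H0
        Initial eye-in-head and head-on-neck orientations (deg).
    params
        Controller constants; defaults to the published values.
    head_enabled
        With False the head gain is forced to 0 (head-fixed simulations).
    error_bound
        Abort threshold on |G_ERR| (deg), diagnosing a non-convergent loop.

    Notes
    -----
    The comparator opens when the desired gaze velocity first exceeds
    ``params.onset_threshold``.  The reported trajectories are shifted by the
    common efferent delay.  Eye-position feedback E(t) comes from the neural
    integrator (the integral of the velocity command); the mechanically
    filtered eye trace is reported separately and plays no role in the loop.
    """
    params = params or ControllerParams()
    if abs(E0) > params.omr_bound:
        raise ConfigError(f"E0 = {E0} deg outside the oculomotor range")

    dt = params.dt_ctrl
    n = int(round(params.horizon / dt))
    t = np.arange(n) * dt
    gdot_des = np.interp(t, trace.t, trace.g_dot_des, left=0.0, right=0.0)

    planned = trace.amplitude
    g_H, dT_H = head_gain_and_delay(planned, E0, params)
    if not head_enabled:
        g_H = 0.0

    above = np.flatnonzero(gdot_des > params.onset_threshold)
    k_on = int(above[0]) if above.size else n  # loop may never open (empty burst)

    E = np.full(n, float(E0))
    H = np.full(n, float(H0))
    Edot = np.zeros(n)
    Hdot = np.zeros(n)
    edot_des_arr = np.zeros(n)
    g_v_arr = np.ones(n)
    hdot_des_arr = np.zeros(n)
    clamped_arr = np.zeros(n, dtype=bool)

    a1 = math.exp(-dt / params.T_H1)
    a2 = math.exp(-dt / params.T_H2)
    s1 = 0.0
    s2 = 0.0

    G_ERR = 0.0
    e = float(E0)
    h = float(H0)
    hdot = 0.0
    k_eye_on = None
    k_head_gate = None
    dt_s = dt / 1000.0

    # fixation anchor: the soft limiter alone cannot hold an eccentric eye
    # (tanh compresses even moderate positions), which would fire a spurious
    # re-centring burst at loop opening; offsetting the limiter so its output
    # equals E0 at onset removes the transient while the hard clip keeps the
    # desired eye position inside the mechanical range
    c_fix0 = E0 - params.omr_bound * math.tanh(params.beta_omr * E0)

    burst_latched = True  # burst generator enabled while the gaze shift runs

    for k in range(k_on, n):
        # comparator: integrate desired minus fed-back gaze velocity
        G_ERR += dt_s * (gdot_des[k] - Edot[k - 1] - Hdot[k - 1]) if k > 0 else 0.0
        if abs(G_ERR) > error_bound:
            raise ControlError(
                f"gaze error diverged (|G_ERR| > {error_bound} deg) at t = {t[k]:.1f} ms")
        # the saccadic latch: the burst path stays active while gaze error
        # remains, and shuts once the error is nulled (omnipause re-engages);
        # a renewed desired-velocity input reopens it
        burst_latched = (abs(G_ERR) > params.off_threshold
                         or gdot_des[k] > params.onset_threshold)
        H_ERR = G_ERR + e
        c_fix = c_fix0 * math.exp(-(t[k] - t[k_on]) / params.fixation_tau)
        H_DES_eye = params.omr_bound * math.tanh(params.beta_omr * H_ERR) + c_fix
        H_DES_eye = min(max(H_DES_eye, -params.omr_bound), params.omr_bound)
        E_ERR = H_DES_eye - e
        if burst_latched:
            edot_des = params.B_E * E_ERR
            g_v = min(max(1.0 - math.tanh(params.vor_slope * G_ERR), 0.0), 1.0)
        else:
            # gaze on target: burst off, VOR fully engaged stabilises gaze
            edot_des = 0.0
            g_v = 1.0

        # head path first, so the VOR senses this sample's head velocity
        gate_open = (k_eye_on is not None
                     and t[k] >= t[k_eye_on] + dT_H)
        if gate_open and k_head_gate is None:
            k_head_gate = k
        # head burst generator: craniocentric error scaled by the head gain,
        # with velocity feedback damping the loop around the sluggish plant
        # (the undamped loop rings badly through the vestibular coupling)
        if gate_open:
            hdot_des = (params.B_H * g_H * H_ERR
                        - params.head_damping * hdot)
        else:
            hdot_des = 0.0

        # head plant: cascaded exact first-order stages
        s1 = a1 * s1 + (1.0 - a1) * hdot_des
        s2 = a2 * s2 + (1.0 - a2) * s1
        hdot = s2

        edot = edot_des - g_v * hdot
        if k_eye_on is None and abs(edot) > params.onset_threshold:
            k_eye_on = k
        elif k_eye_on is None and t[k] >= t[k_on] + 50.0:
            # the eye never left its stop (fully eccentric start): reference
            # the head-onset delay to the loop opening instead
            k_eye_on = k_on

        # mechanical stop: the globe cannot rotate past the oculomotor range,
        # whatever the VOR commands; excess velocity is absorbed by the stop
        e_new = e + dt_s * edot
        clamped = abs(e_new) > params.omr_bound
        if clamped:
            e_new = math.copysign(params.omr_bound, e_new)
            edot = (e_new - e) / dt_s
        e = e_new
        h += dt_s * hdot

        Edot[k] = edot
        clamped_arr[k] = clamped
        Hdot[k] = hdot
        E[k] = e
        H[k] = h
        edot_des_arr[k] = edot_des
        g_v_arr[k] = g_v
        hdot_des_arr[k] = hdot_des

    # common efferent delay: motor output lags the neural command
    shift = int(round(params.efferent_delay / dt))

    def delayed(x: np.ndarray, fill: float) -> np.ndarray:
        if shift == 0:
            return x
        return np.concatenate([np.full(shift, fill), x[:-shift]])

    E_d = delayed(E, E0)
    H_d = delayed(H, H0)
    Edot_d = delayed(Edot, 0.0)
    Hdot_d = delayed(Hdot, 0.0)
    G_d = E_d + H_d
    Gdot_d = Edot_d + Hdot_d
    E_mech = E0 + np.cumsum(plant_filter(Edot_d, params.T_E1, params.T_E2, dt)) * dt_s

    return TrajectoryBundle(
        t=t, E=E_d, H=H_d, G=G_d, Edot=Edot_d, Hdot=Hdot_d, Gdot=Gdot_d,
        edot_des=delayed(edot_des_arr, 0.0), g_v=delayed(g_v_arr, 1.0),
        omr_clamped=delayed(clamped_arr.astype(float), 0.0) > 0.5,
        E_mech=E_mech, delta_T_H=dT_H, g_H=g_H,
        t_loop_on=float(t[k_on]) if k_on < n else float("inf"),
        t_eye_onset=float(t[k_eye_on]) if k_eye_on is not None else float("inf"),
        t_head_gate=float(t[k_head_gate]) if k_head_gate is not None else float("inf"),
        E0=float(E0), H0=float(H0), planned_amplitude=planned,
    )
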