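"""Fixed-step integration kernel for the two-layer spiking network.

Forward Euler on membrane potential and adaptation current at the configured
resolution, with exact exponential decay of the synaptic conductances between
spikes.  Spikes take effect on the following time step (one-step synaptic
latency), which keeps the update order unambiguous and the simulation
bit-reproducible.

Compiled with numba; the kernel is pure (no Python objects) and deterministic.
"""

import numpy as np
from numba import njit

STATUS_OK = 0
STATUS_NONFINITE = 1
STATUS_OVERFLOW = 2

_EXPARG_MAX = 20.0  # clip of the spike-initiation exponent; V resets at V_T anyway


@njit(cache=True)
def integrate_two_layer(
    dt,
    n_steps,
    C, g_L, E_L, eta, V_T, a_sub, b_spike, V_r, E_e, E_i,
    tau_exc, tau_inh, tau_q_input,
    tau_q_sc,          # (n,) adaptation time constants of the SC layer
    I_space,           # (n,) spatial input-current profile, pA
    I_time,            # (n_steps,) temporal input profile, dimensionless
    w_ff,              # (n,) feedforward weights input -> SC, nS
    W_exc,             # (n, n) lateral excitatory weights, W[i, j] from i to j
    W_inh,             # (n, n) lateral inhibitory weights
    max_spikes,
):
    n = tau_q_sc.shape[0]
    dec_e = np.exp(-dt / tau_exc)
    dec_i = np.exp(-dt / tau_inh)

    V_in = np.full(n, E_L)
    q_in = np.zeros(n)
    V_sc = np.full(n, E_L)
    q_sc = np.zeros(n)
    ge = np.zeros(n)
    gi = np.zeros(n)
    inc_e = np.zeros(n)
    inc_i = np.zeros(n)

    in_units = np.empty(max_spikes, np.int64)
    in_times = np.empty(max_spikes, np.float64)
    sc_units = np.empty(max_spikes, np.int64)
    sc_times = np.empty(max_spikes, np.float64)
    n_in = 0
    n_sc = 0

    spiked_in = np.zeros(n, np.bool_)
    spiked_sc = np.zeros(n, np.bool_)

    status = STATUS_OK
    bad_unit = -1
    bad_time = -1.0

    for step in range(n_steps):
        t = step * dt

        # --- input layer: non-interacting AdEx units driven by the current ---
        for j in range(n):
            spiked_in[j] = False
            V = V_in[j]
            q = q_in[j]
            I = I_space[j] * I_time[step]
            arg = (V - V_T) / eta
            if arg > _EXPARG_MAX:
                arg = _EXPARG_MAX
            dV = (dt / C) * (-g_L * (V - E_L) + g_L * eta * np.exp(arg) - q + I)
            dq = (dt / tau_q_input) * (a_sub * (V - E_L) - q)
            V += dV
            q += dq
            if V >= V_T:
                if n_in >= max_spikes:
                    return (in_units, in_times, n_in, sc_units, sc_times, n_sc,
                            STATUS_OVERFLOW, j, t)
                in_units[n_in] = j
                in_times[n_in] = t
                n_in += 1
                V = V_r
                q += b_spike
                spiked_in[j] = True
            if not (np.isfinite(V) and np.isfinite(q)):
                return (in_units, in_times, n_in, sc_units, sc_times, n_sc,
                        STATUS_NONFINITE, j, t)
            V_in[j] = V
            q_in[j] = q

        # --- SC layer: conductance-based synapses, lateral interactions ---
        for j in range(n):
            spiked_sc[j] = False
            g_exc = ge[j] * dec_e + inc_e[j]
            g_inh = gi[j] * dec_i + inc_i[j]
            V = V_sc[j]
            q = q_sc[j]
            I_syn = g_exc * (E_e - V) + g_inh * (E_i - V)
            arg = (V - V_T) / eta
            if arg > _EXPARG_MAX:
                arg = _EXPARG_MAX
            dV = (dt / C) * (-g_L * (V - E_L) + g_L * eta * np.exp(arg) - q + I_syn)
            dq = (dt / tau_q_sc[j]) * (a_sub * (V - E_L) - q)
            V += dV
            q += dq
            if V >= V_T:
                if n_sc >= max_spikes:
                    return (in_units, in_times, n_in, sc_units, sc_times, n_sc,
                            STATUS_OVERFLOW, j, t)
                sc_units[n_sc] = j
                sc_times[n_sc] = t
                n_sc += 1
                V = V_r
                q += b_spike
                spiked_sc[j] = True
            if not (np.isfinite(V) and np.isfinite(q)):
                return (in_units, in_times, n_in, sc_units, sc_times, n_sc,
                        STATUS_NONFINITE, j, t)
            V_sc[j] = V
            q_sc[j] = q
            ge[j] = g_exc
            gi[j] = g_inh

        # --- queue synaptic increments for the next step ---
        for j in range(n):
            inc_e[j] = w_ff[j] if spiked_in[j] else 0.0
            inc_i[j] = 0.0
        for i in range(n):
            if spiked_sc[i]:
                for j in range(n):
                    inc_e[j] += W_exc[i, j]
                    inc_i[j] += W_inh[i, j]

    return (in_units, in_times, n_in, sc_units, sc_times, n_sc,
            status, bad_unit, bad_time)


@njit(cache=True)
def integrate_single_adex(
    dt, n_steps,
    C, g_L, E_L, eta, V_T, a_sub, b_spike, V_r,
    tau_q, I_const, max_spikes,
):
    """One isolated AdEx unit under constant current; used for convergence checks."""
    V = E_L
    q = 0.0
    times = np.empty(max_spikes, np.float64)
    k = 0
    for step in range(n_steps):
        arg = (V - V_T) / eta
        if arg > _EXPARG_MAX:
            arg = _EXPARG_MAX
        dV = (dt / C) * (-g_L * (V - E_L) + g_L * eta * np.exp(arg) - q + I_const)
        dq = (dt / tau_q) * (a_sub * (V - E_L) - q)
        V += dV
        q += dq
        if V >= V_T:
            if k >= max_spikes:
                return times, k
            times[k] = step * dt
            k += 1
            V = V_r
            q += b_spike
    return times, k
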