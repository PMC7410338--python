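"""Independent one-model-at-a-time cable integrator used as a test oracle.

Same mathematical scheme as the production kernel (staggered gates, theta=1/2
semi-implicit voltage step) but written directly against scipy's banded
solver with exact ``exp`` evaluation instead of lookup tables, and without
early termination.  Kept free of any production solver code so that
agreement between the two is a meaningful cross-check.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.linalg import solve_banded

from thermaxon.kinetics import gate_inf, gate_tau, temperature_factor
from thermaxon.membrane import AxonSpec, ChannelSet, MembraneSpec, Q10Set


def reference_velocity(
    axon: AxonSpec,
    membrane: MembraneSpec,
    channels: ChannelSet,
    q10: Q10Set,
    T: float,
    stimulus_nA: float,
    dt: float = 0.0125,
    t_stop: float = 80.0,
):
    """Velocity (m/s) or None if the distal site never crosses 0 mV."""
    N = axon.n_comp
    dx = axon.dx_um * 1e-4
    a = axon.diameter_um * 1e-4 / 2.0
    g_ax = (2 * a) / (4 * axon.R_a * dx * dx) * 1000.0
    gNa, gK, gL = (
        membrane.g_Na_bar * 1e3,
        membrane.g_K_bar * 1e3,
        membrane.g_leak_bar * 1e3,
    )
    E_L = membrane.solve_E_leak(channels)
    gates = (
        channels.na_activation,
        channels.na_inactivation,
        channels.k_activation,
    )
    R_g = {
        "g_Na": temperature_factor(q10.g_Na, T),
        "g_K": temperature_factor(q10.g_K, T),
        "g_leak": temperature_factor(q10.g_leak, T),
    }
    R_tau = [
        temperature_factor(q10.tau_m, T),
        temperature_factor(q10.tau_h, T),
        temperature_factor(q10.tau_n, T),
    ]
    sens = np.arange(N) >= axon.n_insensitive

    V = np.full(N, membrane.V_rest)
    x = [np.full(N, float(gate_inf(membrane.V_rest, g))) for g in gates]

    area0 = math.pi * (2 * a) * dx
    stim = stimulus_nA * 1e-3 / area0
    i1, i2 = axon.rec1_index, axon.rec2_index
    nb = np.full(N, 2.0)
    nb[0] = nb[-1] = 1.0

    t1 = t2 = None
    p1, p2 = V[i1], V[i2]
    nsteps = int(round(t_stop / dt))
    for it in range(nsteps):
        t = it * dt
        for k, g in enumerate(gates):
            xi = gate_inf(V, g)
            tau = gate_tau(V, g) / np.where(sens, R_tau[k], 1.0)
            x[k] = xi + (x[k] - xi) * np.exp(-dt / tau)
        gna = gNa * np.where(sens, R_g["g_Na"], 1.0) * x[0] ** gates[0].exponent * (
            x[1] ** gates[1].exponent
        )
        gk = gK * np.where(sens, R_g["g_K"], 1.0) * x[2] ** gates[2].exponent
        gl = gL * np.where(sens, R_g["g_leak"], 1.0)
        gtot = gna + gk + gl
        src = gna * membrane.E_Na + gk * membrane.E_K + gl * E_L
        if t < 1.0:
            src = src.copy()
            src[0] += stim
        ax_v = np.zeros(N)
        ax_v[1:-1] = g_ax * (V[:-2] - 2 * V[1:-1] + V[2:])
        ax_v[0] = g_ax * (V[1] - V[0])
        ax_v[-1] = g_ax * (V[-2] - V[-1])
        theta = 0.5
        diag = membrane.C_m / dt + theta * gtot + 0.5 * nb * g_ax
        rhs = membrane.C_m / dt * V + 0.5 * ax_v + src - (1 - theta) * gtot * V
        ab = np.zeros((3, N))
        ab[0, 1:] = -0.5 * g_ax
        ab[2, :-1] = -0.5 * g_ax
        ab[1] = diag
        Vn = solve_banded((1, 1), ab, rhs)
        if t1 is None and p1 < 0.0 <= Vn[i1]:
            t1 = t + dt * (0.0 - p1) / (Vn[i1] - p1)
        if t2 is None and p2 < 0.0 <= Vn[i2]:
            t2 = t + dt * (0.0 - p2) / (Vn[i2] - p2)
        p1, p2 = Vn[i1], Vn[i2]
        V = Vn
    if t1 is None or t2 is None:
        return None
    return axon.span_cm / (t2 - t1) * 10.0
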