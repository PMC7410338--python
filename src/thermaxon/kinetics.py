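"""Voltage-dependent gating kinetics and Q10 temperature scaling.

Each Hodgkin-Huxley gate is described by a logistic steady-state curve and a
single-exponential voltage dependence of its time constant:

    x_inf(V) = 1 / (1 + exp(-k_inf * (V_half_inf - V)))
    tau_x(V) = A_tau * exp(k_tau * (V - V_half_tau))        [ms]

Temperature enters through a dimensionless factor R = Q10**((T - T_base)/10)
that multiplies maximal conductances (g(T) = g_base * R) and divides gate time
constants (tau(T) = tau_base / R).  At the baseline temperature R = 1 for any
Q10, so all model variants are identical there.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "GateKinetics",
    "gate_inf",
    "gate_tau",
    "temperature_factor",
    "NA_ACTIVATION",
    "NA_INACTIVATION",
    "K_ACTIVATION",
    "T_BASE",
]

#: Baseline temperature (degC) at which kinetics and conductances are defined.
T_BASE = 10.0


@dataclass(frozen=True)
class GateKinetics:
    """Parameters of one voltage-dependent gate.

    Parameters
    ----------
    k_inf : float
        Slope of the steady-state logistic (1/mV).  Negative values give
        curves that increase with depolarization (activation gates).
    V_half_inf : float
        Half-maximum potential of the steady-state curve (mV).
    A_tau : float
        Time-constant scale (ms); the value of tau at ``V_half_tau``.
    k_tau : float
        Voltage slope of the time constant (1/mV).
    V_half_tau : float
        Reference potential of the time-constant exponential (mV).
    exponent : int
        Power of the gate in the channel's conductance product.
    """

    k_inf: float
    V_half_inf: float
    A_tau: float
    k_tau: float
    V_half_tau: float
    exponent: int = 1

    def __post_init__(self) -> None:
        if self.A_tau <= 0:
            raise ValueError(f"A_tau must be positive, got {self.A_tau}")
        if self.exponent < 1:
            raise ValueError(f"exponent must be >= 1, got {self.exponent}")


def gate_inf(V, gk: GateKinetics):
    """Steady-state open fraction of a gate at membrane potential ``V`` (mV)."""
    with np.errstate(over="ignore"):  # saturates to 0 in the tails
        return 1.0 / (1.0 + np.exp(-gk.k_inf * (gk.V_half_inf - V)))


def gate_tau(V, gk: GateKinetics, R: float = 1.0):
    """Gate time constant (ms) at ``V`` (mV), scaled by temperature factor ``R``.

    The time constant shortens with warming: ``tau(T) = tau_base / R``.
    """
    if np.any(np.asarray(R) <= 0):
        raise ValueError(f"temperature factor R must be positive, got {R}")
    return gk.A_tau * np.exp(gk.k_tau * (V - gk.V_half_tau)) / R


def temperature_factor(Q10, T, T_base: float = T_BASE):
    """Temperature scaling factor ``R = Q10**((T - T_base)/10)``.

    ``R`` is 1 at the baseline temperature and equals ``Q10`` one decade
    (10 degC) above it; it is multiplicative over temperature differences.
    """
    Q10 = np.asarray(Q10, dtype=float)
    if np.any(Q10 <= 0):
        raise ValueError(f"Q10 must be positive, got {Q10}")
    return Q10 ** ((np.asarray(T, dtype=float) - T_base) / 10.0)


# Default gate parameter sets (baseline 10 degC).  The Na activation
# time-constant slope is -0.05/mV, in line with the shallow slopes of the other
# two gates; steeper slopes make activation effectively instantaneous at
# suprathreshold voltages, which produces grid-limited (non-convergent)
# conduction and unphysically fast fronts.
NA_ACTIVATION = GateKinetics(
    k_inf=-0.4, V_half_inf=-36.0, A_tau=2.0, k_tau=-0.05, V_half_tau=-40.0, exponent=3
)
NA_INACTIVATION = GateKinetics(
    k_inf=1.0, V_half_inf=-39.5, A_tau=40.0, k_tau=-0.025, V_half_tau=-55.0, exponent=1
)
K_ACTIVATION = GateKinetics(
    k_inf=-0.125, V_half_inf=-33.0, A_tau=55.0, k_tau=-0.015, V_half_tau=-28.0, exponent=4
)
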