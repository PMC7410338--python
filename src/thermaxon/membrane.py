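"""Membrane, geometry and Q10 specifications for the model axon."""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Iterator

from .kinetics import (
    GateKinetics,
    NA_ACTIVATION,
    NA_INACTIVATION,
    K_ACTIVATION,
    gate_inf,
)

__all__ = ["MembraneSpec", "AxonSpec", "Q10Set", "ChannelSet"]

#: Names of the six temperature-scalable channel properties.
Q10_PROPERTIES = ("g_Na", "tau_m", "g_leak", "tau_h", "g_K", "tau_n")


@dataclass(frozen=True)
class ChannelSet:
    """The three voltage-dependent gates of the Na/K/leak membrane."""

    na_activation: GateKinetics = NA_ACTIVATION
    na_inactivation: GateKinetics = NA_INACTIVATION
    k_activation: GateKinetics = K_ACTIVATION


@dataclass(frozen=True)
class MembraneSpec:
    """Passive membrane and maximal conductances (baseline temperature).

    Conductances are specific (S/cm^2), potentials in mV, capacitance in
    uF/cm^2.  ``E_leak`` is not free: it is solved so that the total membrane
    current vanishes at ``V_rest`` with all gates at steady state, which pins
    the resting potential exactly.
    """

    C_m: float = 1.0
    V_rest: float = -60.0
    g_Na_bar: float = 0.48
    g_K_bar: float = 1.088
    g_leak_bar: float = 0.0016
    E_Na: float = 50.0
    E_K: float = -80.0

    def __post_init__(self) -> None:
        for name in ("C_m", "g_Na_bar", "g_K_bar", "g_leak_bar"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def resting_gates(self, channels: ChannelSet) -> tuple[float, float, float]:
        """Steady-state (m, h, n) at the resting potential."""
        V = self.V_rest
        return (
            float(gate_inf(V, channels.na_activation)),
            float(gate_inf(V, channels.na_inactivation)),
            float(gate_inf(V, channels.k_activation)),
        )

    def solve_E_leak(self, channels: ChannelSet) -> float:
        """Leak reversal potential (mV) balancing the membrane at rest."""
        m0, h0, n0 = self.resting_gates(channels)
        g_na = self.g_Na_bar * m0 ** channels.na_activation.exponent * (
            h0 ** channels.na_inactivation.exponent
        )
        g_k = self.g_K_bar * n0 ** channels.k_activation.exponent
        V = self.V_rest
        return V + (g_na * (V - self.E_Na) + g_k * (V - self.E_K)) / self.g_leak_bar


@dataclass(frozen=True)
class AxonSpec:
    """Cable geometry and measurement layout.

    The axon is a uniform unmyelinated cylinder.  A short temperature-
    insensitive segment at the stimulated end isolates AP initiation from
    temperature; its length is the excess of the total length over the
    4 cm functional distance.  Arrival times are taken at two sites:
    ``rec1_offset`` past the insensitive region and ``rec2_offset`` before the
    distal end, and timing statistics extrapolate each axon's velocity over
    ``functional_distance``.
    """

    diameter_um: float = 3.0
    total_length_cm: float = 4.075
    dx_um: float = 50.0
    R_a: float = 28.0  # axial resistivity, Ohm*cm
    stim_region_cm: float = 0.075
    rec1_offset_cm: float = 0.5
    rec2_offset_cm: float = 1.5
    functional_distance_cm: float = 4.0

    def __post_init__(self) -> None:
        if self.diameter_um <= 0 or self.dx_um <= 0 or self.R_a <= 0:
            raise ValueError("diameter, dx and R_a must be positive")
        if self.rec1_pos_cm >= self.rec2_pos_cm:
            raise ValueError("rec1 must lie proximal to rec2")

    @property
    def n_comp(self) -> int:
        return int(round(self.total_length_cm / (self.dx_um * 1e-4)))

    @property
    def n_insensitive(self) -> int:
        """Compartments in the temperature-insensitive stimulated segment."""
        return int(round(self.stim_region_cm / (self.dx_um * 1e-4)))

    @property
    def rec1_pos_cm(self) -> float:
        return self.stim_region_cm + self.rec1_offset_cm

    @property
    def rec2_pos_cm(self) -> float:
        return self.total_length_cm - self.rec2_offset_cm

    @property
    def rec1_index(self) -> int:
        return int(round(self.rec1_pos_cm / (self.dx_um * 1e-4)))

    @property
    def rec2_index(self) -> int:
        return int(round(self.rec2_pos_cm / (self.dx_um * 1e-4)))

    @property
    def span_cm(self) -> float:
        """Distance between the two recording sites."""
        return (self.rec2_index - self.rec1_index) * self.dx_um * 1e-4


@dataclass(frozen=True)
class Q10Set:
    """Per-property temperature sensitivities of one model variant.

    A Q10 of 1 makes the property temperature-insensitive; the sweep grid uses
    values in {1.5, 2, 3, 4} with the two Potassium properties held at 1.5.
    """

    g_Na: float = 1.0
    tau_m: float = 1.0
    g_leak: float = 1.0
    tau_h: float = 1.0
    g_K: float = 1.0
    tau_n: float = 1.0

    def __post_init__(self) -> None:
        for name in Q10_PROPERTIES:
            if getattr(self, name) <= 0:
                raise ValueError(f"Q10 for {name} must be positive")

    def __getitem__(self, name: str) -> float:
        if name not in Q10_PROPERTIES:
            raise KeyError(name)
        return getattr(self, name)

    def items(self) -> Iterator[tuple[str, float]]:
        return ((name, getattr(self, name)) for name in Q10_PROPERTIES)

    def to_dict(self) -> dict[str, float]:
        return asdict(self)
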