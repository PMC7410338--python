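"""Action-potential propagation along the temperature-scaled cable axon.

The public entry points are :func:`simulate_propagation` for a single model
variant and :func:`simulate_batch` for many Q10 variants sharing one axon,
temperature and stimulus (the sweep workhorse).  Velocity is measured between
two recording sites as span / (t2 - t1) from the first upward crossings of the
detection threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import _kernel
from ._kernel import FAILED, NUMERICAL, OK
from .kinetics import GateKinetics, T_BASE, gate_inf, gate_tau, temperature_factor
from .membrane import AxonSpec, ChannelSet, MembraneSpec, Q10Set

__all__ = [
    "SolverSettings",
    "StimulusSpec",
    "SimulationResult",
    "simulate_propagation",
    "simulate_batch",
    "find_threshold",
    "measure_velocity",
    "default_window_ms",
    "voltage_traces",
]


@dataclass(frozen=True)
class SolverSettings:
    """Time step and detection thresholds of the integrator."""

    dt_ms: float = 0.0125
    detect_mV: float = 0.0
    fail_mV: float = -20.0

    def __post_init__(self) -> None:
        if self.dt_ms <= 0:
            raise ValueError("dt_ms must be positive")


@dataclass(frozen=True)
class StimulusSpec:
    """Square current pulse injected into the first compartment.

    ``amplitude_nA = None`` requests automatic calibration to
    ``threshold_factor`` times the AP threshold found by bisection at the
    baseline temperature; measured velocity is insensitive to the
    suprathreshold amplitude.
    """

    amplitude_nA: float | None = None
    duration_ms: float = 1.0
    threshold_factor: float = 2.0


@dataclass(frozen=True)
class SimulationResult:
    """Arrival times and conduction velocity of one propagated AP."""

    temperature: float
    arrival_time_rec1_ms: float | None
    arrival_time_rec2_ms: float | None
    velocity_m_per_s: float | None
    failed: bool
    status: str  # "ok" | "failed" | "numerical"
    peak_rec2_mV: float = float("nan")
    model: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ok = self.status == "ok"
        if ok and (self.velocity_m_per_s is None or self.velocity_m_per_s <= 0):
            raise ValueError("successful propagation requires a positive velocity")
        if not ok and self.velocity_m_per_s is not None:
            raise ValueError("failed propagation cannot carry a velocity")
        if ok and self.arrival_time_rec2_ms <= self.arrival_time_rec1_ms:
            raise ValueError("distal arrival must come after proximal arrival")

    def to_json(self) -> str:
        import dataclasses
        import json

        return json.dumps(dataclasses.asdict(self), default=float)


_STATUS_NAMES = {OK: "ok", FAILED: "failed", NUMERICAL: "numerical"}


def voltage_traces(
    axon: AxonSpec,
    membrane: MembraneSpec,
    channels: ChannelSet = ChannelSet(),
    q10: Q10Set = Q10Set(),
    T: float = T_BASE,
    stimulus_nA: float = 0.0,
    probe_positions_cm: Sequence[float] = (0.575, 2.575),
    settings: SolverSettings = SolverSettings(),
    t_stop_ms: float = 100.0,
    csv_path=None,
):
    """Voltage time courses at probe positions (cm from the stimulated end).

    Returns a DataFrame with ``time_ms`` and one column per probe; with
    ``csv_path`` set it is also written to CSV.  A zero stimulus records the
    resting behaviour of the membrane.
    """
    import pandas as pd

    out: dict = {}
    simulate_batch(
        axon,
        membrane,
        channels,
        [q10],
        T,
        stimulus_nA,
        settings,
        t_stop_ms,
        probe_positions_cm=probe_positions_cm,
        trace_out=out,
    )
    df = pd.DataFrame(
        {"time_ms": out["times_ms"]}
        | {
            f"V_{p:g}cm_mV": out["traces_mV"][0, :, i]
            for i, p in enumerate(probe_positions_cm)
        }
    ).dropna()
    if csv_path is not None:
        df.to_csv(csv_path, index=False)
    return df


def measure_velocity(t1_ms: float, t2_ms: float, span_cm: float) -> float:
    """Conduction velocity in m/s from arrival times at two sites.

    ``span_cm / (t2 - t1)`` in cm/ms equals 10 m/s, hence the factor.
    """
    if t2_ms <= t1_ms:
        raise ValueError("distal arrival must come after proximal arrival")
    return span_cm / (t2_ms - t1_ms) * 10.0


def default_window_ms(axon: AxonSpec) -> float:
    """Conservative simulation window when no baseline transit is known.

    Sized for fronts as slow as ~0.35 m/s at 3 um (velocity scales with the
    square root of diameter).
    """
    v_floor = 0.35 * math.sqrt(axon.diameter_um / 3.0)  # m/s
    return 1.5 * axon.rec2_pos_cm / (v_floor / 10.0)


def _decay_tables(
    Vg: np.ndarray, gk: GateKinetics, R_values: Sequence[float], dt: float
) -> np.ndarray:
    tau = gate_tau(Vg, gk)  # baseline tau(V)
    return np.exp(-dt * np.asarray(R_values)[:, None] / tau[None, :])


def simulate_batch(
    axon: AxonSpec,
    membrane: MembraneSpec,
    channels: ChannelSet,
    q10_sets: Sequence[Q10Set],
    T: float,
    stimulus_nA: float,
    settings: SolverSettings = SolverSettings(),
    t_stop_ms: float | None = None,
    stim_duration_ms: float = 1.0,
    probe_positions_cm: Sequence[float] | None = None,
    trace_out: dict | None = None,
) -> list[SimulationResult]:
    """Integrate many Q10 variants of one axon at one temperature.

    All variants share geometry, membrane, kinetics and stimulus; they differ
    only in the per-property temperature factors applied outside the
    temperature-insensitive stimulated segment.
    """
    if not 0.0 <= T <= 40.0:
        raise ValueError(f"temperature {T} outside supported range [0, 40] degC")
    M = len(q10_sets)
    N = axon.n_comp
    dt = settings.dt_ms
    if t_stop_ms is None:
        t_stop_ms = default_window_ms(axon)
    nsteps = int(round(t_stop_ms / dt))

    # per-model temperature factors
    fac = {
        name: np.array([temperature_factor(q[name], T) for q in q10_sets])
        for name in ("g_Na", "g_K", "g_leak", "tau_m", "tau_h", "tau_n")
    }

    # gate tables: steady states shared; decay factors per distinct R
    Vg = _kernel.build_voltage_grid()
    gates = {
        "tau_m": channels.na_activation,
        "tau_h": channels.na_inactivation,
        "tau_n": channels.k_activation,
    }
    rows, dec, row1 = {}, {}, {}
    for name, gk in gates.items():
        uniq = np.unique(np.concatenate([fac[name], [1.0]]))
        dec[name] = _decay_tables(Vg, gk, uniq, dt)
        lookup = {r: i for i, r in enumerate(uniq)}
        rows[name] = np.array([lookup[r] for r in fac[name]], dtype=np.int64)
        row1[name] = lookup[1.0]

    inf_tabs = {
        "tau_m": gate_inf(Vg, channels.na_activation),
        "tau_h": gate_inf(Vg, channels.na_inactivation),
        "tau_n": gate_inf(Vg, channels.k_activation),
    }

    # initial state: uniform rest with gates at steady state
    m0, h0, n0 = membrane.resting_gates(channels)
    V = np.full((M, N), membrane.V_rest)
    m = np.full((M, N), m0)
    h = np.full((M, N), h0)
    n = np.full((M, N), n0)

    a_cm = axon.diameter_um * 1e-4 / 2.0
    dx_cm = axon.dx_um * 1e-4
    g_ax = (2.0 * a_cm) / (4.0 * axon.R_a * dx_cm**2) * 1000.0  # mS/cm^2
    area0 = math.pi * (2.0 * a_cm) * dx_cm  # cm^2
    stim_dens = stimulus_nA * 1e-3 / area0  # uA/cm^2
    E_L = membrane.solve_E_leak(channels)

    t1 = np.full(M, -1.0)
    t2 = np.full(M, -1.0)
    peak2 = np.full(M, membrane.V_rest)
    status = np.zeros(M, dtype=np.int64)

    if probe_positions_cm is not None:
        dx = axon.dx_um * 1e-4
        probes = np.array(
            [min(N - 1, int(round(p / dx))) for p in probe_positions_cm],
            dtype=np.int64,
        )
        traces = np.full((M, nsteps + 1, probes.size), np.nan)
    else:
        probes = np.empty(0, dtype=np.int64)
        traces = np.empty((M, 1, 0))

    _kernel.integrate_batch(
        V,
        m,
        h,
        n,
        fac["g_Na"],
        fac["g_K"],
        fac["g_leak"],
        rows["tau_m"],
        rows["tau_h"],
        rows["tau_n"],
        inf_tabs["tau_m"],
        inf_tabs["tau_h"],
        inf_tabs["tau_n"],
        dec["tau_m"],
        dec["tau_h"],
        dec["tau_n"],
        row1["tau_m"],
        row1["tau_h"],
        row1["tau_n"],
        membrane.g_Na_bar * 1000.0,
        membrane.g_K_bar * 1000.0,
        membrane.g_leak_bar * 1000.0,
        channels.na_activation.exponent,
        channels.na_inactivation.exponent,
        channels.k_activation.exponent,
        membrane.E_Na,
        membrane.E_K,
        E_L,
        membrane.C_m,
        g_ax,
        axon.n_insensitive,
        stim_dens,
        int(round(stim_duration_ms / dt)),
        axon.rec1_index,
        axon.rec2_index,
        settings.detect_mV,
        dt,
        nsteps,
        t1,
        t2,
        peak2,
        status,
        probes,
        traces,
    )
    if probe_positions_cm is not None and trace_out is not None:
        trace_out["times_ms"] = dt * np.arange(nsteps + 1)
        trace_out["traces_mV"] = traces
        trace_out["probe_indices"] = probes

    results = []
    for j, q in enumerate(q10_sets):
        stat = _STATUS_NAMES[int(status[j])]
        if stat == "ok":
            vel = measure_velocity(t1[j], t2[j], axon.span_cm)
            res = SimulationResult(
                temperature=T,
                arrival_time_rec1_ms=float(t1[j]),
                arrival_time_rec2_ms=float(t2[j]),
                velocity_m_per_s=vel,
                failed=False,
                status=stat,
                peak_rec2_mV=float(peak2[j]),
                model={"q10": q.to_dict(), "diameter_um": axon.diameter_um},
            )
        else:
            res = SimulationResult(
                temperature=T,
                arrival_time_rec1_ms=float(t1[j]) if t1[j] >= 0 else None,
                arrival_time_rec2_ms=None,
                velocity_m_per_s=None,
                failed=stat == "failed",
                status=stat,
                peak_rec2_mV=float(peak2[j]),
                model={"q10": q.to_dict(), "diameter_um": axon.diameter_um},
            )
        results.append(res)
    return results


def simulate_propagation(
    axon: AxonSpec,
    membrane: MembraneSpec,
    channels: ChannelSet = ChannelSet(),
    q10: Q10Set = Q10Set(),
    T: float = T_BASE,
    stimulus: StimulusSpec = StimulusSpec(),
    settings: SolverSettings = SolverSettings(),
    t_stop_ms: float | None = None,
) -> SimulationResult:
    """Propagate a single AP along one model axon and measure its velocity."""
    amp = stimulus.amplitude_nA
    if amp is None:
        amp = stimulus.threshold_factor * find_threshold(
            axon, membrane, channels, settings=settings
        )
    return simulate_batch(
        axon,
        membrane,
        channels,
        [q10],
        T,
        amp,
        settings,
        t_stop_ms,
        stim_duration_ms=stimulus.duration_ms,
    )[0]


def find_threshold(
    axon: AxonSpec,
    membrane: MembraneSpec,
    channels: ChannelSet = ChannelSet(),
    stimulus_duration_ms: float = 1.0,
    settings: SolverSettings = SolverSettings(),
    rel_tol: float = 0.02,
) -> float:
    """AP threshold current (nA) of the 1 ms pulse, by bisection at baseline.

    An amplitude counts as suprathreshold when the proximal recording site
    fires within a short window; the distal cable does not matter for
    initiation, so the window only needs to cover the stimulated end.
    """
    window = 0.45 * default_window_ms(axon)

    def fires(amp: float) -> bool:
        res = simulate_batch(
            axon, membrane, channels, [Q10Set()], T_BASE, amp, settings, window
        )[0]
        return res.arrival_time_rec1_ms is not None

    lo, hi = 0.0, 4.0 * math.sqrt(axon.diameter_um / 3.0)
    for _ in range(24):
        if fires(hi):
            break
        lo, hi = hi, 2.0 * hi
    else:
        raise RuntimeError("no stimulus amplitude initiated an AP")
    while (hi - lo) > rel_tol * hi:
        mid = 0.5 * (lo + hi)
        if fires(mid):
            hi = mid
        else:
            lo = mid
    return hi
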