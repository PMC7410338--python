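"""Exhaustive Q10 sweeps: enumeration, execution and persistence.

The sweep enumerates every combination of per-property Q10 values in a fixed
nesting order (Na conductance outermost, then Na activation tau, leak
conductance, Na inactivation tau innermost), runs the cable model for each
variant across diameters and temperatures, and collects the velocities into a
flat table.  The baseline temperature is simulated once per diameter and
broadcast to every variant, since all temperature factors are 1 there.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .kinetics import T_BASE
from .membrane import AxonSpec, ChannelSet, MembraneSpec, Q10Set, Q10_PROPERTIES
from .solver import SolverSettings, StimulusSpec, find_threshold, simulate_batch

__all__ = [
    "SweepGrid",
    "enumerate_q10_sets",
    "run_sweep",
    "persist_table",
    "load_table",
    "TABLE_COLUMNS",
]

TABLE_COLUMNS = [
    "model_index",
    "q_gNa",
    "q_tau_m",
    "q_gLeak",
    "q_tau_h",
    "diameter_um",
    "temp_C",
    "velocity_m_per_s",
    "failed",
    "status",
]

_COL_FOR_PROP = {"g_Na": "q_gNa", "tau_m": "q_tau_m", "g_leak": "q_gLeak", "tau_h": "q_tau_h"}


@dataclass(frozen=True)
class SweepGrid:
    """The grid of Q10 combinations, diameters and temperatures to sweep."""

    q10_values: tuple[float, ...] = (1.5, 2.0, 3.0, 4.0)
    varied_properties: tuple[str, ...] = ("g_Na", "tau_m", "g_leak", "tau_h")
    fixed_properties: Mapping[str, float] = field(
        default_factory=lambda: {"g_K": 1.5, "tau_n": 1.5}
    )
    diameters_um: tuple[float, ...] = (3.0, 6.0, 12.0)
    temperatures: tuple[float, ...] = (5.0, 10.0, 15.0, 20.0, 25.0, 30.0)

    def __post_init__(self) -> None:
        if not self.q10_values:
            raise ValueError("q10_values must not be empty")
        if not self.varied_properties:
            raise ValueError("varied_properties must not be empty")
        if not self.diameters_um:
            raise ValueError("diameters_um must not be empty")
        if not self.temperatures:
            raise ValueError("temperatures must not be empty")
        if any(v <= 0 for v in self.q10_values):
            raise ValueError("q10_values must be positive")
        names = list(self.varied_properties) + list(self.fixed_properties)
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate property names in grid: {names}")
        unknown = set(names) - set(Q10_PROPERTIES)
        if unknown:
            raise ValueError(
                f"unknown properties {sorted(unknown)}; allowed: {Q10_PROPERTIES}"
            )

    @property
    def n_models(self) -> int:
        return len(self.q10_values) ** len(self.varied_properties)


def enumerate_q10_sets(grid: SweepGrid) -> list[Q10Set]:
    """All Q10 combinations in deterministic nesting order.

    The first listed property varies outermost (slowest); the last varies
    innermost.  Index 0 has every property at the smallest grid value and the
    last index has every property at the largest.
    """
    sets: list[Q10Set] = []
    k = len(grid.q10_values)
    p = len(grid.varied_properties)
    for idx in range(grid.n_models):
        digits = []
        rem = idx
        for pos in range(p - 1, -1, -1):
            digits.append(rem % k)
            rem //= k
        digits.reverse()  # outermost first
        kwargs = dict(grid.fixed_properties)
        for prop, d in zip(grid.varied_properties, digits):
            kwargs[prop] = grid.q10_values[d]
        sets.append(Q10Set(**kwargs))
    return sets


def _config_hash(
    grid: SweepGrid,
    axon: AxonSpec,
    membrane: MembraneSpec,
    channels: ChannelSet,
    settings: SolverSettings,
    stimulus_nA: float,
) -> str:
    blob = json.dumps(
        {
            "grid": {**asdict(grid), "fixed_properties": dict(grid.fixed_properties)},
            "axon": asdict(axon),
            "membrane": asdict(membrane),
            "channels": asdict(channels),
            "settings": asdict(settings),
            "stimulus_nA": stimulus_nA,
        },
        sort_keys=True,
        default=float,
    )
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_sweep(
    grid: SweepGrid,
    membrane: MembraneSpec = MembraneSpec(),
    channels: ChannelSet = ChannelSet(),
    axon_template: AxonSpec = AxonSpec(),
    settings: SolverSettings = SolverSettings(),
    stimulus: StimulusSpec = StimulusSpec(),
    cache_dir: str | Path | None = None,
    verbose: bool = False,
) -> pd.DataFrame:
    """Run the full sweep and return the velocity table.

    One row per (model, diameter, temperature); failures are recorded, never
    dropped, and solver instabilities are kept distinct from biological
    propagation failures in the ``status`` column.  With ``cache_dir`` set,
    each (diameter, temperature) batch is stored on disk keyed by a hash of
    the full configuration, making re-runs over a partial cache idempotent.
    """
    sets = enumerate_q10_sets(grid)
    frames = []
    for diameter in grid.diameters_um:
        axon = replace(axon_template, diameter_um=diameter)
        amp = stimulus.amplitude_nA
        if amp is None:
            amp = stimulus.threshold_factor * find_threshold(
                axon, membrane, channels, stimulus.duration_ms, settings
            )
        key = _config_hash(grid, axon, membrane, channels, settings, amp)

        # baseline once per diameter; broadcast to all model indices
        base = simulate_batch(
            axon, membrane, channels, [Q10Set()], T_BASE, amp, settings,
            stim_duration_ms=stimulus.duration_ms,
        )[0]
        if base.status != "ok":
            raise RuntimeError(
                f"baseline propagation failed at {diameter} um ({base.status})"
            )
        window = 3.0 * base.arrival_time_rec2_ms

        for T in grid.temperatures:
            cache_file = None
            if cache_dir is not None:
                cache_file = Path(cache_dir) / f"sweep_{key}_d{diameter:g}_T{T:g}.csv"
                if cache_file.exists():
                    frames.append(pd.read_csv(cache_file))
                    if verbose:
                        print(f"  cache hit: d={diameter} um T={T} C")
                    continue
            if T == T_BASE:
                vel = np.full(len(sets), base.velocity_m_per_s)
                status = np.full(len(sets), "ok", dtype=object)
            else:
                res = simulate_batch(
                    axon, membrane, channels, sets, T, amp, settings, window,
                    stim_duration_ms=stimulus.duration_ms,
                )
                vel = np.array(
                    [r.velocity_m_per_s if r.status == "ok" else np.nan for r in res]
                )
                status = np.array([r.status for r in res], dtype=object)
            df = pd.DataFrame(
                {
                    "model_index": np.arange(len(sets)),
                    "q_gNa": [q.g_Na for q in sets],
                    "q_tau_m": [q.tau_m for q in sets],
                    "q_gLeak": [q.g_leak for q in sets],
                    "q_tau_h": [q.tau_h for q in sets],
                    "diameter_um": diameter,
                    "temp_C": T,
                    "velocity_m_per_s": vel,
                    "failed": status == "failed",
                    "status": status,
                }
            )
            if cache_file is not None:
                cache_file.parent.mkdir(parents=True, exist_ok=True)
                df.to_csv(cache_file, index=False)
            frames.append(df)
            if verbose:
                n_bad = int((status != "ok").sum())
                print(f"  d={diameter} um T={T} C done ({n_bad} non-ok)")
    table = pd.concat(frames, ignore_index=True)
    return table[TABLE_COLUMNS]


def persist_table(
    table: pd.DataFrame,
    path: str | Path,
    metadata: dict | None = None,
) -> None:
    """Write the velocity table as CSV plus a JSON sidecar with provenance.

    Velocities are written with full float precision (round-trip exact).
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False, float_format="%.17g")
    sidecar = {"columns": list(table.columns), "n_rows": int(len(table))}
    if metadata:
        sidecar.update(metadata)
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=2, sort_keys=True, default=float) + "\n"
    )


def load_table(path: str | Path) -> pd.DataFrame:
    """Load a velocity table, validating its schema."""
    path = Path(path)
    table = pd.read_csv(path)
    missing = [c for c in TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(
            f"velocity table {path} is missing required column(s): {missing}"
        )
    return table[TABLE_COLUMNS]
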