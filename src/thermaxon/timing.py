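"""Derived statistics of the velocity sweep.

Velocity Q10 estimators, the inter-axon delay matrix, the temperature-
robustness classification, delay-vs-Q10-ratio regressions, necessity and
sufficiency tests of ratio coordination, high/low Q10 proportions and the
coefficient-of-variation analysis.

Conventions
-----------
*Arrival time* of an axon at temperature T is the transit time over the 4 cm
functional distance, ``t(T) = distance / v(T)``.

*Delay* between a small- and a large-diameter axon at T is the change,
relative to the 10 degC baseline, of the difference of their arrival times::

    delay(i, j; T) = [t_small_i(T) - t_small_i(10)] - [t_large_j(T) - t_large_j(10)]

Positive delays mean the AP on the smaller (slower) axon arrives late
relative to the baseline timing.  A pair is *temperature-robust* when the
magnitude of its delay stays below the robustness threshold; pairs in which
either model failed to propagate are never robust.

*Q10 ratios* divide the smaller axon's property by the larger axon's.  This
orientation is the one under which the coordination statistics of the robust
set close: simple algebra on the delay definition shows that robust timing
requires the smaller (slower) axon to speed up *less* than the larger one, so
the robust set is bounded above in the small/large ratio (tau_m ratios up to
~1.5 for 3 vs 6 um) while the large/small orientation leaves it unbounded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "velocity_q10_endpoint",
    "velocity_q10_regression",
    "windowed_q10",
    "DelayMatrix",
    "compute_delay_matrix",
    "RobustnessCriterion",
    "classify_robust",
    "q10_ratio",
    "ratio_matrix",
    "RatioRegression",
    "regress_delay_on_ratio",
    "observed_ratio_range",
    "necessity_test",
    "sufficiency_test",
    "high_low_proportion",
    "cv_analysis",
    "uniform_grid_cv",
    "RATIO_TOL",
]

#: tolerance when comparing grid Q10 ratios against printed interval bounds
RATIO_TOL = 1e-9

_PROP_COLS = {"g_Na": "q_gNa", "tau_m": "q_tau_m", "g_leak": "q_gLeak", "tau_h": "q_tau_h"}


# ---------------------------------------------------------------------------
# velocity Q10 estimators
# ---------------------------------------------------------------------------

def velocity_q10_endpoint(v5: float, v15: float) -> float:
    """Velocity Q10 from the 5 and 15 degC endpoints: ``(v15/v5)**(10/10)``."""
    if v5 <= 0 or v15 <= 0:
        raise ValueError("endpoint velocities must be positive (no failures)")
    return v15 / v5

def velocity_q10_regression(temps: Sequence[float], velocities: Sequence[float]) -> float:
    """Q10 from the slope of log10(velocity) against temperature.

    ``Q10 = 10**(10*slope)``; agrees exactly with the endpoint estimator when
    velocity is perfectly exponential in temperature.
    """
    temps = np.asarray(temps, dtype=float)
    velocities = np.asarray(velocities, dtype=float)
    if temps.size < 3:
        raise ValueError("need at least 3 temperature points")
    if np.any(velocities <= 0):
        raise ValueError("velocities must be positive")
    slope = stats.linregress(temps, np.log10(velocities)).slope
    return float(10.0 ** (10.0 * slope))

def windowed_q10(
    temps: Sequence[float], velocities: Sequence[float]
) -> pd.DataFrame:
    """Per-increment Q10 between successive temperature points.

    For each consecutive pair (T_i, T_{i+1}) the local slope gives
    ``Q10 = (v_{i+1}/v_i)**(10/(T_{i+1}-T_i))``.  Returns a frame with the
    window bounds and the windowed Q10.
    """
    temps = np.asarray(temps, dtype=float)
    velocities = np.asarray(velocities, dtype=float)
    order = np.argsort(temps)
    temps, velocities = temps[order], velocities[order]
    if temps.size < 2:
        raise ValueError("need at least 2 temperature points")
    if np.any(velocities <= 0):
        raise ValueError("velocities must be positive")
    dT = np.diff(temps)
    if np.any(dT <= 0):
        raise ValueError("temperatures must be distinct")
    q = (velocities[1:] / velocities[:-1]) ** (10.0 / dT)
    return pd.DataFrame({"T_lo": temps[:-1], "T_hi": temps[1:], "q10": q})


# ---------------------------------------------------------------------------
# delay matrix
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DelayMatrix:
    """Inter-axon delays at one temperature for one diameter pair.

    ``delays_ms[i, j]`` is the delay of small-axon model ``i`` against
    large-axon model ``j``; entries where either model failed are NaN with
    ``valid`` False.  ``baseline_ms`` holds the two baseline arrival times
    over the functional distance.
    """

    temperature: float
    small_diameter_um: float
    large_diameter_um: float
    delays_ms: np.ndarray  # (n_small, n_large)
    valid: np.ndarray  # bool, same shape
    baseline_small_ms: float
    baseline_large_ms: float
    distance_cm: float = 4.0

    @property
    def n_pairs(self) -> int:
        return self.delays_ms.size


def _slice(table: pd.DataFrame, diameter: float, T: float) -> pd.DataFrame:
    s = table[
        (table["diameter_um"] == diameter) & (table["temp_C"] == T)
    ].sort_values("model_index")
    if s.empty:
        raise ValueError(f"no rows for diameter {diameter} um at {T} C")
    return s

def compute_delay_matrix(
    table: pd.DataFrame,
    small_diameter_um: float,
    large_diameter_um: float,
    temperature: float,
    baseline_temp: float = 10.0,
    distance_cm: float = 4.0,
) -> DelayMatrix:
    """Delay of every (small-axon model, large-axon model) pair at one T."""
    t_ms = {}
    base_ms = {}
    for d in (small_diameter_um, large_diameter_um):
        st = _slice(table, d, temperature)
        sb = _slice(table, d, baseline_temp)
        v = st["velocity_m_per_s"].to_numpy()
        vb = sb["velocity_m_per_s"].to_numpy()
        # transit time over the functional distance: cm / (m/s) -> ms
        t_ms[d] = np.where(v > 0, distance_cm / v * 10.0, np.nan)
        base_ms[d] = distance_cm / vb * 10.0
    dev_small = t_ms[small_diameter_um] - base_ms[small_diameter_um]
    dev_large = t_ms[large_diameter_um] - base_ms[large_diameter_um]
    delays = dev_small[:, None] - dev_large[None, :]
    valid = np.isfinite(delays)
    return DelayMatrix(
        temperature=temperature,
        small_diameter_um=small_diameter_um,
        large_diameter_um=large_diameter_um,
        delays_ms=delays,
        valid=valid,
        baseline_small_ms=float(np.mean(base_ms[small_diameter_um])),
        baseline_large_ms=float(np.mean(base_ms[large_diameter_um])),
        distance_cm=distance_cm,
    )


# ---------------------------------------------------------------------------
# robustness classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RobustnessCriterion:
    """Resolution of "less than 5% deviation from control" into milliseconds.

    The default mode ``absolute`` uses a single threshold of 1.3 ms at every
    temperature — the criterion's quoted value, which equals ~5% of the mean
    baseline transit time over 4 cm for the diameter pairs studied.  Two
    alternative modes support sensitivity analysis:
    ``pair_mean_baseline_fraction`` recomputes ``fraction`` times the mean of
    the two baseline arrival times per pair (1.34 ms for 3v6, 1.17 ms for
    3v12), and ``per_temperature_absolute`` takes an explicit temperature ->
    ms mapping.
    """

    mode: str = "absolute"
    threshold: float = 1.3
    fraction: float = 0.05
    absolute_thresholds: Mapping[float, float] = field(default_factory=dict)

    def threshold_ms(self, delays: DelayMatrix) -> float:
        if self.mode == "absolute":
            if self.threshold <= 0:
                raise ValueError("threshold must be positive")
            return float(self.threshold)
        if self.mode == "pair_mean_baseline_fraction":
            if self.fraction <= 0:
                raise ValueError("fraction must be positive")
            return self.fraction * 0.5 * (
                delays.baseline_small_ms + delays.baseline_large_ms
            )
        if self.mode == "per_temperature_absolute":
            try:
                thr = self.absolute_thresholds[delays.temperature]
            except KeyError:
                raise KeyError(
                    f"no absolute threshold given for T={delays.temperature}"
                ) from None
            if thr <= 0:
                raise ValueError("threshold must be positive")
            return float(thr)
        raise ValueError(f"unknown robustness mode {self.mode!r}")

def classify_robust(
    delays: DelayMatrix, criterion: RobustnessCriterion = RobustnessCriterion()
) -> tuple[np.ndarray, int]:
    """Boolean robustness matrix and the count of robust pairs.

    Failed pairs (NaN delay) are always non-robust but stay in the
    denominator of all percentage statistics.
    """
    thr = criterion.threshold_ms(delays)
    robust = delays.valid & (np.abs(delays.delays_ms) < thr)
    return robust, int(robust.sum())


# ---------------------------------------------------------------------------
# Q10 ratios
# ---------------------------------------------------------------------------

def q10_ratio(small_value: float, large_value: float) -> float:
    """Channel-property Q10 ratio: smaller axon's value over larger axon's.

    On the {1.5, 2, 3, 4} grid the achievable ratios span 0.375 (= 1.5/4)
    through 8/3 (= 4/1.5, printed as 2.67).
    """
    if large_value <= 0 or small_value <= 0:
        raise ValueError("Q10 values must be positive")
    return small_value / large_value

def ratio_matrix(
    table: pd.DataFrame,
    small_diameter_um: float,
    large_diameter_um: float,
    small_property: str,
    large_property: str,
    temperature: float = 10.0,
) -> np.ndarray:
    """Matrix of Q10 ratios (small-axon property / large-axon property).

    Indexed like the delay matrix: rows are small-axon models, columns
    large-axon models.
    """
    qs = _slice(table, small_diameter_um, temperature)[
        _PROP_COLS[small_property]
    ].to_numpy()
    ql = _slice(table, large_diameter_um, temperature)[
        _PROP_COLS[large_property]
    ].to_numpy()
    return qs[:, None] / ql[None, :]


@dataclass(frozen=True)
class RatioRegression:
    """OLS fit of delay against a channel-property Q10 ratio."""

    small_property: str
    large_property: str
    temperature: float
    slope_ms_per_ratio: float
    intercept_ms: float
    r_squared: float
    n: int

def regress_delay_on_ratio(
    delays: DelayMatrix,
    ratios: np.ndarray,
    small_property: str,
    large_property: str,
) -> RatioRegression:
    """Linear regression of delay on ratio over non-failed pairs."""
    mask = delays.valid
    x = ratios[mask]
    y = delays.delays_ms[mask]
    fit = stats.linregress(x, y)
    return RatioRegression(
        small_property=small_property,
        large_property=large_property,
        temperature=delays.temperature,
        slope_ms_per_ratio=float(fit.slope),
        intercept_ms=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        n=int(mask.sum()),
    )

def observed_ratio_range(
    robust: np.ndarray, ratios: np.ndarray
) -> tuple[float, float]:
    """Min/max Q10 ratio represented in the robust set."""
    vals = ratios[robust]
    if vals.size == 0:
        raise ValueError("robust set is empty; ratio range undefined")
    return float(vals.min()), float(vals.max())


# ---------------------------------------------------------------------------
# necessity / sufficiency
# ---------------------------------------------------------------------------

def _in_interval(ratios: np.ndarray, interval: tuple[float, float]) -> np.ndarray:
    lo, hi = interval
    return (ratios >= lo - RATIO_TOL) & (ratios <= hi + RATIO_TOL)

def necessity_test(
    robust: np.ndarray, ratios: np.ndarray, interval: tuple[float, float]
) -> float:
    """Percentage of pairs *outside* the ratio interval that are non-robust.

    100% means the interval is necessary: no pair violating it achieves
    temperature-robust timing.  Raises if no pair lies outside the interval
    (the test would be vacuous).
    """
    outside = ~_in_interval(ratios, interval)
    n_out = int(outside.sum())
    if n_out == 0:
        raise ValueError("no pairs outside the interval; necessity undefined")
    return float(100.0 * (~robust[outside]).sum() / n_out)

def sufficiency_test(
    robust: np.ndarray, ratios_or_mask, interval: tuple[float, float] | None = None
) -> float:
    """Percentage of pairs *inside* the ratio interval that are robust.

    Accepts either a ratio matrix plus interval, or a precomputed boolean
    mask of "coordinated" pairs (e.g. the conjunction of two intervals).
    """
    if interval is not None:
        inside = _in_interval(np.asarray(ratios_or_mask, dtype=float), interval)
    else:
        inside = np.asarray(ratios_or_mask, dtype=bool)
    n_in = int(inside.sum())
    if n_in == 0:
        raise ValueError("no pairs satisfy the predicate; sufficiency undefined")
    return float(100.0 * robust[inside].sum() / n_in)


# ---------------------------------------------------------------------------
# high/low proportions and coefficient of variation
# ---------------------------------------------------------------------------

def _ratio_combos(values: Sequence[float]) -> dict[float, list[tuple[float, float]]]:
    """Achievable (small, large) Q10 pairs per small/large ratio value."""
    combos: dict[float, list[tuple[float, float]]] = {}
    for small in values:
        for large in values:
            r = small / large
            for key in combos:
                if abs(key - r) < RATIO_TOL:
                    r = key
                    break
            combos.setdefault(r, []).append((small, large))
    return combos

def high_low_proportion(
    robust: np.ndarray,
    small_q10: np.ndarray,
    large_q10: np.ndarray,
    grid_values: Sequence[float] = (1.5, 2.0, 3.0, 4.0),
) -> pd.DataFrame:
    """Share of "high" Q10 combinations among robust pairs, per ratio bin.

    Only ratios achievable by more than one (small, large) combination are
    informative; within each such bin the achievable combinations are ranked
    by their Q10 values and the upper half counts as "high" (for the diagonal
    ratio of 1.0 that is {3:3, 4:4} against {1.5:1.5, 2:2}; for ratio 0.5 the
    combination 2:4 against 1.5:3).  An unconstrained robust set puts ~50% of
    pairs in the high half of every bin.
    """
    small_q10 = np.asarray(small_q10, dtype=float)
    large_q10 = np.asarray(large_q10, dtype=float)
    combos = _ratio_combos(grid_values)
    ratios = small_q10[:, None] / large_q10[None, :]
    rows = []
    for r, cc in sorted(combos.items()):
        cc = sorted(set(cc))
        if len(cc) < 2:
            continue
        high = set(cc[len(cc) // 2:])
        in_bin = np.abs(ratios - r) < RATIO_TOL
        sel = in_bin & robust
        n = int(sel.sum())
        if n == 0:
            rows.append({"ratio": r, "n_robust": 0, "percent_high": np.nan})
            continue
        pair_small = np.broadcast_to(small_q10[:, None], ratios.shape)[sel]
        pair_large = np.broadcast_to(large_q10[None, :], ratios.shape)[sel]
        is_high = np.array(
            [(s, l) in high for s, l in zip(pair_small, pair_large)]
        )
        rows.append(
            {"ratio": r, "n_robust": n, "percent_high": 100.0 * is_high.mean()}
        )
    return pd.DataFrame(rows)

def uniform_grid_cv(values: Sequence[float] = (1.5, 2.0, 3.0, 4.0)) -> float:
    """Population CV of the uniform distribution on the Q10 grid (~0.3658)."""
    v = np.asarray(values, dtype=float)
    return float(v.std() / v.mean())

def cv_analysis(
    robust: np.ndarray,
    small_taum: np.ndarray,
    large_taum: np.ndarray,
    property_q10: np.ndarray,
    property_axis: str = "small",
    grid_values: Sequence[float] = (1.5, 2.0, 3.0, 4.0),
) -> pd.DataFrame:
    """CV of one axon's property Q10 among robust pairs, per tau_m ratio bin.

    ``property_q10`` holds the per-model Q10 of the property under test for
    the axon named by ``property_axis`` ("small" or "large").  Properties
    whose CV falls clearly below the uniform-grid baseline are constrained
    (coordinated) at that ratio; properties at the baseline vary freely.
    Bins are the tau_m ratios achievable by more than one combination.
    """
    small_taum = np.asarray(small_taum, dtype=float)
    large_taum = np.asarray(large_taum, dtype=float)
    property_q10 = np.asarray(property_q10, dtype=float)
    combos = _ratio_combos(grid_values)
    ratios = small_taum[:, None] / large_taum[None, :]
    if property_axis == "small":
        vals_full = np.broadcast_to(property_q10[:, None], ratios.shape)
    elif property_axis == "large":
        vals_full = np.broadcast_to(property_q10[None, :], ratios.shape)
    else:
        raise ValueError("property_axis must be 'small' or 'large'")
    baseline = uniform_grid_cv(grid_values)
    rows = []
    for r, cc in sorted(combos.items()):
        if len(set(cc)) < 2:
            continue
        sel = (np.abs(ratios - r) < RATIO_TOL) & robust
        n = int(sel.sum())
        if n == 0:
            rows.append(
                {"ratio": r, "n_robust": 0, "cv": np.nan, "chance_cv": baseline}
            )
            continue
        vals = vals_full[sel]
        mean = vals.mean()
        cv = float(vals.std() / mean) if mean > 0 else np.nan
        rows.append({"ratio": r, "n_robust": n, "cv": cv, "chance_cv": baseline})
    return pd.DataFrame(rows)
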