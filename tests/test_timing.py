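"""Timing statistics on analytically constructed velocity tables.

Most tests here build small velocity tables with known exponential
temperature dependence, so every expected delay, ratio and percentage can be
derived in closed form or by brute-force enumeration, independent of the
cable solver.
"""

import itertools

import numpy as np
import pandas as pd
import pytest

from thermaxon import (
    RobustnessCriterion,
    classify_robust,
    compute_delay_matrix,
    cv_analysis,
    high_low_proportion,
    necessity_test,
    observed_ratio_range,
    q10_ratio,
    ratio_matrix,
    regress_delay_on_ratio,
    sufficiency_test,
    uniform_grid_cv,
    velocity_q10_endpoint,
    velocity_q10_regression,
    windowed_q10,
)
from thermaxon.timing import RATIO_TOL, _in_interval


def make_table(diam_models, temps=(5.0, 10.0, 15.0, 20.0)):
    """Velocity table from {diameter: [(q10_dict, v10, velocity_q10), ...]}.

    Velocities follow v(T) = v10 * vq10**((T-10)/10) exactly.
    """
    rows = []
    for d, models in diam_models.items():
        for i, (q, v10, vq) in enumerate(models):
            for T in temps:
                rows.append(
                    {
                        "model_index": i,
                        "q_gNa": q.get("g_Na", 1.5),
                        "q_tau_m": q.get("tau_m", 1.5),
                        "q_gLeak": q.get("g_leak", 1.5),
                        "q_tau_h": q.get("tau_h", 1.5),
                        "diameter_um": d,
                        "temp_C": T,
                        "velocity_m_per_s": v10 * vq ** ((T - 10.0) / 10.0),
                        "failed": False,
                        "status": "ok",
                    }
                )
    return pd.DataFrame(rows)


class TestVelocityQ10Estimators:
    def test_endpoint_trivials(self):
        assert velocity_q10_endpoint(1.0, 1.0) == 1.0
        assert velocity_q10_endpoint(1.0, 1.5) == 1.5

    def test_endpoint_rejects_failures(self):
        with pytest.raises(ValueError):
            velocity_q10_endpoint(0.0, 1.0)

    def test_regression_exact_exponential(self):
        T = np.arange(5.0, 26.0)
        v = 0.7 * 2.0 ** (T / 10.0)
        assert velocity_q10_regression(T, v) == pytest.approx(2.0, rel=1e-12)

    def test_regression_constant_velocity(self):
        T = np.arange(5.0, 26.0)
        assert velocity_q10_regression(T, np.full(T.size, 1.3)) == pytest.approx(1.0)

    def test_regression_matches_endpoint_on_exponential(self):
        T = np.array([5.0, 10.0, 15.0])
        v = 1.1 * 1.7 ** ((T - 10.0) / 10.0)
        assert velocity_q10_regression(T, v) == pytest.approx(
            velocity_q10_endpoint(v[0], v[2]), rel=1e-12
        )

    def test_regression_recovers_q10_from_noisy_data(self):
        rng = np.random.default_rng(42)
        T = np.arange(5.0, 26.0)  # 21 points
        v = 0.5 * 1.8 ** ((T - 10.0) / 10.0) * (1 + 0.02 * rng.standard_normal(T.size))
        assert velocity_q10_regression(T, v) == pytest.approx(1.8, rel=0.05)

    def test_regression_needs_three_points(self):
        with pytest.raises(ValueError):
            velocity_q10_regression([5.0, 15.0], [1.0, 1.5])

    def test_windowed_constant_on_exponential(self):
        T = np.arange(5.0, 31.0, 5.0)
        v = 1.0 * 2.2 ** ((T - 10.0) / 10.0)
        w = windowed_q10(T, v)
        assert np.allclose(w["q10"], 2.2)

    def test_windowed_decreases_on_saturating_curve(self):
        T = np.arange(5.0, 26.0, 5.0)
        v = 0.2 + 0.4 / (1.0 + np.exp(-(T - 13.0) / 4.0))  # sigmoid velocity
        w = windowed_q10(T, v)
        # past the sigmoid midpoint the local Q10 falls off monotonically
        peak = int(np.argmax(w["q10"].to_numpy()))
        assert np.all(np.diff(w["q10"].to_numpy()[peak:]) < 0)
        assert w["q10"].iloc[-1] < w["q10"].iloc[0]


class TestDelayMatrix:
    def test_identical_axes_give_zero_delay(self):
        table = make_table({3.0: [({}, 1.0, 1.5)], 6.0: [({}, 1.0, 1.5)]})
        dm = compute_delay_matrix(table, 3.0, 6.0, 20.0)
        assert np.allclose(dm.delays_ms, 0.0)

    def test_zero_at_baseline_temperature(self):
        table = make_table(
            {3.0: [({}, 1.0, 1.3), ({}, 1.1, 2.0)], 6.0: [({}, 1.5, 1.7)]}
        )
        dm = compute_delay_matrix(table, 3.0, 6.0, 10.0)
        assert np.allclose(dm.delays_ms, 0.0, atol=1e-12)

    def test_swapping_roles_negates_and_transposes(self, full_table):
        dm = compute_delay_matrix(full_table, 3.0, 6.0, 20.0)
        swapped = compute_delay_matrix(full_table, 6.0, 3.0, 20.0)
        assert np.allclose(
            swapped.delays_ms, -dm.delays_ms.T, atol=1e-12, equal_nan=True
        )

    def test_equal_q10_pairs_diverge_with_temperature(self):
        """With one shared velocity Q10 > 1 but different baseline speeds the
        arrival-time difference shrinks as both axons speed up, so |delay|
        grows with distance from the baseline temperature."""
        table = make_table(
            {3.0: [({}, 1.28, 1.5)], 6.0: [({}, 1.81, 1.5)]},
            temps=(5.0, 10.0, 15.0, 20.0, 25.0),
        )
        mags = [
            abs(compute_delay_matrix(table, 3.0, 6.0, T).delays_ms[0, 0])
            for T in (15.0, 20.0, 25.0)
        ]
        assert mags[0] < mags[1] < mags[2]
        below = abs(compute_delay_matrix(table, 3.0, 6.0, 5.0).delays_ms[0, 0])
        assert below > 0

    def test_failed_entry_is_nan_and_invalid(self):
        table = make_table({3.0: [({}, 1.0, 1.5)], 6.0: [({}, 1.5, 1.5)]})
        table.loc[
            (table.diameter_um == 3.0) & (table.temp_C == 20.0),
            ["velocity_m_per_s", "failed", "status"],
        ] = [np.nan, True, "failed"]
        dm = compute_delay_matrix(table, 3.0, 6.0, 20.0)
        assert np.isnan(dm.delays_ms[0, 0])
        assert not dm.valid[0, 0]


class TestRobustness:
    def test_zero_delays_all_robust(self):
        table = make_table({3.0: [({}, 1.0, 1.5)], 6.0: [({}, 1.0, 1.5)]})
        dm = compute_delay_matrix(table, 3.0, 6.0, 20.0)
        robust, count = classify_robust(dm)
        assert robust.all() and count == dm.n_pairs

    def test_failed_pairs_never_robust_but_counted(self):
        table = make_table({3.0: [({}, 1.0, 1.5)], 6.0: [({}, 1.0, 1.5)]})
        table.loc[
            (table.diameter_um == 3.0) & (table.temp_C == 20.0),
            ["velocity_m_per_s", "failed", "status"],
        ] = [np.nan, True, "failed"]
        dm = compute_delay_matrix(table, 3.0, 6.0, 20.0)
        robust, count = classify_robust(dm)
        assert count == 0
        assert robust.size == 1  # still in the denominator

    def test_threshold_modes(self):
        table = make_table({3.0: [({}, 1.28, 1.5)], 6.0: [({}, 1.81, 1.5)]})
        dm = compute_delay_matrix(table, 3.0, 6.0, 20.0)
        assert RobustnessCriterion().threshold_ms(dm) == pytest.approx(1.3)
        frac = RobustnessCriterion(mode="pair_mean_baseline_fraction")
        t_small, t_large = 40.0 / 1.28, 40.0 / 1.81
        assert frac.threshold_ms(dm) == pytest.approx(
            0.05 * 0.5 * (t_small + t_large)
        )
        per_t = RobustnessCriterion(
            mode="per_temperature_absolute", absolute_thresholds={20.0: 2.0}
        )
        assert per_t.threshold_ms(dm) == 2.0
        with pytest.raises(KeyError):
            RobustnessCriterion(
                mode="per_temperature_absolute", absolute_thresholds={15.0: 2.0}
            ).threshold_ms(dm)
        with pytest.raises(ValueError):
            RobustnessCriterion(mode="bogus").threshold_ms(dm)


class TestRatios:
    def test_grid_extremes(self):
        assert q10_ratio(1.5, 4.0) == pytest.approx(0.375)
        assert q10_ratio(4.0, 1.5) == pytest.approx(8.0 / 3.0)
        assert q10_ratio(2.0, 2.0) == 1.0

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            q10_ratio(0.0, 1.5)

    def test_ratio_matrix_orientation(self):
        table = make_table(
            {
                3.0: [({"tau_m": 4.0}, 1.0, 1.5), ({"tau_m": 1.5}, 1.0, 1.5)],
                6.0: [({"tau_m": 2.0}, 1.5, 1.5)],
            }
        )
        r = ratio_matrix(table, 3.0, 6.0, "tau_m", "tau_m")
        # rows: small-axon models; numerator: small axon's Q10
        assert r[0, 0] == pytest.approx(4.0 / 2.0)
        assert r[1, 0] == pytest.approx(1.5 / 2.0)

    def test_linear_delays_regress_perfectly(self):
        rng = np.random.default_rng(3)
        ratios = rng.choice([0.5, 1.0, 2.0], size=(8, 8))
        delays = 3.0 * ratios - 1.0

        class FakeDelays:
            delays_ms = delays
            valid = np.ones_like(delays, dtype=bool)
            temperature = 20.0

        fit = regress_delay_on_ratio(FakeDelays, ratios, "tau_m", "tau_m")
        assert fit.slope_ms_per_ratio == pytest.approx(3.0)
        assert fit.intercept_ms == pytest.approx(-1.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_observed_range_full_and_empty(self):
        ratios = np.array([[0.375, 1.0], [2.0, 8.0 / 3.0]])
        assert observed_ratio_range(np.ones((2, 2), bool), ratios) == (
            pytest.approx(0.375),
            pytest.approx(8.0 / 3.0),
        )
        with pytest.raises(ValueError):
            observed_ratio_range(np.zeros((2, 2), bool), ratios)


class TestNecessitySufficiency:
    def test_perfect_coordination(self):
        ratios = np.array([[0.5, 2.0], [1.0, 3.0]])
        robust = _in_interval(ratios, (0.4, 1.2))
        assert necessity_test(robust, ratios, (0.4, 1.2)) == 100.0
        assert sufficiency_test(robust, ratios, (0.4, 1.2)) == 100.0

    def test_vacuous_predicates_rejected(self):
        ratios = np.ones((2, 2))
        robust = np.ones((2, 2), bool)
        with pytest.raises(ValueError):
            necessity_test(robust, ratios, (0.0, 10.0))  # nothing outside
        with pytest.raises(ValueError):
            sufficiency_test(robust, ratios, (5.0, 10.0))  # nothing inside

    def test_against_brute_force_enumeration(self):
        """Vectorized percentages must agree with explicit set enumeration on
        a reduced two-value Q10 grid (16 models per axon, 256 pairs)."""
        values = (1.5, 4.0)
        models = list(itertools.product(values, repeat=4))  # (gNa, tm, gl, th)
        rng = np.random.default_rng(11)
        robust = rng.random((16, 16)) < 0.3
        taum_small = np.array([m[1] for m in models])
        taum_large = np.array([m[1] for m in models])
        ratios = taum_small[:, None] / taum_large[None, :]
        interval = (0.375, 1.0)

        # oracle: loop over every pair and count
        n_out = n_out_nonrobust = n_in = n_in_robust = 0
        for i in range(16):
            for j in range(16):
                r = models[i][1] / models[j][1]
                inside = interval[0] - 1e-9 <= r <= interval[1] + 1e-9
                if inside:
                    n_in += 1
                    n_in_robust += bool(robust[i, j])
                else:
                    n_out += 1
                    n_out_nonrobust += not robust[i, j]
        assert necessity_test(robust, ratios, interval) == pytest.approx(
            100.0 * n_out_nonrobust / n_out
        )
        assert sufficiency_test(robust, ratios, interval) == pytest.approx(
            100.0 * n_in_robust / n_in
        )


class TestHighLowAndCV:
    @pytest.fixture()
    def grid_q10s(self):
        values = (1.5, 2.0, 3.0, 4.0)
        models = list(itertools.product(values, repeat=4))
        taum = np.array([m[1] for m in models])
        return values, models, taum

    def test_uniform_robust_set_is_fifty_fifty(self, grid_q10s):
        values, _, taum = grid_q10s
        robust = np.ones((256, 256), bool)
        hl = high_low_proportion(robust, taum, taum, values)
        assert set(np.round(hl["ratio"], 6)) == {0.5, 0.75, 1.0, round(4 / 3, 6), 2.0}
        assert np.allclose(hl["percent_high"], 50.0)

    def test_single_combination_ratios_excluded(self, grid_q10s):
        values, _, taum = grid_q10s
        hl = high_low_proportion(np.ones((256, 256), bool), taum, taum, values)
        for excluded in (0.375, 8 / 3, 1.5, 2 / 3):
            assert not np.any(np.abs(hl["ratio"] - excluded) < RATIO_TOL)

    def test_constrained_bin_detected(self, grid_q10s):
        values, _, taum = grid_q10s
        # only high-value combos of the 1.0 bin are robust
        robust = (taum[:, None] >= 3.0) & (taum[:, None] == taum[None, :])
        hl = high_low_proportion(robust, taum, taum, values)
        row = hl[np.isclose(hl["ratio"], 1.0)].iloc[0]
        assert row["percent_high"] == 100.0

    def test_uniform_grid_cv_value(self):
        # closed form: mean 2.625, population SD 0.9601
        assert uniform_grid_cv() == pytest.approx(0.36576, abs=1e-4)

    def test_cv_uniform_robust_matches_chance(self, grid_q10s):
        values, models, taum = grid_q10s
        gna = np.array([m[0] for m in models])
        robust = np.ones((256, 256), bool)
        cv = cv_analysis(robust, taum, taum, gna, property_axis="small")
        assert np.allclose(cv["cv"], cv["chance_cv"], atol=1e-6)

    def test_cv_degenerate_bin_is_zero(self, grid_q10s):
        values, models, taum = grid_q10s
        gna = np.array([m[0] for m in models])
        robust = np.broadcast_to((gna == 3.0)[:, None], (256, 256)).copy()
        cv = cv_analysis(robust, taum, taum, gna, property_axis="small")
        assert np.allclose(cv["cv"].dropna(), 0.0)
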