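"""Sigmoid velocity curves, the synthetic recording generator, arrival-time
and phase-constancy deviations."""

import math

import numpy as np
import pandas as pd
import pytest

from thermaxon import (
    CyclePeriodModel,
    GeneratorParams,
    SigmoidFit,
    arrival_deviation,
    generate_velocity_dataset,
    phase_deviation,
    sigmoid_velocity,
    velocity_q10_endpoint,
    velocity_q10_regression,
    windowed_q10,
    PD_FIT,
)


class TestSigmoid:
    def test_midpoint_value(self):
        fit = SigmoidFit(offset=0.2, amplitude=0.6, T_half=13.0, scale=4.0)
        assert sigmoid_velocity(13.0, fit) == pytest.approx(0.5)

    def test_asymptotes(self):
        fit = SigmoidFit(offset=0.1, amplitude=0.5, T_half=13.0, scale=4.0)
        assert sigmoid_velocity(1e3, fit) == pytest.approx(0.6)
        assert sigmoid_velocity(-1e3, fit) == pytest.approx(0.1)

    def test_zero_amplitude_is_constant(self):
        fit = SigmoidFit(offset=0.3, amplitude=0.0, T_half=13.0, scale=4.0)
        assert sigmoid_velocity(5.0, fit) == sigmoid_velocity(25.0, fit) == 0.3

    def test_pd_curve_hand_evaluated_at_25(self):
        expected = -0.260 + 0.417 / (1.0 + math.exp(-(25.0 - 13.172) / 4.186))
        assert sigmoid_velocity(25.0, PD_FIT) == pytest.approx(expected, rel=1e-12)

    def test_rejects_nonpositive_scale(self):
        with pytest.raises(ValueError):
            SigmoidFit(offset=0.0, amplitude=1.0, T_half=10.0, scale=0.0)


class TestGenerator:
    def test_seed_is_mandatory(self):
        with pytest.raises(ValueError):
            generate_velocity_dataset(GeneratorParams())

    def test_same_seed_bit_identical(self):
        a = generate_velocity_dataset(seed=5)
        b = generate_velocity_dataset(seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_different_seeds_differ(self):
        a = generate_velocity_dataset(seed=5)
        b = generate_velocity_dataset(seed=6)
        assert not np.allclose(a["velocity"], b["velocity"])

    def test_noise_free_matches_anchored_sigmoid(self):
        p = GeneratorParams(noise_sd=0.0, animal_sd=0.0, n_animals=1)
        data = generate_velocity_dataset(p, seed=0)
        pd_curve = data[data.neuron == "PD"].sort_values("temp_C")
        T = pd_curve["temp_C"].to_numpy()
        fit = p.fits["PD"]
        sig = 1.0 / (1.0 + np.exp(-(T - fit.T_half) / fit.scale))
        sig5 = 1.0 / (1.0 + np.exp(-(5.0 - fit.T_half) / fit.scale))
        expected = p.v5_m_per_s["PD"] * (1.0 + p.gain * (sig - sig5))
        assert np.allclose(pd_curve["velocity"], expected)

    def test_velocities_positive_and_in_range(self):
        data = generate_velocity_dataset(seed=9)
        assert (data["velocity"] > 0).all()
        assert data["temp_C"].between(5.0, 25.0).all()

    def test_provenance_recorded(self):
        data = generate_velocity_dataset(seed=17)
        assert data.attrs["seed"] == 17
        assert "fits" in data.attrs["params"]

    def test_realistic_velocity_q10(self):
        """The default generator should produce axons with velocity Q10 near
        the ~1.5 measured for pyloric axons."""
        p = GeneratorParams(noise_sd=0.0, animal_sd=0.0, n_animals=1)
        data = generate_velocity_dataset(p, seed=0)
        for neuron, grp in data.groupby("neuron"):
            grp = grp.sort_values("temp_C")
            q = velocity_q10_regression(grp["temp_C"], grp["velocity"])
            assert 1.2 < q < 1.8, neuron

    def test_estimator_stability_across_seeds_noiseless(self):
        qs = []
        for seed in range(10):
            p = GeneratorParams(noise_sd=0.0, animal_sd=0.0, n_animals=1)
            data = generate_velocity_dataset(p, seed=seed)
            grp = data[data.neuron == "PD"].sort_values("temp_C")
            qs.append(velocity_q10_regression(grp["temp_C"], grp["velocity"]))
        assert np.std(qs) == pytest.approx(0.0, abs=1e-12)

    def test_windowed_q10_decreases_on_sigmoid_data(self):
        p = GeneratorParams(noise_sd=0.0, animal_sd=0.0, n_animals=1,
                            temperatures=tuple(np.arange(5.0, 26.0, 5.0)))
        data = generate_velocity_dataset(p, seed=0)
        grp = data[data.neuron == "PD"].sort_values("temp_C")
        w = windowed_q10(grp["temp_C"], grp["velocity"])
        assert w["q10"].iloc[-1] < w["q10"].iloc[0]


class TestArrivalDeviation:
    def test_constant_velocity_zero_deviation(self):
        T = np.arange(5.0, 26.0)
        dev = arrival_deviation(T, np.full(T.size, 0.5))
        assert np.allclose(dev["deviation_ms"], 0.0)

    def test_doubled_velocity_halves_transit(self):
        dev = arrival_deviation([10.0, 20.0], [0.5, 1.0], distance_cm=4.0)
        t10 = 4.0 / 0.5 * 10.0  # 80 ms
        assert dev["deviation_ms"].iloc[1] == pytest.approx(-t10 / 2.0)

    def test_requires_reference_temperature(self):
        with pytest.raises(ValueError):
            arrival_deviation([5.0, 15.0], [0.5, 0.6])

    def test_generator_curves_stay_under_thirty_ms(self):
        p = GeneratorParams(noise_sd=0.0, animal_sd=0.0, n_animals=1)
        data = generate_velocity_dataset(p, seed=0)
        for _, grp in data.groupby("neuron"):
            grp = grp.sort_values("temp_C")
            dev = arrival_deviation(grp["temp_C"], grp["velocity"])
            assert dev["deviation_ms"].abs().max() < 30.0


class TestPhaseDeviation:
    @staticmethod
    def exp_dataset(q10s, v10s, temps=np.arange(5.0, 26.0)):
        rows = []
        for (neuron, q), v10 in zip(q10s.items(), v10s):
            for T in temps:
                rows.append(
                    {
                        "neuron": neuron,
                        "temp_C": T,
                        "velocity": v10 * q ** ((T - 10.0) / 10.0),
                    }
                )
        return pd.DataFrame(rows)

    def test_identical_curves_zero_deviation(self):
        data = self.exp_dataset({"PD": 1.5, "LP": 1.5, "PY": 1.5}, [0.5, 0.5, 0.5])
        dev = phase_deviation(data)
        assert np.allclose(dev["phase_deviation_pct"], 0.0, atol=1e-12)

    def test_reference_neuron_identically_zero(self):
        data = self.exp_dataset({"PD": 1.5, "LP": 1.2, "PY": 1.9}, [0.5, 0.6, 0.4])
        dev = phase_deviation(data)
        pd_dev = dev[dev.neuron == "PD"]["phase_deviation_pct"]
        assert np.allclose(pd_dev, 0.0, atol=1e-12)

    def test_sign_flips_with_relative_q10(self):
        """A follower less temperature-sensitive than the reference drifts in
        the opposite direction from one that is more sensitive."""
        data = self.exp_dataset({"PD": 1.5, "LP": 1.2, "PY": 1.9}, [0.5, 0.6, 0.4])
        dev = phase_deviation(data)
        at25 = dev[dev.temp_C == 25.0].set_index("neuron")["phase_deviation_pct"]
        assert at25["LP"] * at25["PY"] < 0

    def test_same_q10_different_baseline_speeds_drift(self):
        """Even with equal velocity Q10s, different baseline speeds break
        phase constancy away from the reference temperature when the period
        is temperature-independent."""
        data = self.exp_dataset({"PD": 1.5, "LP": 1.5}, [0.5, 0.7])
        periods = CyclePeriodModel(period_ref_s=1.0, q10=1.0)  # constant period
        dev = phase_deviation(data, periods)
        lp = dev[dev.neuron == "LP"].sort_values("temp_C")
        mags = lp.set_index("temp_C")["phase_deviation_pct"].abs()
        assert mags[25.0] > mags[15.0] > 0
        assert mags[5.0] > 0

    def test_velocity_rescaling_scales_deviation(self):
        """Scaling all velocities by c scales arrival-time differences, and
        hence phase deviations, by exactly 1/c."""
        data = self.exp_dataset({"PD": 1.5, "LP": 1.2}, [0.5, 0.6])
        scaled = data.assign(velocity=data["velocity"] * 2.0)
        dev = phase_deviation(data)
        dev2 = phase_deviation(scaled)
        assert np.allclose(
            dev2["phase_deviation_pct"], dev["phase_deviation_pct"] / 2.0
        )

    def test_missing_reference_rejected(self):
        data = self.exp_dataset({"LP": 1.2, "PY": 1.9}, [0.6, 0.4])
        with pytest.raises(ValueError, match="reference"):
            phase_deviation(data)

    def test_period_table_must_cover_all_temperatures(self):
        data = self.exp_dataset({"PD": 1.5, "LP": 1.2}, [0.5, 0.6])
        periods = pd.DataFrame({"temp_C": [5.0, 10.0], "period_s": [1.2, 1.0]})
        with pytest.raises(ValueError):
            phase_deviation(data, periods)

    def test_period_model_monotone_decreasing(self):
        m = CyclePeriodModel(period_ref_s=1.0, q10=2.0)
        T = np.arange(5.0, 26.0)
        p = m.period_s(T)
        assert np.all(np.diff(p) < 0)
        assert m.period_s(10.0) == pytest.approx(1.0)
        assert m.period_s(20.0) == pytest.approx(0.5)
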