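"""Energy-balance weight model: initialization, calibration, dynamics."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import brentq

from taxdelay import (
    calibrate_baseline,
    classify_bmi,
    initialize_state,
    simulate_individual,
)
from taxdelay.hall import (
    HallParameters,
    _prepare_cohort,
    baseline_intakes,
    simulate_cohort,
)


class TestInitialization:
    def test_mass_closure(self, person, hall_params):
        state = initialize_state(person, hall_params)
        assert state.weight(hall_params) == pytest.approx(person["weight"],
                                                          abs=1e-9)

    def test_sex_changes_fat_mass(self, person, hall_params):
        male = dict(person, sex="male")
        f_female = initialize_state(person, hall_params).fat_mass
        f_male = initialize_state(male, hall_params).fat_mass
        assert f_female != pytest.approx(f_male)
        assert f_male < f_female   # lower fat fraction at equal BMI

    def test_fat_fraction_matches_regression(self, person, hall_params):
        # direct evaluation of the sex-specific log-BMI regression
        state = initialize_state(person, hall_params)
        expected = (0.14 * 50 + 39.96 * np.log(30.0) - 102.01) / 100
        assert state.fat_mass / person["weight"] == pytest.approx(expected,
                                                                  abs=1e-9)

    def test_implied_negative_fat_rejected(self, hall_params):
        lean_young_male = {"age": 20, "sex": "male", "height": 180.0,
                           "weight": 14.0 * 1.8 ** 2, "pal": 1.6}
        with pytest.raises(ValueError, match="fat mass"):
            initialize_state(lean_young_male, hall_params)


class TestCalibration:
    def test_calibrated_intake_positive_and_flat(self, person, hall_params):
        state = initialize_state(person, hall_params)
        ei = calibrate_baseline(person, state, hall_params)
        assert ei > 0
        traj = simulate_individual(person, ei,
                                   {y: 1.0 for y in range(2021, 2032)},
                                   hall_params)
        assert abs(traj.weight_kg.iloc[-1] - person["weight"]) < 0.2

    def test_doubling_pal_increases_intake(self, person, hall_params):
        state = initialize_state(person, hall_params)
        active = dict(person, pal=2 * 1.0)
        ei_lo = calibrate_baseline(dict(person, pal=1.4), state, hall_params)
        ei_hi = calibrate_baseline(dict(person, pal=2.8), state, hall_params)
        assert ei_hi > ei_lo

    def test_vectorized_equals_scalar_calibration(self, small_cohort,
                                                  hall_params):
        sub = small_cohort.head(5)
        vec = baseline_intakes(sub, hall_params)
        for i, (_, row) in enumerate(sub.iterrows()):
            state = initialize_state(row, hall_params)
            assert vec[i] == pytest.approx(
                calibrate_baseline(row, state, hall_params), abs=1e-6)


def _steady_state_oracle(person, params, ei_b, ei_new):
    """Closed-form equilibrium weight from the model's own balance equation,
    solved independently of the integrator."""
    prep = _prepare_cohort(pd.DataFrame([person]), params)
    F0, L0 = prep["fat"][0], prep["lean"][0]
    K, delta, ecf_b = prep["k"][0], prep["delta"][0], prep["ecf"][0]
    theta = ei_new / ei_b
    g_new = params.glycogen_baseline * np.sqrt(theta)
    ecf_new = ecf_b - (params.xi_ci / params.xi_na) * (1 - theta)
    at = params.beta_at * (ei_new - ei_b)

    def balance(F):
        L = L0 + params.forbes_d * np.log(F / F0)
        bw = F + L + g_new * (1 + params.hydration_factor) + ecf_new
        return ((1 - params.beta_tef) * ei_new - K - params.gamma_fat * F
                - params.gamma_lean * L - delta * bw - at)

    F_star = brentq(balance, 0.5, 80.0)
    L_star = L0 + params.forbes_d * np.log(F_star / F0)
    return F_star + L_star + g_new * (1 + params.hydration_factor) + ecf_new


class TestDynamics:
    def test_constant_intake_keeps_weight_flat_19_years(self, person,
                                                        hall_params,
                                                        flat_multipliers):
        state = initialize_state(person, hall_params)
        ei = calibrate_baseline(person, state, hall_params)
        traj = simulate_individual(person, ei, flat_multipliers, hall_params)
        assert traj.weight_kg.max() - traj.weight_kg.min() < 0.2

    def test_permanent_deficit_reaches_oracle_plateau(self, person,
                                                      hall_params):
        state = initialize_state(person, hall_params)
        ei = calibrate_baseline(person, state, hall_params)
        mult = {y: (1.0 if y == 2021 else (ei - 250) / ei)
                for y in range(2021, 2041)}
        traj = simulate_individual(person, ei, mult, hall_params)
        target = _steady_state_oracle(person, hall_params, ei, ei - 250)
        assert traj.weight_kg.iloc[-1] == pytest.approx(target, abs=0.5)
        assert traj.weight_kg.iloc[-1] < person["weight"]

    def test_weight_tracks_intake_direction(self, person, hall_params):
        state = initialize_state(person, hall_params)
        ei = calibrate_baseline(person, state, hall_params)
        rising = {y: 1.0 + 0.002 * (y - 2021) for y in range(2021, 2041)}
        traj = simulate_individual(person, ei, rising, hall_params)
        diffs = np.diff(traj.weight_kg.to_numpy())
        assert (diffs[1:] > -1e-6).all()
        assert traj.weight_kg.iloc[-1] > person["weight"]

    def test_step_halving_convergence(self, person, hall_params):
        state = initialize_state(person, hall_params)
        ei = calibrate_baseline(person, state, hall_params)
        mult = {y: (1.0 if y == 2021 else 0.97) for y in range(2021, 2041)}
        full = simulate_individual(person, ei, mult, hall_params)
        half = simulate_individual(person, ei, mult,
                                   HallParameters(dt_days=0.5))
        assert np.max(np.abs(full.weight_kg.to_numpy()
                             - half.weight_kg.to_numpy())) < 0.05

    def test_first_year_multiplier_must_be_one(self, small_cohort,
                                               hall_params):
        sub = small_cohort.head(3)
        base = baseline_intakes(sub, hall_params)
        mult = np.full(20, 0.95)
        with pytest.raises(ValueError, match="multiplier"):
            simulate_cohort(sub, base, mult, hall_params)


class TestClassifyBMI:
    @pytest.mark.parametrize("bmi,category", [
        (10.0, 1), (24.999, 1), (25.0, 2), (27.4, 2), (27.5, 3),
        (29.9, 3), (30.0, 4), (34.9, 4), (35.0, 5), (39.9, 5),
        (40.0, 6), (59.0, 6),
    ])
    def test_half_open_boundaries(self, bmi, category):
        assert classify_bmi(bmi) == category

    def test_vectorized(self):
        out = classify_bmi(np.array([22.0, 27.5, 41.0]))
        assert out.tolist() == [1, 3, 6]

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            classify_bmi(float("nan"))
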