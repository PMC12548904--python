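"""Mortality: HR expansion, P[D] estimation, Allison-style decomposition."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from taxdelay import (
    HazardRatioTable,
    assign_pd,
    build_schedule,
    decompose_pd,
    estimate_pd,
    expand_hr,
    generate_projection,
)
from taxdelay.mortality import PDGrid
from taxdelay.synthetic import PopulationProjection


class TestExpandHR:
    def test_unit_hr_expands_to_ones(self):
        assert np.allclose(expand_hr(1.0), 1.0)

    def test_reference_category_is_one_and_increasing(self):
        hrs = expand_hr(1.52)
        assert hrs[0] == pytest.approx(1.0)
        assert (np.diff(hrs) > 0).all()

    def test_protective_hr_decreases_across_categories(self):
        hrs = expand_hr(0.9)
        assert (np.diff(hrs) < 0).all()

    def test_nonpositive_hr_rejected(self):
        with pytest.raises(ValueError):
            expand_hr(0.0)


class TestEstimatePD:
    def test_direct_substitution(self):
        counts = np.full((81, 21), 1000.0)
        counts[31, 5] = 990.0   # age 51, year 2026
        proj = PopulationProjection(np.arange(20, 101),
                                    np.arange(2021, 2042), counts)
        grid = estimate_pd(proj)
        # P[D](50, 2025) = 1 - count(51, 2026)/count(50, 2025)
        assert grid.values[30, 4] == pytest.approx(0.01)
        assert (grid.values[-1, :] == 1.0).all()

    def test_inconsistent_zero_count_rejected(self):
        counts = np.full((81, 21), 100.0)
        counts[10, 3] = 0.0
        proj = PopulationProjection(np.arange(20, 101),
                                    np.arange(2021, 2042), counts)
        with pytest.raises(ValueError):
            estimate_pd(proj)

    def test_round_trip_with_generated_projection(self):
        q = np.clip(8.2e-5 * np.exp(0.08 * np.arange(20, 101)), 0, 0.99)
        proj = generate_projection(np.linspace(2000, 50, 81), q, horizon=2041)
        grid = estimate_pd(proj)
        err = np.abs(grid.values[:-1] - q[:-1, None])
        assert np.nanmax(err) < 1e-12


def _grid_search_h0(pd_value, pi, hr):
    """Two-stage brute-force search for the baseline hazard (oracle)."""
    lo, hi = 0.0, 10.0
    for _ in range(6):
        hs = np.linspace(lo, hi, 10001)
        f = (pi[None, :] * (1 - np.exp(-hs[:, None] * hr[None, :]))).sum(1)
        i = int(np.argmin(np.abs(f - pd_value)))
        lo, hi = hs[max(i - 1, 0)], hs[min(i + 1, hs.size - 1)]
    return 0.5 * (lo + hi)


class TestDecomposePD:
    def test_unit_hazard_ratios_leave_pd_unchanged(self):
        out = decompose_pd(0.07, np.full(6, 1 / 6), np.ones(6))
        assert np.allclose(out, 0.07, atol=1e-12)

    def test_zero_pd_gives_zeros(self):
        out = decompose_pd(0.0, np.full(6, 1 / 6), expand_hr(1.52))
        assert np.allclose(out, 0.0)

    def test_two_category_grid_search_oracle(self):
        pi = np.array([0.5, 0.5])
        hr = np.array([1.0, 2.0])
        out = decompose_pd(0.10, pi, hr)
        h0 = _grid_search_h0(0.10, pi, hr)
        expected = 1 - np.exp(-h0 * hr)
        assert np.allclose(out, expected, atol=1e-8)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), pd_value=st.floats(0.0, 0.95))
    def test_mixture_identity_holds(self, seed, pd_value):
        rng = np.random.default_rng(seed)
        pi = rng.dirichlet(np.ones(6))
        hr = np.exp(rng.normal(0.3, 0.4, 6))
        out = decompose_pd(pd_value, pi, hr)
        assert abs(float(pi @ out) - pd_value) < 1e-10
        assert ((out >= 0) & (out <= 1)).all()

    def test_conditional_probability_increases_with_hr(self):
        pi = np.full(6, 1 / 6)
        out = decompose_pd(0.2, pi, expand_hr(1.52))
        assert (np.diff(out) > 0).all()

    def test_proportional_variant_preserves_mixture(self):
        pi = np.array([0.3, 0.7])
        hr = np.array([1.0, 1.8])
        out = decompose_pd(0.05, pi, hr, method="proportional")
        assert float(pi @ out) == pytest.approx(0.05, abs=1e-12)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            decompose_pd(1.0, np.full(6, 1 / 6), np.ones(6))
        with pytest.raises(ValueError):
            decompose_pd(0.1, np.array([0.5, 0.6]), np.ones(2))


@pytest.fixture(scope="module")
def toy_schedule():
    """Schedule over a flat 2% mortality surface with uniform prevalences."""
    ages = np.arange(20, 101)
    years = np.arange(2021, 2041)
    values = np.full((ages.size, years.size), 0.02)
    values[-1, :] = 1.0
    grid = PDGrid(ages=ages, years=years, values=values)
    prevalence = np.full((ages.size, years.size, 6), 1 / 6)
    return build_schedule(grid, HazardRatioTable.meta_analytic(), prevalence)


class TestAssignPD:
    def test_under_35_gets_unconditional_probability(self, toy_schedule):
        assert assign_pd(30, 2030, 6, toy_schedule) == pytest.approx(0.02)

    def test_terminal_age_is_certain_death(self, toy_schedule):
        assert assign_pd(100, 2030, 1, toy_schedule) == 1.0

    def test_before_decomposition_start_uses_unconditional(self, toy_schedule):
        assert assign_pd(50, 2024, 6, toy_schedule) == pytest.approx(0.02)

    def test_conditional_bracket_after_start(self, toy_schedule):
        low = assign_pd(50, 2030, 1, toy_schedule)
        high = assign_pd(50, 2030, 6, toy_schedule)
        assert low < 0.02 < high

    def test_oldest_group_reused_beyond_89(self, toy_schedule):
        assert assign_pd(95, 2030, 4, toy_schedule) == pytest.approx(
            assign_pd(85, 2030, 4, toy_schedule))

    def test_year_outside_schedule_rejected(self, toy_schedule):
        with pytest.raises(KeyError):
            assign_pd(50, 2055, 1, toy_schedule)


class TestSchedule:
    def test_mixture_identity_across_all_decomposed_cells(self, toy_schedule):
        cond = toy_schedule.conditional
        mask = np.isfinite(cond).all(axis=-1)
        mask[-1, :] = False   # terminal age pinned to 1
        mixed = cond[mask].mean(axis=-1)   # uniform prevalences
        assert np.abs(mixed - 0.02).max() < 1e-10

    def test_expanded_hrs_monotone_across_age_groups(self):
        table = HazardRatioTable.meta_analytic()
        m = table.category_hr_matrix()
        assert m.shape == (3, 6)
        # steeper BMI gradient at younger ages
        assert (m[0] >= m[1]).all() and (m[1] >= m[2]).all()
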