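"""Synthetic-world generators: determinism, invariants, and round trips."""

import numpy as np
import pandas as pd
import pytest

from taxdelay import (
    generate_cohort,
    generate_diet_subsample,
    generate_projection,
    generate_tei_series,
    rake_weights,
)
from taxdelay.mortality import estimate_pd


class TestCohort:
    def test_rejects_nonpositive_n(self):
        with pytest.raises(ValueError):
            generate_cohort(0, seed=1)

    def test_deterministic_given_seed(self):
        a = generate_cohort(500, seed=9)
        b = generate_cohort(500, seed=9)
        assert a.to_csv(index=False) == b.to_csv(index=False)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_anthropometric_invariants_hold_by_construction(self, seed):
        c = generate_cohort(1000, seed=seed)
        bmi = c.weight / (c.height / 100) ** 2
        assert c.height.between(130, 200).all()
        assert bmi.between(10, 59).all()
        assert c.age.between(20, 100).all()
        assert (c.base_weight_sampling > 0).all()

    def test_weighted_obesity_prevalence_near_target(self):
        c = generate_cohort(5000, seed=1)
        bmi = c.weight / (c.height / 100) ** 2
        prev = np.average(bmi >= 30, weights=c.base_weight_sampling)
        assert 0.36 <= prev <= 0.40

    def test_misconfigured_distribution_raises(self):
        # a huge log-scale spread puts most BMI draws outside [10, 59]
        bad = {"bmi": {"female_sigma": 2.5, "male_sigma": 2.5}}
        with pytest.raises(ValueError, match="50%"):
            generate_cohort(500, seed=1, config=bad)


class TestDietSubsample:
    def test_fraction_one_covers_cohort(self, small_cohort):
        d = generate_diet_subsample(small_cohort, 1.0, seed=3)
        assert len(d) == len(small_cohort)
        assert set(d.id) == set(small_cohort.id)

    def test_zero_intake_config_gives_zero_reduction(self, small_cohort):
        from taxdelay import mean_tei_reduction
        d = generate_diet_subsample(small_cohort, 1.0, seed=3,
                                    config={"ssb_mean": 0.0, "nedf_mean": 0.0})
        assert mean_tei_reduction(d) == 0.0

    def test_default_config_reduction_matches_target_band(self):
        # population-mean %TEI removed by the purchase cuts should land in
        # the 0.72%-1.15% band the tax effect is calibrated to
        from taxdelay import mean_tei_reduction
        cohort = generate_cohort(4000, seed=7)
        d = generate_diet_subsample(cohort, 1.0, seed=7)
        assert 0.0072 <= mean_tei_reduction(d) <= 0.0115

    def test_taxed_intake_never_exceeds_total(self, small_cohort):
        d = generate_diet_subsample(small_cohort, 1.0, seed=11)
        assert (d.ssb_kcal + d.nedf_kcal <= d.tei_kcal * (1 + 1e-12)).all()
        assert (d[["ssb_kcal", "nedf_kcal"]] >= 0).all().all()

    def test_empty_cohort_rejected(self, small_cohort):
        with pytest.raises(ValueError):
            generate_diet_subsample(small_cohort.iloc[:0], 1.0, seed=1)
        with pytest.raises(ValueError):
            generate_diet_subsample(small_cohort, 0.0, seed=1)


class TestProjection:
    def test_zero_mortality_keeps_diagonals_constant(self):
        totals = np.linspace(1000, 10, 81)
        proj = generate_projection(totals, np.zeros(81), horizon=2041)
        assert proj.count(25, 2026) == pytest.approx(totals[5 - 5])
        # follow one diagonal
        for k in range(10):
            assert proj.count(30 + k, 2021 + k) == pytest.approx(totals[10])

    def test_half_mortality_halves_the_diagonal(self):
        totals = np.full(81, 1000.0)
        proj = generate_projection(totals, np.full(81, 0.5), horizon=2041)
        assert proj.count(21, 2022) == pytest.approx(500.0)

    def test_negative_hazard_rejected(self):
        with pytest.raises(ValueError):
            generate_projection(np.full(81, 10.0), np.full(81, -0.1))

    def test_round_trip_recovers_death_probabilities(self):
        rng = np.random.default_rng(5)
        q = np.clip(rng.uniform(0.001, 0.3, 81), 0, 0.99)
        proj = generate_projection(rng.uniform(100, 1000, 81), q, horizon=2041)
        grid = estimate_pd(proj)
        recovered = grid.values[:-1, :]          # terminal age is pinned at 1
        expected = np.repeat(q[:-1, None], grid.years.size, axis=1)
        assert np.nanmax(np.abs(recovered - expected)) < 1e-12


class TestTEISeries:
    def test_zero_slope_zero_noise_is_constant(self):
        s = generate_tei_series(0.0, 2000.0, 0.0, seed=1)
        assert (s.mean_tei == 2000.0).all()
        assert len(s) == 22

    def test_linear_series_endpoint(self):
        s = generate_tei_series(3.0, 2000.0, 0.0, seed=1)
        assert s.loc[s.year == 2021, "mean_tei"].item() == pytest.approx(2063.0)

    def test_ols_recovers_slope_within_two_se(self):
        s = generate_tei_series(3.0, 2000.0, 10.0, seed=21)
        x = s.year.to_numpy(dtype=float)
        y = s.mean_tei.to_numpy()
        xc = x - x.mean()
        slope = (xc * (y - y.mean())).sum() / (xc ** 2).sum()
        resid = y - y.mean() - slope * xc
        se = np.sqrt((resid ** 2).sum() / (len(x) - 2) / (xc ** 2).sum())
        assert abs(slope - 3.0) < 2 * se

    def test_nonpositive_intercept_rejected(self):
        with pytest.raises(ValueError):
            generate_tei_series(1.0, 0.0, 0.0, seed=1)


def _ipf_oracle(w, rows, cols, row_t, col_t, iters=500):
    """Brute-force iterative proportional fitting, independent of the
    implementation under test."""
    w = w.astype(float).copy()
    for _ in range(iters):
        for lab, t in row_t.items():
            m = rows == lab
            w[m] *= t / w[m].sum()
        for lab, t in col_t.items():
            m = cols == lab
            w[m] *= t / w[m].sum()
    return w


class TestRaking:
    def test_weights_already_on_margins_are_fixed_point(self):
        w = np.array([2.0, 2.0, 3.0, 3.0])
        rows = np.array([0, 0, 1, 1])
        cols = np.array([0, 1, 0, 1])
        out = rake_weights(w, [(rows, {0: 4.0, 1: 6.0}),
                               (cols, {0: 5.0, 1: 5.0})])
        assert np.allclose(out, w, atol=1e-8)

    def test_two_by_two_matches_ipf_oracle(self):
        w = np.ones(4)
        rows = np.array([0, 0, 1, 1])
        cols = np.array([0, 1, 0, 1])
        row_t = {0: 4.0, 1: 4.0}
        col_t = {0: 2.0, 1: 6.0}
        out = rake_weights(w, [(rows, row_t), (cols, col_t)], tol=1e-10)
        oracle = _ipf_oracle(w, rows, cols, row_t, col_t)
        assert np.allclose(out, oracle, atol=1e-8)
        assert out.sum() == pytest.approx(8.0)

    def test_empty_margin_cell_rejected(self):
        w = np.ones(3)
        rows = np.array([0, 0, 0])
        with pytest.raises(ValueError, match="no sample members"):
            rake_weights(w, [(rows, {0: 2.0, 1: 1.0})])

    def test_total_preserved_when_grand_totals_agree(self):
        rng = np.random.default_rng(2)
        w = rng.uniform(0.5, 2.0, 60)
        rows = rng.integers(0, 3, 60)
        cols = rng.integers(0, 2, 60)
        row_t = {0: 30.0, 1: 40.0, 2: 30.0}
        col_t = {0: 55.0, 1: 45.0}
        out = rake_weights(w, [(rows, row_t), (cols, col_t)])
        assert out.sum() == pytest.approx(100.0, rel=1e-6)
        assert (out > 0).all()
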