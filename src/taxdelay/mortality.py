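"""All-cause mortality by BMI category.

The overall annual death probability P[D](age, year) comes from consecutive
cohort diagonals of a population projection. Within each of three age groups
(35-49, 50-69, 70-89, the last reused above 89) a meta-analytic per-5-BMI-unit
hazard ratio is expanded exponentially to the six BMI categories, anchored at
BMI 25:  HR_k = exp{log(hr5) * (b_k - 25) / 5}, b_k in {25, 27.5, 30, 35, 40,
45}. P[D] is then decomposed into category-conditional probabilities
P[D|A_i] that are consistent with the category prevalences pi_i and the HRs
(the decomposition of Allison and colleagues): on the hazard scale we solve

    sum_i pi_i * (1 - exp(-h0 * HR_i)) = P[D]

for the baseline hazard h0 >= 0, giving P_i = 1 - exp(-h0 * HR_i) with the
mixture identity sum_i pi_i P_i = P[D] holding by construction. A
proportional-probability variant (P_i = pd * HR_i / sum_j pi_j HR_j) is
available for sensitivity analysis.

Individuals aged under 35, or any individual before the decomposition start
year (2026 by default, five years into the simulation, matching the delayed
follow-up of the meta-analytic HRs), receive the unconditional P[D]; age 100
is certain death.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .synthetic import PopulationProjection

__all__ = [
    "CATEGORY_ANCHORS",
    "HazardRatioRow",
    "HazardRatioTable",
    "expand_hr",
    "estimate_pd",
    "decompose_pd",
    "build_schedule",
    "MortalitySchedule",
    "assign_pd",
]

#: Anchor BMI per category for the exponential HR expansion (category 6 at 45).
CATEGORY_ANCHORS = np.array([25.0, 27.5, 30.0, 35.0, 40.0, 45.0])


def expand_hr(hr_per_5: float, anchors=CATEGORY_ANCHORS) -> np.ndarray:
    """Expand a per-5-BMI-unit hazard ratio to the six category HRs."""
    if hr_per_5 <= 0:
        raise ValueError("hr_per_5 must be positive")
    anchors = np.asarray(anchors, dtype=float)
    return np.exp(np.log(hr_per_5) * (anchors - 25.0) / 5.0)


@dataclass(frozen=True)
class HazardRatioRow:
    age_min: int
    age_max: int
    hr_per_5: float
    ci_low: float
    ci_high: float

    @property
    def category_hrs(self) -> np.ndarray:
        return expand_hr(self.hr_per_5)


@dataclass
class HazardRatioTable:
    """Per-5-unit HRs of all-cause mortality by age group, with 95% CIs."""

    rows: tuple

    #: First calendar age at which BMI-conditional mortality applies.
    min_age: int = 35

    @classmethod
    def meta_analytic(cls) -> "HazardRatioTable":
        """The meta-analytic table used in the analysis (ages 35-89; the
        70-89 row is reused above age 89)."""
        return cls(rows=(
            HazardRatioRow(35, 49, 1.52, 1.47, 1.56),
            HazardRatioRow(50, 69, 1.37, 1.35, 1.39),
            HazardRatioRow(70, 89, 1.21, 1.17, 1.25),
        ))

    def group_index(self, age) -> np.ndarray:
        """Row index per age; -1 below ``min_age``; ages above the last
        group's upper bound reuse the last group."""
        a = np.asarray(age, dtype=int)
        idx = np.full(a.shape, -1, dtype=int)
        for i, row in enumerate(self.rows):
            idx[(a >= row.age_min) & (a <= row.age_max)] = i
        idx[a > self.rows[-1].age_max] = len(self.rows) - 1
        idx[a < self.min_age] = -1
        return idx

    def category_hr_matrix(self, hr_per_5: np.ndarray | None = None) -> np.ndarray:
        """(n_groups, 6) expanded HRs; *hr_per_5* overrides the point values
        (used for Monte-Carlo draws)."""
        values = ([row.hr_per_5 for row in self.rows]
                  if hr_per_5 is None else list(np.asarray(hr_per_5, dtype=float)))
        return np.vstack([expand_hr(v) for v in values])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "age_group": [f"{r.age_min}-{r.age_max}" for r in self.rows],
            "hr_per_5": [r.hr_per_5 for r in self.rows],
            "ci_low": [r.ci_low for r in self.rows],
            "ci_high": [r.ci_high for r in self.rows],
        })

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "HazardRatioTable":
        rows = []
        for _, rec in frame.iterrows():
            lo, hi = (int(x) for x in str(rec["age_group"]).split("-"))
            rows.append(HazardRatioRow(lo, hi, float(rec["hr_per_5"]),
                                       float(rec["ci_low"]), float(rec["ci_high"])))
        return cls(rows=tuple(rows))


# ---------------------------------------------------------------------------
# overall death probability from a projection
# ---------------------------------------------------------------------------

@dataclass
class PDGrid:
    """Unconditional annual death probability by (age, year)."""

    ages: np.ndarray
    years: np.ndarray
    values: np.ndarray   # (n_ages, n_years)


def estimate_pd(projection: PopulationProjection,
                terminal_age: int = 100) -> PDGrid:
    """P[D](a, y) = 1 - count(a+1, y+1) / count(a, y), clamped to [0, 1].

    The terminal age has probability 1. Cells where both counts are zero are
    NaN (no population, never queried); a zero denominator with a positive
    numerator is an inconsistency and raises.
    """
    ages = projection.ages
    years = projection.years[:-1]   # need (a+1, y+1) inside the grid
    c = projection.counts
    denom = c[:-1, :-1]
    numer = c[1:, 1:]
    bad = (denom == 0) & (numer > 0)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"count({ages[i]}, {years[j]}) = 0 but the next diagonal cell is "
            "positive"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        pd_vals = 1.0 - numer / denom
    pd_vals = np.clip(pd_vals, 0.0, 1.0)
    pd_vals[(denom == 0)] = np.nan
    values = np.vstack([pd_vals, np.ones((1, years.size))])  # terminal age
    grid = PDGrid(ages=ages.copy(), years=years.copy(), values=values)
    grid.values[grid.ages >= terminal_age, :] = 1.0
    return grid


# ---------------------------------------------------------------------------
# Allison-style decomposition
# ---------------------------------------------------------------------------

def decompose_pd(pd_value: float, prevalences, hrs,
                 method: str = "hazard", tol: float = 1e-12) -> np.ndarray:
    """Decompose an overall death probability into category-conditional ones.

    Parameters
    ----------
    pd_value : float in [0, 1)
        Overall probability (probability 1 is handled upstream).
    prevalences : array (K,)
        Category prevalences, non-negative, summing to 1.
    hrs : array (K,)
        Category hazard ratios (reference category 1).
    method : {"hazard", "proportional"}
        ``hazard`` solves the exponential-survival mixture for the baseline
        hazard (mixture identity exact); ``proportional`` uses
        ``pd * HR_i / sum_j pi_j HR_j`` clamped to [0, 1).

    Returns
    -------
    array (K,) of conditional probabilities.
    """
    pi = np.asarray(prevalences, dtype=float)
    hr = np.asarray(hrs, dtype=float)
    if (pi < 0).any():
        raise ValueError("prevalences must be non-negative")
    if not np.isclose(pi.sum(), 1.0, atol=1e-8):
        raise ValueError("prevalences must sum to 1")
    if not (0.0 <= pd_value < 1.0):
        raise ValueError("pd must be in [0, 1)")
    if method == "proportional":
        denom = float(pi @ hr)
        return np.clip(pd_value * hr / denom, 0.0, 1.0 - 1e-12)
    if method != "hazard":
        raise ValueError(f"unknown decomposition method {method!r}")
    if pd_value == 0.0:
        return np.zeros_like(hr)

    def f(h0):
        return float(pi @ (1.0 - np.exp(-h0 * hr))) - pd_value

    hi = max(1.0, -np.log(max(1e-300, 1.0 - pd_value)))
    while f(hi) < 0:
        hi *= 2.0
        if hi > 1e8:
            raise ValueError("no bracket for the baseline hazard")
    h0 = brentq(f, 0.0, hi, xtol=tol)
    return 1.0 - np.exp(-h0 * hr)


def _solve_h0(pd_vals: np.ndarray, pi: np.ndarray, hr: np.ndarray,
              iters: int = 80) -> np.ndarray:
    """Vectorized Newton solve of sum_i pi_i (1 - exp(-h0 hr_i)) = pd.

    The objective is increasing and concave in h0, so Newton from below
    converges monotonically. Shapes: pd (...,), pi (..., K), hr (..., K).
    """
    h0 = -np.log1p(-np.clip(pd_vals, 0.0, 1.0 - 1e-12))
    h0 = h0 / np.maximum((pi * hr).sum(axis=-1), 1e-12)
    for _ in range(iters):
        e = np.exp(-h0[..., None] * hr)
        f = (pi * (1.0 - e)).sum(axis=-1) - pd_vals
        fp = (pi * hr * e).sum(axis=-1)
        step = f / np.maximum(fp, 1e-300)
        h0 = np.maximum(h0 - step, 0.0)
        if np.nanmax(np.abs(f)) < 1e-14:
            break
    return h0


# ---------------------------------------------------------------------------
# schedule
# ---------------------------------------------------------------------------

@dataclass
class MortalitySchedule:
    """P[D] and P[D|category] grids shared by all scenarios of a run."""

    ages: np.ndarray                # (A,)
    years: np.ndarray               # (Y,)
    pd_grid: np.ndarray             # (A, Y)
    conditional: np.ndarray         # (A, Y, 6); NaN where not decomposed
    decompose_start: int = 2026
    min_age: int = 35
    terminal_age: int = 100

    def lookup(self, age, year, category) -> np.ndarray:
        """Vectorized Eq.-style assignment of an annual death probability.

        Conditional probabilities apply from ``decompose_start`` onwards for
        ages >= ``min_age``; the terminal age is certain death; cells without
        a decomposition (no population of that age) fall back to P[D].
        """
        a = np.clip(np.asarray(age, dtype=int), self.ages[0], self.terminal_age)
        y = np.asarray(year, dtype=int)
        cat = np.asarray(category, dtype=int)
        ai = a - self.ages[0]
        yi = y - self.years[0]
        if (yi < 0).any() or (yi >= self.years.size).any():
            raise KeyError("year outside the mortality schedule")
        out = self.pd_grid[ai, yi].copy()
        cond = self.conditional[ai, yi, cat - 1]
        use = (a >= self.min_age) & (y >= self.decompose_start) & np.isfinite(cond)
        out = np.where(use, cond, out)
        out = np.where(a >= self.terminal_age, 1.0, out)
        if np.isnan(out).any():
            raise KeyError("missing schedule cell (NaN death probability)")
        return out


def assign_pd(individual_age: int, year: int, bmi_category: int,
              schedule: MortalitySchedule) -> float:
    """Scalar convenience wrapper around :meth:`MortalitySchedule.lookup`."""
    return float(schedule.lookup(np.array([individual_age]),
                                 np.array([year]),
                                 np.array([bmi_category]))[0])


def build_schedule(
    pd_grid: PDGrid,
    hr_table: HazardRatioTable,
    prevalence: np.ndarray,
    decompose_start: int = 2026,
    hr_per_5: np.ndarray | None = None,
    method: str = "hazard",
) -> MortalitySchedule:
    """Build the shared mortality schedule.

    Parameters
    ----------
    pd_grid : PDGrid
        Unconditional probabilities by (age, year).
    prevalence : array (A, Y, 6)
        Status-quo BMI-category prevalences by attained age and year (NaN
        where no population); these are the weights of the mixture identity.
    hr_per_5 : array (3,), optional
        Per-5-unit HR draws overriding the table's point values.
    """
    ages, years, pdv = pd_grid.ages, pd_grid.years, pd_grid.values
    A, Y = pdv.shape
    cond = np.full((A, Y, 6), np.nan)
    hr_matrix = hr_table.category_hr_matrix(hr_per_5)
    group = hr_table.group_index(ages)
    y_mask = years >= decompose_start

    for gi in range(len(hr_table.rows)):
        a_mask = (group == gi) & (ages < 100)
        if not a_mask.any():
            continue
        sub_pd = pdv[np.ix_(a_mask, y_mask)]
        sub_pi = prevalence[np.ix_(a_mask, y_mask)]
        ok = (np.isfinite(sub_pd) & (sub_pd < 1.0)
              & np.isfinite(sub_pi).all(axis=-1))
        if not ok.any():
            continue
        pi = sub_pi[ok]
        pdc = sub_pd[ok]
        hr = np.broadcast_to(hr_matrix[gi], pi.shape)
        if method == "hazard":
            h0 = _solve_h0(pdc, pi, hr)
            probs = 1.0 - np.exp(-h0[:, None] * hr)
        elif method == "proportional":
            denom = (pi * hr).sum(axis=-1)
            probs = np.clip(pdc[:, None] * hr / denom[:, None], 0.0, 1.0 - 1e-12)
        else:
            raise ValueError(f"unknown decomposition method {method!r}")
        block = np.full(sub_pd.shape + (6,), np.nan)
        block[ok] = probs
        sub = cond[np.ix_(a_mask, y_mask)]
        sub[...] = block
        cond[np.ix_(a_mask, y_mask)] = sub

    cond[ages >= 100, :, :] = 1.0
    return MortalitySchedule(
        ages=ages.copy(), years=years.copy(), pd_grid=pdv.copy(),
        conditional=cond, decompose_start=decompose_start,
        min_age=hr_table.min_age,
    )


def schedule_to_frame(schedule: MortalitySchedule) -> pd.DataFrame:
    """Long-format (age, year, category, probability); category 0 is the
    unconditional probability."""
    rows = []
    a, y = np.meshgrid(schedule.ages, schedule.years, indexing="ij")
    rows.append(pd.DataFrame({
        "age": a.ravel(), "year": y.ravel(), "category": 0,
        "probability": schedule.pd_grid.ravel(),
    }))
    for k in range(6):
        rows.append(pd.DataFrame({
            "age": a.ravel(), "year": y.ravel(), "category": k + 1,
            "probability": schedule.conditional[:, :, k].ravel(),
        }))
    return pd.concat(rows, ignore_index=True)
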