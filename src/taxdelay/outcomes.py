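"""Cohort accounting: prevalence, deaths, years lived (without obesity).

Deaths are deterministic expectations: each individual carries a survey
"alive weight" w_j(y) (person-count units) that is attrited by the assigned
death probability, w_j(y+1) = w_j(y) * (1 - PD_j(y)). Expected deaths in an
age group m are d_{m,y} = sum_j w_j(y) PD_j(y); years lived follow the
half-year convention YL = (l - d) + a*d with a = 0.5, and years lived
without obesity are YLWO = (1 - pi) * YL with pi the weighted prevalence of
BMI >= 30. The age-group axis is single years of attained age 20-94 plus a
terminal 95+ group. A Bernoulli draw mode is available for comparison but
the expectation accounting is the default (no Monte-Carlo noise, exact
mixture identities).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .mortality import MortalitySchedule
from .hall import classify_bmi

__all__ = [
    "obesity_prevalence",
    "expected_deaths",
    "years_lived",
    "ylwo",
    "cohort_accounting",
    "accounting_to_frame",
    "category_prevalence_grid",
    "delay_comparison",
    "percent_excess",
    "AGE_GROUP_MAX",
]

#: Ages at and above this are pooled into the terminal "95+" group.
AGE_GROUP_MAX = 95


def obesity_prevalence(weights, bmi) -> float:
    """Weighted prevalence of BMI >= 30."""
    w = np.asarray(weights, dtype=float)
    b = np.asarray(bmi, dtype=float)
    total = w.sum()
    if total <= 0:
        raise ValueError("zero total weight in group")
    return float((w * (b >= 30.0)).sum() / total)


def expected_deaths(weights, pd_values) -> float:
    """Expected deaths sum_j w_j * PD_j for one group-year."""
    p = np.asarray(pd_values, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("death probabilities must lie in [0, 1]")
    return float((np.asarray(weights, dtype=float) * p).sum())


def years_lived(l, d, a_frac: float = 0.5):
    """YL = (l - d) + a*d: survivors a full year, decedents *a_frac* of one."""
    l = np.asarray(l, dtype=float)
    d = np.asarray(d, dtype=float)
    if (d > l + 1e-9 * np.maximum(l, 1.0)).any():
        raise ValueError("deaths exceed the population at risk")
    return (l - d) + a_frac * d


def ylwo(yl, prevalence):
    """Years lived without obesity: (1 - pi) * YL."""
    pi = np.asarray(prevalence, dtype=float)
    if ((pi < 0) | (pi > 1)).any():
        raise ValueError("prevalence must lie in [0, 1]")
    return (1.0 - pi) * np.asarray(yl, dtype=float)


# ---------------------------------------------------------------------------
# cohort-level accounting
# ---------------------------------------------------------------------------

def _group_index(attained_age: np.ndarray) -> np.ndarray:
    return np.clip(attained_age, 20, AGE_GROUP_MAX) - 20


def group_labels() -> list:
    return [str(a) for a in range(20, AGE_GROUP_MAX)] + [f"{AGE_GROUP_MAX}+"]


def cohort_accounting(
    age0: np.ndarray,
    w0: np.ndarray,
    bmi: np.ndarray,
    schedule: MortalitySchedule,
    years,
    a_frac: float = 0.5,
    l_convention: str = "start",
    rng: np.random.Generator | None = None,
) -> dict:
    """Run the annual weight-attrition accounting for one scenario.

    Parameters
    ----------
    age0 : (n,) baseline ages in the first simulated year.
    w0 : (n,) calibrated survey weights (alive mass at baseline).
    bmi : (n, Y) annual BMI per individual.
    schedule : shared mortality schedule.
    l_convention : {"start", "midyear"}
        ``start`` takes l_{m,y} as the alive weight entering year y (so
        YL = l - 0.5 d, the standard person-years rule); ``midyear``
        subtracts half the deaths from l first.
    rng : optional Generator
        When given, deaths are Bernoulli draws per individual instead of
        deterministic expectations (comparison mode).

    Returns
    -------
    dict with ``years``, ``groups`` and (G, Y) arrays ``l, d, prevalence,
    yl, ylwo``, plus the scalar ``final_alive`` (total weight surviving past
    the horizon) for mass-balance audits.
    """
    years = np.asarray(list(years), dtype=int)
    n_years = years.size
    age0 = np.asarray(age0, dtype=int)
    w = np.asarray(w0, dtype=float).copy()
    if bmi.shape != (age0.size, n_years):
        raise ValueError("bmi must have shape (n, n_years)")
    n_groups = AGE_GROUP_MAX - 20 + 1
    shape = (n_groups, n_years)
    l_arr = np.zeros(shape)
    d_arr = np.zeros(shape)
    prev_arr = np.zeros(shape)
    yl_arr = np.zeros(shape)
    ylwo_arr = np.zeros(shape)

    for j, year in enumerate(years):
        attained = age0 + (year - years[0])
        gi = _group_index(attained)
        cats = classify_bmi(bmi[:, j])
        pdv = schedule.lookup(attained, np.full_like(attained, year), cats)
        pdv = np.where(attained > schedule.terminal_age, 1.0, pdv)
        if rng is None:
            deaths_ind = w * pdv
            w_next = w * (1.0 - pdv)
        else:
            died = rng.random(w.size) < pdv
            deaths_ind = w * died
            w_next = w * (~died)
        start_w = np.bincount(gi, weights=w, minlength=n_groups)
        dead_w = np.bincount(gi, weights=deaths_ind, minlength=n_groups)
        obese_w = np.bincount(gi, weights=w * (bmi[:, j] >= 30.0),
                              minlength=n_groups)
        with np.errstate(invalid="ignore", divide="ignore"):
            pi = np.where(start_w > 0, obese_w / start_w, 0.0)
        l = start_w if l_convention == "start" else start_w - 0.5 * dead_w
        if l_convention not in ("start", "midyear"):
            raise ValueError("l_convention must be 'start' or 'midyear'")
        # same algebra as years_lived(); the midyear convention can push
        # l below d in terminal cells, so clamp at zero instead of erroring
        yl = np.maximum(l - (1.0 - a_frac) * dead_w, 0.0)
        l_arr[:, j] = l
        d_arr[:, j] = dead_w
        prev_arr[:, j] = pi
        yl_arr[:, j] = yl
        ylwo_arr[:, j] = ylwo(yl, pi)
        w = w_next

    return {
        "years": years, "groups": group_labels(),
        "l": l_arr, "d": d_arr, "prevalence": prev_arr,
        "yl": yl_arr, "ylwo": ylwo_arr,
        "final_alive": float(w.sum()),
    }


def accounting_to_frame(acc: dict, scenario: str) -> pd.DataFrame:
    """Long-format OutcomeTable (scenario, age_group, year, l, d, prevalence,
    yl, ylwo)."""
    groups = acc["groups"]
    years = acc["years"]
    g, y = np.meshgrid(np.arange(len(groups)), years, indexing="ij")
    return pd.DataFrame({
        "scenario": scenario,
        "age_group": np.asarray(groups, dtype=object)[g.ravel()],
        "year": y.ravel(),
        "l": acc["l"].ravel(),
        "d": acc["d"].ravel(),
        "prevalence": acc["prevalence"].ravel(),
        "yl": acc["yl"].ravel(),
        "ylwo": acc["ylwo"].ravel(),
    })


def category_prevalence_grid(
    age0: np.ndarray,
    w0: np.ndarray,
    bmi: np.ndarray,
    pd_grid_values: np.ndarray,
    ages: np.ndarray,
    years,
) -> np.ndarray:
    """Status-quo BMI-category prevalences by (attained age, year).

    Weights are attrited with the *unconditional* probabilities (the
    decomposition inputs must not depend on the decomposition itself).
    Returns an (A, Y, 6) array, NaN where the cohort has no weight.
    """
    years = np.asarray(list(years), dtype=int)
    age0 = np.asarray(age0, dtype=int)
    w = np.asarray(w0, dtype=float).copy()
    A = ages.size
    out_w = np.zeros((A, years.size, 6))
    for j, year in enumerate(years):
        attained = np.clip(age0 + (year - years[0]), ages[0], ages[-1])
        ai = attained - ages[0]
        cats = classify_bmi(bmi[:, j]) - 1
        np.add.at(out_w, (ai, j, cats), w)
        q = pd_grid_values[ai, j]
        q = np.where(np.isfinite(q), q, 1.0)
        w = w * (1.0 - q)
    totals = out_w.sum(axis=-1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        pi = out_w / totals
    pi[np.broadcast_to(totals == 0, pi.shape)] = np.nan
    return pi


# ---------------------------------------------------------------------------
# delay comparison
# ---------------------------------------------------------------------------

def delay_comparison(intervention: pd.DataFrame,
                     status_quo: pd.DataFrame) -> dict:
    """Cumulative deaths averted and YLWO saved over the shared grid.

    deaths averted = sum (d_SQ - d_INT); YLWO saved = sum (YLWO_INT -
    YLWO_SQ), both over every (age group, year) cell. Also returns the
    cumulative-by-year paths used for dominance checks.
    """
    keys = ["age_group", "year"]
    a = intervention.set_index(keys).sort_index()
    b = status_quo.set_index(keys).sort_index()
    if not a.index.equals(b.index):
        raise ValueError("outcome tables do not cover the same (group, year) grid")
    deaths_by_year = (b["d"] - a["d"]).groupby("year").sum()
    ylwo_by_year = (a["ylwo"] - b["ylwo"]).groupby("year").sum()
    return {
        "deaths_averted": float(deaths_by_year.sum()),
        "ylwo_saved": float(ylwo_by_year.sum()),
        "deaths_averted_cumulative": deaths_by_year.cumsum(),
        "ylwo_saved_cumulative": ylwo_by_year.cumsum(),
    }


def percent_excess(early: float, late: float) -> float:
    """Ratio metric 100 * (early / late - 1), e.g. 'x% more deaths averted'."""
    if late == 0:
        raise ValueError("late-scenario value is zero")
    return 100.0 * (early / late - 1.0)
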