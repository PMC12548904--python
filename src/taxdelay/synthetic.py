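"""Synthetic pipeline inputs.

The analysis was designed around three restricted data sources: a national
health-and-nutrition survey (anthropometry, survey design, weights), a dietary
subsample with taxed-beverage/taxed-food energy intakes, and official
population projections by single year of age. None are redistributable, so
this module generates stand-ins with the statistical structure the pipeline
assumes:

* a baseline adult cohort (ages 20-100) with sex-specific heights, truncated
  log-normal BMI tuned to a target weighted obesity prevalence, physical
  activity levels, and a stratified multi-PSU survey design with log-normal
  base weights;
* a right-skewed diet subsample whose mean taxed-intake share of total energy
  is steerable via configuration;
* a deterministic closed-cohort population projection driven by a configurable
  (Gompertz by default) death-probability surface, so mortality estimation can
  recover the configured probabilities exactly;
* a historical population-mean total-energy-intake series (linear + noise).

Every generator is a pure function of ``(seed, config)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PopulationProjection",
    "generate_cohort",
    "generate_diet_subsample",
    "generate_projection",
    "generate_tei_series",
    "gompertz_q",
    "rake_weights",
]

COHORT_COLUMNS = [
    "id", "age", "sex", "height", "weight", "pal",
    "base_weight_sampling", "stratum", "psu",
]


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

def _truncated_lognormal(rng, meanlog, sdlog, lo, hi, size):
    """Rejection-sampled truncated log-normal; returns draws and acceptance rate."""
    out = np.empty(size)
    filled = 0
    drawn = 0
    accepted = 0
    while filled < size:
        block = max(size - filled, 1000)
        x = rng.lognormal(meanlog, sdlog, block)
        ok = x[(x >= lo) & (x <= hi)]
        drawn += block
        accepted += ok.size
        take = min(ok.size, size - filled)
        out[filled:filled + take] = ok[:take]
        filled += take
        if drawn > 50 * size and accepted == 0:
            raise ValueError(
                "distribution parameters place essentially all draws outside "
                f"[{lo}, {hi}]"
            )
    return out, accepted / drawn


def generate_cohort(n: int, seed: int, config: dict | None = None) -> pd.DataFrame:
    """Generate a baseline adult cohort table.

    Parameters
    ----------
    n : int
        Number of individuals (> 0).
    seed : int
        RNG seed; identical ``(n, seed, config)`` reproduce identical tables.
    config : dict, optional
        The ``cohort`` section of the run configuration
        (see :func:`taxdelay.config.default_config`).

    Returns
    -------
    pandas.DataFrame
        One row per individual with columns ``id, age, sex, height, weight,
        pal, base_weight_sampling, stratum, psu``. Anthropometric exclusion
        rules (height 130-200 cm, BMI 10-59) hold by construction. Base
        weights are already divided by the wave-pooling divisor.

    Raises
    ------
    ValueError
        If ``n < 1`` or the configured distributions put more than half of
        the draws outside the anthropometric bounds (misconfiguration).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    from .config import default_config
    cfg = default_config()["cohort"]
    if config:
        from .config import _deep_merge
        cfg = _deep_merge(cfg, config)

    rng = np.random.default_rng(seed)
    ages_all = np.arange(cfg["age"]["min"], cfg["age"]["max"] + 1)
    age_p = np.exp(-cfg["age"]["decay"] * (ages_all - ages_all[0]))
    age_p /= age_p.sum()
    age = rng.choice(ages_all, size=n, p=age_p)
    female = rng.random(n) < cfg["female_share"]
    sex = np.where(female, "female", "male")

    h = cfg["height"]
    height = np.where(
        female,
        rng.normal(h["female_mean"], h["female_sd"], n),
        rng.normal(h["male_mean"], h["male_sd"], n),
    )
    height = np.clip(height, h["min"], h["max"])

    b = cfg["bmi"]
    # meanlog chosen so P(BMI >= 30) equals the target before truncation
    z = stats.norm.ppf(1.0 - b["obesity_target"])
    bmi = np.empty(n)
    accept = 1.0
    for is_f, sigma in ((True, b["female_sigma"]), (False, b["male_sigma"])):
        mask = female == is_f
        if not mask.any():
            continue
        meanlog = np.log(30.0) - z * sigma
        draws, acc = _truncated_lognormal(
            rng, meanlog, sigma, b["min"], b["max"], int(mask.sum())
        )
        bmi[mask] = draws
        accept = min(accept, acc)
    if accept < 0.5:
        raise ValueError(
            "more than 50% of BMI draws fall outside the anthropometric bounds; "
            "check the configured distribution parameters"
        )
    weight = bmi * (height / 100.0) ** 2

    p = cfg["pal"]
    pal = np.clip(rng.normal(p["mean"], p["sd"], n), p["min"], p["max"])

    stratum = rng.integers(0, int(cfg["strata"]), n)
    psu = rng.integers(0, int(cfg["psus_per_stratum"]), n)
    mean_w = cfg["population_total"] * cfg["wave_divisor"] / n
    sig = cfg["weight_sigma"]
    base_w = rng.lognormal(np.log(mean_w) - 0.5 * sig ** 2, sig, n)
    base_w = base_w / cfg["wave_divisor"]

    return pd.DataFrame({
        "id": np.arange(n, dtype=np.int64),
        "age": age.astype(np.int64),
        "sex": sex,
        "height": height,
        "weight": weight,
        "pal": pal,
        "base_weight_sampling": base_w,
        "stratum": stratum.astype(np.int64),
        "psu": psu.astype(np.int64),
    })


# ---------------------------------------------------------------------------
# diet subsample
# ---------------------------------------------------------------------------

def generate_diet_subsample(
    cohort: pd.DataFrame,
    fraction: float,
    seed: int,
    config: dict | None = None,
) -> pd.DataFrame:
    """Draw a diet subsample with right-skewed taxed-item intakes.

    ``ssb_kcal`` and ``nedf_kcal`` are log-normal; ``tei_kcal`` is an
    independent log-normal questionnaire-style total energy intake. The
    invariant ``ssb + nedf <= tei`` is enforced by proportional shrinkage of
    the rare violating rows.
    """
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must be in (0, 1]")
    from .config import default_config
    cfg = default_config()["diet"]
    if config:
        cfg = {**cfg, **config}

    rng = np.random.default_rng(seed)
    n = len(cohort)
    m = max(1, int(round(fraction * n)))
    idx = np.sort(rng.choice(n, size=m, replace=False)) if m < n else np.arange(n)
    ids = cohort["id"].to_numpy()[idx]

    def logn(mean, sigma, size):
        if mean <= 0.0:
            return np.zeros(size)
        return rng.lognormal(np.log(mean) - 0.5 * sigma ** 2, sigma, size)

    ssb = logn(cfg["ssb_mean"], cfg["ssb_sigma"], m)
    nedf = logn(cfg["nedf_mean"], cfg["nedf_sigma"], m)
    tei = logn(cfg["tei_mean"], cfg["tei_sigma"], m)
    tei = np.maximum(tei, 1.0)
    taxed = ssb + nedf
    over = taxed > tei
    if over.any():
        shrink = tei[over] / taxed[over]
        ssb[over] *= shrink
        nedf[over] *= shrink
    return pd.DataFrame(
        {"id": ids, "ssb_kcal": ssb, "nedf_kcal": nedf, "tei_kcal": tei}
    )


# ---------------------------------------------------------------------------
# population projection
# ---------------------------------------------------------------------------

@dataclass
class PopulationProjection:
    """Mid-year population counts on an (age, year) grid.

    ``counts[i, j]`` is the population aged ``ages[i]`` in ``years[j]``.
    """

    ages: np.ndarray
    years: np.ndarray
    counts: np.ndarray

    def __post_init__(self):
        self.ages = np.asarray(self.ages, dtype=int)
        self.years = np.asarray(self.years, dtype=int)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (self.ages.size, self.years.size):
            raise ValueError("counts must have shape (n_ages, n_years)")
        if (self.counts < 0).any():
            raise ValueError("population counts must be non-negative")

    def count(self, age: int, year: int) -> float:
        i = int(np.searchsorted(self.ages, age))
        j = int(np.searchsorted(self.years, year))
        if i >= self.ages.size or self.ages[i] != age:
            raise KeyError(f"age {age} not in projection")
        if j >= self.years.size or self.years[j] != year:
            raise KeyError(f"year {year} not in projection")
        return float(self.counts[i, j])

    def to_frame(self) -> pd.DataFrame:
        """Long format (age, year, count)."""
        a, y = np.meshgrid(self.ages, self.years, indexing="ij")
        return pd.DataFrame({
            "age": a.ravel(), "year": y.ravel(), "count": self.counts.ravel()
        })

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "PopulationProjection":
        pivot = frame.pivot(index="age", columns="year", values="count")
        return cls(pivot.index.to_numpy(), pivot.columns.to_numpy(),
                   pivot.to_numpy())


def gompertz_q(ages, a: float = 8.2e-5, b: float = 0.08, cap: float = 0.99):
    """Gompertz annual death probability ``min(a * exp(b * age), cap)``.

    Standard demographic shape: log-linear increase of mortality with age.
    Defaults give q(40) ~ 0.002, q(80) ~ 0.05, q(100) ~ 0.25.
    """
    if a < 0 or b < 0:
        raise ValueError("Gompertz parameters must be non-negative")
    return np.minimum(a * np.exp(b * np.asarray(ages, dtype=float)), cap)


def generate_projection(
    cohort_totals: np.ndarray,
    mortality_surface: np.ndarray,
    horizon: int = 2041,
    *,
    ages: np.ndarray | None = None,
    start_year: int = 2021,
) -> PopulationProjection:
    """Deterministic closed-cohort projection from a death-probability surface.

    Parameters
    ----------
    cohort_totals : array, shape (n_ages,)
        Population by single year of age at ``start_year``.
    mortality_surface : array, shape (n_ages,) or (n_ages, n_years - 1)
        Annual death probability ``q(age[, year])`` in [0, 1).
    horizon : int
        Last projected calendar year (inclusive).

    The defining identity is ``count(a+1, y+1) = count(a, y) * (1 - q(a, y))``
    for every diagonal; the youngest age is refilled each year at its
    ``start_year`` level (entrants outside the simulated closed cohort), and
    the oldest age is terminal.
    """
    totals = np.asarray(cohort_totals, dtype=float)
    if (totals < 0).any():
        raise ValueError("cohort totals must be non-negative")
    n_ages = totals.size
    if ages is None:
        ages = np.arange(20, 20 + n_ages)
    years = np.arange(start_year, horizon + 1)
    n_years = years.size
    q = np.asarray(mortality_surface, dtype=float)
    if q.ndim == 1:
        q = np.repeat(q[:, None], n_years - 1, axis=1)
    if q.shape != (n_ages, n_years - 1):
        raise ValueError("mortality surface shape does not match the grid")
    if (q < 0).any():
        raise ValueError("negative death probability in mortality surface")
    if (q >= 1).any():
        raise ValueError("death probabilities must be < 1")

    counts = np.zeros((n_ages, n_years))
    counts[:, 0] = totals
    for j in range(n_years - 1):
        counts[1:, j + 1] = counts[:-1, j] * (1.0 - q[:-1, j])
        counts[0, j + 1] = totals[0]
    return PopulationProjection(ages, years, counts)


# ---------------------------------------------------------------------------
# historical energy-intake series
# ---------------------------------------------------------------------------

def generate_tei_series(
    slope: float,
    intercept: float,
    noise_sd: float,
    seed: int,
    *,
    start_year: int = 2000,
    end_year: int = 2021,
) -> pd.DataFrame:
    """Historical population-mean total-energy-intake series.

    ``mean_tei(year) = intercept + slope * (year - start_year) + noise``;
    with ``noise_sd = 0`` the series is exactly linear. ``intercept`` is the
    kcal/day level at ``start_year``.
    """
    if intercept <= 0:
        raise ValueError("intercept must be positive")
    years = np.arange(start_year, end_year + 1)
    values = intercept + slope * (years - start_year).astype(float)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        values = values + rng.normal(0.0, noise_sd, years.size)
    if (values <= 0).any():
        raise ValueError("generated series is not strictly positive")
    return pd.DataFrame({"year": years, "mean_tei": values})


# ---------------------------------------------------------------------------
# raking (iterative proportional fitting)
# ---------------------------------------------------------------------------

def rake_weights(
    weights: np.ndarray,
    margins: list[tuple[np.ndarray, dict]],
    max_iter: int = 200,
    tol: float = 1e-8,
) -> np.ndarray:
    """Calibrate survey weights to marginal totals by iterative proportional
    fitting.

    Parameters
    ----------
    weights : array (n,)
        Positive starting weights.
    margins : list of (labels, targets)
        One entry per margin dimension: ``labels`` assigns each sample member
        to a cell (any hashable dtype), ``targets`` maps every cell label to
        its positive population total. Every target cell must contain at
        least one sample member.
    tol : float
        Convergence tolerance on the maximum relative deviation from every
        marginal total.

    Returns
    -------
    array (n,) of adjusted weights (> 0).
    """
    w = np.asarray(weights, dtype=float).copy()
    if (w <= 0).any():
        raise ValueError("starting weights must be positive")
    prepared = []
    for labels, targets in margins:
        labels = np.asarray(labels)
        if labels.shape[0] != w.shape[0]:
            raise ValueError("margin labels must align with weights")
        cells = []
        for label, target in targets.items():
            if target <= 0:
                raise ValueError(f"margin target for cell {label!r} must be positive")
            mask = labels == label
            if not mask.any():
                raise ValueError(f"margin cell {label!r} has no sample members")
            cells.append((mask, float(target)))
        prepared.append(cells)

    def max_dev(wv):
        dev = 0.0
        for cells in prepared:
            for mask, target in cells:
                dev = max(dev, abs(wv[mask].sum() - target) / target)
        return dev

    for _ in range(max_iter):
        for cells in prepared:
            for mask, target in cells:
                total = w[mask].sum()
                w[mask] *= target / total
        if max_dev(w) <= tol:
            return w
    raise RuntimeError(
        f"raking did not converge in {max_iter} iterations "
        f"(max relative deviation {max_dev(w):.3e})"
    )
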