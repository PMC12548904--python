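"""Population-mean total energy intake (TEI) projection and tax scenarios.

The status-quo path continues the historical linear trend of mean intake,
optionally damping the slope in five-year blocks (75% of the fitted slope in
2026-2030, 50% in 2031-2035, 25% in 2036-2040) so long-horizon extrapolation
flattens — the drift-damping device used by the Nordpred cancer-projection
model. Doubling the SSB/NEDF taxes removes a fixed percentage of TEI
(point estimate 0.93%, from the observed 7.6%/6.0% purchase reductions under
the existing taxes), phased in linearly over two years from the
implementation year. No substitution to untaxed items is modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "TrendFit",
    "TEITrajectory",
    "TaxEffect",
    "fit_linear_trend",
    "project_status_quo",
    "apply_tax",
    "mean_tei_reduction",
    "implied_elasticity",
    "NORDPRED_DAMPING",
]

#: Slope multiplier per calendar-year block under drift damping.
NORDPRED_DAMPING = ((2022, 2025, 1.00), (2026, 2030, 0.75),
                    (2031, 2035, 0.50), (2036, 9999, 0.25))


@dataclass
class TrendFit:
    """OLS linear trend of mean TEI on calendar year."""

    slope: float            # kcal/day per year
    intercept: float        # kcal/day at year 0 of the regressor scale
    adjusted_r2: float
    slope_se: float = float("nan")

    def predict(self, year) -> np.ndarray | float:
        return self.intercept + self.slope * np.asarray(year, dtype=float)


@dataclass
class TEITrajectory:
    """Scenario-labelled map year -> population-mean intake (kcal/day)."""

    label: str
    years: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        self.years = np.asarray(self.years, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.years.shape != self.values.shape:
            raise ValueError("years and values must align")
        if (self.values <= 0).any():
            raise ValueError("trajectory values must be positive")

    def value(self, year: int) -> float:
        j = int(np.searchsorted(self.years, year))
        if j >= self.years.size or self.years[j] != year:
            raise KeyError(f"year {year} not in trajectory")
        return float(self.values[j])

    def multipliers(self, base_year: int | None = None) -> np.ndarray:
        """Intake path normalised to the first (or given) year's value."""
        base = self.value(base_year if base_year is not None else self.years[0])
        return self.values / base

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "scenario": self.label, "year": self.years, "kcal_per_day": self.values
        })


@dataclass
class TaxEffect:
    """Fractional intake reductions attributed to doubling the taxes."""

    ssb_reduction: float = 0.076
    nedf_reduction: float = 0.060
    tei_reduction: float = 0.0093
    tei_reduction_ui: tuple = (0.0072, 0.0115)
    phase_in_years: int = 2

    def __post_init__(self):
        for name in ("ssb_reduction", "nedf_reduction", "tei_reduction"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise ValueError(f"{name} must be in [0, 1)")

    def phase_in(self, year, impl_year: int) -> np.ndarray:
        """Fraction of the full effect in force in *year* (linear ramp)."""
        y = np.asarray(year, dtype=float)
        if self.phase_in_years == 0:
            return (y >= impl_year).astype(float)
        return np.clip((y - impl_year) / self.phase_in_years, 0.0, 1.0)


def fit_linear_trend(series) -> TrendFit:
    """OLS fit of mean intake on calendar year.

    *series* is a DataFrame with ``year``/``mean_tei`` columns or an iterable
    of ``(year, value)`` pairs. Requires at least three points and two
    distinct years.
    """
    if isinstance(series, pd.DataFrame):
        years = series["year"].to_numpy(dtype=float)
        values = series["mean_tei"].to_numpy(dtype=float)
    else:
        pairs = np.asarray(list(series), dtype=float)
        years, values = pairs[:, 0], pairs[:, 1]
    if years.size < 3:
        raise ValueError("need at least 3 points to fit a trend")
    if np.unique(years).size < 2:
        raise ValueError("all years identical; trend is undefined")
    with np.errstate(divide="ignore", invalid="ignore"):  # constant series
        model = sm.OLS(values, sm.add_constant(years)).fit()
        return TrendFit(
            slope=float(model.params[1]),
            intercept=float(model.params[0]),
            adjusted_r2=float(model.rsquared_adj),
            slope_se=float(model.bse[1]),
        )


def _damping(year: int, mode: str) -> float:
    if mode == "linear":
        return 1.0
    if mode == "nordpred":
        for lo, hi, m in NORDPRED_DAMPING:
            if lo <= year <= hi:
                return m
        return 1.0  # at/before the anchor year
    raise ValueError(f"unknown projection mode {mode!r}")


def project_status_quo(
    fit: TrendFit,
    mode: str = "nordpred",
    years=range(2021, 2041),
    *,
    slope: float | None = None,
    label: str = "status_quo",
) -> TEITrajectory:
    """Project mean TEI forward from the fitted line.

    The trajectory is anchored at the fitted value for the first projection
    year; each subsequent annual increment is ``slope * m(year)`` with the
    damping multiplier ``m`` of :data:`NORDPRED_DAMPING` (``m = 1``
    everywhere in ``linear`` mode, the sensitivity specification).

    ``slope`` overrides the fitted slope (used by the uncertainty propagation,
    which perturbs the slope while keeping the anchor level fixed).
    """
    years = np.asarray(list(years), dtype=int)
    s = fit.slope if slope is None else float(slope)
    values = np.empty(years.size)
    values[0] = fit.predict(years[0])
    for j in range(1, years.size):
        values[j] = values[j - 1] + s * _damping(int(years[j]), mode)
    return TEITrajectory(label, years, values)


def apply_tax(
    status_quo: TEITrajectory,
    effect: TaxEffect,
    impl_year: int,
    *,
    tei_reduction: float | None = None,
    label: str | None = None,
) -> TEITrajectory:
    """Apply the phased tax-induced %TEI reduction to a status-quo path.

    ``value(y) = status_quo(y) * (1 - f(y) * r)`` with the linear phase-in
    fraction ``f`` of :meth:`TaxEffect.phase_in`. Years before the
    implementation year are identical to the status quo.
    """
    if not (status_quo.years[0] <= impl_year <= status_quo.years[-1]):
        raise ValueError("implementation year outside the trajectory range")
    r = effect.tei_reduction if tei_reduction is None else float(tei_reduction)
    f = effect.phase_in(status_quo.years, impl_year)
    return TEITrajectory(
        label or f"tax_{impl_year}",
        status_quo.years.copy(),
        status_quo.values * (1.0 - f * r),
    )


def mean_tei_reduction(
    diet: pd.DataFrame,
    weights=None,
    ssb_cut: float = 0.076,
    nedf_cut: float = 0.060,
) -> float:
    """Population-mean fractional TEI reduction implied by the purchase cuts.

    Weighted mean over diet-subsample members of
    ``(ssb_cut * ssb_kcal + nedf_cut * nedf_kcal) / tei_kcal``. Invariant to
    rescaling all weights by a constant.
    """
    if len(diet) == 0:
        raise ValueError("diet subsample is empty")
    for cut, name in ((ssb_cut, "ssb_cut"), (nedf_cut, "nedf_cut")):
        if not (0.0 <= cut < 1.0):
            raise ValueError(f"{name} must be in [0, 1)")
    tei = diet["tei_kcal"].to_numpy(dtype=float)
    if (tei <= 0).any():
        raise ValueError("tei_kcal must be positive for every record")
    frac = (ssb_cut * diet["ssb_kcal"].to_numpy(dtype=float)
            + nedf_cut * diet["nedf_kcal"].to_numpy(dtype=float)) / tei
    if weights is None:
        return float(frac.mean())
    w = np.asarray(weights, dtype=float)
    return float(np.average(frac, weights=w))


def implied_elasticity(consumption_reduction: float, price_increase: float) -> float:
    """Own-price elasticity bookkeeping: −reduction / price increase.

    A 7.6% purchase reduction under a 10% price increase implies −0.76.
    """
    if price_increase <= 0:
        raise ValueError("price increase must be positive")
    return -consumption_reduction / price_increase
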