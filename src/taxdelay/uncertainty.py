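"""Uncertainty propagation.

Three sources are propagated and combined per replicate: sampling
uncertainty via a stratified PSU bootstrap of the survey weights (Rao-Wu
rescaling: resample n_h - 1 of the n_h PSUs in each stratum with
replacement and scale by n_h / (n_h - 1), so replicate totals are unbiased
for the full-sample total); Monte-Carlo draws of the tax effect (Normal on
the %TEI reduction, sd backed out of the 95% interval, truncated at zero)
and of the three per-5-BMI-unit hazard ratios (Normal on the log scale);
and the energy-intake trend slope (Normal around the OLS fit with its
standard error). Parameters are drawn once per replicate. Outcome intervals
are the empirical 2.5th and 97.5th percentiles across replicates (linear
interpolation between order statistics). The weight-model parameters carry
no uncertainty: the model is deterministic and no covariance information is
available for its constants.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mortality import HazardRatioTable

__all__ = [
    "IntervalEstimate",
    "make_replicate_weights",
    "draw_parameters",
    "interval",
]

Z975 = 1.959963984540054


@dataclass
class IntervalEstimate:
    """Point value with a 2.5-97.5 percentile uncertainty interval."""

    point: float
    lower: float
    upper: float

    def __post_init__(self):
        if self.lower > self.upper:
            raise ValueError("interval bounds are out of order")


def make_replicate_weights(
    cohort: pd.DataFrame,
    R: int = 1000,
    seed: int = 0,
    weight_col: str = "base_weight_sampling",
) -> np.ndarray:
    """Stratified PSU bootstrap replicate weights, shape (R, n).

    Within each stratum h the n_h distinct PSUs are resampled n_h - 1 times
    with replacement; each member's weight is multiplied by
    m_psu * n_h / (n_h - 1), where m_psu counts how often its PSU was drawn.
    Requires at least two PSUs in every stratum.
    """
    if R < 1:
        raise ValueError("R must be >= 1")
    w = cohort[weight_col].to_numpy(dtype=float)
    strata = cohort["stratum"].to_numpy()
    psus = cohort["psu"].to_numpy()
    n = w.size
    rng = np.random.default_rng(seed)
    mult = np.zeros((R, n))
    for h in np.unique(strata):
        in_h = strata == h
        labels, psu_idx = np.unique(psus[in_h], return_inverse=True)
        n_h = labels.size
        if n_h < 2:
            raise ValueError(f"stratum {h!r} has a single PSU; cannot bootstrap")
        draws = rng.integers(0, n_h, size=(R, n_h - 1))
        counts = np.zeros((R, n_h))
        rows = np.repeat(np.arange(R), n_h - 1)
        np.add.at(counts, (rows, draws.ravel()), 1.0)
        mult[:, in_h] = counts[:, psu_idx] * (n_h / (n_h - 1))
    return mult * w[None, :]


def draw_parameters(
    R: int,
    seed: int,
    tax_mean: float = 0.0093,
    tax_ui: tuple = (0.0072, 0.0115),
    hr_table: HazardRatioTable | None = None,
    slope: float | None = None,
    slope_se: float = 0.0,
) -> dict:
    """Per-replicate Monte-Carlo parameter draws.

    Returns a dict with ``tax`` (R,), ``hr_per_5`` (R, n_groups) and, when a
    slope is supplied, ``slope`` (R,). The tax draw is
    Normal(tax_mean, (ui_hi - ui_lo) / (2 * 1.96)) truncated at zero; log-HR
    draws are Normal(log point, (log ci_hi - log ci_lo) / (2 * 1.96)).
    """
    if hr_table is None:
        hr_table = HazardRatioTable.meta_analytic()
    lo, hi = tax_ui
    if not (0 <= lo <= hi):
        raise ValueError("tax UI must be an ordered non-negative pair")
    rng = np.random.default_rng(seed)
    tax_sd = (hi - lo) / (2.0 * Z975)
    tax = np.maximum(rng.normal(tax_mean, tax_sd, R), 0.0) if tax_sd > 0 \
        else np.full(R, tax_mean)

    hr_draws = np.empty((R, len(hr_table.rows)))
    for i, row in enumerate(hr_table.rows):
        if row.ci_low <= 0 or row.ci_high <= 0:
            raise ValueError("hazard-ratio CIs must be positive")
        log_sd = (np.log(row.ci_high) - np.log(row.ci_low)) / (2.0 * Z975)
        hr_draws[:, i] = np.exp(rng.normal(np.log(row.hr_per_5), log_sd, R))

    out = {"tax": tax, "hr_per_5": hr_draws}
    if slope is not None:
        out["slope"] = rng.normal(slope, slope_se, R) if slope_se > 0 \
            else np.full(R, slope)
    return out


def interval(samples, point: float | None = None) -> IntervalEstimate:
    """Empirical 2.5/97.5 percentile interval (linear interpolation between
    order statistics, the default numpy convention)."""
    arr = np.asarray(samples, dtype=float)
    if arr.size == 0:
        raise ValueError("no samples")
    lower, upper = np.percentile(arr, [2.5, 97.5])
    if point is None:
        point = float(np.median(arr))
    return IntervalEstimate(point=float(point), lower=float(lower),
                            upper=float(upper))
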