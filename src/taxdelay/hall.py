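"""Dynamic energy-balance (Hall-type) body-weight model.

Body weight is the sum of four compartments — fat mass F, lean tissue L,
glycogen G (carried with 2.7 kg of water per kg), and extracellular fluid —
evolving under daily energy balance:

    rho_L dL/dt = p * EB,   rho_F dF/dt = (1 - p) * EB,
    EB = EI - EE,
    EE = K + gamma_F F + gamma_L L + delta * BW + beta_TEF * EI + AT
         + eta_F dF/dt + eta_L dL/dt,

with the Forbes partition p = C / (C + F) (C = forbes_d * rho_L / rho_F),
adaptive thermogenesis AT relaxing towards beta_AT * (EI - EI_b) with a
14-day time constant, glycogen following carbohydrate balance
rho_G dG/dt = CI - CI_b (G/G_b)^2, and extracellular fluid responding to
carbohydrate (and, if varied, sodium) intake changes. Because the synthesis
costs eta multiply the rates, EB is resolved algebraically each step.

Baseline closure: resting expenditure from the Mifflin-St Jeor equations,
total baseline expenditure PAL * RMR, the activity coefficient
delta = ((1 - beta_TEF) * PAL - 1) * RMR / BW, and the constant K chosen so
the measured state is an exact equilibrium at the calibrated intake. Initial
fat mass comes from the sex-specific log-BMI regression commonly paired with
this model. Integration is explicit first-order with a 1-day step
(convergence is checked by step-halving in the test suite).
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import brentq

__all__ = [
    "HallParameters",
    "BodyState",
    "body_fat_fraction",
    "initialize_state",
    "calibrate_baseline",
    "simulate_individual",
    "simulate_cohort",
    "classify_bmi",
    "BMI_EDGES",
]

#: Category boundaries (lower bound inclusive): <25, 25-27.5, 27.5-30,
#: 30-35, 35-40, >=40.
BMI_EDGES = np.array([25.0, 27.5, 30.0, 35.0, 40.0])


@dataclass(frozen=True)
class HallParameters:
    """Adult parameter set for the energy-balance model.

    Units: energy densities kcal/kg, specific expenditures kcal/kg/day,
    synthesis costs kcal/kg, time constants days.
    """

    rho_fat: float = 9440.0
    rho_lean: float = 1807.0
    gamma_fat: float = 3.2
    gamma_lean: float = 22.0
    eta_fat: float = 180.0
    eta_lean: float = 230.0
    beta_tef: float = 0.10          # thermic effect of food, fraction of EI
    beta_at: float = 0.14           # adaptive thermogenesis, fraction of dEI
    tau_at: float = 14.0            # days
    forbes_d: float = 10.4          # kg, Forbes lean-fat log coefficient
    glycogen_baseline: float = 0.5  # kg
    hydration_factor: float = 2.7   # kg water per kg glycogen
    rho_glycogen: float = 4180.0
    carb_fraction: float = 0.5      # carbohydrate share of intake
    xi_na: float = 3000.0           # mg/L/day, sodium excretion response
    xi_ci: float = 4000.0           # mg/day, carb effect on fluid balance
    sodium_conc: float = 3220.0     # mg/L extracellular sodium
    ecf_fraction: float = 0.1645    # baseline extracellular fluid / weight
    dt_days: float = 1.0
    intake_min: float = 500.0       # kcal/day, calibration bracket
    intake_max: float = 8000.0
    age_drift: bool = False         # advance the RMR age term with the cohort

    def __post_init__(self):
        for name in ("rho_fat", "rho_lean", "rho_glycogen", "forbes_d", "dt_days"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def forbes_c(self) -> float:
        """Forbes constant on the fat-mass scale (kg)."""
        return self.forbes_d * self.rho_lean / self.rho_fat

    @classmethod
    def from_dict(cls, overrides: Mapping | None = None) -> "HallParameters":
        overrides = dict(overrides or {})
        valid = {f.name for f in fields(cls)}
        unknown = set(overrides) - valid
        if unknown:
            raise ValueError(f"unknown Hall parameter(s): {sorted(unknown)}")
        return cls(**overrides)


@dataclass
class BodyState:
    """Compartment state of one individual (kg; AT in kcal/day)."""

    fat_mass: float
    lean_mass: float
    glycogen: float
    extracellular_fluid: float
    adaptive_thermogenesis: float = 0.0

    def weight(self, params: HallParameters) -> float:
        return (self.fat_mass + self.lean_mass
                + self.glycogen * (1.0 + params.hydration_factor)
                + self.extracellular_fluid)


def _person(individual) -> dict:
    """Accept a mapping/Series/dataclass-ish row and pull the needed fields."""
    def get(name):
        if isinstance(individual, Mapping) or isinstance(individual, pd.Series):
            return individual[name]
        return getattr(individual, name)
    return {k: get(k) for k in ("age", "sex", "height", "weight", "pal")}


def body_fat_fraction(age, sex, bmi):
    """Initial body-fat fraction from the sex-specific log-BMI regression.

    female: (0.14 * age + 39.96 * ln(BMI) - 102.01) / 100
    male:   (0.14 * age + 37.31 * ln(BMI) - 103.94) / 100
    """
    age = np.asarray(age, dtype=float)
    bmi = np.asarray(bmi, dtype=float)
    male = np.asarray(sex) == "male"
    pct = np.where(
        male,
        0.14 * age + 37.31 * np.log(bmi) - 103.94,
        0.14 * age + 39.96 * np.log(bmi) - 102.01,
    )
    return pct / 100.0


def resting_metabolic_rate(weight, height, age, sex):
    """Mifflin-St Jeor resting expenditure (kcal/day)."""
    male = np.asarray(sex) == "male"
    return (9.99 * np.asarray(weight, dtype=float)
            + 6.25 * np.asarray(height, dtype=float)
            - 4.92 * np.asarray(age, dtype=float)
            + np.where(male, 5.0, -161.0))


def initialize_state(individual, params: HallParameters) -> BodyState:
    """Partition measured weight into the four compartments.

    The reconstructed weight equals the measured weight to machine precision.
    Raises ``ValueError`` when the regression implies fat mass < 0 or more
    than the body weight, or a non-positive lean compartment.
    """
    p = _person(individual)
    w, h = float(p["weight"]), float(p["height"])
    bmi = w / (h / 100.0) ** 2
    fat = float(body_fat_fraction(p["age"], p["sex"], bmi)) * w
    if fat < 0 or fat > w:
        raise ValueError(
            f"implied fat mass {fat:.2f} kg outside [0, weight] for "
            f"age={p['age']}, sex={p['sex']}, bmi={bmi:.1f}"
        )
    glyc = params.glycogen_baseline
    ecf = params.ecf_fraction * w
    lean = w - fat - glyc * (1.0 + params.hydration_factor) - ecf
    if lean <= 0:
        raise ValueError("implied lean mass is non-positive")
    return BodyState(fat, lean, glyc, ecf, 0.0)


def _baseline_constants(age, sex, height, weight, pal, state_f, state_l,
                        params: HallParameters):
    """Per-person constants: baseline intake, activity delta, offset K."""
    rmr = resting_metabolic_rate(weight, height, age, sex)
    ei_b = np.asarray(pal, dtype=float) * rmr
    delta = (((1.0 - params.beta_tef) * np.asarray(pal, dtype=float) - 1.0)
             * rmr / np.asarray(weight, dtype=float))
    k = rmr - params.gamma_fat * state_f - params.gamma_lean * state_l
    return ei_b, delta, k


def calibrate_baseline(individual, state: BodyState, params: HallParameters) -> float:
    """Baseline intake (kcal/day) that makes the measured state an equilibrium.

    Solves ``EI = EE_ss(EI)`` on the baseline composition (adaptive
    thermogenesis at zero) by bracketed root-finding over
    ``[intake_min, intake_max]``. Raises ``ValueError`` when no root lies in
    the bracket.
    """
    p = _person(individual)
    w = float(p["weight"])
    _, delta, k = _baseline_constants(
        p["age"], p["sex"], p["height"], w, p["pal"],
        state.fat_mass, state.lean_mass, params,
    )
    fixed = (float(k) + params.gamma_fat * state.fat_mass
             + params.gamma_lean * state.lean_mass + float(delta) * w)

    def imbalance(ei):
        return ei - (fixed + params.beta_tef * ei)

    lo, hi = params.intake_min, params.intake_max
    if imbalance(lo) * imbalance(hi) > 0:
        raise ValueError(
            f"no energy-balance root in [{lo}, {hi}] kcal/day"
        )
    return float(brentq(imbalance, lo, hi, xtol=1e-10))


# ---------------------------------------------------------------------------
# vectorized engine
# ---------------------------------------------------------------------------

def _prepare_cohort(cohort: pd.DataFrame, params: HallParameters) -> dict:
    age = cohort["age"].to_numpy(dtype=float)
    sex = cohort["sex"].to_numpy()
    height = cohort["height"].to_numpy(dtype=float)
    weight = cohort["weight"].to_numpy(dtype=float)
    pal = cohort["pal"].to_numpy(dtype=float)
    bmi = weight / (height / 100.0) ** 2
    fat = body_fat_fraction(age, sex, bmi) * weight
    if (fat < 0).any() or (fat > weight).any():
        bad = int(np.argmax((fat < 0) | (fat > weight)))
        raise ValueError(
            f"implied fat mass outside [0, weight] for cohort row {bad}"
        )
    glyc = np.full(weight.shape, params.glycogen_baseline)
    ecf = params.ecf_fraction * weight
    lean = weight - fat - glyc * (1.0 + params.hydration_factor) - ecf
    if (lean <= 0).any():
        raise ValueError("implied lean mass is non-positive for some rows")
    ei_b, delta, k = _baseline_constants(age, sex, height, weight, pal,
                                         fat, lean, params)
    return {
        "height_m": height / 100.0, "weight0": weight,
        "fat": fat, "lean": lean, "glycogen": glyc, "ecf": ecf,
        "ei_b": ei_b, "delta": delta, "k": k,
    }


def baseline_intakes(cohort: pd.DataFrame, params: HallParameters) -> np.ndarray:
    """Vectorized equilibrium baseline intake for every cohort row.

    Identical (to solver tolerance) to calling :func:`calibrate_baseline`
    per row; the balance equation is linear in intake, so the root is exact.
    """
    return _prepare_cohort(cohort, params)["ei_b"].copy()


def simulate_cohort(
    cohort: pd.DataFrame,
    baseline_intake: np.ndarray,
    multipliers: np.ndarray,
    params: HallParameters,
    years=range(2021, 2041),
) -> dict:
    """Integrate the model for every individual (and trajectory variant).

    Parameters
    ----------
    cohort : DataFrame
        Rows with ``age, sex, height, weight, pal``.
    baseline_intake : array (n,)
        Calibrated equilibrium intakes (kcal/day).
    multipliers : array (Y,) or (M, Y)
        Population-mean intake path divided by its first-year value; the
        first column must be 1 (the first year is the calibrated baseline).
        A leading axis simulates M intake variants (scenarios/replicates)
        for the whole cohort at once.
    years : iterable of int
        Calendar years; the state for year y (y > start) is recorded at the
        end of calendar year y.

    Returns
    -------
    dict with ``years`` (Y,), ``weight`` and ``bmi`` arrays of shape
    (M, n, Y) (M = 1 when *multipliers* is one-dimensional).
    """
    years = np.asarray(list(years), dtype=int)
    n_years = years.size
    mult = np.asarray(multipliers, dtype=float)
    squeeze = mult.ndim == 1
    if squeeze:
        mult = mult[None, :]
    if mult.shape[1] != n_years:
        raise ValueError("multipliers must cover every simulated year")
    if not np.allclose(mult[:, 0], 1.0):
        raise ValueError("first-year multiplier must be 1 (baseline anchoring)")

    prep = _prepare_cohort(cohort, params)
    n = len(cohort)
    m = mult.shape[0]
    ei_b = np.asarray(baseline_intake, dtype=float)
    if ei_b.shape != (n,):
        raise ValueError("baseline_intake must have one entry per individual")

    ones = np.ones((m, 1))
    F = ones * prep["fat"][None, :]
    L = ones * prep["lean"][None, :]
    G = ones * prep["glycogen"][None, :]
    E = ones * prep["ecf"][None, :]
    AT = np.zeros((m, n))
    ecf_b = prep["ecf"][None, :]
    g_b = params.glycogen_baseline
    delta = prep["delta"][None, :]
    k0 = prep["k"][None, :]
    height2 = prep["height_m"] ** 2

    pr = params
    c_forbes = pr.forbes_c
    dt = pr.dt_days
    steps_per_year = int(round(365.0 / dt))
    hyd = 1.0 + pr.hydration_factor

    weight_out = np.empty((m, n, n_years))
    bmi_out = np.empty((m, n, n_years))

    def record(j):
        bw = F + L + G * hyd + E
        weight_out[:, :, j] = bw
        bmi_out[:, :, j] = bw / height2[None, :]

    record(0)
    for j in range(1, n_years):
        ei = ei_b[None, :] * mult[:, j][:, None]      # (m, n)
        theta = mult[:, j][:, None]                   # CI / CI_b
        dei = ei - ei_b[None, :]
        tef = pr.beta_tef * ei
        k = k0 - (4.92 * (years[j] - years[0]) if pr.age_drift else 0.0)
        ci_term = pr.xi_ci * (1.0 - theta)
        for _ in range(steps_per_year):
            p = c_forbes / (c_forbes + F)
            bw = F + L + G * hyd + E
            num = ei - k - pr.gamma_fat * F - pr.gamma_lean * L \
                - delta * bw - tef - AT
            eb = num / (1.0 + p * (pr.eta_lean / pr.rho_lean)
                        + (1.0 - p) * (pr.eta_fat / pr.rho_fat))
            F += dt * (1.0 - p) * eb / pr.rho_fat
            L += dt * p * eb / pr.rho_lean
            G += dt * (theta - (G / g_b) ** 2) * (pr.carb_fraction * ei_b[None, :]
                                                  / pr.rho_glycogen)
            E += dt * (-pr.xi_na * (E - ecf_b) - ci_term) / pr.sodium_conc
            AT += dt * (pr.beta_at * dei - AT) / pr.tau_at
        if not np.isfinite(F).all():
            raise RuntimeError(
                f"non-finite state while integrating calendar year {years[j]}; "
                "reduce dt_days"
            )
        record(j)

    if squeeze:
        weight_out = weight_out[0]
        bmi_out = bmi_out[0]
    return {"years": years, "weight": weight_out, "bmi": bmi_out}


def simulate_individual(
    individual,
    baseline_intake: float,
    intake_multipliers: Mapping,
    params: HallParameters,
) -> pd.DataFrame:
    """Annual weight/BMI trajectory for one individual.

    ``intake_multipliers`` maps every simulated year to the population
    trajectory value divided by its first-year value. Returns a DataFrame
    with ``year, weight_kg, bmi, bmi_category``.
    """
    years = sorted(intake_multipliers)
    mult = np.array([intake_multipliers[y] for y in years], dtype=float)
    row = pd.DataFrame([_person(individual)])
    out = simulate_cohort(row, np.array([baseline_intake]), mult, params,
                          years=years)
    weight = out["weight"][0]
    bmi = out["bmi"][0]
    return pd.DataFrame({
        "year": out["years"],
        "weight_kg": weight,
        "bmi": bmi,
        "bmi_category": classify_bmi(bmi),
    })


def classify_bmi(bmi):
    """BMI category 1-6 (half-open intervals, lower bound inclusive)."""
    arr = np.asarray(bmi, dtype=float)
    if not np.isfinite(arr).all():
        raise ValueError("non-finite BMI")
    cats = np.digitize(arr, BMI_EDGES) + 1
    if np.isscalar(bmi) or arr.ndim == 0:
        return int(cats)
    return cats
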