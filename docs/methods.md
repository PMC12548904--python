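# Methods

This note documents the model, the synthetic-data generators, the numerical
choices, and the design decisions taken where the design was genuinely open.
Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Scope and structure

The package estimates the cost of *delaying* a doubling of Mexico-style SSB
(10% → 20%) and NEDF (8% → 16%) excise taxes in a closed cohort of adults
aged 20–100 at baseline (2021), simulated to 2040. Four scenarios — status
quo and implementation in 2025, 2030, 2035 — share one synthetic world, one
mortality schedule, and one set of parameter draws; only the population
intake trajectory differs between scenarios, so every scenario contrast is a
pure intake effect.

## Synthetic world

The generators replace three restricted inputs. They define the study
conditions of every test and example; their defaults are fixed once and are
not tuned to outcomes.

* **Cohort** (`synthetic.generate_cohort`). Ages 20–100 with an
  exponentially decaying density (rate 0.03/year, a conventional adult age
  pyramid); sex 52% female; heights Normal(156, 6) / Normal(167, 7) cm
  clipped to [130, 200]; BMI sex-specific log-normal truncated to [10, 59]
  with σ = 0.17 (women) / 0.15 (men) and the log-mean set so that
  P(BMI ≥ 30) equals the configured target, 38% by default — the baseline
  obesity level the analysis anchors on. Physical activity level
  Normal(1.55, 0.10) clipped to [1.3, 2.0] (sedentary-to-moderately-active
  adults). Survey design: 30 strata × 10 PSUs with log-normal base weights
  (σ = 0.5) scaled to an 89-million adult population; a single configurable
  divisor (default 3) represents pooling across three survey waves. The
  generator raises if the configured distributions would reject more than
  half of the draws at the anthropometric bounds.
* **Diet subsample** (`generate_diet_subsample`). A 15.23% subsample
  (matching the ratio of a dietary-questionnaire subsample to a ~27k
  analytic sample). SSB and NEDF intakes are log-normal with means
  150/140 kcal/day and log-sd 0.8 (right-skewed, many low consumers, a long
  upper tail); questionnaire TEI log-normal with mean 2100 kcal/day. With
  the 7.6%/6.0% purchase cuts these defaults put the population-mean %TEI
  reduction near 1%, inside the 0.72–1.15% band used for the tax effect.
* **Population projection** (`generate_projection`). Deterministic cohort
  book-keeping `N(a+1, y+1) = N(a, y)(1 − q(a, y))` from a configurable
  death-probability surface; the default is Gompertz
  `q(a) = 8.2·10⁻⁵·e^{0.08a}` (capped at 0.99), giving q(40) ≈ 0.002,
  q(80) ≈ 0.05, q(100) ≈ 0.25. Because the identity is exact, mortality
  estimation inverts the generator to machine precision — a deliberate
  round-trip oracle. Baseline totals use the smooth configured age density
  (not realized sample counts) so every grid cell is positive.
* **Intake series** (`generate_tei_series`). 2000–2021,
  `1950 + 7·(year − 2000)` kcal/day plus Normal(0, 15) noise. No public
  series of the historical mean-intake estimates exists to calibrate
  against, so the series is parameterised, not calibrated to Mexico; the
  level and slope are ordinary for an adult population with rising intake.
* **Raking** (`rake_weights`). Plain iterative proportional fitting over
  age-band and sex margins, with explicit errors for empty margin cells and
  non-convergence (reporting the maximum deviation).

What the synthetic world does **not** emulate: the true survey's sampling
frame and non-response adjustments, intake–anthropometry correlation at the
individual level (the tax effect is a population scalar anyway),
geographic/secular structure, and cohort entry after baseline. Passing
tests therefore demonstrate the *mechanics* of the pipeline — identities,
orderings, convergence, calibration — not Mexico-specific magnitudes.

## Intake projection and tax scenarios

OLS of mean TEI on calendar year (statsmodels; slope standard error kept
for uncertainty propagation). The status-quo path is anchored at the fitted
value for 2021 — continuous with the fit rather than the noisy 2021 datum —
and grows by `slope · m(y)` with damping multipliers m = 1 (2022–2025),
0.75 (2026–2030), 0.50 (2031–2035), 0.25 (2036–2040). Damping applies to
the annual increment (the slope), not to levels. `linear` mode (m ≡ 1) is
the sensitivity specification.

The tax multiplies the status-quo path by `1 − f(y)·r`. The phase-in f is a
linear ramp reaching 1 two years after implementation (0, 0.5, 1); the ramp
shape is a design choice (the simplest monotone interpolation of "full
effect after two years") and is configurable. No substitution effects. The
point reduction r is computed from the synthetic diet subsample as the
weighted mean of `(0.076·ssb + 0.060·nedf)/tei`, and can be overridden in
config; the same scalar applies to every individual, since per-individual
reductions cannot be estimated from a subsample that does not cover the
cohort.

## Weight model

An adult dynamic energy-balance model with state (F, L, G, ECF, AT):

* energy densities ρ_F = 9440, ρ_L = 1807 kcal/kg; Forbes partition
  p = C/(C + F), C = 10.4·ρ_L/ρ_F kg;
* expenditure K + γ_F F + γ_L L + δ·BW + β_TEF·EI + AT with γ_F = 3.2,
  γ_L = 22 kcal/kg/day, β_TEF = 0.1, plus tissue-synthesis costs
  η_F = 180, η_L = 230 kcal/kg that multiply the rates (resolved
  algebraically each step);
* adaptive thermogenesis τ dAT/dt = β_AT·ΔEI − AT, β_AT = 0.14, τ = 14 d;
* glycogen ρ_G dG/dt = CI − CI_b (G/G_b)², G_b = 0.5 kg, 2.7 kg bound water
  per kg, carbohydrate share 0.5 of intake;
* extracellular fluid responding to carbohydrate perturbations
  (ξ_Na = 3000 mg/L/d, ξ_CI = 4000 mg/d, [Na] = 3.22 g/L); sodium intake is
  held constant, so only the carbohydrate term acts.

Baseline closure: resting expenditure from Mifflin–St Jeor; baseline intake
is the root of `EI = EE(EI)` at the measured composition (linear in EI, so
the bracketed root on [500, 8000] kcal/day is exact); the activity
coefficient δ = ((1 − β_TEF)·PAL − 1)·RMR/BW and the constant
K = RMR − γ_F F₀ − γ_L L₀ make the measured state an exact equilibrium.
Initial fat mass uses the sex-specific log-BMI regression
(women: 0.14·age + 39.96·ln BMI − 102.01 %, men: 0.14·age + 37.31·ln BMI −
103.94 %); implied fat outside [0, weight] is an error, not clamped.
Heights are constant over the simulation, so BMI moves only through weight.

Integration is explicit first-order with a 1-day step, vectorised over
individuals and trajectory variants; state recorded at calendar-year ends
(19 integrated years). The glycogen pool is the stiffest component
(≈0.8-day time constant), which bounds the usable step near one day —
halving the step moves annual weights by well under 0.05 kg (tested).
Steady-state behaviour is verified against an independent closed-form
solver of the balance equation along the Forbes path.

**Ageing and expenditure.** Age enters expenditure only through the
baseline calibration. Advancing the Mifflin–St Jeor age term with the
cohort would add a ≈ −4.9 kcal/day/year expenditure drift and several kg of
weight gain over 19 years at constant intake, breaking the steady-state
property that anchors the whole calibration (constant intake ⇒ flat
weight). An `age_drift` parameter (default off) enables the advancing-age
variant for exploration; because the drift is scenario-independent it has
little effect on scenario *contrasts*.

## Mortality

`P[D](a, y) = 1 − N(a+1, y+1)/N(a, y)` clamped to [0, 1]; age 100 is
pinned at 1; a zero denominator with a positive numerator raises.

Hazard-ratio expansion anchors the six categories at BMI 25, 27.5, 30, 35,
40, 45. The decomposition solves the exponential-survival mixture for the
baseline hazard with a vectorised Newton iteration (the objective is
increasing and concave in h₀, so the iteration is globally convergent;
scalar calls use Brent's method to 10⁻¹² and a brute-force grid search
serves as the test oracle). A proportional-probability variant
(`P_i = pd·HR_i/Σπ_j HR_j`) is available behind
`mortality.decompose_method` for sensitivity; the hazard-scale variant is
the default because it guarantees P_i ∈ [0, 1] and the exact mixture
identity. Which functional link the original analysis used is not
documented publicly; neither variant is claimed as it.

Decomposition prevalences π(age, year) are the status-quo category
prevalences with weights attrited by the *unconditional* probabilities.
Using conditionally-attrited weights would make the schedule depend on
itself; the single-pass convention keeps the schedule well-defined and the
mixture identity exact at the π actually used. Conditional probabilities
apply from 2026 (five years into the simulation, mirroring the delayed
follow-up of the meta-analytic hazard ratios) and from age 35; ages 90+
reuse the 70–89 group; cells with no cohort population fall back to the
unconditional probability. One schedule object per parameter draw is shared
by all scenarios.

## Outcomes

Expectation accounting, not Bernoulli simulation: weights attrite as
`w(y+1) = w(y)(1 − PD(y))`, deaths are `Σ w·PD`. This removes Monte-Carlo
noise, preserves the mixture identities exactly, and makes total deaths +
surviving weight equal the baseline total to machine precision (audited in
the tests). A Bernoulli mode (`rng` argument of `cohort_accounting`)
exists for comparison.

The age-group axis is single years 20–94 plus 95+. `l_{m,y}` is the alive
weight entering year y (convention `start`, the default), so
`YL = (l − d) + 0.5·d` is the standard half-year person-years rule. The
`midyear` convention (l minus half the deaths) is available but note that
feeding a mid-year population into the same YL formula discounts deaths
twice; it is provided for comparability only. Deaths averted and YLWO saved
sum over the identical (group, year) grid; the ratio metric is
`100·(x_early/x_late − 1)`.

## Uncertainty

Per replicate (R = 50 in the `test` profile, R = 1000 in `paper`):

* **Sampling**: stratified PSU bootstrap with Rao–Wu rescaling (resample
  n_h − 1 of n_h PSUs with replacement, multiply weights by
  m·n_h/(n_h − 1)); replicate totals are unbiased for the full-sample
  total (tested at 2%). Replicates are not re-raked; the bootstrap is
  applied to the calibrated weights.
* **Trend**: slope ~ Normal(fitted slope, SE), with the 2021 anchor held at
  the point fit. The historical series is external to the survey, so its
  uncertainty cannot come from the weight bootstrap; coefficient sampling
  is the chosen interpretation, and anchor-level uncertainty is left to the
  bootstrap.
* **Tax effect**: Normal(point, (0.0115 − 0.0072)/(2·1.96)) truncated at
  zero (a tax cannot raise intake in this model).
* **Hazard ratios**: log-HR ~ Normal(log point, (log CI_hi − log CI_lo)/
  (2·1.96)), independent across the three age groups.

Parameters are drawn once per replicate; weight-model constants carry no
uncertainty (the model is deterministic and no covariance information is
available for them). Intervals are empirical 2.5/97.5 percentiles with
numpy's linear interpolation between order statistics. Every replicate
re-simulates the weight model under its own trajectory and re-builds its
own mortality schedule from its own weights and HR draws.

## Problem sizes and profiles

The `test` profile (n = 2000, R = 50) is the package's desk-scale default:
a full four-scenario run with intervals takes on the order of two minutes
on one CPU, and the acceptance suite's dominance/convergence checks run at
this size. The `paper` profile (n = 26854, R = 1000) reproduces the scale
of the original design and is intended for dedicated runs. Byte-identical
reproducibility holds at any size: all randomness flows from one seed
through fixed child streams (cohort, diet, series, bootstrap, draws).

## Known limitations

* Magnitudes are synthetic-world magnitudes; only identities, orderings and
  calibration properties are asserted.
* The tax effect is a single population scalar; individual heterogeneity in
  tax response is out of scope.
* Closed cohort: no entrants after baseline, so late-horizon prevalence
  reflects an ageing cohort only.
* No cause-specific mortality, HR time trends, competing risks,
  discounting, or economic outcomes.
* The bootstrap omits re-raking within replicates; calibration uncertainty
  is therefore slightly understated.
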