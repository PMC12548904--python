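"""Generate the synthetic inputs: cohort, diet subsample, intake series,
population projection — and check the structure the pipeline assumes."""

import numpy as np

from taxdelay import (
    generate_cohort, generate_diet_subsample, generate_tei_series,
    generate_projection, gompertz_q, mean_tei_reduction,
)

cohort = generate_cohort(n=3000, seed=1)
bmi = cohort.weight / (cohort.height / 100) ** 2
prev = np.average(bmi >= 30, weights=cohort.base_weight_sampling)
print(f"cohort: {len(cohort)} adults, weighted obesity prevalence "
      f"{100 * prev:.1f}% (target ~38%)")

diet = generate_diet_subsample(cohort, fraction=0.15, seed=2)
red = mean_tei_reduction(diet)  # 7.6% SSB / 6.0% NEDF purchase cuts
print(f"diet subsample: {len(diet)} records; doubling the taxes removes "
      f"{100 * red:.2f}% of total energy intake on average (band 0.72-1.15%)")

series = generate_tei_series(slope=7.0, intercept=1950.0, noise_sd=15.0, seed=3)
print(f"intake series 2000-2021: {series.mean_tei.iloc[0]:.0f} -> "
      f"{series.mean_tei.iloc[-1]:.0f} kcal/day")

ages = np.arange(20, 101)
proj = generate_projection(np.full(81, 1e6), gompertz_q(ages), horizon=2041)
print(f"projection: ages 20-100, years 2021-2041; the 2021 cohort of "
      f"60-year-olds shrinks to {proj.count(79, 2040):,.0f} by 2040")
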