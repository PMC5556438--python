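"""Generate a synthetic geriatric cohort, analyze everyone, and summarise.

The generator emulates the demographic shape of a heavily comorbid clinic
sample (ages 65-92, 3-10 comorbidities, mean initial impairment ~57%, 5-year
mortality ~49%) and calibrates the drawn cohort onto those targets.
"""

from comorben import (
    CohortGenSpec,
    analyze_patient,
    cohort_mean_curve,
    cohort_summary,
    demonstration_case,
    generate_cohort,
)

spec = CohortGenSpec(n=50, seed=2024)
cohort = generate_cohort(spec)
_, treatment = demonstration_case()

summary = cohort_summary(cohort)
print("cohort summary:")
for key, value in summary.items():
    print(f"  {key}: {value:.4g}" if isinstance(value, float) else f"  {key}: {value}")

curves = [analyze_patient(p, treatment).relative_curve for p in cohort]
mean_curve = cohort_mean_curve(curves)
print()
print(f"mean P(any benefit) = {100 * mean_curve.intercept:.2f}% "
      f"(baseline efficacy {100 * treatment.total_efficacy:.1f}%)")
print(f"mean P(>= 50% of baseline benefit) = {100 * mean_curve.evaluate(0.5):.2f}%")
print()
print("Reading: the gap between the 5% baseline efficacy and the mean curve "
      "is the comorbidity effect — death and impairment risks leave only a "
      "fraction of patients able to derive a benefit comparable to baseline.")
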