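# comorben

**Comorbidity-adjusted probability distributions of treatment benefit.**

Clinical trials report a treatment's probability of benefit for patients
largely free of other disease. For an older patient with several
comorbidities the honest question is different: *what is the probability of
still being well enough, at the horizon, to derive at least a given magnitude
of that benefit?* `comorben` answers it with a decision-tree analysis:
it enumerates every combination of comorbidity outcomes, converts each
combination into a utility (wellness) state, and reports the complementary
cumulative distribution function of the treatment-benefit magnitude —
per patient, with sensitivity envelopes and single-number simplifications.

Intended users: biostatisticians, clinical epidemiologists and
decision-analysis researchers studying external validity under
multimorbidity.

## The model

- **Utility and impairment.** Wellness is a utility u ∈ [0, 1]
  (0 = death, 1 = complete well-being); impairment is i = 1 − u.
- **Multiplicative combination.** A new impairment is weighted by the
  pre-existing well-being: combining e and a gives
  1 − (1 − e)(1 − a). A joint state's utility is the product of its
  per-condition well-beings, and 0 if any outcome is death.
- **Outcome enumeration.** Each risk factor (a comorbidity, age-related
  mortality, or a certain time-zero impairment) is a small discrete
  distribution over branches {death, added impairment, no event} at the
  horizon (default 5 years). Under mutual independence, the joint outcome
  space is the Cartesian product; each combination carries the product of
  branch probabilities.
- **Benefit curves.** For threshold t, the *comorbidity effect* is
  P(u ≥ t). A treatment with efficacy components (p_j, b_j) — probability
  p_j of preventing an event whose prevention is worth b_j at baseline —
  yields the relative-benefit curve Σ_j p_j · P(u ≥ f) and the
  absolute-benefit curve Σ_j p_j · P(b_j · u ≥ x). Intercurrent death
  abolishes benefit; non-fatal impairment scales it down.
- **Sensitivity.** Inputs can be perturbed ±50% (efficacy, event
  probabilities), impairments transformed through a two-regime ±factor rule
  that is continuous at i = 0.5, age mortality eliminated, and the horizon
  rescaled assuming risks and benefit accumulate at a constant rate.

## Worked example

```bash
python examples/demonstration.py    # or: comorben demo
```

prints

```
baseline efficacy: 5.0% probability of a 25% benefit
P(alive at 5 years): 50.0%

how the 5% benefit probability subdivides:
   2.5%  at benefit magnitude  0.0%
   0.5%  at benefit magnitude  7.5%
   2.0%  at benefit magnitude 15.0%

P(benefit >= 7.5%) = 2.5%
P(benefit >= 15.0%) = 2.0%
P(benefit >= 15.1%) = 0.0%
```

A 75-year-old man with treated lung cancer (50% five-year survival, 40%
impairment if alive) and AF (20% stroke probability, 50% impairment) has a
15% untreated five-year MI risk; a statin cuts it by one-third, so without
comorbidity he would have a 5% chance of a 25%-magnitude benefit. The
enumeration splits that 5% into: 2.5% where cancer death abolishes the
benefit, 0.5% where he is alive with cancer *and* a stroke (benefit scaled
to 25% × 50% × 60% = 7.5%), and 2.0% alive with cancer alone (25% × 60% =
15%). Read as advice: a 2.5% probability of at least a 7.5% benefit, 2.0%
of at least 15%, and no chance of more.

Other entry points: `examples/custom_patient.py` (profiles built in code,
point estimates), `examples/sensitivity_envelope.py` (perturbation
envelopes), `examples/synthetic_cohort.py` (a calibrated synthetic geriatric
cohort and its mean curve), and the `comorben` CLI (`demo`, `analyze`,
`sensitivity`, `cohort`) for YAML/JSON configs — see `comorben --help`.

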