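# Methods

## Model and assumptions

`comorben` evaluates the *state at a fixed horizon* (default 5 years), not
benefit accumulated over time. Each risk factor is a discrete distribution
over mutually exclusive branches — death, an added impairment, or no event —
with probabilities cumulative to the horizon. Three assumptions carry the
whole construction:

1. **Independence.** Outcomes of different risk factors are mutually
   independent, so joint probabilities are products. Known dependence must be
   folded into the inputs themselves (e.g. a stroke risk already conditioned
   on AF). Conditional structure of the form "a stroke only matters if alive"
   needs no machinery: a stroke branch co-occurring with a death branch
   contributes its probability to the utility-0 death state automatically.
2. **Multiplicative impairment combination.** Combining impairments e and a
   gives 1 − (1 − e)(1 − a): a new impairment is weighted by the remaining
   well-being, is commutative/associative, and can approach but never exceed
   total impairment. Utility of a joint state is therefore the product of
   per-branch well-beings, 0 on death. The same rule scales treatment
   benefit: a benefit worth b at baseline is worth b · u in a state of
   utility u.
3. **Benefits only.** Adverse treatment effects are out of scope; the
   residual 1 − Σ p_j probability mass simply derives no benefit.

Because only the horizon state matters, event ordering within the horizon is
irrelevant and enumeration is a pure Cartesian product. Time-zero chronic
impairments are encoded as degenerate single-branch risk factors
(probability 1), so enumeration treats them uniformly with stochastic
outcomes.

## Curves and conventions

The *comorbidity effect* is the complementary CDF P(u ≥ t), a non-increasing
step function. Conventions, chosen once:

- **Thresholds are inclusive** (≥): "at least 7.5% benefit" includes the
  7.5%-magnitude state. Numerically, comparisons allow 1e-9 slack so printed
  thresholds like 0.075 hit their state exactly.
- **The value at threshold 0 vs 0⁺ differ.** At exactly 0 the curve reports
  total mass (everyone derives ≥ 0 benefit); the 0⁺ limit is P(u > 0) — the
  probability of being alive and deriving *any* benefit, which is how the
  y-axis crossing is read clinically. `StepCurve` stores both (`at_zero`,
  `intercept`).
- **Relative vs absolute curves.** The relative curve Σ_j p_j · P(u ≥ f) is
  well-defined for any number of efficacy components but mixes benefit
  scales when the b_j differ; the absolute curve Σ_j p_j · P(b_j · u ≥ x) is
  the mixture over components and is the primary multi-component output.
- **Death vs total non-fatal impairment** both have utility 0 and are
  indistinguishable on curves, but the distribution tracks a death flag so
  P(alive) stays recoverable and the two states are not merged together.

`merge_atoms` pools states of (near-)equal utility by single-linkage
clustering at tolerance `tol` (default 0: exact duplicates only), summing
probabilities at the probability-weighted mean utility. Single-linkage makes
the merge idempotent: representatives of distinct clusters stay more than
`tol` apart. Enumeration is capped at 10⁶ combinations (a ~10-factor,
2–3-branch profile is ~10⁵); beyond that a resource error advises pruning to
the major comorbidities, which is also the clinically sensible
simplification.

## Point estimates

Each simplification pairs P(alive) × Σ p_j with one magnitude
b̄ · u*, where b̄ is the efficacy-weighted mean baseline benefit and u* is:
the maximum utility over alive states (`best`, an optimistic bound), the
expected utility given alive (`mean`), or the supplied time-zero utility
(`initial`). The profile stores time-zero utility explicitly rather than
inferring it from the degenerate factors, leaving the user free to include
or exclude acute impairments from it. For multi-component treatments the
b̄ rule is an extension beyond the single-component case and reports flag it.

## Sensitivity machinery

- **±50% scaling** of efficacies and event probabilities multiplies by
  1 ± f and clamps to [0, 1]. Freed or demanded probability mass is
  renormalised onto the factor's *complement branch*, defined as the
  non-death branch with the smallest added impairment (the best outcome).
  This choice makes each factor improve stochastically as event
  probabilities shrink, which yields pointwise curve dominance. A factor
  with only death branches has no complement and is a config error to
  perturb. If scaled non-complement mass exceeds 1 it is renormalised to 1
  and the complement gets 0.
- **Impairment transformation.** For i ≤ 0.5, i′ = (1 ± f) · i (capped at
  1); for i > 0.5 the *utility* is scaled the opposite way,
  u′ = (1 ∓ f) · u, keeping scores inside [0, 1] and symmetric about the
  regimes. The two formulas agree at i = 0.5, so the map is continuous.
  Deep reductions (f = 0.75, 0.90) reuse the same two-regime rule, including
  above 50% — the natural reading of treating them "the same way", though
  other conventions are defensible.
- **Progression reductions** scale only non-death impairment-event branch
  probabilities, and only downward. Whether "progression" should instead
  target impairment magnitudes is genuinely open; targeting probabilities is
  the default, and magnitude changes are available via the impairment
  target.
- **Age-mortality elimination** replaces factors tagged `age` that carry a
  death branch with a certain survive branch; absent such a factor it is a
  warning no-op.
- **Time rescaling** assumes constant accumulation of risk and benefit:
  every cumulative event probability (and each efficacy component) scales by
  t/T, with complements renormalised and impairment magnitudes unchanged.
  Linear scaling is the default; a constant-hazard alternative
  (1 − (1 − p)^(t/T)) sits behind `method="exponential"` for comparison.
  Both compose exactly (5→2→1 ≡ 5→1). Keeping the complement's impairment
  unchanged means impairment-if-event does not shrink with the horizon; only
  event probabilities do.

All perturbations are pure functions of their inputs.

## Synthetic cohort generator

`generate_cohort` emulates the demographic *shape* of a heavily comorbid
geriatric sample: ages uniform on 65–92, comorbidity counts uniform on 3–10
drawn without replacement from a condition catalog, per-condition death /
progression probabilities and impairments uniform within template ranges,
an age-mortality factor from a piecewise-linear age→5-year-mortality lookup,
and a degenerate initial-impairment factor. Two calibrations align the drawn
cohort with its targets (defaults: mean initial impairment 57.45%, 5-year
mortality 49.05%):

- initial impairments are rescaled multiplicatively to the target mean
  (capped at 0.98), making the n = 200 calibration essentially exact;
- the age-mortality probabilities are scaled by a common factor found by
  bisection on the closed-form mean mortality
  1 − (1 − s·p_age) · Π(1 − p_death,condition), exact under independence.

The catalog ranges and the age lookup are illustrative, not reproductions of
any life table; condition-specific death probabilities are kept modest so
age mortality carries most of the death risk (mirroring the practice of
subtracting condition-attributable components from age mortality to avoid
double counting). Because the "conditional impairment if alive" aggregation
is ambiguous, `cohort_summary` reports both candidates (mean over patients
of each patient's E[i | alive], and the pooled expectation over all alive
mass).

What passing cohort tests do **not** show: real patients have correlated
conditions, non-uniform severity distributions, and literature-derived
rather than sampled inputs. The generator validates the *machinery* at
realistic scale and shape, not any clinical conclusion.

## Numerical choices

- Probabilities and fractions are floats with a global tolerance of 1e-9
  (inputs carry ≤ 3 significant figures); branch-sum validation uses 10×
  that to absorb accumulated rounding from parsed configs.
- Utilities within 1e-12 are the same support point when building curves.
- Curve evaluation above threshold 1 returns 0 (nothing exceeds full
  benefit); negative thresholds are domain errors.
- Double counting of a condition under two headings is detected only as a
  warning (shared condition-specific name tokens, generic words like
  "mortality" excluded) — resolving it requires clinical judgement, never
  automation.
- All randomness flows through explicitly seeded `numpy` generators; no
  function reads global random state.

## Validation strategy and problem sizes

The test suite checks the enumeration engine against an independent
recursive oracle (exact, ≤ 4 factors × 3 branches) and a seeded 10⁶-draw
Monte-Carlo sampler (each discrete utility state within 3 binomial standard
errors; the fixture uses a tabulated impairment grid, as impairment scores
are in practice, so states are few and well-populated). Curve properties
(monotonicity, conservation, dominance under impairment reduction, added
comorbidity, and horizon extension) are asserted on dense grids. The worked
bedside example is reproduced exactly end to end. Cohort-level runs use
n ≤ 200 patients, which the vectorised enumeration handles in well under a
second; the full suite runs in a few seconds on one CPU.

## Known limitations

- Correlated comorbidity outcomes are not modelled; dependence must be
  curated into the inputs.
- Benefit is evaluated at a single time point; accumulated (QALY-style)
  benefit over the horizon is out of scope.
- Treatment harms and costs are out of scope.
- Whether a prevented *fatal* event's 100% baseline benefit should scale
  with comorbid utility or with survival alone is not settled; the engine
  applies the same multiplicative scaling to every component, which is the
  conservative choice for fatal-event components.
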