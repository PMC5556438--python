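"""Fixtures and synthetic cohort generation.

`demonstration_case` encodes the worked bedside example: a 75-year-old man
with treated lung cancer and atrial fibrillation weighing statin therapy for
hypercholesterolaemia (15% untreated 5-year MI risk, reduced by one-third;
prevented non-fatal MI worth a 25% baseline benefit).

`generate_cohort` emulates the statistical shape of a geriatric study sample:
ages 65-92, 3-10 comorbidities per patient, heavy chronic impairment (mean
~57%) and ~49% 5-year mortality.  It is a synthetic stand-in for real
patients whose literature-derived inputs are not published: per-condition
probabilities and impairments are drawn from illustrative template ranges,
then calibrated so the cohort hits the target mean initial impairment
(multiplicative rescaling) and 5-year mortality (bisection on a scale factor
for the age-related death probabilities, using the closed-form independence
survival product).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import (
    ConfigError,
    OutcomeBranch,
    PatientProfile,
    RiskFactor,
    EfficacyComponent,
    Treatment,
    validate_patient,
)
from .enumeration import enumerate_joint_outcomes, merge_atoms, probability_alive

__all__ = [
    "FactorTemplate",
    "CohortGenSpec",
    "default_catalog",
    "age_mortality_5y",
    "demonstration_case",
    "generate_cohort",
    "cohort_summary",
]


@dataclass(frozen=True)
class FactorTemplate:
    """Sampling template for one condition: uniform ranges for its 5-year
    death probability, progression-event probability, the impairment added by
    the event, and the chronic impairment already present at time zero."""

    name: str
    death_prob: tuple[float, float] = (0.0, 0.0)
    event_prob: tuple[float, float] = (0.0, 0.0)
    event_impairment: tuple[float, float] = (0.0, 0.0)
    initial_impairment: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        for attr in ("death_prob", "event_prob", "event_impairment", "initial_impairment"):
            lo, hi = getattr(self, attr)
            if not (0.0 <= lo <= hi <= 1.0):
                raise ConfigError(f"template {self.name!r}: {attr} range {lo, hi} is ill-ordered")


def default_catalog() -> tuple[FactorTemplate, ...]:
    """Illustrative condition templates spanning the comorbidity spectrum of a
    geriatric clinic population (dementia, cancers, organ failure, sensory and
    musculoskeletal impairment...).  Ranges are plausible 5-year figures, not
    reproductions of any particular literature source."""
    return (
        FactorTemplate("dementia", (0.05, 0.2), (0.3, 0.6), (0.3, 0.6), (0.1, 0.4)),
        FactorTemplate("cancer", (0.05, 0.3), (0.2, 0.5), (0.2, 0.5), (0.05, 0.3)),
        FactorTemplate("heart_failure", (0.05, 0.25), (0.2, 0.5), (0.2, 0.4), (0.1, 0.3)),
        FactorTemplate("obstructive_lung_disease", (0.03, 0.15), (0.2, 0.5), (0.1, 0.4), (0.05, 0.3)),
        FactorTemplate("af_stroke", (0.0, 0.05), (0.1, 0.3), (0.3, 0.6), (0.0, 0.05)),
        FactorTemplate("hypertension_stroke", (0.0, 0.02), (0.05, 0.15), (0.3, 0.6), (0.0, 0.02)),
        FactorTemplate("osteoporosis_fracture", (0.0, 0.05), (0.1, 0.3), (0.1, 0.3), (0.0, 0.1)),
        FactorTemplate("diabetes", (0.0, 0.0), (0.0, 0.0), (0.0, 0.0), (0.05, 0.2)),
        FactorTemplate("arthritis", (0.0, 0.0), (0.0, 0.0), (0.0, 0.0), (0.05, 0.3)),
        FactorTemplate("parkinsons", (0.02, 0.1), (0.2, 0.4), (0.2, 0.4), (0.1, 0.4)),
        FactorTemplate("blindness", (0.0, 0.0), (0.0, 0.0), (0.0, 0.0), (0.2, 0.5)),
        FactorTemplate("deafness", (0.0, 0.0), (0.0, 0.0), (0.0, 0.0), (0.1, 0.3)),
    )


#: Illustrative 5-year all-cause death probabilities by age (interpolated
#: linearly between knots); configurable per cohort spec.
DEFAULT_AGE_MORTALITY = (
    (65, 0.06),
    (70, 0.10),
    (75, 0.17),
    (80, 0.27),
    (85, 0.42),
    (90, 0.58),
    (95, 0.75),
)


def age_mortality_5y(age: float, table=None) -> float:
    table = tuple(table) if table is not None else DEFAULT_AGE_MORTALITY
    ages, probs = zip(*table)
    return float(np.interp(age, ages, probs))


@dataclass(frozen=True)
class CohortGenSpec:
    """Parameters of the synthetic cohort generator.

    Defaults mirror the demographic shape of a geriatric study sample: ages
    65-92, 3-10 comorbidities each, mean initial impairment 57.45% and 5-year
    mortality 49.05%.
    """

    n: int
    seed: int
    age_range: tuple[float, float] = (65, 92)
    comorbidity_count_range: tuple[int, int] = (3, 10)
    catalog: tuple[FactorTemplate, ...] = field(default_factory=default_catalog)
    target_mean_initial_impairment: float | None = 0.5745
    target_mortality_5y: float | None = 0.4905
    age_mortality_table: tuple[tuple[float, float], ...] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "catalog", tuple(self.catalog))
        if self.n < 1:
            raise ConfigError(f"n must be >= 1, got {self.n}")
        lo, hi = self.age_range
        if lo > hi:
            raise ConfigError(f"age_range {self.age_range} is ill-ordered")
        clo, chi = self.comorbidity_count_range
        if not (1 <= clo <= chi):
            raise ConfigError(
                f"comorbidity_count_range {self.comorbidity_count_range} is ill-ordered"
            )
        if chi > len(self.catalog):
            raise ConfigError(
                f"catalog has {len(self.catalog)} templates but up to {chi} comorbidities "
                "are requested; supply a larger catalog"
            )


def demonstration_case(cancer_death_probability: float = 0.5):
    """The worked demonstration fixture.

    Returns ``(patient, treatment)``: lung cancer with a 50% 5-year death
    probability (60% in the alternative no-cancer-treatment scenario) and 40%
    impairment if alive; AF with a 20% 5-year stroke probability adding 50%
    impairment; statin efficacy 5% (15% MI risk reduced by one-third) with a
    25% baseline benefit for the prevented non-fatal MI.
    """
    alive_p = 1.0 - cancer_death_probability
    patient = PatientProfile(
        id="demonstration-75M",
        age_years=75,
        horizon_years=5.0,
        risk_factors=(
            RiskFactor(
                "lung_cancer",
                (
                    OutcomeBranch("death from cancer", cancer_death_probability, is_death=True),
                    OutcomeBranch("alive with cancer", alive_p, added_impairment=0.40),
                ),
            ),
            RiskFactor(
                "af_stroke",
                (
                    OutcomeBranch("stroke", 0.20, added_impairment=0.50),
                    OutcomeBranch("no stroke", 0.80),
                ),
            ),
        ),
        initial_utility=1.0,
    )
    treatment = Treatment(
        "statin",
        (EfficacyComponent("prevented non-fatal MI", probability=0.15 / 3, baseline_benefit=0.25),),
    )
    return patient, treatment


def _mean_mortality(age_death: np.ndarray, other_alive: np.ndarray, s: float) -> float:
    return float(np.mean(1.0 - (1.0 - s * age_death) * other_alive))


def generate_cohort(spec: CohortGenSpec) -> list[PatientProfile]:
    """Draw a deterministic synthetic cohort from the spec's seed.

    Each patient gets an age, an age-mortality risk factor, a degenerate
    initial-impairment factor, and a sampled subset of catalog conditions with
    probabilities/impairments drawn uniformly from the template ranges; the
    cohort is then calibrated toward the target mean initial impairment and
    5-year mortality.  Every returned profile validates.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.age_range
    clo, chi = spec.comorbidity_count_range

    ages = rng.integers(int(lo), int(hi) + 1, size=spec.n)
    counts = rng.integers(clo, chi + 1, size=spec.n)

    drawn = []
    initial_impairments = np.zeros(spec.n)
    for i in range(spec.n):
        idx = rng.choice(len(spec.catalog), size=counts[i], replace=False)
        conditions = []
        well = 1.0
        for j in idx:
            tpl = spec.catalog[j]
            sample = lambda r: float(rng.uniform(*r)) if r[1] > r[0] else r[0]
            cond = {
                "name": tpl.name,
                "death": sample(tpl.death_prob),
                "event": sample(tpl.event_prob),
                "impairment": sample(tpl.event_impairment),
                "initial": sample(tpl.initial_impairment),
            }
            well *= 1.0 - cond["initial"]
            conditions.append(cond)
        drawn.append(conditions)
        initial_impairments[i] = 1.0 - well

    # calibrate initial impairment by multiplicative rescaling, capped below 1
    if spec.target_mean_initial_impairment is not None and initial_impairments.mean() > 0:
        scale = spec.target_mean_initial_impairment / initial_impairments.mean()
        initial_impairments = np.minimum(initial_impairments * scale, 0.98)

    # calibrate 5-year mortality by bisection on an age-mortality scale factor
    age_death = np.array(
        [age_mortality_5y(a, spec.age_mortality_table) for a in ages], dtype=float
    )
    other_alive = np.array(
        [np.prod([1.0 - c["death"] for c in conds]) if conds else 1.0 for conds in drawn]
    )
    s = 1.0
    if spec.target_mortality_5y is not None and np.any(age_death > 0):
        s_max = float(1.0 / age_death.max())
        lo_s, hi_s = 0.0, s_max
        if _mean_mortality(age_death, other_alive, 0.0) >= spec.target_mortality_5y:
            s = 0.0
        elif _mean_mortality(age_death, other_alive, s_max) <= spec.target_mortality_5y:
            s = s_max
        else:
            for _ in range(60):
                mid = 0.5 * (lo_s + hi_s)
                if _mean_mortality(age_death, other_alive, mid) < spec.target_mortality_5y:
                    lo_s = mid
                else:
                    hi_s = mid
            s = 0.5 * (lo_s + hi_s)

    cohort = []
    for i in range(spec.n):
        factors = [
            RiskFactor(
                "initial_impairment",
                (OutcomeBranch("chronic impairment", 1.0, added_impairment=initial_impairments[i]),),
            ),
            RiskFactor(
                "age_mortality",
                (
                    OutcomeBranch("death", min(1.0, s * age_death[i]), is_death=True),
                    OutcomeBranch("survives", 1.0 - min(1.0, s * age_death[i])),
                ),
            ),
        ]
        for cond in drawn[i]:
            p_death = cond["death"]
            p_event = (1.0 - p_death) * cond["event"]
            branches = []
            if p_death > 0:
                branches.append(OutcomeBranch("death", p_death, is_death=True))
            if p_event > 0:
                branches.append(
                    OutcomeBranch("progression", p_event, added_impairment=cond["impairment"])
                )
            branches.append(OutcomeBranch("stable", 1.0 - p_death - p_event))
            factors.append(RiskFactor(cond["name"], tuple(branches)))
        cohort.append(
            PatientProfile(
                id=f"synthetic-{i + 1:03d}",
                age_years=float(ages[i]),
                horizon_years=5.0,
                risk_factors=tuple(factors),
                initial_utility=1.0 - initial_impairments[i],
            )
        )
    return cohort


def cohort_summary(cohort: list[PatientProfile]) -> dict:
    """Achieved cohort moments.

    Because the aggregation of "conditional impairment if alive" is ambiguous,
    both candidates are reported: the mean over patients of each patient's
    expected impairment given alive, and the pooled expectation over all alive
    probability mass.
    """
    ages = [p.age_years for p in cohort if p.age_years is not None]
    counts = [
        sum(
            1
            for rf in p.risk_factors
            if rf.name not in ("initial_impairment", "age_mortality")
        )
        for p in cohort
    ]
    initial = [
        1.0 - p.initial_utility if p.initial_utility is not None else 0.0 for p in cohort
    ]

    mortalities = []
    per_patient_cond = []
    pooled_num = 0.0
    pooled_den = 0.0
    for p in cohort:
        dist = merge_atoms(enumerate_joint_outcomes(p))
        pa = probability_alive(dist)
        mortalities.append(1.0 - pa)
        alive = ~dist.death
        mass = float(dist.probabilities[alive].sum())
        impairment_mass = float(
            np.dot(dist.probabilities[alive], 1.0 - dist.utilities[alive])
        )
        pooled_num += impairment_mass
        pooled_den += mass
        if mass > 0:
            per_patient_cond.append(impairment_mass / mass)

    return {
        "n": len(cohort),
        "mean_age": float(np.mean(ages)) if ages else None,
        "mean_comorbidity_count": float(np.mean(counts)),
        "mean_initial_impairment": float(np.mean(initial)),
        "mean_mortality_5y": float(np.mean(mortalities)),
        "conditional_impairment_if_alive_per_patient_mean": (
            float(np.mean(per_patient_cond)) if per_patient_cond else None
        ),
        "conditional_impairment_if_alive_pooled": (
            pooled_num / pooled_den if pooled_den > 0 else None
        ),
    }
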