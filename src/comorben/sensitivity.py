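"""Sensitivity machinery: input perturbations, the two-regime impairment
transformation, age-mortality elimination, and time-frame rescaling.

All perturbations are pure: they return transformed deep copies and never
touch the inputs, so an envelope of scenarios can be built from one baseline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

from .model import (
    ConfigError,
    DomainError,
    OutcomeBranch,
    PatientProfile,
    RiskFactor,
    Treatment,
    _check_fraction,
    _condition_tokens,
)
from .enumeration import StepCurve, enumerate_joint_outcomes, merge_atoms, comorbidity_effect_curve
from .benefit import absolute_benefit_curve, relative_benefit_curve

__all__ = [
    "SENSITIVITY_TARGETS",
    "SensitivitySpec",
    "adjust_impairment",
    "perturb_inputs",
    "drop_age_mortality",
    "rescale_timeframe",
    "sensitivity_envelope",
]

SENSITIVITY_TARGETS = frozenset({"efficacy", "event_probability", "impairment", "progression"})


@dataclass(frozen=True)
class SensitivitySpec:
    """One perturbation scenario.

    ``targets`` selects which inputs move: treatment efficacies, risk-factor
    event probabilities, impairment magnitudes, or disease-progression
    probabilities (reduction only — progression data err on the pessimistic
    side, so only the optimistic direction is meaningful).  ``factor`` is the
    fractional change (0.5 for the standard +/-50%; 0.75 and 0.90 for the
    deeper impairment reductions); 0 is the identity.  ``horizon_years``
    optionally rescales the analysis time frame as part of the scenario.
    """

    targets: frozenset[str] = frozenset()
    direction: str = "down"
    factor: float = 0.5
    horizon_years: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "targets", frozenset(self.targets))
        unknown = self.targets - SENSITIVITY_TARGETS
        if unknown:
            raise ConfigError(f"unknown sensitivity targets: {sorted(unknown)}")
        if self.direction not in ("up", "down"):
            raise DomainError(f"direction must be 'up' or 'down', got {self.direction!r}")
        if not (0.0 <= self.factor <= 1.0):
            raise DomainError(f"factor must lie in [0, 1], got {self.factor!r}")
        if "progression" in self.targets and self.direction != "down":
            raise ConfigError("progression perturbations admit only direction='down'")
        if self.horizon_years is not None and not self.horizon_years > 0:
            raise DomainError("horizon_years must be positive")

    @property
    def key(self) -> str:
        """Stable label for keyed envelopes and long-format CSV export."""
        parts = []
        if self.targets:
            parts.append("+".join(sorted(self.targets)))
            parts.append(f"{self.direction}_{round(self.factor * 100):g}")
        if self.horizon_years is not None:
            parts.append(f"{self.horizon_years:g}y")
        return "_".join(parts) if parts else "identity"


def adjust_impairment(i: float, direction: str, factor: float) -> float:
    """Two-regime sensitivity transformation of an impairment score.

    Low scores (i <= 0.5) are scaled directly: ``i' = (1 +/- factor) * i``,
    capped at 1.  High scores (i > 0.5) would overflow 100% when scaled up,
    so the *utility* u = 1 - i is scaled in the opposite direction instead:
    ``u' = (1 -/+ factor) * u``.  The two regimes agree at i = 0.5, so the
    transformation is continuous, order-preserving within each regime, and
    maps [0, 1] onto [0, 1] for any factor in [0, 1].
    """
    i = _check_fraction(i, "impairment")
    if direction not in ("up", "down"):
        raise DomainError(f"direction must be 'up' or 'down', got {direction!r}")
    if not (0.0 <= factor <= 1.0):
        raise DomainError(f"factor must lie in [0, 1], got {factor!r}")
    if i <= 0.5:
        mult = 1.0 + factor if direction == "up" else 1.0 - factor
        return min(1.0, mult * i)
    u = 1.0 - i
    mult = 1.0 - factor if direction == "up" else 1.0 + factor
    return min(1.0, max(0.0, 1.0 - mult * u))


# ---------------------------------------------------------------------------
# probability rescaling helpers


def _rescale_factor_probs(rf: RiskFactor, scaled: dict[int, float]) -> RiskFactor:
    """Rebuild a risk factor with branches at ``scaled`` probabilities and the
    complement (best-outcome) branch carrying the remaining mass.  If the
    scaled non-complement mass exceeds 1, it is renormalised down to 1 and the
    complement gets 0 (the clamp case)."""
    comp = rf.complement_index()
    if comp is None:
        raise ConfigError(
            f"risk factor {rf.name!r} has no non-death branch to renormalise onto"
        )
    others = [i for i in range(len(rf.branches)) if i != comp]
    probs = {i: scaled.get(i, rf.branches[i].probability) for i in others}
    total = sum(probs.values())
    if total > 1.0:
        probs = {i: p / total for i, p in probs.items()}
        total = 1.0
    new_branches = []
    for i, b in enumerate(rf.branches):
        if i == comp:
            new_branches.append(replace(b, probability=1.0 - total))
        else:
            new_branches.append(replace(b, probability=min(1.0, max(0.0, probs[i]))))
    return RiskFactor(rf.name, tuple(new_branches))


def _scale_events(rf: RiskFactor, mult: float, only_progression: bool) -> RiskFactor:
    comp = rf.complement_index()
    if comp is None:
        if abs(mult - 1.0) <= 1e-15:
            return rf
        raise ConfigError(
            f"risk factor {rf.name!r} has no non-death branch to renormalise onto"
        )
    scaled: dict[int, float] = {}
    for i, b in enumerate(rf.branches):
        if i == comp:
            continue
        if only_progression and (b.is_death or b.added_impairment <= 0.0):
            continue
        scaled[i] = min(1.0, b.probability * mult)
    if not scaled:
        return rf
    return _rescale_factor_probs(rf, scaled)


# ---------------------------------------------------------------------------
# perturbations


def perturb_inputs(
    patient: PatientProfile, treatment: Treatment, spec: SensitivitySpec
) -> tuple[PatientProfile, Treatment]:
    """Apply a sensitivity scenario, returning transformed copies.

    Efficacy and event probabilities are multiplied by ``1 +/- factor`` and
    clamped to [0, 1], with risk-factor branch probabilities renormalised onto
    the complement (best-outcome) branch; impairment magnitudes go through
    :func:`adjust_impairment`; progression reductions scale only the non-death
    impairment branches.  A ``horizon_years`` in the spec additionally
    rescales the time frame.
    """
    mult = 1.0 + spec.factor if spec.direction == "up" else 1.0 - spec.factor

    new_treatment = treatment
    if "efficacy" in spec.targets:
        comps = [replace(c, probability=min(1.0, c.probability * mult)) for c in treatment.components]
        total = sum(c.probability for c in comps)
        if total > 1.0:
            comps = [replace(c, probability=c.probability / total) for c in comps]
        new_treatment = Treatment(treatment.name, tuple(comps))

    new_factors = list(patient.risk_factors)
    if "impairment" in spec.targets:
        adjusted = []
        for rf in new_factors:
            branches = tuple(
                b
                if b.is_death or b.added_impairment <= 0.0
                else replace(
                    b,
                    added_impairment=adjust_impairment(
                        b.added_impairment, spec.direction, spec.factor
                    ),
                )
                for b in rf.branches
            )
            adjusted.append(RiskFactor(rf.name, branches))
        new_factors = adjusted
    if "event_probability" in spec.targets:
        new_factors = [_scale_events(rf, mult, only_progression=False) for rf in new_factors]
    if "progression" in spec.targets:
        new_factors = [_scale_events(rf, mult, only_progression=True) for rf in new_factors]

    initial_utility = patient.initial_utility
    if "impairment" in spec.targets and initial_utility is not None:
        initial_utility = 1.0 - adjust_impairment(
            1.0 - initial_utility, spec.direction, spec.factor
        )

    new_patient = replace(
        patient, risk_factors=tuple(new_factors), initial_utility=initial_utility
    )
    if spec.horizon_years is not None:
        new_patient, new_treatment = rescale_timeframe(
            new_patient, new_treatment, spec.horizon_years
        )
    return new_patient, new_treatment


def drop_age_mortality(patient: PatientProfile, tag: str = "age") -> PatientProfile:
    """Eliminate age-related mortality: every risk factor whose name carries
    the ``tag`` token and that has a death branch is replaced by a certain
    survive branch.  A no-op (with a warning) if no such factor exists."""
    tag = tag.lower()
    new_factors = []
    found = False
    for rf in patient.risk_factors:
        tokens = {t for t in _condition_tokens(rf.name)} | set(
            rf.name.lower().replace("-", "_").split("_")
        )
        if tag in tokens and rf.has_death:
            found = True
            new_factors.append(
                RiskFactor(rf.name, (OutcomeBranch("survives (age mortality removed)", 1.0),))
            )
        else:
            new_factors.append(rf)
    if not found:
        warnings.warn(
            f"patient {patient.id!r}: no risk factor tagged {tag!r} with a death branch; "
            "age-mortality elimination is a no-op",
            stacklevel=2,
        )
    return replace(patient, risk_factors=tuple(new_factors))


def rescale_timeframe(
    patient: PatientProfile,
    treatment: Treatment,
    years: float,
    method: str = "linear",
) -> tuple[PatientProfile, Treatment]:
    """Shorten the analysis horizon assuming risks and benefit accumulate at a
    constant rate: every cumulative event probability p (death, impairment
    events, and the treatment's efficacy components) becomes ``p * years /
    horizon``, with complement branches renormalised.  Progression impairment
    magnitudes are left unchanged, and the horizon metadata is updated.

    ``method='exponential'`` instead applies the constant-hazard form
    ``1 - (1 - p)**(years / horizon)``; both compose consistently (5 -> 2 ->
    1 equals 5 -> 1).
    """
    horizon = patient.horizon_years
    if not (0.0 < years <= horizon + 1e-12):
        raise DomainError(f"years must lie in (0, {horizon}], got {years!r}")
    if method not in ("linear", "exponential"):
        raise DomainError(f"method must be 'linear' or 'exponential', got {method!r}")
    ratio = years / horizon

    if method == "linear":
        scale = lambda p: p * ratio
    else:
        scale = lambda p: 1.0 - (1.0 - p) ** ratio

    new_factors = []
    for rf in patient.risk_factors:
        comp = rf.complement_index()
        if comp is None:
            if abs(ratio - 1.0) <= 1e-15:
                new_factors.append(rf)
                continue
            raise ConfigError(
                f"risk factor {rf.name!r} has no non-death branch to renormalise onto"
            )
        scaled = {
            i: scale(b.probability)
            for i, b in enumerate(rf.branches)
            if i != comp
        }
        new_factors.append(_rescale_factor_probs(rf, scaled) if scaled else rf)

    comps = tuple(replace(c, probability=scale(c.probability)) for c in treatment.components)
    new_patient = replace(patient, risk_factors=tuple(new_factors), horizon_years=years)
    return new_patient, Treatment(treatment.name, comps)


# ---------------------------------------------------------------------------
# envelopes


_CURVE_BUILDERS = {
    "comorbidity": lambda dist, treatment: comorbidity_effect_curve(dist),
    "relative": relative_benefit_curve,
    "absolute": absolute_benefit_curve,
}


def sensitivity_envelope(
    patient: PatientProfile,
    treatment: Treatment,
    specs,
    *,
    curve: str = "relative",
    merge_tol: float = 0.0,
) -> dict[str, StepCurve]:
    """Baseline curve plus one curve per scenario, keyed by the scenario key —
    ready for overlay plotting or long-format CSV export."""
    if curve not in _CURVE_BUILDERS:
        raise DomainError(f"curve must be one of {sorted(_CURVE_BUILDERS)}, got {curve!r}")
    build = _CURVE_BUILDERS[curve]

    def _one(p: PatientProfile, t: Treatment) -> StepCurve:
        return build(merge_atoms(enumerate_joint_outcomes(p), tol=merge_tol), t)

    out = {"baseline": _one(patient, treatment)}
    for spec in specs:
        p2, t2 = perturb_inputs(patient, treatment, spec)
        out[spec.key] = _one(p2, t2)
    return out
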