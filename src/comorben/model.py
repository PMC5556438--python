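"""Domain types and the multiplicative impairment/utility algebra.

The central convention throughout the package: *utility* quantifies wellness
on [0, 1] (0 = death, 1 = complete well-being) and *impairment* is its
complement, ``utility = 1 - impairment``.  Impairments from independent
conditions combine multiplicatively — a new impairment is weighted by the
pre-existing well-being — so that combined impairment can approach but never
exceed 1 (total impairment, equivalent to death).

A patient is described at a fixed horizon (default 5 years) by a set of risk
factors, each a small discrete distribution over mutually exclusive outcome
branches (death, added impairment, or no event).  Chronic impairments already
present at time zero are encoded as degenerate single-branch risk factors
with probability 1, so downstream enumeration treats them uniformly.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = [
    "TOL",
    "DomainError",
    "ConfigError",
    "ResourceError",
    "OutcomeBranch",
    "RiskFactor",
    "PatientProfile",
    "EfficacyComponent",
    "Treatment",
    "ValidationReport",
    "combine_impairments",
    "utility_from_impairments",
    "validate_patient",
]

#: Global comparison tolerance for probabilities and impairment fractions.
#: Inputs in this field are percentages with at most three significant
#: figures, so 1e-9 is far below any meaningful difference.
TOL = 1e-9


class DomainError(ValueError):
    """An argument lies outside its mathematical domain (e.g. a fraction not in [0, 1])."""


class ConfigError(ValueError):
    """Inputs are individually valid but jointly inconsistent (e.g. efficacies summing over 1)."""


class ResourceError(RuntimeError):
    """A computation would exceed a configured resource cap."""


def _check_fraction(value: float, name: str) -> float:
    value = float(value)
    if not (-TOL <= value <= 1.0 + TOL):
        raise DomainError(f"{name} must lie in [0, 1], got {value!r}")
    return min(max(value, 0.0), 1.0)


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class OutcomeBranch:
    """One possible outcome of a risk factor at the horizon.

    Parameters
    ----------
    label:
        Short human-readable description ("stroke", "death", "stable").
    probability:
        Probability of this branch over the horizon, in [0, 1].
    added_impairment:
        Impairment added if this branch occurs, in [0, 1].  Ignored when
        ``is_death`` is set: a death branch forces utility 0 for any joint
        outcome containing it.
    is_death:
        Whether this branch represents death.
    """

    label: str
    probability: float
    added_impairment: float = 0.0
    is_death: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "probability", _check_fraction(self.probability, "probability"))
        object.__setattr__(
            self, "added_impairment", _check_fraction(self.added_impairment, "added_impairment")
        )


@dataclass(frozen=True)
class RiskFactor:
    """A condition (or age, or a time-zero impairment stub) as a set of
    mutually exclusive outcome branches.

    Branch probabilities are expected to sum to 1; this aggregate condition is
    reported by :func:`validate_patient` rather than enforced at construction,
    so partially-built inputs can still be inspected.
    """

    name: str
    branches: tuple[OutcomeBranch, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "branches", tuple(self.branches))
        if not self.branches:
            raise DomainError(f"risk factor {self.name!r} needs at least one branch")

    @property
    def probability_sum(self) -> float:
        return sum(b.probability for b in self.branches)

    @property
    def has_death(self) -> bool:
        return any(b.is_death for b in self.branches)

    def complement_index(self) -> int | None:
        """Index of the best-outcome branch: non-death with the smallest added
        impairment.  Probability mass freed (or demanded) by perturbing the
        other branches is renormalised onto it.  ``None`` if every branch is a
        death branch."""
        best: int | None = None
        for i, b in enumerate(self.branches):
            if b.is_death:
                continue
            if best is None or b.added_impairment < self.branches[best].added_impairment - 1e-12:
                best = i
        return best


@dataclass(frozen=True)
class PatientProfile:
    """A named individual: metadata plus their risk factors at one horizon.

    ``initial_utility`` optionally stores the utility at time zero (1 minus
    the combined chronic impairment); it is required only by the "initial"
    point-estimate simplification and is stored explicitly rather than
    inferred from the degenerate risk factors.
    """

    id: str
    age_years: float | None = None
    horizon_years: float = 5.0
    risk_factors: tuple[RiskFactor, ...] = ()
    initial_utility: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "risk_factors", tuple(self.risk_factors))
        if not self.horizon_years > 0:
            raise DomainError(f"horizon_years must be positive, got {self.horizon_years!r}")
        if self.initial_utility is not None:
            object.__setattr__(
                self, "initial_utility", _check_fraction(self.initial_utility, "initial_utility")
            )


@dataclass(frozen=True)
class EfficacyComponent:
    """One way the treatment can help: a probability of preventing an event,
    with the benefit magnitude that prevention has in a person free of
    comorbidity (e.g. 25% for a prevented non-fatal MI, 100% for a fatal one).
    """

    label: str
    probability: float
    baseline_benefit: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "probability", _check_fraction(self.probability, "probability"))
        b = _check_fraction(self.baseline_benefit, "baseline_benefit")
        if b <= 0.0:
            raise DomainError(f"baseline_benefit must be in (0, 1], got {self.baseline_benefit!r}")
        object.__setattr__(self, "baseline_benefit", b)


@dataclass(frozen=True)
class Treatment:
    """A preventive treatment as a set of mutually exclusive efficacy
    components whose probabilities partition the overall "benefit" event."""

    name: str
    components: tuple[EfficacyComponent, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "components", tuple(self.components))
        if not self.components:
            raise DomainError(f"treatment {self.name!r} needs at least one efficacy component")
        if self.total_efficacy > 1.0 + TOL:
            raise ConfigError(
                f"treatment {self.name!r}: component probabilities sum to "
                f"{self.total_efficacy:.6g} > 1"
            )

    @property
    def total_efficacy(self) -> float:
        """Total probability of deriving any benefit, ignoring comorbidity."""
        return sum(c.probability for c in self.components)

    @property
    def mean_baseline_benefit(self) -> float:
        """Efficacy-weighted mean of the component baseline benefits."""
        total = self.total_efficacy
        if total <= TOL:
            return sum(c.baseline_benefit for c in self.components) / len(self.components)
        return sum(c.probability * c.baseline_benefit for c in self.components) / total


# ---------------------------------------------------------------------------
# impairment algebra


def combine_impairments(existing: float, added: float) -> float:
    """Combine two impairments multiplicatively.

    The added impairment is weighted by the pre-existing well-being::

        combined = existing + added * (1 - existing) = 1 - (1 - existing)(1 - added)

    The operation is commutative, associative, monotone in each argument, and
    bounded by 1 (total impairment absorbs everything).

    >>> combine_impairments(0.25, 0.40)
    0.55
    """
    e = _check_fraction(existing, "existing impairment")
    a = _check_fraction(added, "added impairment")
    return e + a * (1.0 - e)


def utility_from_impairments(impairments, any_death: bool = False) -> float:
    """Utility of a joint state: 0 on death, else the product of the
    per-condition well-beings ``(1 - impairment_k)``.

    Equivalent to 1 minus the fold of :func:`combine_impairments` over the
    list, in any order.
    """
    if any_death:
        for imp in impairments:
            _check_fraction(imp, "impairment")
        return 0.0
    u = 1.0
    for imp in impairments:
        u *= 1.0 - _check_fraction(imp, "impairment")
    return u


# ---------------------------------------------------------------------------
# validation


@dataclass
class ValidationReport:
    """Outcome of :func:`validate_patient`: hard errors and advisory warnings."""

    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        lines = [f"error: {e}" for e in self.errors] + [f"warning: {w}" for w in self.warnings]
        return "\n".join(lines) if lines else "ok"


# Tokens too generic to indicate that two risk factors describe the same
# condition; shared *condition* tokens trigger a possible-double-count warning.
_GENERIC_TOKENS = frozenset(
    {
        "risk",
        "risks",
        "mortality",
        "death",
        "impairment",
        "impairments",
        "initial",
        "baseline",
        "progression",
        "year",
        "years",
        "rate",
        "factor",
        "related",
        "incl",
        "including",
        "with",
        "without",
        "from",
        "event",
    }
)


def _condition_tokens(name: str) -> frozenset[str]:
    tokens = re.split(r"[^a-z0-9]+", name.lower())
    return frozenset(t for t in tokens if len(t) >= 4 and t not in _GENERIC_TOKENS)


def validate_patient(patient: PatientProfile) -> ValidationReport:
    """Check a patient profile; all problems are returned, never raised.

    Errors: branch probabilities not summing to 1 (tolerance ``TOL``),
    out-of-range values, duplicate risk-factor names.  Warnings: pairs of risk factors sharing a
    condition-specific name token, flagged as possible double counting of the
    same condition under two headings.  The input is never mutated.
    """
    report = ValidationReport()
    seen: set[str] = set()
    for rf in patient.risk_factors:
        if rf.name in seen:
            report.errors.append(f"duplicate risk factor name {rf.name!r}")
        seen.add(rf.name)
        total = rf.probability_sum
        if abs(total - 1.0) > 10 * TOL:
            report.errors.append(
                f"risk factor {rf.name!r}: branch probabilities sum to {total:.6g}, not 1"
            )
        for b in rf.branches:
            # construction already range-checks; re-check defensively so
            # hand-built objects bypassing the constructor still get caught
            if not (0.0 <= b.probability <= 1.0):
                report.errors.append(
                    f"risk factor {rf.name!r}, branch {b.label!r}: probability "
                    f"{b.probability!r} outside [0, 1]"
                )
            if not (0.0 <= b.added_impairment <= 1.0):
                report.errors.append(
                    f"risk factor {rf.name!r}, branch {b.label!r}: added_impairment "
                    f"{b.added_impairment!r} outside [0, 1]"
                )
    if not patient.horizon_years > 0:
        report.errors.append(f"horizon_years must be positive, got {patient.horizon_years!r}")

    factors = list(patient.risk_factors)
    for i in range(len(factors)):
        for j in range(i + 1, len(factors)):
            shared = _condition_tokens(factors[i].name) & _condition_tokens(factors[j].name)
            if shared:
                report.warnings.append(
                    f"risk factors {factors[i].name!r} and {factors[j].name!r} share "
                    f"condition token(s) {sorted(shared)}: possible double counting; "
                    "record each condition under one heading only"
                )
    return report


def require_valid(patient: PatientProfile) -> ValidationReport:
    """Validate and raise :class:`DomainError` if the profile has errors."""
    report = validate_patient(patient)
    if not report.ok:
        raise DomainError(
            f"patient {patient.id!r} failed validation:\n" + "\n".join(report.errors)
        )
    return report
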