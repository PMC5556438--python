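"""Joint outcome enumeration and the complementary CDF of utility.

All of a patient's risk factors are combined under mutual independence: the
joint outcome space is the Cartesian product of the per-factor branches, each
joint outcome carrying the product of branch probabilities and the utility of
the combined impairments (0 if any selected branch is death).  The resulting
discrete utility distribution is summarised as a step curve giving, for each
threshold, the probability of having utility at least that large — the
"comorbidity effect" curve.

Because only the state at the horizon matters (not the order of intermediate
events), and adverse treatment effects are excluded, enumeration is a pure
product construction.  Conditional structure such as "stroke only matters if
alive" needs no special handling: a stroke branch co-occurring with a death
branch simply contributes its mass to the death (utility-0) state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import reduce
from itertools import product as _iterproduct

import numpy as np

from .model import (
    TOL,
    DomainError,
    PatientProfile,
    ResourceError,
    require_valid,
)

__all__ = [
    "UtilityAtom",
    "UtilityDistribution",
    "StepCurve",
    "enumerate_joint_outcomes",
    "merge_atoms",
    "utility_ccdf",
    "comorbidity_effect_curve",
    "probability_alive",
]

#: Default cap on the number of joint combinations; ~10 factors of 2-3
#: branches stay well under it, and anything larger signals an input that
#: should be pruned to the major comorbidities.
DEFAULT_COMBINATION_CAP = 10**6

# utilities within this distance are treated as the same discrete state
_EQ_TOL = 1e-12
# inclusive ">= threshold" comparisons allow this much float slack
_CCDF_EPS = 1e-9


@dataclass(frozen=True)
class UtilityAtom:
    """One discrete joint-outcome state: probability, utility, and optionally
    the branch labels it came from."""

    probability: float
    utility: float
    is_death: bool = False
    provenance: tuple[str, ...] = ()


class UtilityDistribution:
    """A discrete probability distribution over utility states.

    Stored internally as parallel numpy arrays for speed (enumerations may
    have up to 10^6 atoms); :attr:`atoms` materialises ``UtilityAtom`` objects
    on demand.  Atom probabilities sum to 1 and utilities lie in [0, 1];
    death states are tracked separately from non-death states of utility 0 so
    that the probability of being alive remains recoverable.
    """

    __slots__ = ("probabilities", "utilities", "death", "provenance")

    def __init__(self, probabilities, utilities, death=None, provenance=None, check=True):
        p = np.atleast_1d(np.asarray(probabilities, dtype=float))
        u = np.atleast_1d(np.asarray(utilities, dtype=float))
        d = (
            np.zeros(p.shape, dtype=bool)
            if death is None
            else np.atleast_1d(np.asarray(death, dtype=bool))
        )
        if check:
            if not (p.shape == u.shape == d.shape):
                raise DomainError("probabilities, utilities and death must have equal length")
            if p.size == 0:
                raise DomainError("a utility distribution needs at least one atom")
            if np.any(p < -TOL):
                raise DomainError("atom probabilities must be non-negative")
            if np.any((u < -TOL) | (u > 1 + TOL)):
                raise DomainError("utilities must lie in [0, 1]")
            total = float(p.sum())
            if abs(total - 1.0) > 1e-6:
                raise DomainError(f"atom probabilities sum to {total:.6g}, not 1")
        self.probabilities = p
        self.utilities = np.clip(u, 0.0, 1.0)
        self.death = d
        self.provenance = tuple(provenance) if provenance is not None else None

    @classmethod
    def from_atoms(cls, atoms) -> "UtilityDistribution":
        atoms = list(atoms)
        return cls(
            [a.probability for a in atoms],
            [a.utility for a in atoms],
            [a.is_death for a in atoms],
            provenance=[a.provenance for a in atoms],
        )

    @property
    def atoms(self) -> list[UtilityAtom]:
        prov = self.provenance or [()] * len(self)
        return [
            UtilityAtom(float(p), float(u), bool(d), tuple(pr))
            for p, u, d, pr in zip(self.probabilities, self.utilities, self.death, prov)
        ]

    def __len__(self) -> int:
        return int(self.probabilities.size)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"UtilityDistribution({len(self)} atoms, mean utility {self.mean_utility:.4g})"

    @property
    def total_probability(self) -> float:
        return float(self.probabilities.sum())

    @property
    def mean_utility(self) -> float:
        return float(np.dot(self.probabilities, self.utilities))


def enumerate_joint_outcomes(
    patient: PatientProfile,
    *,
    cap: int = DEFAULT_COMBINATION_CAP,
    trace: bool = False,
    check: bool = True,
) -> UtilityDistribution:
    """Enumerate every combination of risk-factor outcomes.

    One atom per element of the Cartesian product of branches (un-merged).
    Atom probability is the product of branch probabilities (independence);
    atom utility is the product of the selected branches' well-beings, 0 if
    any selected branch is death.  A patient with no risk factors yields the
    single certain state of full utility.

    Parameters
    ----------
    cap:
        Maximum admitted product size; beyond it a :class:`ResourceError`
        advises pruning the profile to its major comorbidities.
    trace:
        Record ``"factor: branch"`` labels per atom (slower; intended for
        small profiles and reporting).
    check:
        Validate the patient first (raises on errors).
    """
    if check:
        require_valid(patient)
    factors = patient.risk_factors
    if not factors:
        return UtilityDistribution([1.0], [1.0], [False], provenance=[()] if trace else None)

    n_combo = math.prod(len(f.branches) for f in factors)
    if n_combo > cap:
        raise ResourceError(
            f"patient {patient.id!r}: {n_combo} joint outcome combinations exceed the cap "
            f"of {cap}; prune the profile to its major comorbidities or raise `cap`"
        )

    prob_arrays = [np.array([b.probability for b in f.branches]) for f in factors]
    # per-branch well-being; a death branch contributes factor 0, so any joint
    # outcome containing it gets utility 0 automatically
    wellbeing_arrays = [
        np.array([0.0 if b.is_death else 1.0 - b.added_impairment for b in f.branches])
        for f in factors
    ]
    death_arrays = [np.array([b.is_death for b in f.branches]) for f in factors]

    outer = lambda a, b: np.multiply.outer(a, b).ravel()
    probabilities = reduce(outer, prob_arrays)
    utilities = reduce(outer, wellbeing_arrays)
    death = reduce(lambda a, b: np.logical_or.outer(a, b).ravel(), death_arrays)

    provenance = None
    if trace:
        labels = [[f"{f.name}: {b.label}" for b in f.branches] for f in factors]
        provenance = [tuple(combo) for combo in _iterproduct(*labels)]

    return UtilityDistribution(probabilities, utilities, death, provenance=provenance, check=check)


def merge_atoms(dist: UtilityDistribution, tol: float = 0.0) -> UtilityDistribution:
    """Merge atoms of (near-)equal utility into single discrete states.

    Non-death atoms are sorted by utility and clustered by single-linkage:
    consecutive utilities at most ``tol`` apart join the same cluster.  Each
    cluster becomes one atom at the probability-weighted mean utility, with
    the probabilities summed, so total probability and mean utility are
    conserved.  All death atoms collapse to one utility-0 death atom.

    Single-linkage guarantees idempotence: merged representatives of distinct
    clusters are separated by more than ``tol``.
    """
    if tol < 0:
        raise DomainError("tol must be non-negative")
    alive = ~dist.death
    out_p: list[float] = []
    out_u: list[float] = []
    out_d: list[bool] = []

    p_alive = dist.probabilities[alive]
    u_alive = dist.utilities[alive]
    if p_alive.size:
        order = np.argsort(u_alive, kind="stable")
        u_sorted = u_alive[order]
        p_sorted = p_alive[order]
        starts = np.flatnonzero(np.concatenate(([True], np.diff(u_sorted) > tol)))
        p_merged = np.add.reduceat(p_sorted, starts)
        wsum = np.add.reduceat(p_sorted * u_sorted, starts)
        with np.errstate(invalid="ignore", divide="ignore"):
            u_merged = np.where(p_merged > 0, wsum / np.where(p_merged > 0, p_merged, 1.0),
                                u_sorted[starts])
        out_p.extend(p_merged.tolist())
        out_u.extend(np.clip(u_merged, 0.0, 1.0).tolist())
        out_d.extend([False] * len(starts))

    if np.any(dist.death):
        out_p.append(float(dist.probabilities[dist.death].sum()))
        out_u.append(0.0)
        out_d.append(True)

    return UtilityDistribution(out_p, out_u, out_d, check=False)


def utility_ccdf(dist: UtilityDistribution, threshold: float) -> float:
    """P(utility >= threshold), inclusive at the threshold.

    Non-increasing in the threshold; 1 at threshold 0.
    """
    t = float(threshold)
    if not (-TOL <= t <= 1.0 + TOL):
        raise DomainError(f"threshold must lie in [0, 1], got {threshold!r}")
    return float(dist.probabilities[dist.utilities >= t - _CCDF_EPS].sum())


class StepCurve:
    """A right-of-threshold survival curve P(X >= x): non-increasing step
    function on [0, 1] — the shape of every benefit curve in this package.

    ``thresholds`` are the ascending positive support points of the underlying
    discrete variable; ``values[i] = P(X >= thresholds[i])``.  ``at_zero`` is
    the value at threshold exactly 0 (total mass, or total efficacy for
    relative-benefit curves); :attr:`intercept` is the limit as the threshold
    approaches 0 from above, i.e. P(X > 0) — for a comorbidity-effect curve,
    the probability of being alive and deriving *any* benefit.
    """

    __slots__ = ("thresholds", "values", "at_zero")

    def __init__(self, thresholds, values, at_zero: float, check: bool = True):
        t = np.asarray(thresholds, dtype=float).reshape(-1)
        v = np.asarray(values, dtype=float).reshape(-1)
        if check:
            if t.shape != v.shape:
                raise DomainError("thresholds and values must have equal length")
            if t.size and (np.any(np.diff(t) <= 0) or t[0] <= 0 or t[-1] > 1 + TOL):
                raise DomainError("thresholds must be strictly ascending within (0, 1]")
            if np.any(np.diff(v) > TOL):
                raise DomainError("curve values must be non-increasing")
            if np.any((v < -TOL) | (v > 1 + TOL)):
                raise DomainError("curve values must lie in [0, 1]")
        self.thresholds = t
        self.values = np.clip(v, 0.0, 1.0)
        self.at_zero = float(at_zero)

    @classmethod
    def from_points(cls, weights, xs, at_zero: float | None = None) -> "StepCurve":
        """Build the survival curve of a discrete distribution given as point
        masses ``(weight, x)``.  ``at_zero`` defaults to the total weight."""
        w = np.asarray(weights, dtype=float)
        x = np.asarray(xs, dtype=float)
        total = float(w.sum())
        positive = x > _EQ_TOL
        w_pos, x_pos = w[positive], x[positive]
        if x_pos.size:
            order = np.argsort(x_pos, kind="stable")
            x_sorted, w_sorted = x_pos[order], w_pos[order]
            starts = np.flatnonzero(np.concatenate(([True], np.diff(x_sorted) > _EQ_TOL)))
            support = x_sorted[starts]
            mass = np.add.reduceat(w_sorted, starts)
            values = np.cumsum(mass[::-1])[::-1]
        else:
            support = np.array([], dtype=float)
            values = np.array([], dtype=float)
        return cls(support, values, total if at_zero is None else at_zero, check=False)

    @property
    def intercept(self) -> float:
        """Limit of the curve as the threshold approaches 0 from above."""
        return float(self.values[0]) if self.values.size else 0.0

    def evaluate(self, threshold):
        """Curve value at one or many thresholds (inclusive >=).

        Thresholds above 1 return 0 (nothing exceeds full benefit); negative
        thresholds are a domain error.
        """
        t = np.asarray(threshold, dtype=float)
        if np.any(t < -TOL):
            raise DomainError("threshold must be non-negative")
        idx = np.searchsorted(self.thresholds, t - _CCDF_EPS, side="left")
        padded = np.concatenate((self.values, [0.0]))
        out = np.where(t <= _EQ_TOL, self.at_zero, padded[idx])
        return float(out) if np.isscalar(threshold) or out.ndim == 0 else out

    __call__ = evaluate

    def to_arrays(self):
        """(thresholds, values) including the threshold-0 point, for export."""
        return (
            np.concatenate(([0.0], self.thresholds)),
            np.concatenate(([self.at_zero], self.values)),
        )

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, StepCurve)
            and np.array_equal(self.thresholds, other.thresholds)
            and np.array_equal(self.values, other.values)
            and self.at_zero == other.at_zero
        )

    def __hash__(self):  # pragma: no cover
        return hash((self.thresholds.tobytes(), self.values.tobytes(), self.at_zero))

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"StepCurve({self.thresholds.size} steps, intercept {self.intercept:.4g})"


def comorbidity_effect_curve(dist: UtilityDistribution) -> StepCurve:
    """The full step function of :func:`utility_ccdf` over (0, 1].

    Its limit at 0+ equals P(utility > 0) (the probability of being alive,
    when no non-death state has utility exactly 0) and its largest threshold
    with positive value is the maximum attainable utility.
    """
    return StepCurve.from_points(dist.probabilities, dist.utilities)


def probability_alive(dist: UtilityDistribution) -> float:
    """Probability of not being dead at the horizon — hence of deriving *any*
    treatment benefit.  Distinguishes death from non-death total impairment."""
    return 1.0 - float(dist.probabilities[dist.death].sum())
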