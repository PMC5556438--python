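import math

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from comorben import (
    OutcomeBranch,
    PatientProfile,
    RiskFactor,
    demonstration_case,
)

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def demo():
    """The worked demonstration fixture: (patient, treatment)."""
    return demonstration_case()


@pytest.fixture
def no_comorbidity_patient():
    return PatientProfile(id="healthy", horizon_years=5.0, initial_utility=1.0)


def random_patient(rng, n_factors=None, max_branches=3, allow_death=True,
                   discrete_impairments=None):
    """A random valid patient profile for property tests.

    ``discrete_impairments`` optionally restricts impairments to a tabulated
    grid, mirroring how impairment scores are quoted in practice (and pooling
    joint outcomes onto a few well-populated utility states)."""
    n_factors = n_factors if n_factors is not None else int(rng.integers(1, 5))
    factors = []
    for i in range(n_factors):
        k = int(rng.integers(1, max_branches + 1))
        raw = rng.uniform(0.05, 1.0, size=k)
        probs = raw / raw.sum()
        branches = []
        for j in range(k):
            is_death = bool(allow_death and k > 1 and j == 0 and rng.uniform() < 0.3)
            if discrete_impairments is not None:
                impairment = float(rng.choice(discrete_impairments))
            else:
                impairment = float(rng.uniform(0, 0.9))
            branches.append(
                OutcomeBranch(
                    f"b{j}",
                    float(probs[j]),
                    added_impairment=0.0 if is_death else impairment,
                    is_death=is_death,
                )
            )
        factors.append(RiskFactor(f"condition_{i}", tuple(branches)))
    return PatientProfile(id="random", risk_factors=tuple(factors), initial_utility=1.0)


def brute_force_outcomes(patient):
    """Independent recursive enumeration oracle: list of (probability,
    utility, any_death) tuples, one per joint branch combination."""
    factors = list(patient.risk_factors)
    results = []

    def recurse(i, prob, wellbeing, death):
        if i == len(factors):
            results.append((prob, 0.0 if death else wellbeing, death))
            return
        for b in factors[i].branches:
            recurse(
                i + 1,
                prob * b.probability,
                wellbeing * (1.0 - b.added_impairment),
                death or b.is_death,
            )

    recurse(0, 1.0, 1.0, False)
    return results


def aggregate_states(pairs, ndigits=9):
    """Collapse (probability, utility, death) tuples onto rounded
    (utility, death) states, for order-free comparison."""
    states = {}
    for p, u, d in pairs:
        key = (round(u, ndigits), bool(d))
        states[key] = states.get(key, 0.0) + p
    return {k: v for k, v in states.items() if v > 1e-15}


def assert_states_equal(a, b, tol=1e-9):
    sa, sb = aggregate_states(a), aggregate_states(b)
    assert set(sa) == set(sb)
    for key in sa:
        assert math.isclose(sa[key], sb[key], abs_tol=tol), (key, sa[key], sb[key])


def dist_states(dist):
    return list(zip(dist.probabilities, dist.utilities, dist.death))


def monte_carlo_states(patient, n_draws, seed):
    """Seeded sampling oracle: draws joint outcomes branch by branch and
    returns the empirical probability of every joint combination, in the same
    mixed-radix order the product enumeration uses."""
    rng = np.random.default_rng(seed)
    factors = list(patient.risk_factors)
    sizes = [len(f.branches) for f in factors]
    idx = np.zeros(n_draws, dtype=np.int64)
    for f, size in zip(factors, sizes):
        probs = np.array([b.probability for b in f.branches])
        draws = rng.choice(size, size=n_draws, p=probs / probs.sum())
        idx = idx * size + draws
    counts = np.bincount(idx, minlength=int(np.prod(sizes)))
    return counts / n_draws
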