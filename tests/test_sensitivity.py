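"""Tests of the sensitivity transforms: the two-regime impairment adjustment,
input perturbation, age-mortality elimination, and time-frame rescaling."""

import warnings

import numpy as np
import pytest

from comorben import (
    ConfigError,
    DomainError,
    OutcomeBranch,
    PatientProfile,
    RiskFactor,
    SensitivitySpec,
    adjust_impairment,
    comorbidity_effect_curve,
    drop_age_mortality,
    enumerate_joint_outcomes,
    perturb_inputs,
    rescale_timeframe,
    sensitivity_envelope,
)
from comorben.io import patient_to_dict, treatment_to_dict


GRID = np.linspace(0, 1, 201)


def _curve(patient):
    return comorbidity_effect_curve(enumerate_joint_outcomes(patient))


class TestAdjustImpairment:
    @pytest.mark.parametrize(
        "i, direction, factor, expected",
        [
            (0.40, "up", 0.5, 0.60),  # low-score regime: scale impairment
            (0.40, "down", 0.5, 0.20),
            (0.80, "down", 0.5, 0.70),  # high-score regime: scale utility
            (0.80, "up", 0.5, 0.90),
            (0.40, "down", 0.9, 0.04),  # deep reductions reuse the same regime
            (0.40, "down", 0.75, 0.10),
        ],
    )
    def test_examples(self, i, direction, factor, expected):
        assert adjust_impairment(i, direction, factor) == pytest.approx(expected)

    def test_continuous_at_half_by_both_formulas(self):
        # at i = 0.5 the impairment-side and utility-side formulas coincide
        for factor in (0.5, 0.75, 0.9):
            low_side = (1 + factor) * 0.5
            high_side = 1 - (1 - factor) * (1 - 0.5)
            assert low_side == pytest.approx(high_side)
            assert adjust_impairment(0.5, "up", factor) == pytest.approx(low_side)
            assert adjust_impairment(0.5, "down", factor) == pytest.approx(
                (1 - factor) * 0.5
            )

    @pytest.mark.parametrize("direction", ["up", "down"])
    @pytest.mark.parametrize("factor", [0.25, 0.5, 0.75, 0.9, 1.0])
    def test_continuity_bounds_and_order_on_grid(self, direction, factor):
        grid = np.linspace(0, 1, 2001)
        out = np.array([adjust_impairment(i, direction, factor) for i in grid])
        assert np.all((out >= 0) & (out <= 1))
        # continuity: no jump larger than the local slope allows
        assert np.max(np.abs(np.diff(out))) <= (1 + factor) * (grid[1] - grid[0]) + 1e-12
        # order preservation within each regime
        low = grid <= 0.5
        assert np.all(np.diff(out[low]) >= -1e-12)
        assert np.all(np.diff(out[~low]) >= -1e-12)

    def test_domain_errors(self):
        with pytest.raises(DomainError):
            adjust_impairment(1.2, "up", 0.5)
        with pytest.raises(DomainError):
            adjust_impairment(0.5, "sideways", 0.5)
        with pytest.raises(DomainError):
            adjust_impairment(0.5, "up", 1.5)


class TestSensitivitySpec:
    def test_progression_only_down(self):
        with pytest.raises(ConfigError):
            SensitivitySpec(targets={"progression"}, direction="up")

    def test_unknown_target(self):
        with pytest.raises(ConfigError):
            SensitivitySpec(targets={"weather"})

    def test_keys_are_stable(self):
        spec = SensitivitySpec(targets={"impairment"}, direction="down", factor=0.9)
        assert spec.key == "impairment_down_90"
        assert SensitivitySpec(horizon_years=3).key == "3y"


class TestPerturbInputs:
    def test_efficacy_up_fifty_percent(self, demo):
        patient, treatment = demo
        _, t2 = perturb_inputs(
            patient, treatment, SensitivitySpec(targets={"efficacy"}, direction="up")
        )
        assert t2.components[0].probability == pytest.approx(0.075)

    def test_event_probability_clamped_with_complement_zero(self):
        rf = RiskFactor(
            "x", (OutcomeBranch("event", 0.8, added_impairment=0.3), OutcomeBranch("none", 0.2))
        )
        patient = PatientProfile(id="p", risk_factors=(rf,))
        treatment_patient, _ = perturb_inputs(
            patient,
            _dummy_treatment(),
            SensitivitySpec(targets={"event_probability"}, direction="up"),
        )
        branches = treatment_patient.risk_factors[0].branches
        assert branches[0].probability == pytest.approx(1.0)  # 0.8 x 1.5 clamped
        assert branches[1].probability == pytest.approx(0.0)

    def test_factor_zero_is_identity(self, demo):
        patient, treatment = demo
        spec = SensitivitySpec(
            targets={"efficacy", "event_probability", "impairment"}, direction="up", factor=0.0
        )
        p2, t2 = perturb_inputs(patient, treatment, spec)
        assert patient_to_dict(p2) == patient_to_dict(patient)
        assert treatment_to_dict(t2) == treatment_to_dict(treatment)

    def test_purity_and_repeatability(self, demo):
        patient, treatment = demo
        before = patient_to_dict(patient), treatment_to_dict(treatment)
        spec = SensitivitySpec(targets={"impairment", "event_probability"}, direction="down")
        once = perturb_inputs(patient, treatment, spec)
        assert (patient_to_dict(patient), treatment_to_dict(treatment)) == before
        twice = perturb_inputs(patient, treatment, spec)
        assert patient_to_dict(once[0]) == patient_to_dict(twice[0])

    def test_impairment_perturbation_moves_curves_monotonically(self, demo):
        patient, treatment = demo
        base = _curve(patient)
        down, _ = perturb_inputs(
            patient, treatment, SensitivitySpec(targets={"impairment"}, direction="down")
        )
        up, _ = perturb_inputs(
            patient, treatment, SensitivitySpec(targets={"impairment"}, direction="up")
        )
        assert np.all(_curve(down).evaluate(GRID) >= base.evaluate(GRID) - 1e-12)
        assert np.all(_curve(up).evaluate(GRID) <= base.evaluate(GRID) + 1e-12)

    def test_progression_reduction_scales_only_impairment_events(self):
        rf = RiskFactor(
            "copd",
            (
                OutcomeBranch("death", 0.2, is_death=True),
                OutcomeBranch("progression", 0.3, added_impairment=0.4),
                OutcomeBranch("stable", 0.5),
            ),
        )
        patient = PatientProfile(id="p", risk_factors=(rf,))
        p2, _ = perturb_inputs(
            patient, _dummy_treatment(), SensitivitySpec(targets={"progression"}, direction="down")
        )
        by_label = {b.label: b.probability for b in p2.risk_factors[0].branches}
        assert by_label["death"] == pytest.approx(0.2)  # untouched
        assert by_label["progression"] == pytest.approx(0.15)
        assert by_label["stable"] == pytest.approx(0.65)

    def test_all_death_factor_has_no_complement(self):
        rf = RiskFactor("x", (OutcomeBranch("death", 1.0, is_death=True),))
        patient = PatientProfile(id="p", risk_factors=(rf,))
        with pytest.raises(ConfigError, match="no non-death branch"):
            perturb_inputs(
                patient,
                _dummy_treatment(),
                SensitivitySpec(targets={"event_probability"}, direction="down"),
            )


class TestDropAgeMortality:
    def _aged_patient(self):
        return PatientProfile(
            id="aged",
            risk_factors=(
                RiskFactor(
                    "age_mortality",
                    (OutcomeBranch("death", 0.6, is_death=True), OutcomeBranch("survives", 0.4)),
                ),
                RiskFactor(
                    "fracture",
                    (OutcomeBranch("hip", 0.2, added_impairment=0.2), OutcomeBranch("none", 0.8)),
                ),
            ),
        )

    def test_removal_lifts_curve_toward_its_ceiling(self):
        patient = self._aged_patient()
        dropped = drop_age_mortality(patient)
        base, lifted = _curve(patient), _curve(dropped)
        assert np.all(lifted.evaluate(GRID) >= base.evaluate(GRID) - 1e-12)
        assert lifted.intercept == pytest.approx(1.0)

    def test_noop_with_warning_when_absent(self, demo):
        patient, _ = demo
        with pytest.warns(UserWarning, match="no-op"):
            unchanged = drop_age_mortality(patient)
        assert patient_to_dict(unchanged) == patient_to_dict(patient)

    def test_idempotent(self):
        patient = self._aged_patient()
        once = drop_age_mortality(patient)
        with pytest.warns(UserWarning):
            twice = drop_age_mortality(once)
        assert patient_to_dict(once) == patient_to_dict(twice)


class TestRescaleTimeframe:
    def test_identity_at_full_horizon(self, demo):
        patient, treatment = demo
        p2, t2 = rescale_timeframe(patient, treatment, 5.0)
        assert patient_to_dict(p2) == patient_to_dict(patient)
        assert treatment_to_dict(t2) == treatment_to_dict(treatment)

    def test_linear_rule(self, demo):
        patient, treatment = demo
        p2, t2 = rescale_timeframe(patient, treatment, 1.0)
        cancer = {b.label: b.probability for b in p2.risk_factors[0].branches}
        assert cancer["death from cancer"] == pytest.approx(0.1)  # 0.5 x 1/5
        assert cancer["alive with cancer"] == pytest.approx(0.9)
        assert t2.components[0].probability == pytest.approx(0.01)
        assert p2.horizon_years == 1.0

    @pytest.mark.parametrize("method", ["linear", "exponential"])
    def test_composition_consistency(self, demo, method):
        patient, treatment = demo
        via = rescale_timeframe(*rescale_timeframe(patient, treatment, 2.0, method), 1.0, method)
        direct = rescale_timeframe(patient, treatment, 1.0, method)
        assert _profiles_close(via[0], direct[0])
        assert via[1].components[0].probability == pytest.approx(
            direct[1].components[0].probability
        )

    def test_curve_non_increasing_in_horizon(self, demo):
        """More time means more opportunity to accumulate impairment: at any
        threshold the comorbidity-effect curve falls as years increase."""
        patient, treatment = demo
        previous = None
        for years in (1, 2, 3, 4, 5):
            p2, _ = rescale_timeframe(patient, treatment, float(years))
            values = _curve(p2).evaluate(GRID)
            if previous is not None:
                assert np.all(values <= previous + 1e-12)
            previous = values

    def test_out_of_range_years(self, demo):
        patient, treatment = demo
        for years in (0.0, -1.0, 6.0):
            with pytest.raises(DomainError):
                rescale_timeframe(patient, treatment, years)


def _profiles_close(a, b, tol=1e-12):
    da, db = patient_to_dict(a), patient_to_dict(b)
    for rfa, rfb in zip(da["risk_factors"], db["risk_factors"]):
        for ba, bb in zip(rfa["branches"], rfb["branches"]):
            if abs(ba["probability"] - bb["probability"]) > tol:
                return False
            if abs(ba["added_impairment"] - bb["added_impairment"]) > tol:
                return False
    return True


def _dummy_treatment():
    from comorben import EfficacyComponent, Treatment

    return Treatment("t", (EfficacyComponent("c", 0.05, 0.25),))


class TestSensitivityEnvelope:
    def test_empty_specs_gives_baseline_only(self, demo):
        patient, treatment = demo
        env = sensitivity_envelope(patient, treatment, [])
        assert list(env) == ["baseline"]

    def test_efficacy_up_scales_relative_curve(self, demo):
        patient, treatment = demo
        env = sensitivity_envelope(
            patient, treatment, [SensitivitySpec(targets={"efficacy"}, direction="up")]
        )
        base = env["baseline"]
        up = env["efficacy_up_50"]
        grid = GRID[GRID > 0]
        assert np.allclose(up.evaluate(grid), 1.5 * base.evaluate(grid))

    def test_deep_impairment_reduction_dominates_baseline(self, demo):
        patient, treatment = demo
        env = sensitivity_envelope(
            patient,
            treatment,
            [SensitivitySpec(targets={"impairment"}, direction="down", factor=0.9)],
        )
        assert np.all(
            env["impairment_down_90"].evaluate(GRID) >= env["baseline"].evaluate(GRID) - 1e-12
        )
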