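"""Reading and writing the YAML/JSON config dialect and CSV/JSON outputs.

Patients and treatments are plain mappings::

    id: demo
    age_years: 75
    horizon_years: 5
    initial_utility: 1.0
    risk_factors:
      - name: lung_cancer
        branches:
          - {label: death, probability: 0.5, is_death: true}
          - {label: alive with cancer, probability: 0.5, added_impairment: 0.4}

    name: statin
    components:
      - {label: prevented non-fatal MI, probability: 0.05, baseline_benefit: 0.25}

Unknown keys are warnings (forward compatibility), schema violations raise a
single error listing every failure with its key path, and malformed files
raise a parse error carrying the YAML line/column context.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import pandas as pd
import yaml

from .model import (
    DomainError,
    EfficacyComponent,
    OutcomeBranch,
    PatientProfile,
    RiskFactor,
    Treatment,
)
from .enumeration import StepCurve, UtilityDistribution
from .benefit import PatientAnalysis
from .sensitivity import SensitivitySpec

__all__ = [
    "ParseError",
    "SchemaError",
    "read_patient",
    "read_treatment",
    "write_patient",
    "write_treatment",
    "patient_to_dict",
    "patient_from_dict",
    "treatment_to_dict",
    "treatment_from_dict",
    "curve_to_csv",
    "curve_from_csv",
    "distribution_to_csv",
    "envelope_to_csv",
    "read_sensitivity_specs",
    "build_report",
    "write_report",
]


class ParseError(ValueError):
    """The file is not well-formed YAML/JSON."""


class SchemaError(ValueError):
    """The file parsed but does not conform to the published schema."""


def _load_mapping(path) -> dict:
    path = Path(path)
    try:
        data = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if not isinstance(data, dict):
        raise SchemaError(f"{path}: top level must be a mapping, got {type(data).__name__}")
    return data


def _dump(data, path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))


class _Collector:
    """Accumulates schema failures so one read reports all of them."""

    def __init__(self, source: str):
        self.source = source
        self.errors: list[str] = []

    def fail(self, path: str, message: str) -> None:
        self.errors.append(f"{path}: {message}")

    def number(self, mapping: dict, key: str, path: str, default=None, required=False):
        if key not in mapping:
            if required:
                self.fail(path, f"missing required key {key!r}")
            return default
        value = mapping[key]
        if isinstance(value, bool) or not isinstance(value, (int, float)):
            self.fail(f"{path}.{key}", f"expected a number, got {value!r}")
            return default
        return float(value)

    def finish(self) -> None:
        if self.errors:
            raise SchemaError(
                f"{self.source}: schema violations:\n  " + "\n  ".join(self.errors)
            )


def _warn_unknown(mapping: dict, known: set[str], path: str, source: str) -> None:
    for key in mapping:
        if key not in known:
            warnings.warn(f"{source}: unknown key {path}.{key!r} ignored", stacklevel=3)


# ---------------------------------------------------------------------------
# patients


def patient_from_dict(data: dict, source: str = "<dict>") -> PatientProfile:
    col = _Collector(source)
    _warn_unknown(
        data, {"id", "age_years", "horizon_years", "initial_utility", "risk_factors"},
        "patient", source,
    )
    pid = data.get("id")
    if not isinstance(pid, str) or not pid:
        col.fail("patient.id", f"required non-empty string, got {pid!r}")
    factors = []
    raw_factors = data.get("risk_factors", [])
    if not isinstance(raw_factors, list):
        col.fail("patient.risk_factors", "must be a list")
        raw_factors = []
    for i, rf in enumerate(raw_factors):
        fpath = f"patient.risk_factors[{i}]"
        if not isinstance(rf, dict):
            col.fail(fpath, "must be a mapping")
            continue
        _warn_unknown(rf, {"name", "branches"}, fpath, source)
        name = rf.get("name")
        if not isinstance(name, str) or not name:
            col.fail(f"{fpath}.name", f"required non-empty string, got {name!r}")
            name = f"factor_{i}"
        branches = []
        raw_branches = rf.get("branches", [])
        if not isinstance(raw_branches, list) or not raw_branches:
            col.fail(f"{fpath}.branches", "must be a non-empty list")
            raw_branches = []
        for j, br in enumerate(raw_branches):
            bpath = f"{fpath}.branches[{j}]"
            if not isinstance(br, dict):
                col.fail(bpath, "must be a mapping")
                continue
            _warn_unknown(
                br, {"label", "probability", "added_impairment", "is_death"}, bpath, source
            )
            prob = col.number(br, "probability", bpath, required=True)
            imp = col.number(br, "added_impairment", bpath, default=0.0)
            try:
                branches.append(
                    OutcomeBranch(
                        str(br.get("label", f"branch_{j}")),
                        prob if prob is not None else 0.0,
                        imp if imp is not None else 0.0,
                        bool(br.get("is_death", False)),
                    )
                )
            except DomainError as exc:
                col.fail(bpath, str(exc))
        if branches:
            factors.append(RiskFactor(name, tuple(branches)))
    horizon = col.number(data, "horizon_years", "patient", default=5.0)
    age = col.number(data, "age_years", "patient")
    initial_utility = col.number(data, "initial_utility", "patient")
    col.finish()
    try:
        return PatientProfile(
            id=pid,
            age_years=age,
            horizon_years=horizon,
            risk_factors=tuple(factors),
            initial_utility=initial_utility,
        )
    except DomainError as exc:
        raise SchemaError(f"{source}: {exc}") from exc


def patient_to_dict(patient: PatientProfile) -> dict:
    data = {
        "id": patient.id,
        "age_years": patient.age_years,
        "horizon_years": patient.horizon_years,
        "initial_utility": patient.initial_utility,
        "risk_factors": [
            {
                "name": rf.name,
                "branches": [
                    {
                        "label": b.label,
                        "probability": b.probability,
                        "added_impairment": b.added_impairment,
                        "is_death": b.is_death,
                    }
                    for b in rf.branches
                ],
            }
            for rf in patient.risk_factors
        ],
    }
    return {k: v for k, v in data.items() if v is not None}


def read_patient(path) -> PatientProfile:
    return patient_from_dict(_load_mapping(path), source=str(path))


def write_patient(patient: PatientProfile, path) -> None:
    _dump(patient_to_dict(patient), path)


# ---------------------------------------------------------------------------
# treatments


def treatment_from_dict(data: dict, source: str = "<dict>") -> Treatment:
    col = _Collector(source)
    _warn_unknown(data, {"name", "components"}, "treatment", source)
    name = data.get("name")
    if not isinstance(name, str) or not name:
        col.fail("treatment.name", f"required non-empty string, got {name!r}")
        name = "treatment"
    comps = []
    raw = data.get("components", [])
    if not isinstance(raw, list) or not raw:
        col.fail("treatment.components", "must be a non-empty list")
        raw = []
    for i, c in enumerate(raw):
        cpath = f"treatment.components[{i}]"
        if not isinstance(c, dict):
            col.fail(cpath, "must be a mapping")
            continue
        _warn_unknown(c, {"label", "probability", "baseline_benefit"}, cpath, source)
        prob = col.number(c, "probability", cpath, required=True)
        benefit = col.number(c, "baseline_benefit", cpath, required=True)
        if prob is None or benefit is None:
            continue
        try:
            comps.append(EfficacyComponent(str(c.get("label", f"component_{i}")), prob, benefit))
        except DomainError as exc:
            col.fail(cpath, str(exc))
    col.finish()
    try:
        return Treatment(name, tuple(comps))
    except (DomainError, ValueError) as exc:
        raise SchemaError(f"{source}: {exc}") from exc


def treatment_to_dict(treatment: Treatment) -> dict:
    return {
        "name": treatment.name,
        "components": [
            {
                "label": c.label,
                "probability": c.probability,
                "baseline_benefit": c.baseline_benefit,
            }
            for c in treatment.components
        ],
    }


def read_treatment(path) -> Treatment:
    return treatment_from_dict(_load_mapping(path), source=str(path))


def write_treatment(treatment: Treatment, path) -> None:
    _dump(treatment_to_dict(treatment), path)


# ---------------------------------------------------------------------------
# sensitivity specs


def read_sensitivity_specs(path) -> list[SensitivitySpec]:
    """Read a list of scenarios from ``{specs: [{targets, direction, factor,
    horizon_years}, ...]}`` (or a bare top-level list)."""
    p = Path(path)
    try:
        data = yaml.safe_load(p.read_text())
    except yaml.YAMLError as exc:
        raise ParseError(f"{p}: {exc}") from exc
    if isinstance(data, dict):
        data = data.get("specs", [])
    if not isinstance(data, list):
        raise SchemaError(f"{p}: expected a list of sensitivity specs")
    specs = []
    for i, item in enumerate(data):
        if not isinstance(item, dict):
            raise SchemaError(f"{p}: specs[{i}] must be a mapping")
        _warn_unknown(item, {"targets", "direction", "factor", "horizon_years"},
                      f"specs[{i}]", str(p))
        specs.append(
            SensitivitySpec(
                targets=frozenset(item.get("targets", [])),
                direction=item.get("direction", "down"),
                factor=item.get("factor", 0.5),
                horizon_years=item.get("horizon_years"),
            )
        )
    return specs


# ---------------------------------------------------------------------------
# CSV exports


def curve_to_csv(curve: StepCurve, path) -> None:
    """Two-column export (threshold, probability); the first row is the
    threshold-0 value."""
    thresholds, values = curve.to_arrays()
    pd.DataFrame({"threshold": thresholds, "probability": values}).to_csv(path, index=False)


def curve_from_csv(path) -> StepCurve:
    frame = pd.read_csv(path)
    thresholds = frame["threshold"].to_numpy(dtype=float)
    values = frame["probability"].to_numpy(dtype=float)
    if thresholds.size == 0:
        raise SchemaError(f"{path}: empty curve")
    if thresholds[0] == 0.0:
        return StepCurve(thresholds[1:], values[1:], at_zero=float(values[0]))
    return StepCurve(thresholds, values, at_zero=float(values[0]))


def distribution_to_csv(dist: UtilityDistribution, path) -> None:
    prov = dist.provenance or [()] * len(dist)
    pd.DataFrame(
        {
            "probability": dist.probabilities,
            "utility": dist.utilities,
            "is_death": dist.death,
            "provenance": [" | ".join(p) for p in prov],
        }
    ).to_csv(path, index=False)


def envelope_to_csv(envelope: dict[str, StepCurve], path) -> None:
    """Long-format export (spec_key, threshold, probability) of a keyed set of
    curves, one block per scenario."""
    rows = []
    for key, curve in envelope.items():
        thresholds, values = curve.to_arrays()
        for t, v in zip(thresholds, values):
            rows.append({"spec_key": key, "threshold": t, "probability": v})
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# combined report


def _curve_dict(curve: StepCurve) -> dict:
    thresholds, values = curve.to_arrays()
    return {
        "thresholds": [float(t) for t in thresholds],
        "probabilities": [float(v) for v in values],
        "intercept": curve.intercept,
    }


def build_report(analysis: PatientAnalysis) -> dict:
    """JSON-ready per-patient report: the merged utility distribution, the
    three curves, and all available point estimates."""
    dist = analysis.distribution
    return {
        "patient": patient_to_dict(analysis.patient),
        "treatment": treatment_to_dict(analysis.treatment),
        "probability_alive": analysis.probability_alive,
        "distribution": [
            {"probability": float(p), "utility": float(u), "is_death": bool(d)}
            for p, u, d in zip(dist.probabilities, dist.utilities, dist.death)
        ],
        "benefit_atoms": [
            {"probability": a.probability, "benefit": a.benefit, "source": a.source}
            for a in analysis.benefit_atoms
        ],
        "curves": {
            "comorbidity_effect": _curve_dict(analysis.comorbidity_curve),
            "relative_benefit": _curve_dict(analysis.relative_curve),
            "absolute_benefit": _curve_dict(analysis.absolute_curve),
        },
        "point_estimates": {
            mode: {"probability": pe.probability, "magnitude": pe.magnitude}
            for mode, pe in analysis.point_estimates.items()
        },
        "notes": list(analysis.notes),
    }


def write_report(analysis: PatientAnalysis, path) -> None:
    Path(path).write_text(json.dumps(build_report(analysis), indent=2) + "\n")
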