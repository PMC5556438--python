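"""Stress-test the demonstration conclusions: +/-50% efficacy, deep
impairment reductions, and a shortened time frame, overlaid as an envelope of
relative-benefit curves.
"""

from comorben import SensitivitySpec, demonstration_case, sensitivity_envelope

patient, treatment = demonstration_case()
specs = [
    SensitivitySpec(targets={"efficacy"}, direction="up", factor=0.5),
    SensitivitySpec(targets={"efficacy"}, direction="down", factor=0.5),
    SensitivitySpec(targets={"impairment"}, direction="down", factor=0.9),
    SensitivitySpec(targets={"event_probability"}, direction="up", factor=0.5),
    SensitivitySpec(horizon_years=1.0),
]

envelope = sensitivity_envelope(patient, treatment, specs, curve="relative")
print(f"{'scenario':30s} {'P(any benefit)':>15s} {'P(>=50% of baseline)':>22s}")
for key, curve in envelope.items():
    print(f"{key:30s} {100 * curve.intercept:14.2f}% {100 * curve.evaluate(0.5):21.2f}%")
print()
print("Reading: each row is one perturbed re-analysis. Only large input "
      "changes (90% impairment reduction, +50% efficacy) move the curves "
      "much, so the conclusion — low probability of large benefit — is robust.")
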