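"""Scenario analysis: compounded annual changes to incidence or detection.

Re-runs the projection with a probability multiplied by (1 + r)^(t - 2007)
and reports final-year differences against the baseline.
"""

from ckdproj import ScenarioSpec, load_configuration, run_sensitivity

config = load_configuration()
params = config.model_parameters()

prevention = ScenarioSpec(incidence_change={("non", "1-2"): -0.01})
screening = ScenarioSpec(detection_change={"1-2": 0.01})

for name, scenario in (("1%/yr fewer stage 1-2 onsets", prevention),
                       ("1%/yr better stage 1-2 detection", screening)):
    d = run_sensitivity(params, scenario)
    print(f"{name}:")
    print(f"  2035 CKD cases vs baseline: {d['delta_total_ckd']:+,.0f}")
    print(f"  2035 undetected cases vs baseline: {d['delta_undetected']:+,.0f}")
# Primary prevention removes cases outright; better detection leaves the
# case total essentially unchanged but moves people from the undetected to
# the detected compartments, where treatment can slow progression.
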