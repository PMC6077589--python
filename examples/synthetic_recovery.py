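"""Validate the estimators by parameter recovery on a synthetic registry.

Generates registry-like observations (coverage-thinned prevalent and
incident counts with binomial/Poisson noise) from known ground truth, runs
the full estimation pipeline — coverage, mortality, transition and
detection probabilities — and reports the relative errors.
"""

from ckdproj import (
    GroundTruth,
    generate_national_series,
    generate_registry_observations,
    parameter_recovery_report,
    recover_parameters,
    simulate_truth,
)

truth = GroundTruth(seed=7).with_ratio_consistent_detection()
trajectory = simulate_truth(truth)
national = generate_national_series(truth, trajectory)
observations = generate_registry_observations(truth, trajectory)

estimates = recover_parameters(national, observations)
report = parameter_recovery_report(truth, estimates)
print(report.to_string(index=False, float_format=lambda x: f"{x:.4f}"))
print(f"\nmax relative error: {report['relative_error'].max():.2%}")
# With a million-person population and realistic registry coverage the
# transition and detection probabilities come back within a few percent;
# rerun with noise disabled (generate_registry_observations(..., noise=False))
# and the inversion is exact to machine precision.
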