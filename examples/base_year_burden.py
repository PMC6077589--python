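"""Calibrate the 2007 base year from the packaged printed inputs.

Builds the starting state vector — survey prevalences with the albuminuria
persistence adjustment for stages 1-2, registry-coverage-derived counts for
stages 4-5, detected/undetected splits from the undiagnosed fractions —
and prints the burden metrics it implies.
"""

from ckdproj import load_configuration, run_model, summarize

config = load_configuration()
result = run_model(config.model_parameters())
s = summarize(result, 2007)

print(f"2007 CKD cases by stage: "
      f"1-2: {s['stage12_count']:,.0f}  3: {s['stage3_count']:,.0f}  "
      f"4: {s['stage4_count']:,.0f}  5: {s['stage5_count']:,.0f}")
print(f"total CKD {s['total_ckd']:,.0f}  prevalence {s['prevalence_pct']}%")
print(f"undiagnosed prevalence {s['undiag_prevalence_pct']}% "
      f"(stages 1-2: {s['stage12_undiag_prevalence_pct']}%)")
print(f"proportion of CKD undiagnosed {s['proportion_undiagnosed_pct']}%, "
      f"detection rate {s['detection_rate_pct']}%")
print(f"stage shares of CKD: stage 4 {s['stage4_share_pct']}%, "
      f"stage 5 {s['stage5_share_pct']}%")
# The prevalence line says roughly one in eight adults has CKD in the base
# year; the undiagnosed lines show that nearly three-quarters of them do
# not know it, mostly in the early stages.
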