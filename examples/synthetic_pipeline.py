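"""Full synthetic end-to-end run: generate, estimate, project, staff.

Generates every input the pipeline needs from a seeded configuration
(facility panel, baseline, population, norms, roster), estimates transition
probabilities from the panel, and runs them through the projection and
staffing stages.  Because the panel was generated from known truth, the
estimated-pipeline output should track the true-pipeline output closely —
the parameter-recovery loop that validates the whole chain.
"""
import hwforecast as hw

cfg = hw.GeneratorConfig(seed=11, years=5)
census, tp_true = hw.make_ghana_fixture()
norms = hw.synth_norms(cfg)

panel = hw.simulate_panel(cfg)
tp_hat, est = hw.estimate_transitions(panel)

req_hat = hw.compute_requirements(hw.project(census, tp_hat, horizon=10), norms)
req_true = hw.compute_requirements(hw.project(census, tp_true, horizon=10), norms)

print("national requirement in 2026, estimated vs true transition table:")
for staff in ("Registered general nurse", "Midwife", "Pharmacist"):
    a = req_hat.national_value(staff, 2026)
    b = req_true.national_value(staff, 2026)
    print(f"  {staff:28s} {a:10.0f} vs {b:10.0f}  ({100 * (a / b - 1):+.1f}%)")
print("differences reflect only estimation noise in the panel.")
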