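"""Estimate transition probabilities from a simulated facility panel.

Simulates a five-year facility-category panel in which each facility moves
one rung up the workload ladder each year with its true probability, then
re-estimates those probabilities with the pooled binomial estimator.  The
printed table shows the estimate, its binomial standard error and the
denominators; every estimate should sit within a couple of standard errors
of the truth it was generated from.
"""
import hwforecast as hw
from hwforecast.estimation import estimates_to_frame

cfg = hw.GeneratorConfig(seed=7, years=5)
panel = hw.simulate_panel(cfg)
print(f"panel: {panel.n_facilities} facilities x {len(panel.years)} years")

tp_hat, estimates = hw.estimate_transitions(panel)
table = estimates_to_frame(estimates)
table["truth"] = cfg.tp_true.p
print(table.to_string(index=False))
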