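"""Predictive intervals for workforce requirements.

Shifts all ten transition probabilities simultaneously to their lower and
upper 95% confidence limits, re-runs the whole pipeline under each limit
scenario, and reports per-cell min/max bounds around the base forecast.
Widths grow with the forecast year because parameter uncertainty compounds
through the annual cycles.
"""
import hwforecast as hw

census, tp = hw.make_ghana_fixture()
norms = hw.synth_norms(hw.GeneratorConfig(seed=0))

req = hw.predictive_interval(census, tp, norms=norms, horizon=10)
nat = req.national()
one = nat[nat.staff_type == "Midwife"].round(0).astype({"year": int})
print("Midwife national requirement with 95% predictive bounds:")
print(one.to_string(index=False))
width = one["upper"] - one["lower"]
print(f"\ninterval width grows from {width.iloc[1]:.0f} (year 2) "
      f"to {width.iloc[-1]:.0f} (year 11) as uncertainty compounds")
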