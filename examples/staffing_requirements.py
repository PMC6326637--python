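"""Translate a projected census into workforce requirements and SAR.

Projects the published 2016 baseline forward, applies a synthetic staffing
norms matrix (23 cadres; the real Ministry norms are not public), and prints
the national requirement per cadre and year, then compares a synthetic
employment roster against the 2016 requirement: the staff-availability
ratio (SAR) is employed / required, and 1 - SAR is the shortfall.
"""
import hwforecast as hw
from hwforecast.io import render_requirements_national

census, tp = hw.make_ghana_fixture()
cfg = hw.GeneratorConfig(seed=0)
norms = hw.synth_norms(cfg)

proj = hw.project(census, tp, horizon=10)
req = hw.compute_requirements(proj, norms)
print("National requirements per cadre (synthetic norms, rounded):")
print(render_requirements_national(req).iloc[:, :6].to_string())

roster = hw.synth_roster(cfg, req, year=2016)
print("\nStaff-availability ratios, 2016:")
print(hw.sar_report(roster, req, 2016).round(3).to_string(index=False))
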