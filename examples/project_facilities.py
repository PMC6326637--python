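"""Project the national facility census ten years forward.

Starts from the published 2016 national baseline and the published annual
transition probabilities, runs the Markov cohort projection with no
construction, and prints the national census table (half-up integers) plus
the modelled per-pair transition flows.  Each column is a year; rising
counts in the middle of the ladder reflect facilities upgrading as their
workload grows.
"""
import hwforecast as hw
from hwforecast.io import render_census_national, render_flows

census, tp = hw.make_ghana_fixture()
proj = hw.project(census, tp, horizon=10)

print("National facility census (expected counts, rounded):")
print(render_census_national(proj).to_string())

print("\nModelled upward transitions per pair and year (facilities):")
print(render_flows(hw.transition_flows(proj, tp)).to_string())
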