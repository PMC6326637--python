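# hwforecast

Facility-capacity and health-workforce demand forecasting for facility-based
(staffing-norms) planning, modelled on Ghana's public-sector system.

Health ministries that allocate staff by facility type face two linked
questions: how many facilities of each type will exist over the next decade,
and how many staff of each cadre those facilities will require. `hwforecast`
answers both with a two-level pipeline:

1. **Facility projection.** Public facilities sit on an ordered 11-level
   workload ladder (CHPS compound < health centre A/B < polyclinic < primary
   hospital A–D < regional hospital < emerging < established teaching
   hospital). Growing utilisation moves a facility one rung up; downgrades
   and closures are assumed away. A discrete-time Markov cohort model with a
   one-year cycle propagates expected counts: for a non-bottom category $c$
   with successor $c'$ in region $i$,

   $$N_{c,i,j} = N_{c,i,j-1}\,(1 - p_{c \to c'}) + N_{c^-,i,j-1}\,p_{c^- \to c} + \text{new}_{c,i,j},$$

   where $c^-$ is the predecessor category, $p$ are annual transition
   probabilities, and $\text{new}$ is the construction schedule. The top
   category absorbs (no outflow). The bottom tier (CHPS) can instead be
   demarcated from population, one zone per 1500 people:
   $\text{CHPS}_{i,j} = \text{Population}_{i,j} / 1500$.

2. **Staffing translation.** A staffing-norms matrix $SS_{k,c}$ (required
   headcount of cadre $k$ per facility of category $c$) converts each
   region-year census into a requirement
   $HWF_{k,i,j} = \sum_c N_{c,i,j}\, SS_{k,c}$, optionally adjusted for
   sub-threshold workload changes by a piecewise ladder (±23.5% / 14.3% /
   6.3% / 0 for workload shifts ≥15%, 10–15%, 5–10%, <5%). The
   staff-availability ratio (SAR) is employed headcount divided by the
   modelled requirement.

Transition probabilities are estimated from a longitudinal facility-category
panel by a pooled binomial MLE with binomial standard errors, and parameter
uncertainty is propagated into 95% predictive intervals by re-running the
whole pipeline with all probabilities shifted simultaneously to their lower
and upper confidence limits (plus an optional seeded Monte-Carlo mode).

A seeded synthetic-data module generates every input — facility panels with
adjacent-upward Bernoulli dynamics, the published national 2016 baseline and
transition table, a fictional 23-cadre norms matrix, population series,
construction schedules and employment rosters — so the whole pipeline is
testable without any private data.

## Worked example

```python
import hwforecast as hw
from hwforecast.io import render_census_national

census, tp = hw.make_ghana_fixture()   # published 2016 baseline + probabilities
proj = hw.project(census, tp, horizon=10)
print(render_census_national(proj))
```

The first columns of the printed table:

```
category                 2016  2017  2018  2019  2020
CHPS                     4449  4405  4360  4317  4274
HCA                       903   918   931   944   956
HCB                       158   183   209   233   258
PolyC                      40    43    46    50    54
PHA                        96    82    70    60    52
PHB                        49    59    65    68    69
...
Total facilities         5749  5751  5749  5748  5747
```

Each cell is the expected number of facilities in that category (rounded for
display). Health-centre-B counts grow (inflow from the 903 HCA stock at
p=0.033 outweighs outflow at p=0.028) while primary-hospital-A counts shrink
(heavy outflow at p=0.167): expansion hollows out the lower-middle rungs.
With zero construction the unrounded total is conserved exactly; the ±1–2
wobble in the printed total row is display rounding.

Continuing with staffing and intervals:

```python
norms = hw.synth_norms(hw.GeneratorConfig(seed=0))  # fictional norms matrix
req = hw.predictive_interval(census, tp, norms=norms, horizon=10)
print(req.national(staff_type="Midwife"))
```

yields the national midwife requirement per year with bounds, e.g. 10 275
(10 265–10 284) in 2017 growing to 11 028 (10 925–11 132) in 2026 — interval
widths compound from ±10 to ±100 as transition-probability uncertainty
propagates through ten annual cycles.

There is a thin CLI over the same functions (`hwforecast estimate | project |
staff | intervals | simulate | report`); `examples/` contains one short
narrative script per capability, and `fixtures/` holds the published baseline
and transition-probability CSVs.

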