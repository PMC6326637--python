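# Methods

## Model

The pipeline is a deterministic discrete-time Markov **cohort** model over an
ordered 11-category facility ladder, run with a one-year cycle over a
ten-year horizon (annual planning cycles make half-cycle correction
inapplicable). The state is the real-valued expected count of facilities per
(region, category); individual facilities are not tracked in the
deterministic engine. Structural assumptions, enforced in code rather than
checked at run time:

- the only transition from rank *r* is to rank *r + 1*; no downgrades, no
  closures; the top rung (established teaching hospital) absorbs;
- newly constructed facilities enter the end-of-year census and first
  transition in the following cycle (construction is added after the
  transition update);
- regions are independent: the update is applied per region and national
  figures are sums over regions. The update is linear, so partitioning a
  baseline across regions leaves national totals unchanged — a property the
  tests exploit as an oracle.

**CHPS stock rule.** The bottom tier has two modes. In *markov* mode CHPS
follows the same outflow-plus-construction bookkeeping as every other
category. In *population* mode the CHPS stock for each projected year is set
exogenously to population / 1500 (the national demarcation policy), while
its outflow into health-centre-A is still computed from the current stock.
Both modes are exposed because the published national CHPS trajectory cannot
be reconciled with either rule alone: the printed series grows ~320/year
early on, which is far below any plausible population/1500 level (~28M/1500
≈ 18 700) and has the opposite sign from pure Markov depletion. The
population series and demarcation pace actually used upstream are not
recoverable, so the engine takes them as inputs. For the same reason the
published regional-hospital row (constant at 7 despite a net modelled
outflow of ~0.3/year) implies small unpublished construction entries; the
acceptance checks therefore cover only one-cycle values for categories whose
update involves no construction, plus the baseline-year flows.

**Reported precision.** All arithmetic is on unrounded reals; report
renderers round half-up — integers for census and requirement tables, one
decimal for flow tables — matching the conventions of the source tables.
Two baseline-year flow cells (CHPS→HCA, HCA→HCB) are *not* reproducible from
the three-decimal published probabilities (they imply unpublished extra
digits); they are excluded from the checks and documented here rather than
approximated.

## Transition-probability estimation

The estimator is a pooled binomial MLE over all observed consecutive-year
intervals: facility-years in category *r* with a next-year observation are
at risk; those observed in *r + 1* the next year are events;
p̂ = events / at-risk with SE = sqrt(p̂(1 − p̂)/n). Pooling is across regions
and years; the upstream analysis specifies neither its pooling nor its SE
formula, and the binomial choice is adopted here because the published SE
magnitudes are consistent with binomial scaling at plausible denominators.
Facilities missing a year are censored for the affected intervals (no
interpolation). Intervals that violate the ladder (downward moves, jumps of
more than one rung) are rejected by default; a policy flag can drop them or
count any upward jump as a single one-rung event. Pairs with no at-risk
facility-years return p̂ = 0, SE = 0 with a `sparse` flag rather than NaN.

## Staffing translation

Base requirements are the dot product of the region-year census vector with
the cadre's norms vector. The workload-change adjustment is applied per
(region, category) cell before summing over categories — the printed
formula's summation is ambiguous between categories and facilities, and the
per-cell reading is adopted (and flagged as a choice, not an assertion of
upstream intent). Ladder boundaries: the printed intervals leave exactly 10%
ambiguous between the 6.3% and 14.3% rules; 10% maps to 6.3% ("5% up to 10%"
read as inclusive), a single documented constant. A workload shift at or
beyond 15% additionally triggers a `WorkloadReviewWarning`, since the norms
require a facility reassessment there, which is outside the model. The SAR
report includes a requirement-weighted aggregate row; shortfall is floored
at zero for cadres in surplus.

## Predictive intervals

Parameter uncertainty is dominated by the transition probabilities. The
default propagation shifts all ten probabilities simultaneously by ±1.96 SE
(clamped to [0, 1]), re-runs the entire pipeline under each limit scenario,
and takes per-cell min/max over {lower, base, upper} runs. Min/max — rather
than mapping the lower scenario to the lower bound — is deliberate: faster
upgrading raises high-category counts while draining low ones, so neither
limit scenario is one-sidedly extreme for every output cell; min/max
guarantees lower ≤ base ≤ upper by construction, which the published
interval table exhibits for every printed cell. Whether the upstream bounds
were built this way is not recoverable; this is the package's own rule. z is
configurable (1.96 default). A seeded Monte-Carlo mode (per-pair normal
truncated to [0, 1], empirical quantiles, intervals clipped to include the
base value) is provided as a clearly optional extension.

## Synthetic data

The generator emulates the study-shaped conditions: a five-year national
facility panel (adjacent-upward Bernoulli moves at the published
probabilities, top rung absorbing, optional per-record censoring), the
published 2016 baseline (5749 facilities) and probability table as fixture,
ten regions, population ~28M growing at 2.2%/year split across regions by a
seeded Dirichlet, and a roster drawn to hit a 68% aggregate
staff-availability target with ±30% per-cadre jitter. The 23-cadre norms
matrix is deterministic, monotone non-decreasing in facility rank, and
**explicitly fictional** — the real Ministry of Health norms are not public,
so no output of this package reproduces the published requirement or
interval tables; those are covered by shape and bracketing properties only.
What passing tests show: the cohort engine equals the microsimulation in
expectation, the estimator recovers known truth with nominal coverage, and
the translation obeys its algebraic identities. What they cannot show:
fidelity to the unpublished norms values, real reporting artefacts beyond
random missingness, or facility behaviour that violates the
no-downgrade/one-rung assumptions.

## Numerical choices and problem sizes

- Internal state float64 throughout; conservation (zero construction,
  markov mode) is asserted at 1e−9 relative.
- Half-up rounding via decimal on the shortest float repr, so printed-table
  comparisons are not disturbed by binary representation.
- Bound sanity (lower ≤ required ≤ upper) tolerates 1e−9 absolute slack.
- Test problem sizes are chosen for tight-but-fast checks: the
  microsimulation oracle uses 2000 facilities per category × 15–20
  replicates against a ±3 Monte-Carlo-SE band (with a 0.75-facility floor
  for near-degenerate cells); estimator coverage uses 200 replicate
  five-year panels at 1200 facilities per category over the five
  well-populated pairs, asserting coverage in [0.92, 0.985] (Wald intervals
  genuinely undercover when expected events are in the single digits, so
  sparse top-of-ladder pairs are exercised in the point-recovery test
  instead).

## Known limitations

- No structural uncertainty (alternative ladder topologies), no uncertainty
  on norms or construction, no geospatial siting, no supply-side (training/
  attrition) modelling.
- The published multi-year census trajectory is not reproduced beyond one
  cycle, for the documented reasons above (unpublished CHPS demarcation pace
  and construction entries), and the published requirement/interval tables
  are not reproducible without the proprietary norms.
- Regional mechanics are fully supported but ship with synthetic regional
  inputs only.
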