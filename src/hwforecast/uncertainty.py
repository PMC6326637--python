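"""Predictive intervals from transition-probability uncertainty.

The dominant parameter uncertainty in the pipeline is in the estimated
transition probabilities.  It is propagated with limit scenarios: all ten
probabilities are shifted simultaneously to their lower (``p - z se``) or
upper (``p + z se``) 95 % confidence limits, clamped to [0, 1], the whole
pipeline is re-run under each variant, and per output cell the bound is the
min/max over the three scenario runs.  The min/max rule is what guarantees
``lower <= base <= upper`` for every cell: shifting all probabilities up
does not move every requirement up (faster upgrading drains low categories
while filling high ones), so neither limit scenario alone is a one-sided
bound.

A seeded Monte-Carlo mode is also provided as an optional extension: each
probability is drawn from a normal truncated to [0, 1] and the interval is
taken from empirical quantiles of the resulting requirement distribution.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .projection import (ConstructionSchedule, FacilityCensus,
                         PopulationSeries, TransitionTable, project)
from .staffing import RequirementTable, StaffingNorms, WorkloadChange, compute_requirements

__all__ = ["IntervalScenario", "ci_limits", "scenario_tables",
           "predictive_interval", "monte_carlo_interval"]


@dataclass(frozen=True)
class IntervalScenario:
    """One limit scenario: a label and the transition-table variant it uses."""

    label: str  # "lower" | "base" | "upper"
    tp_variant: TransitionTable


def ci_limits(tp: TransitionTable, z: float = 1.96) -> tuple[TransitionTable, TransitionTable]:
    """Lower and upper confidence-limit variants of a transition table.

    All pairs are shifted simultaneously by ``z`` standard errors and
    clamped to [0, 1]; the variants keep the original standard errors.
    """
    if not (z > 0):
        raise ValidationError(f"z must be > 0, got {z}")
    lower = np.clip(tp.p - z * tp.se, 0.0, 1.0)
    upper = np.clip(tp.p + z * tp.se, 0.0, 1.0)
    return TransitionTable(lower, tp.se), TransitionTable(upper, tp.se)


def scenario_tables(tp: TransitionTable, z: float = 1.96) -> list[IntervalScenario]:
    lo, hi = ci_limits(tp, z)
    return [
        IntervalScenario("lower", lo),
        IntervalScenario("base", tp),
        IntervalScenario("upper", hi),
    ]


def _bounded_requirements(base_run: pd.DataFrame, scenario_runs: list[pd.DataFrame]) -> RequirementTable:
    """Combine per-scenario requirement tables into one table with bounds."""
    key = ["staff_type", "region", "year"]
    out = base_run.set_index(key)[["required"]].copy()
    stack = np.stack([df.set_index(key).loc[out.index, "required"].to_numpy()
                      for df in scenario_runs])
    out["lower"] = stack.min(axis=0)
    out["upper"] = stack.max(axis=0)
    return RequirementTable(out.reset_index())


def predictive_interval(baseline: FacilityCensus,
                        tp: TransitionTable,
                        cons: ConstructionSchedule | None = None,
                        pop: PopulationSeries | None = None,
                        norms: StaffingNorms | None = None,
                        horizon: int = 10,
                        z: float = 1.96,
                        workload: WorkloadChange | None = None) -> RequirementTable:
    """Run the full projection-to-requirements pipeline under limit scenarios.

    Returns the base-scenario requirement table with ``lower``/``upper``
    columns holding the per-cell min/max over the lower/base/upper scenario
    runs, so ``lower <= required <= upper`` holds by construction.
    """
    if norms is None:
        raise ValidationError("staffing norms are required to compute requirements")
    runs: dict[str, pd.DataFrame] = {}
    for scenario in scenario_tables(tp, z):
        census = project(baseline, scenario.tp_variant, cons=cons, pop=pop, horizon=horizon)
        runs[scenario.label] = compute_requirements(census, norms, workload=workload).table
    return _bounded_requirements(runs["base"], list(runs.values()))


def monte_carlo_interval(baseline: FacilityCensus,
                         tp: TransitionTable,
                         cons: ConstructionSchedule | None = None,
                         pop: PopulationSeries | None = None,
                         norms: StaffingNorms | None = None,
                         horizon: int = 10,
                         n_draws: int = 500,
                         level: float = 0.95,
                         seed: int | np.random.Generator = 0,
                         workload: WorkloadChange | None = None) -> RequirementTable:
    """Monte-Carlo alternative to the limit-scenario interval (optional extension).

    Each draw samples every pair's probability from a normal truncated to
    [0, 1] centred at the point estimate with its standard error as scale,
    runs the pipeline, and the interval is the empirical ``(1-level)/2`` and
    ``(1+level)/2`` quantiles per cell.  Fully reproducible under ``seed``;
    the base column remains the point-estimate run, so cells keep
    ``lower <= required <= upper`` only up to sampling error and are clipped
    to include the base value.
    """
    if norms is None:
        raise ValidationError("staffing norms are required to compute requirements")
    if not (0 < level < 1):
        raise ValidationError(f"level must be in (0, 1), got {level}")
    if n_draws < 2:
        raise ValidationError("n_draws must be >= 2")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    base_census = project(baseline, tp, cons=cons, pop=pop, horizon=horizon)
    base_run = compute_requirements(base_census, norms, workload=workload).table
    key = ["staff_type", "region", "year"]
    base_idx = base_run.set_index(key)

    draws = np.empty((n_draws, len(base_idx)))
    for d in range(n_draws):
        p = np.empty_like(tp.p)
        for r in range(tp.p.size):
            if tp.se[r] == 0:
                p[r] = tp.p[r]
            else:
                a = (0.0 - tp.p[r]) / tp.se[r]
                b = (1.0 - tp.p[r]) / tp.se[r]
                p[r] = stats.truncnorm.rvs(a, b, loc=tp.p[r], scale=tp.se[r],
                                           random_state=rng)
        census = project(baseline, TransitionTable(p, tp.se), cons=cons, pop=pop,
                         horizon=horizon)
        run = compute_requirements(census, norms, workload=workload).table
        draws[d] = run.set_index(key).loc[base_idx.index, "required"].to_numpy()

    alpha = (1.0 - level) / 2.0
    lo = np.quantile(draws, alpha, axis=0)
    hi = np.quantile(draws, 1.0 - alpha, axis=0)
    out = base_idx[["required"]].copy()
    out["lower"] = np.minimum(lo, out["required"].to_numpy())
    out["upper"] = np.maximum(hi, out["required"].to_numpy())
    return RequirementTable(out.reset_index())
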