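"""Deterministic Markov cohort projection of healthcare facilities.

The cohort state is the real-valued count of facilities in each workload
category, per administrative region.  One annual cycle moves the expected
fraction ``p(r -> r+1)`` of each category's stock one rung up the ladder,
then adds newly commissioned facilities from the construction schedule.  The
top category has no outflow, so it absorbs.  The bottom category (CHPS) can
either follow the same Markov bookkeeping or be driven exogenously by
population: national policy demarcates one CHPS zone per 1500 population, so
when a population series is supplied the CHPS stock for each projected year
is ``population / 1500`` and the Markov rule applies only to the other ten
categories.

Counts stay fractional internally ("expected facilities"); rounding to the
printed-table conventions happens only in the report renderers.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .categories import CATEGORIES, N_CATEGORIES, PAIRS, as_category
from .errors import MissingDataError, ValidationError

__all__ = [
    "TransitionTable",
    "FacilityCensus",
    "ConstructionSchedule",
    "PopulationSeries",
    "FlowTable",
    "demarcate_chps",
    "step_census",
    "project",
    "transition_flows",
]

_RANK = {code: r for r, code in enumerate(CATEGORIES)}


# ---------------------------------------------------------------------------
# transition probabilities
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TransitionTable:
    """Annual upward transition probabilities for the 10 adjacent pairs.

    ``p[r]`` is the probability that a facility in the category of rank ``r``
    moves to rank ``r + 1`` within one annual cycle; ``se[r]`` is its
    standard error.  Both arrays are in ladder order (CHPS->HCA first).
    """

    p: np.ndarray
    se: np.ndarray

    def __post_init__(self):
        p = np.asarray(self.p, dtype=float).copy()
        se = np.asarray(self.se, dtype=float).copy()
        if p.shape != (N_CATEGORIES - 1,) or se.shape != (N_CATEGORIES - 1,):
            raise ValidationError(
                f"transition table needs {N_CATEGORIES - 1} adjacent pairs, "
                f"got shapes {p.shape} and {se.shape}"
            )
        if not np.all(np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
            raise ValidationError("transition probabilities must lie in [0, 1]")
        if not np.all(np.isfinite(se)) or np.any(se < 0):
            raise ValidationError("standard errors must be finite and >= 0")
        p.flags.writeable = False
        se.flags.writeable = False
        object.__setattr__(self, "p", p)
        object.__setattr__(self, "se", se)

    @classmethod
    def from_pairs(cls, entries: Mapping[tuple[str, str], tuple[float, float]]) -> "TransitionTable":
        """Build from a mapping ``(from_code, to_code) -> (p, se)``; all 10 pairs required."""
        p = np.empty(N_CATEGORIES - 1)
        se = np.empty(N_CATEGORIES - 1)
        for r, pair in enumerate(PAIRS):
            if pair not in entries:
                raise ValidationError(f"missing transition pair {pair[0]} -> {pair[1]}")
            p[r], se[r] = entries[pair]
        extra = set(entries) - set(PAIRS)
        if extra:
            raise ValidationError(f"non-adjacent transition pairs not allowed: {sorted(extra)}")
        return cls(p, se)

    def probability(self, frm: str, to: str) -> float:
        r = _pair_rank(frm, to)
        return float(self.p[r])

    def standard_error(self, frm: str, to: str) -> float:
        r = _pair_rank(frm, to)
        return float(self.se[r])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "from_category": [a for a, _ in PAIRS],
                "to_category": [b for _, b in PAIRS],
                "probability": self.p,
                "standard_error": self.se,
            }
        )


def _pair_rank(frm: str, to: str) -> int:
    frm_c, to_c = as_category(frm), as_category(to)
    if to_c.rank != frm_c.rank + 1:
        raise ValidationError(
            f"only adjacent upward transitions exist; {frm_c.code} -> {to_c.code} is not one"
        )
    return frm_c.rank


# ---------------------------------------------------------------------------
# census / schedule / population containers
# ---------------------------------------------------------------------------

def _census_vector(counts: Mapping[str, float] | np.ndarray, what: str = "census") -> np.ndarray:
    """Coerce a per-category mapping (or ladder-ordered array) to a length-11 vector."""
    if isinstance(counts, np.ndarray):
        vec = np.asarray(counts, dtype=float)
        if vec.shape != (N_CATEGORIES,):
            raise ValidationError(f"{what} vector must have length {N_CATEGORIES}")
        vec = vec.copy()
    else:
        vec = np.zeros(N_CATEGORIES)
        for key, value in counts.items():
            vec[as_category(key).rank] = float(value)
        missing = set(CATEGORIES) - {as_category(k).code for k in counts}
        if missing and what == "census":
            raise ValidationError(f"census must cover all categories; missing {sorted(missing)}")
    if not np.all(np.isfinite(vec)) or np.any(vec < 0):
        raise ValidationError(f"{what} counts must be finite and >= 0")
    return vec


@dataclass
class FacilityCensus:
    """Facility counts per (region, category, year) — the Markov cohort state.

    Internally a mapping ``(region, year) -> length-11 vector`` in ladder
    order.  Counts are real-valued; integer rounding is a rendering concern.
    """

    counts: dict[tuple[str, int], np.ndarray]
    baseline_year: int

    def __post_init__(self):
        clean: dict[tuple[str, int], np.ndarray] = {}
        for (region, year), vec in self.counts.items():
            clean[(str(region), int(year))] = _census_vector(vec)
        self.counts = clean
        if not self.counts:
            raise ValidationError("census is empty")
        if not any(y == self.baseline_year for _, y in self.counts):
            raise ValidationError(f"baseline year {self.baseline_year} absent from census")

    # -- construction -------------------------------------------------
    @classmethod
    def from_mapping(cls, counts: Mapping[tuple[str, str, int], float], baseline_year: int) -> "FacilityCensus":
        """Build from a flat mapping ``(region, category, year) -> count``."""
        acc: dict[tuple[str, int], np.ndarray] = {}
        for (region, cat, year), value in counts.items():
            vec = acc.setdefault((str(region), int(year)), np.zeros(N_CATEGORIES))
            vec[as_category(cat).rank] = float(value)
        return cls(acc, baseline_year)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, baseline_year: int) -> "FacilityCensus":
        """Build from a long DataFrame with columns region, category, year, count."""
        acc: dict[tuple[str, int], np.ndarray] = {}
        for row in df.itertuples(index=False):
            vec = acc.setdefault((str(row.region), int(row.year)), np.zeros(N_CATEGORIES))
            vec[as_category(row.category).rank] = float(row.count)
        return cls(acc, baseline_year)

    # -- access --------------------------------------------------------
    @property
    def regions(self) -> list[str]:
        return sorted({r for r, _ in self.counts})

    @property
    def years(self) -> list[int]:
        return sorted({y for _, y in self.counts})

    def vector(self, region: str, year: int) -> np.ndarray:
        try:
            return self.counts[(region, year)]
        except KeyError:
            raise MissingDataError(f"no census for region {region!r}, year {year}") from None

    def get(self, region: str, category: str, year: int) -> float:
        return float(self.vector(region, year)[as_category(category).rank])

    def national(self, year: int) -> np.ndarray:
        """Sum over regions for one year."""
        vecs = [v for (r, y), v in self.counts.items() if y == year]
        if not vecs:
            raise MissingDataError(f"no census for year {year}")
        return np.sum(vecs, axis=0)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (region, cat, year, float(vec[r]))
            for (region, year), vec in sorted(self.counts.items())
            for r, cat in enumerate(CATEGORIES)
        ]
        return pd.DataFrame(rows, columns=["region", "category", "year", "count"])


@dataclass
class ConstructionSchedule:
    """Newly commissioned facilities per (region, category, year); missing cells are 0."""

    entries: dict[tuple[str, int], np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        clean: dict[tuple[str, int], np.ndarray] = {}
        for (region, year), vec in self.entries.items():
            clean[(str(region), int(year))] = _census_vector(vec, what="construction")
        self.entries = clean

    @classmethod
    def from_mapping(cls, entries: Mapping[tuple[str, str, int], float]) -> "ConstructionSchedule":
        acc: dict[tuple[str, int], np.ndarray] = {}
        for (region, cat, year), value in entries.items():
            vec = acc.setdefault((str(region), int(year)), np.zeros(N_CATEGORIES))
            vec[as_category(cat).rank] = float(value)
        return cls(acc)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ConstructionSchedule":
        return cls.from_mapping(
            {(str(r.region), str(r.category), int(r.year)): float(r.count)
             for r in df.itertuples(index=False)}
        )

    @property
    def regions(self) -> list[str]:
        return sorted({r for r, _ in self.entries})

    def vector(self, region: str, year: int) -> np.ndarray:
        return self.entries.get((region, year), np.zeros(N_CATEGORIES))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (region, cat, year, float(vec[r]))
            for (region, year), vec in sorted(self.entries.items())
            for r, cat in enumerate(CATEGORIES)
            if vec[r] != 0.0
        ]
        return pd.DataFrame(rows, columns=["region", "category", "year", "count"])


@dataclass
class PopulationSeries:
    """Regional population by year, plus the CHPS demarcation divisor.

    Policy demarcates one CHPS zone per ``chps_divisor`` population
    (1500 by default), which makes the CHPS stock exogenous when this
    series is supplied to :func:`project`.
    """

    population: dict[tuple[str, int], float]
    chps_divisor: float = 1500.0

    def __post_init__(self):
        if not (self.chps_divisor > 0):
            raise ValidationError("chps_divisor must be > 0")
        clean = {}
        for (region, year), pop in self.population.items():
            pop = float(pop)
            if not (pop > 0) or not np.isfinite(pop):
                raise ValidationError(
                    f"population must be > 0 (region {region!r}, year {year}: {pop})"
                )
            clean[(str(region), int(year))] = pop
        self.population = clean

    @classmethod
    def from_frame(cls, df: pd.DataFrame, chps_divisor: float = 1500.0) -> "PopulationSeries":
        return cls(
            {(str(r.region), int(r.year)): float(r.population) for r in df.itertuples(index=False)},
            chps_divisor=chps_divisor,
        )

    def get(self, region: str, year: int) -> float:
        try:
            return self.population[(region, year)]
        except KeyError:
            raise MissingDataError(f"no population for region {region!r}, year {year}") from None

    def to_frame(self) -> pd.DataFrame:
        rows = [(r, y, p) for (r, y), p in sorted(self.population.items())]
        return pd.DataFrame(rows, columns=["region", "year", "population"])


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def demarcate_chps(pop: PopulationSeries, region: str, year: int) -> float:
    """Population-implied CHPS zone count: ``population / divisor``, un-rounded."""
    return pop.get(region, year) / pop.chps_divisor


def _step_vector(current: np.ndarray, p: np.ndarray,
                 construction: np.ndarray, chps_next: float | None) -> np.ndarray:
    """One annual Markov cycle on a length-11 ladder vector.

    Outflow from rank r (r < top) is ``current[r] * p[r]`` and arrives at
    rank r+1; the top rank absorbs.  Construction is added after the
    transition update, so new facilities first transition the following
    cycle.  If ``chps_next`` is given it replaces the CHPS stock (its
    outflow into the next rung is still computed from the current stock).
    """
    flows = current[:-1] * p
    nxt = current.copy()
    nxt[:-1] -= flows
    nxt[1:] += flows
    nxt += construction
    if chps_next is not None:
        if chps_next < 0:
            raise ValidationError("demarcated CHPS count must be >= 0")
        nxt[0] = chps_next
    return nxt


def step_census(census_year: Mapping[str, float] | np.ndarray,
                tp: TransitionTable,
                construction_year: Mapping[str, float] | np.ndarray | None = None,
                chps_next: float | None = None) -> dict[str, float]:
    """Advance one region's census one annual cycle.

    Parameters
    ----------
    census_year
        Current counts per category (all 11 categories).
    tp
        Adjacent-pair transition probabilities.
    construction_year
        Newly commissioned facilities per category, added at the end of the
        cycle; omitted categories are 0.
    chps_next
        Exogenous CHPS stock for the next year (population demarcation).
        When absent the CHPS stock follows the Markov rule like every other
        category.

    Returns
    -------
    dict
        Next-year counts per category code.
    """
    cur = _census_vector(census_year)
    cons = (np.zeros(N_CATEGORIES) if construction_year is None
            else _census_vector(construction_year, what="construction"))
    nxt = _step_vector(cur, tp.p, cons, chps_next)
    return {cat: float(nxt[r]) for r, cat in enumerate(CATEGORIES)}


def project(baseline: FacilityCensus,
            tp: TransitionTable,
            cons: ConstructionSchedule | None = None,
            pop: PopulationSeries | None = None,
            horizon: int = 10) -> FacilityCensus:
    """Project the facility census ``horizon`` annual cycles past baseline.

    Applies :func:`step_census` per region per year.  When ``pop`` is given,
    each projected year's CHPS stock is set by population demarcation
    (population mode); otherwise CHPS follows the Markov update like the
    other categories (markov mode).  The result contains the baseline year
    plus ``horizon`` projected years and is fully deterministic.
    """
    if horizon < 1:
        raise ValidationError(f"horizon must be >= 1, got {horizon}")
    cons = cons or ConstructionSchedule()
    regions = baseline.regions
    unknown = set(cons.regions) - set(regions)
    if unknown:
        raise ValidationError(f"construction schedule names unknown regions: {sorted(unknown)}")

    y0 = baseline.baseline_year
    out: dict[tuple[str, int], np.ndarray] = {
        (region, y0): baseline.vector(region, y0).copy() for region in regions
    }
    for region in regions:
        current = out[(region, y0)]
        for year in range(y0 + 1, y0 + horizon + 1):
            chps_next = demarcate_chps(pop, region, year) if pop is not None else None
            current = _step_vector(current, tp.p, cons.vector(region, year), chps_next)
            out[(region, year)] = current
    return FacilityCensus(out, baseline_year=y0)


@dataclass(frozen=True)
class FlowTable:
    """Modelled facility transitions per adjacent pair and year, summed over regions.

    ``flows`` is indexed by year with one column per pair label
    (``"CHPS->HCA"`` etc.); ``totals`` sums each column over the horizon.
    """

    flows: pd.DataFrame
    totals: pd.Series

    def flow(self, frm: str, to: str, year: int) -> float:
        return float(self.flows.loc[year, f"{as_category(frm).code}->{as_category(to).code}"])


def transition_flows(census: FacilityCensus, tp: TransitionTable) -> FlowTable:
    """Expected upward transitions ``count(r, year) * p(r -> r+1)`` per pair and year."""
    years = census.years
    labels = [f"{a}->{b}" for a, b in PAIRS]
    data = np.vstack([census.national(year)[:-1] * tp.p for year in years])
    flows = pd.DataFrame(data, index=pd.Index(years, name="year"), columns=labels)
    return FlowTable(flows=flows, totals=flows.sum(axis=0))
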