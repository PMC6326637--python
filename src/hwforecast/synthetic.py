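"""Synthetic inputs with the statistical structure the pipeline assumes.

The study's raw inputs are a national routine-information-system extract
(facility utilisation panel), Ministry of Health staffing norms, a
construction plan and an employment roster — none of which are publicly
deposited.  This module generates statistically analogous stand-ins so
every pipeline stage can be exercised and validated end-to-end:

* a facility panel in which each facility independently moves one rung up
  the workload ladder each year with its pair's true probability
  (adjacent-upward Bernoulli process, top rung absorbing) — the process the
  Markov cohort model takes expectations over, which makes the panel both
  an estimation input and a microsimulation oracle for the projection;
* a published-values fixture: the national 2016 baseline census and the
  10 transition probability/standard-error pairs as printed;
* a staffing-norms matrix shaped like the Ghana norms (23 cadres x 11
  categories, headcount non-decreasing in facility rank) with explicitly
  fictional magnitudes;
* a population series (geometric growth) and an employment roster drawn to
  hit a target aggregate staff-availability ratio.

Everything is reproducible from ``GeneratorConfig.seed``.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .categories import CATEGORIES, N_CATEGORIES, PAIRS
from .errors import ValidationError
from .estimation import FacilityPanel
from .projection import (ConstructionSchedule, FacilityCensus,
                         PopulationSeries, TransitionTable)
from .staffing import EmploymentRoster, RequirementTable, StaffingNorms

__all__ = [
    "GeneratorConfig",
    "ghana_baseline_counts",
    "ghana_transition_table",
    "make_ghana_fixture",
    "split_census",
    "simulate_panel",
    "panel_counts",
    "synth_norms",
    "synth_population",
    "synth_roster",
    "synth_construction",
]

# National baseline census, March 2016 (published values).
_GHANA_BASELINE_2016: dict[str, float] = {
    "CHPS": 4449, "HCA": 903, "HCB": 158, "PolyC": 40, "PHA": 96,
    "PHB": 49, "PHC": 29, "PHD": 14, "RH": 7, "EmTH": 2, "EsTH": 2,
}

# Published annual transition probabilities and standard errors per adjacent pair.
_GHANA_TP: dict[tuple[str, str], tuple[float, float]] = {
    ("CHPS", "HCA"): (0.010, 0.001),
    ("HCA", "HCB"): (0.033, 0.002),
    ("HCB", "PolyC"): (0.028, 0.002),
    ("PolyC", "PHA"): (0.042, 0.002),
    ("PHA", "PHB"): (0.167, 0.005),
    ("PHB", "PHC"): (0.129, 0.004),
    ("PHC", "PHD"): (0.084, 0.003),
    ("PHD", "RH"): (0.021, 0.002),
    ("RH", "EmTH"): (0.091, 0.003),
    ("EmTH", "EsTH"): (0.001, 0.000),
}

# Fictional staffing-norms shape: cadre -> (first rank present, headcount
# there, multiplicative growth per rank).  Magnitudes are order-of-magnitude
# plausible (tens of nurses per hospital, fractional specialists per primary
# facility) but are NOT the Ministry of Health norms, which are not
# reproduced here.
_NORMS_SHAPE: dict[str, tuple[int, float, float]] = {
    "Biomedical scientist": (2, 0.5, 1.6),
    "Community health nurse": (0, 3.0, 1.25),
    "Critical care nurse": (4, 1.0, 1.7),
    "Dental surgeon": (4, 0.2, 1.6),
    "Emergency nurse": (3, 0.8, 1.6),
    "Enrolled nurse": (0, 3.0, 1.25),
    "Family medicine physician": (4, 0.2, 1.6),
    "General surgeon": (5, 0.5, 1.6),
    "Medical officer (general practitioner)": (2, 0.5, 1.7),
    "Mental health nurse": (1, 0.4, 1.5),
    "Midwife": (0, 1.5, 1.3),
    "Obstetrician & gynaecologist": (4, 0.3, 1.7),
    "Ophthalmic nurse": (2, 0.3, 1.5),
    "Ophthalmologist": (6, 0.3, 1.7),
    "Paediatrician": (4, 0.3, 1.7),
    "Pharmacist": (3, 0.5, 1.7),
    "Pharmacy technician": (1, 0.6, 1.5),
    "Physician assistant (anaesthesia)": (3, 0.5, 1.5),
    "Physician assistant (medical)": (1, 0.4, 1.5),
    "Public health nurse": (2, 0.3, 1.5),
    "Radiographer/x-ray technician": (3, 0.4, 1.6),
    "Registered general nurse": (0, 2.5, 1.45),
    "Technical officer (laboratory)": (1, 0.7, 1.5),
}


def _default_fac_counts() -> dict[str, int]:
    return {k: int(v) for k, v in _GHANA_BASELINE_2016.items()}


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs for all synthetic generators; ``seed`` fixes every draw.

    Defaults emulate the study conditions: a 2011–2015 five-year national
    panel with the published transition probabilities as truth, ten regions,
    ~2.2 %/year population growth from ~28 M people, and a 68 % aggregate
    staff-availability target for the roster.
    """

    seed: int = 0
    n_regions: int = 10
    n_facilities_per_category: Mapping[str, int] = field(default_factory=_default_fac_counts)
    tp_true: TransitionTable = field(
        default_factory=lambda: TransitionTable.from_pairs(_GHANA_TP))
    years: int = 5                    #: panel span in years
    panel_start_year: int = 2011
    baseline_year: int = 2016
    pop_growth_rate: float = 0.022    #: fraction per year
    base_population: float = 28_000_000.0
    norms_scale: float = 1.0
    roster_sar_target: float = 0.68
    missing_rate: float = 0.0         #: per-record censoring probability in the panel

    def __post_init__(self):
        if self.years < 2:
            raise ValidationError("panel span must be >= 2 years")
        if self.n_regions < 1:
            raise ValidationError("n_regions must be >= 1")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValidationError("missing_rate must be in [0, 1)")
        if not (self.norms_scale > 0):
            raise ValidationError("norms_scale must be > 0")
        if not (0.0 < self.roster_sar_target):
            raise ValidationError("roster_sar_target must be > 0")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent, reproducible stream per generator."""
        return np.random.default_rng([int(self.seed) % (2**31), stream])


# ---------------------------------------------------------------------------
# published-values fixture
# ---------------------------------------------------------------------------

def ghana_baseline_counts() -> dict[str, float]:
    """The published national 2016 baseline counts per category."""
    return dict(_GHANA_BASELINE_2016)


def ghana_transition_table() -> TransitionTable:
    """The published 10 probability / standard-error pairs."""
    return TransitionTable.from_pairs(_GHANA_TP)


def make_ghana_fixture(baseline_year: int = 2016) -> tuple[FacilityCensus, TransitionTable]:
    """Single-region census holding the published 2016 baseline, plus the published table."""
    census = FacilityCensus.from_mapping(
        {("Ghana", cat, baseline_year): n for cat, n in _GHANA_BASELINE_2016.items()},
        baseline_year=baseline_year,
    )
    return census, ghana_transition_table()


def split_census(census: FacilityCensus, n_regions: int) -> FacilityCensus:
    """Partition each baseline count evenly across ``n_regions`` synthetic regions.

    Useful for exercising regional mechanics: by linearity of the projection
    the national sums of a split run equal the unsplit run.
    """
    if n_regions < 1:
        raise ValidationError("n_regions must be >= 1")
    y0 = census.baseline_year
    nat = census.national(y0)
    counts = {
        (f"R{i + 1:02d}", y0): nat / n_regions for i in range(n_regions)
    }
    return FacilityCensus(counts, baseline_year=y0)


# ---------------------------------------------------------------------------
# facility panel (microsimulation)
# ---------------------------------------------------------------------------

def simulate_panel(cfg: GeneratorConfig) -> FacilityPanel:
    """Simulate a facility-year category panel under the true transition table.

    Each facility starts in its assigned category; each year it moves one
    rung up with its pair's probability, otherwise stays (top rung
    absorbing, no downward moves).  With ``missing_rate > 0``, individual
    facility-year records are censored independently, emulating incomplete
    routine reporting.
    """
    rng = cfg.rng(1)
    start_ranks = np.concatenate([
        np.full(int(cfg.n_facilities_per_category.get(cat, 0)), r, dtype=np.int64)
        for r, cat in enumerate(CATEGORIES)
    ])
    n_fac = start_ranks.size
    if n_fac == 0:
        raise ValidationError("no facilities configured")

    p_ext = np.append(cfg.tp_true.p, 0.0)  # absorbing top rung
    ranks = np.empty((cfg.years, n_fac), dtype=np.int64)
    ranks[0] = start_ranks
    for t in range(1, cfg.years):
        cur = ranks[t - 1]
        move = rng.random(n_fac) < p_ext[cur]
        ranks[t] = cur + move

    years = np.repeat(np.arange(cfg.panel_start_year,
                                cfg.panel_start_year + cfg.years), n_fac)
    fac_ids = np.tile(np.char.add("F", np.arange(n_fac).astype(str)), cfg.years)
    cats = np.asarray(CATEGORIES, dtype=object)[ranks.ravel()]

    df = pd.DataFrame({"facility_id": fac_ids, "year": years, "category": cats})
    if cfg.missing_rate > 0:
        df = df[rng.random(len(df)) >= cfg.missing_rate]
        if df.empty:
            raise ValidationError("missing_rate censored the entire panel")
    return FacilityPanel(df)


def panel_counts(panel: FacilityPanel) -> pd.DataFrame:
    """Facilities per category and year (microsimulation census), year x category."""
    out = (panel.records.groupby(["year", "category"], observed=True)
           .size().unstack(fill_value=0))
    return out.reindex(columns=list(CATEGORIES), fill_value=0)


# ---------------------------------------------------------------------------
# norms / population / roster / construction
# ---------------------------------------------------------------------------

def synth_norms(cfg: GeneratorConfig) -> StaffingNorms:
    """Fictional staffing-norms matrix, 23 cadres x 11 categories.

    Headcounts are non-decreasing in facility rank for every cadre
    (higher-level facilities need at least as many staff) and scale
    linearly with ``norms_scale``.  Deterministic given the config.
    """
    rows = {}
    for cadre, (start, base, growth) in _NORMS_SHAPE.items():
        vec = np.zeros(N_CATEGORIES)
        ranks = np.arange(start, N_CATEGORIES)
        vec[start:] = np.round(base * growth ** (ranks - start), 1)
        rows[cadre] = vec * cfg.norms_scale
    return StaffingNorms(pd.DataFrame.from_dict(rows, orient="index",
                                                columns=list(CATEGORIES)))


def synth_population(cfg: GeneratorConfig, n_years: int = 11) -> PopulationSeries:
    """Regional populations growing geometrically at ``pop_growth_rate``.

    The national baseline total is split across regions with seeded,
    moderately uneven shares (Dirichlet), mirroring real regional
    heterogeneity.
    """
    rng = cfg.rng(2)
    shares = rng.dirichlet(np.full(cfg.n_regions, 8.0))
    pop = {}
    for i, share in enumerate(shares):
        region = f"R{i + 1:02d}" if cfg.n_regions > 1 else "Ghana"
        base = cfg.base_population * share
        for t in range(n_years):
            year = cfg.baseline_year + t
            pop[(region, year)] = base * (1.0 + cfg.pop_growth_rate) ** t
    return PopulationSeries(pop)


def synth_roster(cfg: GeneratorConfig, requirements: RequirementTable,
                 year: int | None = None) -> EmploymentRoster:
    """Employment roster whose aggregate staff-availability ratio hits the target.

    Per-cadre employment is the target share of the national requirement
    with seeded multiplicative jitter (so cadres spread around the target),
    then rescaled so the aggregate ratio equals ``roster_sar_target`` up to
    integer rounding.
    """
    rng = cfg.rng(3)
    year = requirements.years[0] if year is None else year
    nat = requirements.national(year=year).set_index("staff_type")["required"]
    jitter = rng.uniform(0.7, 1.3, size=len(nat))
    raw = cfg.roster_sar_target * nat.to_numpy() * jitter
    # rescale so the realised aggregate ratio matches the target exactly pre-rounding
    raw *= cfg.roster_sar_target * nat.sum() / raw.sum()
    employed = {k: int(round(v)) for k, v in zip(nat.index, raw)}
    return EmploymentRoster(employed)


def synth_construction(cfg: GeneratorConfig, regions: list[str],
                       horizon: int = 10,
                       mean_per_region_year: float = 1.0) -> ConstructionSchedule:
    """Sparse Poisson construction schedule over the projection years.

    New facilities are overwhelmingly low-tier in practice, so draws are
    weighted toward the bottom rungs of the ladder.
    """
    rng = cfg.rng(4)
    weights = np.array([0.55, 0.20, 0.10, 0.06, 0.04, 0.02, 0.01, 0.01, 0.005, 0.0045, 0.0005])
    weights /= weights.sum()
    entries: dict[tuple[str, str, int], float] = {}
    for region in regions:
        for t in range(1, horizon + 1):
            year = cfg.baseline_year + t
            n_new = rng.poisson(mean_per_region_year)
            if n_new:
                cats = rng.choice(N_CATEGORIES, size=n_new, p=weights)
                for c in cats:
                    key = (region, CATEGORIES[c], year)
                    entries[key] = entries.get(key, 0.0) + 1.0
    return ConstructionSchedule.from_mapping(entries)
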