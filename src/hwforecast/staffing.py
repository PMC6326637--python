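"""Translation of projected facility counts into workforce requirements.

Each staff cadre has a stipulated headcount per facility of each workload
category (the staffing norm).  The base requirement for cadre ``k`` in a
region-year is the dot product of the census vector with the cadre's norms
vector.  When the workload of facilities shifts without triggering a
category change, a piecewise adjustment ladder from the national staffing
norms applies on top:

======================  =====================
absolute workload shift  staffing adjustment
======================  =====================
>= 15 %                  23.5 % (flagged for review)
> 10 % and < 15 %        14.3 %
5 % up to 10 %            6.3 %
< 5 %                     none
======================  =====================

The sign of the adjustment follows the sign of the workload change.  Exactly
10 % falls in the 6.3 % band ("5 % up to 10 %" read as inclusive).

The staff-availability ratio (SAR) compares the current employed headcount
of a cadre with its modelled national requirement.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .categories import CATEGORIES, N_CATEGORIES, as_category
from .errors import MissingDataError, ValidationError
from .projection import FacilityCensus

__all__ = [
    "StaffingNorms",
    "WorkloadChange",
    "RequirementTable",
    "EmploymentRoster",
    "adjustment_factor",
    "base_requirement",
    "adjusted_requirement",
    "compute_requirements",
    "staff_availability_ratio",
    "SARResult",
]

#: Workload shift at or beyond which the norms call for a full facility reassessment.
REVIEW_THRESHOLD = 0.15


class WorkloadReviewWarning(UserWarning):
    """A cell's workload change is at/above the thorough-reassessment threshold."""


def adjustment_factor(delta: float) -> float:
    """Staffing adjustment fraction for a fractional workload change ``delta``.

    Piecewise-constant in ``|delta|`` (0.235 / 0.143 / 0.063 / 0) with the
    sign of ``delta``.
    """
    delta = float(delta)
    if not math.isfinite(delta):
        raise ValidationError(f"workload change must be finite, got {delta}")
    a = abs(delta)
    if a >= 0.15:
        mag = 0.235
    elif a > 0.10:
        mag = 0.143
    elif a >= 0.05:
        mag = 0.063
    else:
        mag = 0.0
    return math.copysign(mag, delta) if mag else 0.0


@dataclass
class StaffingNorms:
    """Required headcount per facility: staff type x workload category.

    ``standard`` is a DataFrame indexed by staff type with one column per
    category code, all values >= 0.
    """

    standard: pd.DataFrame

    def __post_init__(self):
        df = pd.DataFrame(self.standard).copy()
        missing = set(CATEGORIES) - set(df.columns)
        if missing:
            raise ValidationError(f"staffing norms missing categories {sorted(missing)}")
        df = df[list(CATEGORIES)].astype(float)
        if df.isna().any().any() or (df.values < 0).any():
            raise ValidationError("staffing norms must be non-negative and complete")
        self.standard = df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "StaffingNorms":
        """Build from a long DataFrame with columns staff_type, category, headcount."""
        wide = df.pivot_table(index="staff_type", columns="category",
                              values="headcount", aggfunc="sum", fill_value=0.0)
        return cls(wide)

    @property
    def staff_types(self) -> list[str]:
        return self.standard.index.tolist()

    def vector(self, staff_type: str) -> np.ndarray:
        """Norms for one cadre as a ladder-ordered length-11 vector."""
        if staff_type not in self.standard.index:
            raise MissingDataError(f"staff type {staff_type!r} absent from staffing norms")
        return self.standard.loc[staff_type].to_numpy()

    def to_frame(self) -> pd.DataFrame:
        long = self.standard.stack().rename("headcount").reset_index()
        long.columns = ["staff_type", "category", "headcount"]
        return long


@dataclass
class WorkloadChange:
    """Fractional workload change per (region, category); missing cells are 0."""

    delta: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self):
        clean = {}
        for (region, cat), d in self.delta.items():
            d = float(d)
            if not math.isfinite(d):
                raise ValidationError(f"workload change for ({region}, {cat}) is not finite")
            clean[(str(region), as_category(cat).code)] = d
        self.delta = clean

    def get(self, region: str, category: str) -> float:
        return self.delta.get((region, as_category(category).code), 0.0)

    def vector(self, region: str) -> np.ndarray:
        return np.array([self.get(region, c) for c in CATEGORIES])


@dataclass
class RequirementTable:
    """Required headcount per (staff type, region, year), with optional bounds.

    ``table`` is a long DataFrame with columns staff_type, region, year,
    required and, when predictive bounds have been propagated, lower/upper.
    National values are sums over regions, computed on demand.
    """

    table: pd.DataFrame

    def __post_init__(self):
        df = pd.DataFrame(self.table).copy()
        needed = {"staff_type", "region", "year", "required"}
        if not needed <= set(df.columns):
            raise ValidationError(f"requirement table needs columns {sorted(needed)}")
        if (df["required"] < 0).any():
            raise ValidationError("requirements must be >= 0")
        if {"lower", "upper"} <= set(df.columns):
            bad = (df["lower"] > df["required"] + 1e-9) | (df["upper"] < df["required"] - 1e-9)
            if bad.any():
                raise ValidationError("bounds must satisfy lower <= required <= upper")
        self.table = df

    @property
    def has_bounds(self) -> bool:
        return {"lower", "upper"} <= set(self.table.columns)

    @property
    def staff_types(self) -> list[str]:
        return sorted(self.table["staff_type"].unique().tolist())

    @property
    def years(self) -> list[int]:
        return sorted(self.table["year"].unique().tolist())

    def required(self, staff_type: str, region: str, year: int) -> float:
        df = self.table
        sel = df[(df.staff_type == staff_type) & (df.region == region) & (df.year == year)]
        if sel.empty:
            raise MissingDataError(
                f"no requirement for staff {staff_type!r}, region {region!r}, year {year}"
            )
        return float(sel["required"].sum())

    def national(self, staff_type: str | None = None, year: int | None = None) -> pd.DataFrame:
        """Requirements summed over regions, optionally filtered."""
        df = self.table
        if staff_type is not None:
            df = df[df.staff_type == staff_type]
        if year is not None:
            df = df[df.year == year]
        if df.empty:
            raise MissingDataError(
                f"no requirement rows for staff {staff_type!r}, year {year!r}"
            )
        cols = [c for c in ("required", "lower", "upper") if c in df.columns]
        return df.groupby(["staff_type", "year"], as_index=False)[cols].sum()

    def national_value(self, staff_type: str, year: int) -> float:
        return float(self.national(staff_type, year)["required"].iloc[0])


@dataclass
class EmploymentRoster:
    """Currently employed headcount per staff type."""

    employed: dict[str, int]

    def __post_init__(self):
        clean = {}
        for staff, n in self.employed.items():
            n = int(n)
            if n < 0:
                raise ValidationError(f"employed count for {staff!r} must be >= 0")
            clean[str(staff)] = n
        self.employed = clean

    def get(self, staff_type: str) -> int:
        if staff_type not in self.employed:
            raise MissingDataError(f"staff type {staff_type!r} absent from roster")
        return self.employed[staff_type]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.employed.items()), columns=["staff_type", "employed"]
        )


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def base_requirement(census: FacilityCensus, norms: StaffingNorms,
                     staff_type: str, region: str, year: int) -> float:
    """Unadjusted requirement: census vector . norms vector for one cadre/region/year."""
    return float(census.vector(region, year) @ norms.vector(staff_type))


def adjusted_requirement(base: float, delta: float) -> float:
    """Apply the workload-change adjustment ladder to a base requirement."""
    if base < 0:
        raise ValidationError("base requirement must be >= 0")
    return base * (1.0 + adjustment_factor(delta))


def compute_requirements(census: FacilityCensus, norms: StaffingNorms,
                         workload: WorkloadChange | None = None,
                         years: list[int] | None = None) -> RequirementTable:
    """Requirements for every staff type, region and year of a projected census.

    The workload adjustment is applied per (region, category) cell before
    summing over categories; the default all-zero workload change reproduces
    the unadjusted norms arithmetic exactly.  Cells whose workload shift is
    at or beyond 15 % are flagged with a :class:`WorkloadReviewWarning` —
    the norms require a facility reassessment there, which is outside this
    model.
    """
    years = census.years if years is None else years
    norm_matrix = norms.standard.to_numpy()       # staff x category
    staff = norms.staff_types

    rows = []
    for region in census.regions:
        deltas = workload.vector(region) if workload is not None else np.zeros(N_CATEGORIES)
        factors = 1.0 + np.array([adjustment_factor(d) for d in deltas])
        flagged = [CATEGORIES[i] for i in np.flatnonzero(np.abs(deltas) >= REVIEW_THRESHOLD)]
        if flagged:
            warnings.warn(
                f"region {region!r}: workload change >= {REVIEW_THRESHOLD:.0%} for "
                f"{flagged}; staffing norms require a facility reassessment",
                WorkloadReviewWarning,
                stacklevel=2,
            )
        for year in years:
            vec = census.vector(region, year) * factors
            req = norm_matrix @ vec               # per staff type
            rows.extend(
                (k, region, year, float(v)) for k, v in zip(staff, req)
            )
    return RequirementTable(
        pd.DataFrame(rows, columns=["staff_type", "region", "year", "required"])
    )


@dataclass(frozen=True)
class SARResult:
    """Staff-availability ratio and the corresponding shortfall fraction."""

    staff_type: str
    year: int
    employed: int
    required: float
    sar: float
    shortfall: float  #: max(0, 1 - sar)


def staff_availability_ratio(roster: EmploymentRoster, requirements: RequirementTable,
                             staff_type: str, year: int) -> SARResult:
    """Employed / national requirement for one cadre, with shortfall floored at 0."""
    required = requirements.national_value(staff_type, year)
    if required <= 0:
        raise ValidationError(
            f"national requirement for {staff_type!r} in {year} is zero; SAR undefined"
        )
    employed = roster.get(staff_type)
    sar = employed / required
    return SARResult(
        staff_type=staff_type, year=year, employed=employed, required=required,
        sar=sar, shortfall=max(0.0, 1.0 - sar),
    )


def sar_report(roster: EmploymentRoster, requirements: RequirementTable,
               year: int) -> pd.DataFrame:
    """SAR per staff type for one year, plus the requirement-weighted aggregate row."""
    rows = [
        staff_availability_ratio(roster, requirements, k, year)
        for k in requirements.staff_types
        if k in roster.employed
    ]
    if not rows:
        raise MissingDataError("roster shares no staff types with the requirement table")
    df = pd.DataFrame(
        [(r.staff_type, r.employed, r.required, r.sar, r.shortfall) for r in rows],
        columns=["staff_type", "employed", "required", "sar", "shortfall"],
    )
    total_emp = df["employed"].sum()
    total_req = df["required"].sum()
    agg = total_emp / total_req
    df.loc[len(df)] = ["ALL", total_emp, total_req, agg, max(0.0, 1.0 - agg)]
    return df
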