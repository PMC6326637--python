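"""CSV readers/writers and report renderers.

Long-format CSV is canonical for every schema; the wide "published-table"
renderings (integer census table, one-decimal flow table, national
requirement table) are produced only for reports and are never parsed back,
so no consumer ever reads a rounded number.
"""
from __future__ import annotations

from pathlib import Path

import pandas as pd

from ._rounding import round_half_up
from .categories import CATEGORIES, PAIRS
from .errors import SchemaError
from .estimation import FacilityPanel
from .projection import (ConstructionSchedule, FacilityCensus, FlowTable,
                         PopulationSeries, TransitionTable)
from .staffing import (EmploymentRoster, RequirementTable, StaffingNorms,
                       WorkloadChange)

__all__ = [
    "read_baseline_census", "read_transition_table", "read_construction",
    "read_population", "read_norms", "read_workload_change", "read_roster",
    "read_panel", "write_census", "write_transition_table", "write_requirements",
    "write_panel", "render_census_national", "render_flows",
    "render_requirements_national",
]


def _read_csv(path: str | Path, required: list[str], numeric: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise SchemaError("file not found", path=str(path))
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # malformed CSV
        raise SchemaError(f"could not parse CSV: {exc}", path=str(path)) from exc
    missing = set(required) - set(df.columns)
    if missing:
        raise SchemaError(f"missing columns {sorted(missing)}", path=str(path))
    for col in numeric:
        coerced = pd.to_numeric(df[col], errors="coerce")
        if coerced.isna().any() and not df[col].isna().any():
            row = int(coerced.index[coerced.isna()][0])
            raise SchemaError(
                f"non-numeric value {df[col][row]!r}", path=str(path),
                row=row + 2, column=col,  # +2: header line + 1-based
            )
        if coerced.isna().any():
            row = int(coerced.index[coerced.isna()][0])
            raise SchemaError("missing value", path=str(path), row=row + 2, column=col)
        df[col] = coerced
    return df


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_baseline_census(path: str | Path, baseline_year: int) -> FacilityCensus:
    """columns: region, category, count."""
    df = _read_csv(path, ["region", "category", "count"], ["count"])
    df = df.assign(year=baseline_year)
    return FacilityCensus.from_frame(df, baseline_year=baseline_year)


def read_census(path: str | Path, baseline_year: int) -> FacilityCensus:
    """columns: region, category, year, count (projected-census round trip)."""
    df = _read_csv(path, ["region", "category", "year", "count"], ["year", "count"])
    return FacilityCensus.from_frame(df, baseline_year=baseline_year)


def read_transition_table(path: str | Path) -> TransitionTable:
    """columns: from_category, to_category, probability, standard_error (10 rows)."""
    df = _read_csv(path, ["from_category", "to_category", "probability", "standard_error"],
                   ["probability", "standard_error"])
    entries = {
        (str(r.from_category), str(r.to_category)): (float(r.probability), float(r.standard_error))
        for r in df.itertuples(index=False)
    }
    return TransitionTable.from_pairs(entries)


def read_construction(path: str | Path) -> ConstructionSchedule:
    """columns: region, category, year, count."""
    df = _read_csv(path, ["region", "category", "year", "count"], ["year", "count"])
    return ConstructionSchedule.from_frame(df)


def read_population(path: str | Path, chps_divisor: float = 1500.0) -> PopulationSeries:
    """columns: region, year, population."""
    df = _read_csv(path, ["region", "year", "population"], ["year", "population"])
    return PopulationSeries.from_frame(df, chps_divisor=chps_divisor)


def read_norms(path: str | Path) -> StaffingNorms:
    """columns: staff_type, category, headcount."""
    df = _read_csv(path, ["staff_type", "category", "headcount"], ["headcount"])
    return StaffingNorms.from_frame(df)


def read_workload_change(path: str | Path) -> WorkloadChange:
    """columns: region, category, delta."""
    df = _read_csv(path, ["region", "category", "delta"], ["delta"])
    return WorkloadChange(
        {(str(r.region), str(r.category)): float(r.delta) for r in df.itertuples(index=False)}
    )


def read_roster(path: str | Path) -> EmploymentRoster:
    """columns: staff_type, employed."""
    df = _read_csv(path, ["staff_type", "employed"], ["employed"])
    return EmploymentRoster(
        {str(r.staff_type): int(r.employed) for r in df.itertuples(index=False)}
    )


def read_panel(path: str | Path) -> FacilityPanel:
    """columns: facility_id, year, category."""
    df = _read_csv(path, ["facility_id", "year", "category"], ["year"])
    return FacilityPanel(df)


# ---------------------------------------------------------------------------
# writers (long format, canonical)
# ---------------------------------------------------------------------------

def write_census(census: FacilityCensus, path: str | Path) -> None:
    census.to_frame().to_csv(path, index=False)


def write_transition_table(tp: TransitionTable, path: str | Path) -> None:
    tp.to_frame().to_csv(path, index=False)


def write_requirements(req: RequirementTable, path: str | Path) -> None:
    req.table.to_csv(path, index=False)


def write_panel(panel: FacilityPanel, path: str | Path) -> None:
    panel.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# report renderers (published-table shapes; render-only)
# ---------------------------------------------------------------------------

def render_census_national(census: FacilityCensus) -> pd.DataFrame:
    """Wide national census, categories as rows, years as columns, half-up ints.

    Mirrors the published facility-forecast table, including the primary
    (district) hospital subtotal and the grand total.
    """
    years = census.years
    data = {year: census.national(year) for year in years}
    wide = pd.DataFrame(data, index=list(CATEGORIES))
    out = wide.map(lambda x: int(round_half_up(x)))
    out.loc["Total primary hospitals"] = out.loc[["PHA", "PHB", "PHC", "PHD"]].sum()
    out.loc["Total facilities"] = out.loc[list(CATEGORIES)].sum()
    out.index.name = "category"
    return out


def render_flows(flows: FlowTable) -> pd.DataFrame:
    """Per-year transition flows at one decimal, plus the horizon-total row."""
    out = flows.flows.map(lambda x: round_half_up(x, 1))
    out.loc["Total"] = [round_half_up(v) for v in flows.totals]
    return out


def render_requirements_national(req: RequirementTable) -> pd.DataFrame:
    """National requirements, staff types as rows and years as columns, half-up ints."""
    nat = req.national()
    wide = nat.pivot(index="staff_type", columns="year", values="required")
    out = wide.map(lambda x: int(round_half_up(x)))
    out.loc["Total"] = out.sum()
    return out
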