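"""Estimation of upward transition probabilities from a facility panel.

The input is a longitudinal panel assigning each facility a workload
category per year.  For every adjacent pair ``r -> r+1`` the estimator pools
all observed year-to-year intervals: a facility-year in category ``r`` with
an observation the following year is "at risk", and counts as an event when
the following year's category is ``r + 1``.  The estimate is the pooled
binomial MLE ``n_events / n_at_risk`` with the binomial standard error
``sqrt(p_hat (1 - p_hat) / n_at_risk)``.

Facilities missing a year are censored for the affected intervals — no
interpolation.  Downward moves and jumps of more than one rung violate the
model's no-downgrade / one-rung assumption; by default they raise, but a
policy flag can drop the offending intervals instead.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .categories import CATEGORIES, N_CATEGORIES, PAIRS, as_category
from .errors import ValidationError
from .projection import TransitionTable

__all__ = ["FacilityPanel", "TransitionEstimate", "estimate_transitions"]

IrregularMovePolicy = Literal["reject", "drop", "count_adjacent"]


@dataclass
class FacilityPanel:
    """One record per facility-year: the facility's workload category that year."""

    records: pd.DataFrame  # columns facility_id, year, category

    def __post_init__(self):
        df = pd.DataFrame(self.records, columns=["facility_id", "year", "category"]).copy()
        if df.empty:
            raise ValidationError("facility panel is empty")
        df["facility_id"] = df["facility_id"].astype(str)
        df["year"] = df["year"].astype(int)
        rank_of = {code: r for r, code in enumerate(CATEGORIES)}
        ranks = df["category"].map(rank_of)
        if ranks.isna().any():
            bad = df.loc[ranks.isna(), "category"].iloc[0]
            raise ValidationError(
                f"unknown facility category {bad!r}; expected one of {', '.join(CATEGORIES)}"
            )
        df["rank"] = ranks.astype(int)
        df["category"] = df["category"].astype(str)
        if df.duplicated(["facility_id", "year"]).any():
            dup = df[df.duplicated(["facility_id", "year"])].iloc[0]
            raise ValidationError(
                f"duplicate facility-year record: {dup.facility_id!r}, {dup.year}"
            )
        self.records = df.sort_values(["facility_id", "year"], ignore_index=True)

    @classmethod
    def from_records(cls, rows: Iterable[tuple[str, int, str]]) -> "FacilityPanel":
        return cls(pd.DataFrame(rows, columns=["facility_id", "year", "category"]))

    @property
    def years(self) -> list[int]:
        return sorted(self.records["year"].unique().tolist())

    @property
    def n_facilities(self) -> int:
        return self.records["facility_id"].nunique()

    def to_frame(self) -> pd.DataFrame:
        return self.records[["facility_id", "year", "category"]].copy()


@dataclass(frozen=True)
class TransitionEstimate:
    """Pooled binomial estimate for one adjacent pair."""

    pair: tuple[str, str]
    p_hat: float
    se: float
    n_at_risk: int
    n_events: int
    sparse: bool = False  #: no at-risk facility-years observed for this pair

    def __post_init__(self):
        if not (0.0 <= self.p_hat <= 1.0):
            raise ValidationError(f"p_hat out of [0,1] for {self.pair}: {self.p_hat}")
        if self.n_events > self.n_at_risk:
            raise ValidationError(f"more events than at-risk for {self.pair}")


def estimate_transitions(
    panel: FacilityPanel,
    irregular_moves: IrregularMovePolicy = "reject",
) -> tuple[TransitionTable, list[TransitionEstimate]]:
    """Estimate the 10 adjacent-pair transition probabilities from a panel.

    Parameters
    ----------
    panel
        Facility-year category panel spanning at least two years.
    irregular_moves
        What to do with intervals whose rank change is negative or larger
        than +1: ``"reject"`` (default) raises, ``"drop"`` censors the
        interval, ``"count_adjacent"`` treats any upward jump as a single
        one-rung event.

    Returns
    -------
    (TransitionTable, list of TransitionEstimate)
        The table feeds directly into :func:`hwforecast.projection.project`;
        the estimate list carries denominators and event counts per pair.
        Pairs with no at-risk facility-years get ``p_hat = 0, se = 0`` and
        a ``sparse`` flag.
    """
    if irregular_moves not in ("reject", "drop", "count_adjacent"):
        raise ValidationError(f"unknown irregular-move policy {irregular_moves!r}")
    df = panel.records
    if len(panel.years) < 2:
        raise ValidationError("panel must span at least two years to observe transitions")

    # consecutive-year intervals within each facility
    same_fac = df["facility_id"].values[1:] == df["facility_id"].values[:-1]
    adjacent = df["year"].values[1:] == df["year"].values[:-1] + 1
    keep = same_fac & adjacent
    r_from = df["rank"].values[:-1][keep]
    r_to = df["rank"].values[1:][keep]

    delta = r_to - r_from
    irregular = (delta < 0) | (delta > 1)
    if irregular.any():
        if irregular_moves == "reject":
            i = int(np.flatnonzero(keep)[np.flatnonzero(irregular)[0]])
            raise ValidationError(
                "panel contains a non-adjacent category move "
                f"({df['category'].iloc[i]} -> {df['category'].iloc[i + 1]} for "
                f"facility {df['facility_id'].iloc[i]!r}); the ladder only allows "
                "one-rung upward moves. Use irregular_moves='drop' to censor them."
            )
        if irregular_moves == "drop":
            ok = (delta >= 0) & (delta <= 1)
            r_from, r_to, delta = r_from[ok], r_to[ok], delta[ok]
        else:  # count_adjacent: any upward jump counts as one upward event
            delta = np.clip(delta, None, 1)
            bad = delta < 0
            r_from, delta = r_from[~bad], delta[~bad]

    at_risk = np.bincount(r_from, minlength=N_CATEGORIES)[: N_CATEGORIES - 1]
    events = np.bincount(r_from[delta == 1], minlength=N_CATEGORIES)[: N_CATEGORIES - 1]

    p_hat = np.zeros(N_CATEGORIES - 1)
    se = np.zeros(N_CATEGORIES - 1)
    nz = at_risk > 0
    p_hat[nz] = events[nz] / at_risk[nz]
    se[nz] = np.sqrt(p_hat[nz] * (1.0 - p_hat[nz]) / at_risk[nz])

    estimates = [
        TransitionEstimate(
            pair=PAIRS[r],
            p_hat=float(p_hat[r]),
            se=float(se[r]),
            n_at_risk=int(at_risk[r]),
            n_events=int(events[r]),
            sparse=not bool(nz[r]),
        )
        for r in range(N_CATEGORIES - 1)
    ]
    return TransitionTable(p_hat, se), estimates


def estimates_to_frame(estimates: Sequence[TransitionEstimate]) -> pd.DataFrame:
    """Long table of per-pair estimates (transition-table schema + denominators)."""
    return pd.DataFrame(
        {
            "from_category": [e.pair[0] for e in estimates],
            "to_category": [e.pair[1] for e in estimates],
            "probability": [e.p_hat for e in estimates],
            "standard_error": [e.se for e in estimates],
            "n_at_risk": [e.n_at_risk for e in estimates],
            "n_events": [e.n_events for e in estimates],
            "sparse": [e.sparse for e in estimates],
        }
    )
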