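"""The facility workload ladder.

Ghana's Ministry of Health classifies publicly funded healthcare facilities
into an ordered ladder of workload categories, from community CHPS compounds
up to established teaching hospitals.  A facility whose utilisation grows may
be upgraded one rung; the model assumes no downgrades and no closures, so the
only permitted move from rank ``r`` is to rank ``r + 1`` and the top rung is
absorbing.
"""
from __future__ import annotations

import enum

from .errors import ValidationError

__all__ = ["FacilityCategory", "CATEGORIES", "PAIRS", "N_CATEGORIES", "as_category"]


class FacilityCategory(enum.Enum):
    """One rung of the 11-level workload ladder, ordered by rank."""

    CHPS = 0    #: community-based health planning and services compound
    HCA = 1     #: health centre, workload category A
    HCB = 2     #: health centre, workload category B
    PolyC = 3   #: polyclinic (urban health centre)
    PHA = 4     #: primary (district) hospital, category A
    PHB = 5     #: primary hospital, category B
    PHC = 6     #: primary hospital, category C
    PHD = 7     #: primary hospital, category D
    RH = 8      #: regional hospital
    EmTH = 9    #: emerging teaching hospital
    EsTH = 10   #: established teaching hospital (absorbing)

    @property
    def rank(self) -> int:
        return self.value

    @property
    def code(self) -> str:
        return self.name

    @property
    def is_absorbing(self) -> bool:
        return self is FacilityCategory.EsTH

    @property
    def successor(self) -> "FacilityCategory | None":
        """Next rung up, or ``None`` for the absorbing top category."""
        if self.is_absorbing:
            return None
        return FacilityCategory(self.value + 1)

    def __lt__(self, other: "FacilityCategory") -> bool:
        return self.value < other.value


#: Category codes in ladder order.
CATEGORIES: tuple[str, ...] = tuple(c.name for c in FacilityCategory)

#: The 10 adjacent (from, to) pairs along which upward transitions occur.
PAIRS: tuple[tuple[str, str], ...] = tuple(
    (CATEGORIES[r], CATEGORIES[r + 1]) for r in range(len(CATEGORIES) - 1)
)

N_CATEGORIES = len(CATEGORIES)


def as_category(value: "FacilityCategory | str") -> FacilityCategory:
    """Coerce a code string or enum member to a :class:`FacilityCategory`."""
    if isinstance(value, FacilityCategory):
        return value
    try:
        return FacilityCategory[str(value)]
    except KeyError:
        raise ValidationError(
            f"unknown facility category {value!r}; expected one of {', '.join(CATEGORIES)}"
        ) from None
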