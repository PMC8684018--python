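"""Stratification vocabulary: dietary factors, sex, race/ethnicity, age bands.

Every table in the pipeline is keyed by (factor, age band, sex, race).
``persons`` and ``all`` are pooled strata: they are computed by pooling
individual records, never by averaging sub-stratum summaries.
"""

from __future__ import annotations

import re
from enum import Enum
from functools import total_ordering

from pydantic import BaseModel


class Factor(str, Enum):
    """Dietary exposures with an established colorectal-cancer dose-response."""

    red_meat = "red_meat"
    processed_meat = "processed_meat"
    fiber = "fiber"
    calcium = "calcium"


class Sex(str, Enum):
    men = "men"
    women = "women"
    persons = "persons"  # pooled


class Race(str, Enum):
    nh_white = "nh_white"
    nh_black = "nh_black"
    hispanic = "hispanic"
    other = "other"
    all = "all"  # pooled


class Unit(str, Enum):
    g_per_day = "g_per_day"
    mg_per_day = "mg_per_day"


class Direction(str, Enum):
    detrimental = "detrimental"  # consumption above the reference raises risk
    protective = "protective"  # intake below the reference raises risk


#: Unit each factor is measured in throughout the pipeline (never converted).
FACTOR_UNITS: dict[Factor, Unit] = {
    Factor.red_meat: Unit.g_per_day,
    Factor.processed_meat: Unit.g_per_day,
    Factor.fiber: Unit.g_per_day,
    Factor.calcium: Unit.mg_per_day,
}

_BAND_RE = re.compile(r"^(\d+)(?:-(\d+)|\+)$")


@total_ordering
class AgeBand:
    """A closed age interval like ``"25-34"``, or open-ended like ``"70+"``.

    Ordered by lower bound; equality is by the normalized label.
    """

    __slots__ = ("lo", "hi")

    def __init__(self, label: str):
        m = _BAND_RE.match(str(label).strip())
        if not m:
            raise ValueError(f"unparseable age band {label!r}; expected 'LO-HI' or 'LO+'")
        self.lo = int(m.group(1))
        self.hi = int(m.group(2)) if m.group(2) is not None else None
        if self.hi is not None and self.hi < self.lo:
            raise ValueError(f"age band {label!r} has upper bound below lower bound")

    @property
    def label(self) -> str:
        return f"{self.lo}+" if self.hi is None else f"{self.lo}-{self.hi}"

    @property
    def open_ended(self) -> bool:
        return self.hi is None

    def __contains__(self, age: int) -> bool:
        return age >= self.lo and (self.hi is None or age <= self.hi)

    def __eq__(self, other) -> bool:
        other = other if isinstance(other, AgeBand) else AgeBand(other)
        return (self.lo, self.hi) == (other.lo, other.hi)

    def __lt__(self, other) -> bool:
        other = other if isinstance(other, AgeBand) else AgeBand(other)
        return self.lo < other.lo

    def __hash__(self) -> int:
        return hash((self.lo, self.hi))

    def __repr__(self) -> str:
        return f"AgeBand({self.label!r})"


def check_bands(labels: list[str]) -> list[AgeBand]:
    """Parse an ordered band set, requiring non-overlapping ascending bands."""
    bands = [AgeBand(b) for b in labels]
    for a, b in zip(bands, bands[1:]):
        if a.open_ended or b.lo <= (a.hi if a.hi is not None else b.lo):
            raise ValueError(f"age bands {a.label!r} and {b.label!r} overlap or are out of order")
    return bands


#: Exposure-side bands (dietary-recall data stop at 69 for the meats).
DEFAULT_PREVALENCE_BANDS = ["18-24", "25-34", "35-44", "45-54", "55-59", "60-69"]
#: Incidence-side bands, one latency offset (10 y) older; 70+ is open-ended.
DEFAULT_INCIDENCE_BANDS = ["25-34", "35-44", "45-54", "55-64", "65-69", "70+"]


class StratumKey(BaseModel, frozen=True):
    """Population cell: age band x sex x race/ethnicity.

    ``sex=persons`` / ``race=all`` denote pooled cells; ``age_band`` may be
    ``"all"`` for age-aggregated results.
    """

    age_band: str
    sex: Sex
    race: Race

    def __str__(self) -> str:
        return f"{self.age_band}/{self.sex.value}/{self.race.value}"

    def matches_record(self, rec_band: str, rec_sex: Sex, rec_race: Race) -> bool:
        """Does an individual record (with concrete sex/race) fall in this cell?"""
        if self.age_band != "all" and AgeBand(self.age_band) != AgeBand(rec_band):
            return False
        if self.sex is not Sex.persons and self.sex is not rec_sex:
            return False
        if self.race is not Race.all and self.race is not rec_race:
            return False
        return True
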