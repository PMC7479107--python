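"""Per-species sensitivity (SS) and conservation value (VS).

Sensitivity sums four groups of subscores, each with a printed ceiling:

* morphological (max 1): body-size class — small birds and bats resist
  blade turbulence least, so small scores highest;
* ethological (max 4.5): seasonality, phenology, flight height relative
  to the turbine risk zones, flight type, flock size;
* historical (max 2): prior collision record in monitoring studies;
* demographic (max 2.5): K/R strategy plus the species' frequency and
  abundance shares in the community survey.

SS is at most 10.  The species value VS (max 10) is the Red-Book threat
value (Critical 9 ... not threatened 1) plus one point for species with
management, hunting or other socioeconomic interest.

Bats are scored through the same trait schema; size class ``small`` is
the expected choice for them but is not forced.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Union

from .errors import DomainError, ValidationError
from .turbine_geometry import RiskZones

SIZE_CLASSES = ("small", "medium", "large")
PERIODS = ("breeding", "winter", "passage")
FLIGHT_TYPES = ("direct", "indirect")
FLOCK_CLASSES = ("1", "2-5", "6-10", ">10")
COLLISION_RECORDS = ("usual", "medium", "scarce", "none")
STRATEGIES = ("K", "R")
REDBOOK_CATEGORIES = ("CR", "E", "V", "NT", "DD", "LC", "NE", "NC")

#: Monthly increment of the seasonality subscore (12 months is
#: special-cased to exactly 1.0 for sedentary species).
MONTH_VALUE = 0.083

_SIZE_SCORES = {"small": 1.0, "medium": 0.75, "large": 0.5}
_PERIOD_SCORES = {"breeding": 0.75, "passage": 0.5, "winter": 0.25}
_FLIGHT_TYPE_SCORES = {"direct": 0.25, "indirect": 0.5}
_FLOCK_SCORES = {"1": 0.25, "2-5": 0.5, "6-10": 0.75, ">10": 1.0}
_COLLISION_SCORES = {"usual": 2.0, "medium": 1.0, "scarce": 0.5, "none": 0.0}
_STRATEGY_SCORES = {"K": 0.5, "R": 0.2}

#: Red-Book threat categories mapped to conservation value.
REDBOOK_VALUES = {
    "CR": 9.0,  # critically endangered
    "E": 8.0,   # endangered
    "V": 6.0,   # vulnerable
    "NT": 4.0,  # near threatened
    "DD": 2.0,  # data deficient
    "LC": 1.0,  # not threatened
    "NE": 1.0,  # not evaluated
    "NC": 1.0,  # not catalogued
}

#: Zone values for flight height (Zone I below rotor, Zone II rotor-swept,
#: Zone III above).
ZONE_VALUES = (0.5, 1.0, 0.0)


@dataclass(frozen=True)
class SpeciesTraits:
    """The trait inputs the sensitivity and value scores depend on.

    Attributes
    ----------
    name:
        Species identifier (scientific or common name).
    size_class:
        ``small`` (up to a turtledove), ``medium`` (turtledove to heron)
        or ``large`` (above a heron).
    months_present:
        Number of months per year the species is detected (0-12).
    periods:
        Phenological periods of presence, subset of
        ``{breeding, winter, passage}``.
    flight_height_m:
        Typical flight height: a single height or an ``(low, high)``
        interval in metres.
    modal_flight_height_m:
        Optional most-frequent flight height; when given it overrides
        the interval rule when scoring flight height.
    flight_type:
        ``direct`` (transiting) or ``indirect`` (cycloid/soaring, longer
        exposure).
    flock_class:
        ``1``, ``2-5``, ``6-10`` or ``>10`` individuals per group.
    collision_record:
        Prior collision record category, or ``None`` when a study
        percentage is supplied instead.
    collision_study_pct:
        Percentage of monitoring studies reporting collisions of this
        species; mapped to the categorical scale when no category is
        given.
    strategy:
        Reproductive strategy ``K`` (slow, survival-investing) or ``R``.
    redbook:
        Red-Book threat category (CR, E, V, NT, DD, LC, NE, NC).
    socioeconomic:
        Whether the species has management, hunting or cultural interest.
    """

    name: str
    size_class: str
    months_present: int
    periods: frozenset[str]
    flight_height_m: tuple[float, float]
    flight_type: str
    flock_class: str
    strategy: str
    redbook: str
    socioeconomic: bool = False
    collision_record: Optional[str] = None
    collision_study_pct: Optional[float] = None
    modal_flight_height_m: Optional[float] = None

    def __post_init__(self) -> None:
        if self.size_class not in _SIZE_SCORES:
            raise ValidationError(
                f"{self.name}: unknown size class {self.size_class!r} "
                f"(expected one of {SIZE_CLASSES})", code="invalid-category")
        if not 0 <= self.months_present <= 12:
            raise ValidationError(
                f"{self.name}: months_present must lie in [0, 12], got "
                f"{self.months_present}", code="invalid-value")
        if not self.periods <= frozenset(PERIODS):
            raise ValidationError(
                f"{self.name}: unknown phenological period(s) "
                f"{sorted(self.periods - frozenset(PERIODS))}",
                code="invalid-category")
        lo, hi = self.flight_height_m
        if lo < 0 or hi < lo:
            raise ValidationError(
                f"{self.name}: flight height interval must satisfy "
                f"0 <= low <= high, got {self.flight_height_m}",
                code="invalid-value")
        if (self.modal_flight_height_m is not None
                and self.modal_flight_height_m < 0):
            raise ValidationError(
                f"{self.name}: modal flight height must be >= 0",
                code="invalid-value")
        if self.flight_type not in _FLIGHT_TYPE_SCORES:
            raise ValidationError(
                f"{self.name}: unknown flight type {self.flight_type!r}",
                code="invalid-category")
        if self.flock_class not in _FLOCK_SCORES:
            raise ValidationError(
                f"{self.name}: unknown flock class {self.flock_class!r} "
                f"(expected one of {FLOCK_CLASSES})", code="invalid-category")
        if (self.collision_record is not None
                and self.collision_record not in _COLLISION_SCORES):
            raise ValidationError(
                f"{self.name}: unknown collision record "
                f"{self.collision_record!r}", code="invalid-category")
        if self.collision_study_pct is not None and not (
                0 <= self.collision_study_pct <= 100):
            raise DomainError(
                f"{self.name}: collision study percentage must lie in "
                f"[0, 100], got {self.collision_study_pct}")
        if self.strategy not in _STRATEGY_SCORES:
            raise ValidationError(
                f"{self.name}: unknown strategy {self.strategy!r} "
                f"(expected K or R)", code="invalid-category")
        if self.redbook not in REDBOOK_VALUES:
            raise ValidationError(
                f"{self.name}: unknown Red-Book category {self.redbook!r}",
                code="invalid-category")


@dataclass(frozen=True)
class CommunitySurvey:
    """Per-species presence and individual counts from a field survey.

    ``presence_counts[s]`` is the number of survey occasions on which
    species ``s`` was recorded; ``individual_counts[s]`` the total number
    of individuals counted.  Shares over the community totals feed the
    demographic subscore.
    """

    presence_counts: Mapping[str, int]
    individual_counts: Mapping[str, int]

    def __post_init__(self) -> None:
        if set(self.presence_counts) != set(self.individual_counts):
            raise ValidationError(
                "presence and individual tables must cover the same species",
                code="invalid-value")
        if any(v < 0 for v in self.presence_counts.values()) or any(
                v < 0 for v in self.individual_counts.values()):
            raise ValidationError("survey counts must be >= 0",
                                  code="invalid-value")
        if self.total_presences <= 0 or self.total_individuals <= 0:
            raise ValidationError(
                "survey must record at least one presence and one individual",
                code="empty-survey")

    @property
    def total_presences(self) -> int:
        return sum(self.presence_counts.values())

    @property
    def total_individuals(self) -> int:
        return sum(self.individual_counts.values())

    def presence_share(self, name: str) -> float:
        self._require(name)
        return self.presence_counts[name] / self.total_presences

    def individual_share(self, name: str) -> float:
        self._require(name)
        return self.individual_counts[name] / self.total_individuals

    def _require(self, name: str) -> None:
        if name not in self.presence_counts:
            raise ValidationError(
                f"species {name!r} is absent from the community survey",
                code="missing-species")


# ---------------------------------------------------------------------------
# morphological

def morphological_score(s: SpeciesTraits) -> float:
    """Body-size subscore: small 1, medium 0.75, large 0.5."""
    return _SIZE_SCORES[s.size_class]


# ---------------------------------------------------------------------------
# ethological

def seasonality_score(s: SpeciesTraits) -> float:
    """Months-of-presence subscore: 0.083 per month, exactly 1.0 for a
    sedentary species (12 months)."""
    if s.months_present == 12:
        return 1.0
    return s.months_present * MONTH_VALUE


def phenology_score(s: SpeciesTraits) -> float:
    """Period-of-presence subscore.

    Breeding-only 0.75, passage-only 0.5, winter-only 0.25; presence in
    two or more periods scores the maximum 1.0 (the species is exposed
    across the annual cycle); absence scores 0.
    """
    if len(s.periods) >= 2:
        return 1.0
    if not s.periods:
        return 0.0
    (period,) = s.periods
    return _PERIOD_SCORES[period]


def flight_height_score(s: SpeciesTraits, z: RiskZones) -> float:
    """Flight-height subscore against the turbine risk zones.

    The species' flight interval is intersected with the three strata and
    the highest zone value among non-empty intersections is returned
    (Zone I 0.5, Zone II 1, Zone III 0) — a deterministic, conservative
    reading of "the more frequent and riskier zone".  A modal height,
    when provided, overrides the interval and scores its containing zone.
    """
    if s.modal_flight_height_m is not None:
        point = s.modal_flight_height_m
        return ZONE_VALUES[_zone_of(point, z)]
    lo, hi = s.flight_height_m
    values = []
    if lo < z.zone1_top_m:              # overlaps Zone I
        values.append(ZONE_VALUES[0])
    if hi >= z.zone1_top_m and lo <= z.zone2_top_m:   # overlaps Zone II
        values.append(ZONE_VALUES[1])
    if hi > z.zone2_top_m:              # overlaps Zone III
        values.append(ZONE_VALUES[2])
    if not values:                      # degenerate point on a boundary
        values.append(ZONE_VALUES[_zone_of(lo, z)])
    return max(values)


def _zone_of(height: float, z: RiskZones) -> int:
    if height < 0:
        raise ValidationError(f"flight height must be >= 0, got {height}",
                              code="invalid-value")
    if height < z.zone1_top_m:
        return 0
    if height <= z.zone2_top_m:
        return 1
    return 2


def flight_type_score(s: SpeciesTraits) -> float:
    """Flight-style subscore: direct 0.25, indirect (cycloid/soaring) 0.5."""
    return _FLIGHT_TYPE_SCORES[s.flight_type]


def flock_score(s: SpeciesTraits) -> float:
    """Gregariousness subscore: 1 individual 0.25 up to >10 individuals 1.0."""
    return _FLOCK_SCORES[s.flock_class]


def ethological_score(s: SpeciesTraits, z: RiskZones) -> float:
    """Sum of the five ethological subscores (max 4.5)."""
    return (seasonality_score(s) + phenology_score(s)
            + flight_height_score(s, z) + flight_type_score(s)
            + flock_score(s))


# ---------------------------------------------------------------------------
# historical

def historical_score(s: SpeciesTraits) -> float:
    """Prior-collision subscore: usual 2, medium 1, scarce 0.5, none 0.

    A categorical record wins when both it and a study percentage are
    given.  Percentages map as: above 30% of studies -> usual; 15-30%
    (15 inclusive, 30 inclusive) -> medium; 1-15% -> scarce; below 1% ->
    none.
    """
    if s.collision_record is not None:
        return _COLLISION_SCORES[s.collision_record]
    pct = s.collision_study_pct
    if pct is None:
        return 0.0
    if pct > 30:
        return 2.0
    if pct > 15:
        return 1.0
    if pct >= 1:
        return 0.5
    return 0.0


# ---------------------------------------------------------------------------
# demographic

def demographic_score(s: SpeciesTraits, survey: CommunitySurvey) -> float:
    """Strategy value (K 0.5, R 0.2) plus the species' presence share and
    individual share of the community survey (max 2.5)."""
    return (_STRATEGY_SCORES[s.strategy]
            + survey.presence_share(s.name)
            + survey.individual_share(s.name))


# ---------------------------------------------------------------------------
# totals

def sensitivity(s: SpeciesTraits, z: RiskZones,
                survey: CommunitySurvey) -> float:
    """Species sensitivity SS: morphological + ethological + historical +
    demographic subscores, at most 10."""
    return (morphological_score(s) + ethological_score(s, z)
            + historical_score(s) + demographic_score(s, survey))


def species_value(s: SpeciesTraits) -> float:
    """Species value VS: Red-Book threat value plus 1 for socioeconomic
    interest, in [1, 10]."""
    return REDBOOK_VALUES[s.redbook] + (1.0 if s.socioeconomic else 0.0)


def subscores(s: SpeciesTraits, z: RiskZones,
              survey: CommunitySurvey) -> dict[str, float]:
    """All eight SS subscores by name; their sum equals :func:`sensitivity`."""
    return {
        "morphological": morphological_score(s),
        "seasonality": seasonality_score(s),
        "phenology": phenology_score(s),
        "flight_height": flight_height_score(s, z),
        "flight_type": flight_type_score(s),
        "flock": flock_score(s),
        "historical": historical_score(s),
        "demographic": demographic_score(s, survey),
    }
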