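"""Farm-level value VWF, location value UF and the wind-farm constant WF.

The farm value VWF compares the summed hazard incidence of all turbines
with the frontal area the farm occupies, adjusted for the number of rows
a crossing bird must negotiate:

    VWF = (sum_i N_i * WT_i / AWF) ** (1 / F)

where ``N_i`` is the count of turbines of type ``i``, ``WT_i`` their
per-turbine incidence, ``AWF`` the frontal ("vertical rectangle") area in
square metres and ``F`` the number of rows.  The incidence quotient is
capped at 1 before the root — the hazard area cannot exceed the area the
farm occupies — so VWF lies in (0, 1].

The location value UF sums four context subscores, each capped at 0.25:
visibility (fog-day frequency), proximity to sensitive areas, presence
on a migratory pass, and proximity to neighbouring farms.  UF lies in
[0, 1], and the wind-farm constant WF = VWF + UF in (0, 2].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .errors import DomainError, GeometryError, ValidationError
from .turbine_geometry import TurbineSpec, turbine_incidence

#: Ceiling shared by the four location subscores.
COMPONENT_MAX = 0.25


@dataclass(frozen=True)
class FarmDescriptor:
    """Layout of a wind farm: turbine types and counts, rows, frontal area.

    Heterogeneous farms are supported: ``turbines`` pairs each distinct
    turbine model with its count.  ``frontal_area_m2`` (AWF) is the area
    of the vertical rectangle spanned by each row, summed over rows;
    it may be given directly or computed with :func:`frontal_area_from_rows`.
    """

    turbines: tuple[tuple[TurbineSpec, int], ...]
    rows: int
    frontal_area_m2: float

    def __post_init__(self) -> None:
        if not self.turbines:
            raise ValidationError("farm needs at least one turbine type",
                                  code="missing-field")
        total = sum(n for _, n in self.turbines)
        if total < 1 or any(n < 1 for _, n in self.turbines):
            raise ValidationError(
                f"turbine counts must be positive integers (total {total})",
                code="invalid-value")
        if self.rows < 1:
            raise ValidationError(f"rows must be >= 1, got {self.rows}",
                                  code="invalid-value")
        if not self.frontal_area_m2 > 0:
            raise GeometryError(
                f"frontal_area_m2 must be > 0, got {self.frontal_area_m2}")

    @property
    def turbine_count(self) -> int:
        return sum(n for _, n in self.turbines)


def frontal_area_from_rows(row_widths_m: Sequence[float],
                           turbine: TurbineSpec) -> float:
    """AWF from per-row widths: each row contributes width x (L + r),
    the height of the tallest point of the rotor."""
    height = turbine.tower_height_m + turbine.blade_length_m
    if any(w <= 0 for w in row_widths_m):
        raise ValidationError("row widths must be positive",
                              code="invalid-value")
    return float(sum(w * height for w in row_widths_m))


@dataclass(frozen=True)
class LocationContext:
    """Environmental context of the farm site.

    Attributes
    ----------
    low_visibility_days, observation_days:
        Fog / low-visibility day count out of the total observation days.
    sensitive_area_distance_km:
        Distance to the nearest sensitive area (breeding, feeding,
        roosting concentration or protected site); ``None`` when no such
        area is relevant.
    on_migratory_pass:
        Whether the farm sits on a daily or migratory movement corridor.
    neighbour_farm_distances_km:
        Distances to other wind farms in the area (synergistic barrier
        effect); empty when the farm stands alone.
    """

    low_visibility_days: int = 0
    observation_days: int = 1
    sensitive_area_distance_km: Optional[float] = None
    on_migratory_pass: bool = False
    neighbour_farm_distances_km: tuple[float, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.observation_days < 1:
            raise ValidationError(
                f"observation_days must be >= 1, got {self.observation_days}",
                code="invalid-value")
        if not 0 <= self.low_visibility_days <= self.observation_days:
            raise ValidationError(
                f"low_visibility_days must lie in [0, observation_days], "
                f"got {self.low_visibility_days}/{self.observation_days}",
                code="invalid-value")
        d = self.sensitive_area_distance_km
        if d is not None and d < 0:
            raise ValidationError(
                f"sensitive_area_distance_km must be >= 0, got {d}",
                code="negative-distance")
        if any(x < 0 for x in self.neighbour_farm_distances_km):
            raise ValidationError("neighbour farm distances must be >= 0",
                                  code="negative-distance")


def farm_value(f: FarmDescriptor) -> float:
    """Farm value VWF in (0, 1].

    Sums count x incidence over turbine types, divides by the frontal
    area, caps the quotient at 1, and takes the F-th root.  More rows
    push the value toward 1 (a multi-row farm is harder to cross).
    """
    incidence = sum(n * turbine_incidence(t) for t, n in f.turbines)
    quotient = incidence / f.frontal_area_m2
    quotient = min(quotient, 1.0)
    return quotient ** (1.0 / f.rows)


def visibility_score(c: LocationContext) -> float:
    """VI: fraction of low-visibility days, capped at 0.25."""
    return min(c.low_visibility_days / c.observation_days, COMPONENT_MAX)


def sensitive_area_score(c: LocationContext) -> float:
    """ZS: 0.25 below 10 km, 0.15 from 10 to 50 km, 0 beyond (or absent).

    Boundary distances fall in the lower-risk bin (exactly 10 km scores
    0.15, exactly 50 km scores 0.15).
    """
    d = c.sensitive_area_distance_km
    if d is None:
        return 0.0
    if d < 0:
        raise ValidationError(f"distance must be >= 0, got {d}",
                              code="negative-distance")
    if d < 10:
        return 0.25
    if d <= 50:
        return 0.15
    return 0.0


def migratory_pass_score(c: LocationContext) -> float:
    """MP: 0.25 on a migratory pass, otherwise 0."""
    return COMPONENT_MAX if c.on_migratory_pass else 0.0


def _pwf_bin(d: float) -> float:
    # boundary distances fall in the farther (lower-risk) bin
    if d < 3:
        return 0.25
    if d < 5:
        return 0.15
    if d < 10:
        return 0.10
    return 0.0


def neighbour_farm_score(c: LocationContext) -> float:
    """PWF: nearest neighbouring farm binned (<3 km 0.25, 3-5 km 0.15,
    5-10 km 0.10, beyond 0); every additional farm within 10 km adds its
    bin value again; the total is capped at the component ceiling 0.25
    so the location value UF can never exceed 1."""
    if not c.neighbour_farm_distances_km:
        return 0.0
    ordered = sorted(c.neighbour_farm_distances_km)
    total = sum(_pwf_bin(d) for d in ordered)
    return min(total, COMPONENT_MAX)


def location_value(c: LocationContext) -> float:
    """UF = VI + ZS + MP + PWF, in [0, 1] by construction."""
    return (visibility_score(c) + sensitive_area_score(c)
            + migratory_pass_score(c) + neighbour_farm_score(c))


def wf_constant(f: FarmDescriptor, c: LocationContext) -> float:
    """Wind-farm constant WF = VWF + UF, the farm-level multiplier in (0, 2]."""
    wf = farm_value(f) + location_value(c)
    if not 0 < wf <= 2 + 1e-12:
        raise DomainError(f"wind-farm constant out of range (0, 2]: {wf}")
    return wf
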