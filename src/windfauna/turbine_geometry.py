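"""Single-turbine hazard geometry and vertical risk zones.

A turbine's hazard footprint is modelled as a closed-form frontal area:
the disc swept by the rotor, plus the triangle the blades sketch against
the ground when they lean 60 degrees off the support tower, minus the
overlap of the two figures.  Scaling that area by a logarithmic
blade-rotation score yields the *turbine incidence* used by the
farm-level aggregation.

The same dimensions partition the air column into three vertical strata:
below the rotor (Zone I), the rotor-swept band (Zone II, highest
collision risk) and above the rotor (Zone III).

Notation: ``r`` is the blade length, ``L`` the tower (hub) height, both
in metres; ``SB`` the rotor speed in revolutions per minute.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

from .errors import DomainError, GeometryError

logger = logging.getLogger(__name__)

#: Base of the logarithm in the blade-rotation score.  Base 10 keeps the
#: score in a narrow band (1–2.3 for realistic 1–20 rpm rotors).
LOG_BASE = 10.0

_SIN60 = math.sqrt(3.0) / 2.0
_COS60 = 0.5


@dataclass(frozen=True)
class TurbineSpec:
    """Dimensions and rotation speed of one turbine model.

    Attributes
    ----------
    blade_length_m:
        Rotor blade length ``r`` in metres (rotor radius); > 0.
    tower_height_m:
        Support-tower (hub) height ``L`` in metres; must exceed the blade
        length so the rotor clears the ground.
    rotor_speed_rpm:
        Rotor speed ``SB`` in revolutions per minute; > 0.
    """

    blade_length_m: float
    tower_height_m: float
    rotor_speed_rpm: float

    def __post_init__(self) -> None:
        if not self.blade_length_m > 0:
            raise GeometryError(
                f"blade_length_m must be > 0, got {self.blade_length_m}"
            )
        if not self.tower_height_m > self.blade_length_m:
            raise GeometryError(
                "tower_height_m must exceed blade_length_m so the rotor "
                f"clears the ground (L={self.tower_height_m}, "
                f"r={self.blade_length_m})"
            )
        if not self.rotor_speed_rpm > 0:
            raise DomainError(
                f"rotor_speed_rpm must be > 0, got {self.rotor_speed_rpm}"
            )


@dataclass(frozen=True)
class RiskZones:
    """Vertical collision-risk strata derived from turbine dimensions.

    Zone I spans ``[0, zone1_top_m)`` (below the rotor, value 0.5),
    Zone II spans ``[zone1_top_m, zone2_top_m]`` (rotor-swept, value 1)
    and Zone III is everything above (value 0).
    """

    zone1_top_m: float
    zone2_top_m: float

    def __post_init__(self) -> None:
        if not 0 < self.zone1_top_m < self.zone2_top_m:
            raise GeometryError(
                f"risk zones require 0 < zone1_top < zone2_top, got "
                f"({self.zone1_top_m}, {self.zone2_top_m})"
            )


def affected_area(t: TurbineSpec) -> float:
    """Frontal hazard area AFM of one turbine, in square metres.

    AFM = a + b - c with

    * ``a = pi * r**2`` — the rotor disc,
    * ``b = (sin60 * r) * (L - cos60 * r)`` — the blade-ground triangle at
      a 60-degree blade inclination,
    * ``c = pi * r**2 / 3 - (sin60 * r) * (cos60 * r)`` — the overlap of
      disc and triangle.

    Strictly positive and strictly increasing in both ``r`` and ``L``.
    """
    r = t.blade_length_m
    L = t.tower_height_m
    a = math.pi * r * r
    b = (_SIN60 * r) * (L - _COS60 * r)
    c = (math.pi * r * r / 3.0) - (_SIN60 * r) * (_COS60 * r)
    return a + b - c


def blade_rotation_score(t: TurbineSpec) -> float:
    """Dimensionless rotation score BRS = 1 + log10(SB).

    The collision hazard of rotation grows sub-linearly in rotor speed:
    past a moderate speed the blades are effectively a moving wall, so a
    logarithmic ramp is used.  Speeds below 1 rpm give a score below 1
    (damping the area); this is allowed but logged, as working rotors
    turn at 1 rpm or more.
    """
    sb = t.rotor_speed_rpm
    if not sb > 0:
        raise DomainError(f"rotor speed must be > 0, got {sb}")
    if sb < 1:
        logger.warning(
            "rotor speed %.3g rpm is below 1; blade rotation score will "
            "damp the affected area", sb,
        )
    return 1.0 + math.log(sb, LOG_BASE)


def turbine_incidence(t: TurbineSpec) -> float:
    """Per-turbine incidence WT = AFM * BRS (area-weighted hazard)."""
    return affected_area(t) * blade_rotation_score(t)


def risk_zones(t: TurbineSpec) -> RiskZones:
    """Vertical risk strata for this turbine.

    Zone I ends at ``L - r`` (bottom of the rotor) and Zone II at
    ``L + r`` (top of the rotor); the band width is always the rotor
    diameter ``2r``.
    """
    return RiskZones(
        zone1_top_m=t.tower_height_m - t.blade_length_m,
        zone2_top_m=t.tower_height_m + t.blade_length_m,
    )
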