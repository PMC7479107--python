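"""Affection index, sensitivity classes and the weighted species ranking.

The per-species affection index is

    AS_i = WF * (SS_i + VS_i)

with WF the wind-farm constant (0, 2], SS the species sensitivity
(0, 10] and VS the species value [1, 10]; AS lies on a nominal 1-40
scale.  Total Valuation maps AS to four sensitivity classes (low,
sensitive, very sensitive, extremely sensitive); Weighted Valuation
rescales the community so the most affected species scores exactly 1.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .errors import DomainError, ValidationError
from .farm_constant import (FarmDescriptor, LocationContext, farm_value,
                            location_value)
from .species_scoring import (CommunitySurvey, SpeciesTraits, sensitivity,
                              species_value, subscores)
from .turbine_geometry import risk_zones

logger = logging.getLogger(__name__)

#: Version stamp written into every report document.
SCHEMA_VERSION = "1.0"

#: Class boundaries: upper bound of classes I-IV.  Intervals are half-open
#: at the lower printed bound — (0, 5] is Class I, (5, 10] Class II,
#: (10, 20] Class III, (20, 40] Class IV — so every value in (0, 40]
#: receives exactly one class.
CLASS_BOUNDS = ((5.0, "I"), (10.0, "II"), (20.0, "III"), (40.0, "IV"))

CLASS_LABELS = {
    "I": "low sensitivity",
    "II": "sensitive",
    "III": "very sensitive",
    "IV": "extremely sensitive",
}


def affection(wf: float, ss: float, vs: float) -> float:
    """Affection index AS = WF * (SS + VS), at most 40."""
    if not 0 < wf <= 2:
        raise DomainError(f"wind-farm constant must lie in (0, 2], got {wf}")
    if not 0 < ss <= 10:
        raise DomainError(f"sensitivity must lie in (0, 10], got {ss}")
    if not 1 <= vs <= 10:
        raise DomainError(f"species value must lie in [1, 10], got {vs}")
    return wf * (ss + vs)


def classify(as_value: float) -> str:
    """Sensitivity class for an affection value.

    Returns "I" (low sensitivity) through "IV" (extremely sensitive).
    Values below the nominal floor of 1 are classified as Class I with a
    logged warning — the formula can produce them even though they are
    practically unreachable in the field.
    """
    if not as_value > 0:
        raise DomainError(f"affection value must be > 0, got {as_value}")
    if as_value > 40:
        raise DomainError(f"affection value must be <= 40, got {as_value}")
    if as_value < 1:
        logger.warning(
            "affection value %.4g is below the nominal scale floor of 1",
            as_value)
    for bound, label in CLASS_BOUNDS:
        if as_value <= bound:
            return label
    raise AssertionError("unreachable")  # pragma: no cover


def weighted_valuation(as_values: Sequence[float]) -> list[float]:
    """Weighted Valuation: each AS divided by the community maximum.

    The most affected species weighs exactly 1 (ties share it); the
    ranking is scale-free and order-preserving.
    """
    if len(as_values) == 0:
        raise ValidationError("weighted valuation needs at least one species",
                              code="empty-community")
    top = max(as_values)
    return [v / top for v in as_values]


@dataclass(frozen=True)
class SpeciesRecord:
    """One row of an assessment: all scores for one species."""

    name: str
    ss: float
    vs: float
    affection: float
    sensitivity_class: str
    weighted: float
    ss_subscores: dict[str, float]


@dataclass(frozen=True)
class AssessmentReport:
    """Community-level assessment: farm constants plus one record per species."""

    vwf: float
    uf: float
    wf: float
    records: tuple[SpeciesRecord, ...]
    schema_version: str = SCHEMA_VERSION

    def to_dict(self) -> dict:
        """Machine-readable document with all intermediate scores."""
        return {
            "schema_version": self.schema_version,
            "farm": {"vwf": self.vwf, "uf": self.uf, "wf": self.wf},
            "species": [
                {
                    "name": r.name,
                    "ss": r.ss,
                    "vs": r.vs,
                    "affection": r.affection,
                    "class": r.sensitivity_class,
                    "class_label": CLASS_LABELS[r.sensitivity_class],
                    "weighted": r.weighted,
                    "ss_subscores": dict(r.ss_subscores),
                }
                for r in self.records
            ],
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text + "\n")
        return text

    def to_frame(self) -> pd.DataFrame:
        """Summary table, one species per row; weights rounded to 3
        decimals for reading (the JSON document keeps full precision)."""
        return pd.DataFrame(
            {
                "species": [r.name for r in self.records],
                "SS": [r.ss for r in self.records],
                "VS": [r.vs for r in self.records],
                "AS": [r.affection for r in self.records],
                "class": [r.sensitivity_class for r in self.records],
                "weighted": [round(r.weighted, 3) for r in self.records],
            }
        )

    def to_csv(self, path) -> None:
        frame = self.to_frame()
        frame.insert(0, "schema_version", self.schema_version)
        frame.to_csv(path, index=False)


def assess_community(farm: FarmDescriptor, context: LocationContext,
                     species: Iterable[SpeciesTraits],
                     survey: CommunitySurvey) -> AssessmentReport:
    """Assess every species of a community against one wind farm.

    Farm-level constants are computed once; each species is scored
    against the risk zones of every turbine type in the farm, taking the
    highest flight-height exposure (for a homogeneous farm this is just
    its single zone set).  Errors are re-raised with the offending
    species named.
    """
    species = list(species)
    if not species:
        raise ValidationError("assessment needs at least one species",
                              code="empty-community")
    vwf = farm_value(farm)
    uf = location_value(context)
    wf = vwf + uf
    zone_sets = [risk_zones(t) for t, _ in farm.turbines]

    names, ss_list, vs_list, as_list, sub_list = [], [], [], [], []
    for s in species:
        try:
            per_zone = [(sensitivity(s, z, survey), subscores(s, z, survey))
                        for z in zone_sets]
            ss, sub = max(per_zone, key=lambda p: p[0])
            vs = species_value(s)
            as_value = affection(wf, ss, vs)
        except (DomainError, ValidationError) as exc:
            raise type(exc)(f"species {s.name!r}: {exc}") from exc
        names.append(s.name)
        ss_list.append(ss)
        vs_list.append(vs)
        as_list.append(as_value)
        sub_list.append(sub)

    weights = weighted_valuation(as_list)
    records = tuple(
        SpeciesRecord(
            name=n, ss=ss, vs=vs, affection=a,
            sensitivity_class=classify(a), weighted=w, ss_subscores=sub,
        )
        for n, ss, vs, a, w, sub in zip(
            names, ss_list, vs_list, as_list, weights, sub_list)
    )
    return AssessmentReport(vwf=vwf, uf=uf, wf=wf, records=records)
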