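"""Seeded synthetic fixtures: farms, communities and surveys.

The generator emulates a temperate onshore wind farm and the mixed bird
and bat community a pre-construction survey would record there: modern
utility-scale turbines (blades 20-60 m, hub heights comfortably above
the rotor radius, 5-20 rpm), farms of a handful of rows, and species
whose traits are drawn independently from realistic category
frequencies (mostly small passerine-like species, few large soaring
ones; a small minority of threatened Red-Book categories).

All randomness funnels through one :class:`numpy.random.Generator`
seeded from :class:`FixtureSpec`; the scoring pipeline itself is fully
deterministic, so a fixed seed yields byte-identical fixture files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ValidationError
from .farm_constant import FarmDescriptor, LocationContext
from .io import save_farm, save_species_table, save_survey
from .species_scoring import (COLLISION_RECORDS, FLOCK_CLASSES,
                              REDBOOK_CATEGORIES, SIZE_CLASSES, STRATEGIES,
                              CommunitySurvey, SpeciesTraits)
from .turbine_geometry import TurbineSpec

_PERIOD_SETS = (
    frozenset({"breeding"}),
    frozenset({"winter"}),
    frozenset({"passage"}),
    frozenset({"breeding", "winter"}),
    frozenset({"breeding", "passage"}),
    frozenset({"winter", "passage"}),
    frozenset({"breeding", "winter", "passage"}),
)


def _check_probs(name: str, probs, categories) -> np.ndarray:
    p = np.asarray(probs, dtype=float)
    if len(p) != len(categories) or (p < 0).any() or not np.isclose(
            p.sum(), 1.0):
        raise ValidationError(
            f"{name}: probabilities must be non-negative, one per "
            f"category, and sum to 1", code="invalid-value")
    return p


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a synthetic study.

    Ranges are inclusive; ``tower_margin_m`` bounds how far above the
    blade length the hub sits, keeping the L > r invariant by
    construction.  Category probabilities reflect a typical temperate
    community: passerine-dominated, few large soaring species, threat
    categories dominated by least-concern.
    """

    seed: int = 0
    n_species: int = 20
    blade_length_range_m: tuple[float, float] = (20.0, 60.0)
    tower_margin_m: tuple[float, float] = (10.0, 80.0)
    rotor_speed_range_rpm: tuple[float, float] = (5.0, 20.0)
    n_turbines_range: tuple[int, int] = (5, 30)
    rows_range: tuple[int, int] = (1, 4)
    turbine_spacing_m: float = 200.0
    presences_per_species: tuple[int, int] = (1, 60)
    individuals_per_presence: tuple[int, int] = (1, 8)
    size_probs: tuple[float, ...] = (0.6, 0.25, 0.15)
    period_probs: tuple[float, ...] = (0.25, 0.1, 0.25, 0.15, 0.1, 0.05, 0.1)
    flight_type_probs: tuple[float, ...] = (0.55, 0.45)
    flock_probs: tuple[float, ...] = (0.45, 0.3, 0.15, 0.1)
    collision_probs: tuple[float, ...] = (0.05, 0.15, 0.3, 0.5)
    strategy_probs: tuple[float, ...] = (0.35, 0.65)
    redbook_probs: tuple[float, ...] = (
        0.02, 0.03, 0.08, 0.12, 0.05, 0.55, 0.1, 0.05)
    socioeconomic_prob: float = 0.2

    def __post_init__(self) -> None:
        if self.n_species < 1:
            raise ValidationError("n_species must be >= 1",
                                  code="invalid-value")
        for name, rng in (("blade_length_range_m", self.blade_length_range_m),
                          ("tower_margin_m", self.tower_margin_m),
                          ("rotor_speed_range_rpm",
                           self.rotor_speed_range_rpm),
                          ("n_turbines_range", self.n_turbines_range),
                          ("rows_range", self.rows_range),
                          ("presences_per_species",
                           self.presences_per_species),
                          ("individuals_per_presence",
                           self.individuals_per_presence)):
            lo, hi = rng
            if not (0 < lo <= hi):
                raise ValidationError(f"{name}: infeasible range {rng}",
                                      code="invalid-value")
        _check_probs("size_probs", self.size_probs, SIZE_CLASSES)
        _check_probs("period_probs", self.period_probs, _PERIOD_SETS)
        _check_probs("flight_type_probs", self.flight_type_probs,
                     ("direct", "indirect"))
        _check_probs("flock_probs", self.flock_probs, FLOCK_CLASSES)
        _check_probs("collision_probs", self.collision_probs,
                     COLLISION_RECORDS)
        _check_probs("strategy_probs", self.strategy_probs, STRATEGIES)
        _check_probs("redbook_probs", self.redbook_probs, REDBOOK_CATEGORIES)


def generate_farm(spec: FixtureSpec,
                  rng: np.random.Generator) -> tuple[FarmDescriptor,
                                                     LocationContext]:
    """Draw one farm layout and its location context."""
    r = rng.uniform(*spec.blade_length_range_m)
    L = r + rng.uniform(*spec.tower_margin_m)
    sb = rng.uniform(*spec.rotor_speed_range_rpm)
    turbine = TurbineSpec(blade_length_m=round(r, 1),
                          tower_height_m=round(L, 1),
                          rotor_speed_rpm=round(sb, 1))
    n = int(rng.integers(spec.n_turbines_range[0],
                         spec.n_turbines_range[1] + 1))
    rows = int(rng.integers(spec.rows_range[0], spec.rows_range[1] + 1))
    rows = min(rows, n)
    per_row = -(-n // rows)  # ceil
    width = per_row * spec.turbine_spacing_m
    height = turbine.tower_height_m + turbine.blade_length_m
    farm = FarmDescriptor(turbines=((turbine, n),), rows=rows,
                          frontal_area_m2=rows * width * height)

    obs = 360
    context = LocationContext(
        low_visibility_days=int(rng.integers(0, 120)),
        observation_days=obs,
        sensitive_area_distance_km=(
            float(round(rng.uniform(0, 80), 1))
            if rng.random() < 0.7 else None),
        on_migratory_pass=bool(rng.random() < 0.3),
        neighbour_farm_distances_km=tuple(
            round(float(d), 1)
            for d in rng.uniform(1, 30, size=rng.integers(0, 4))),
    )
    return farm, context


def generate_species(spec: FixtureSpec, rng: np.random.Generator,
                     max_height_m: float = 400.0) -> list[SpeciesTraits]:
    """Draw a community of species-trait records (``sp001`` ...)."""
    species = []
    for i in range(spec.n_species):
        lo = float(rng.uniform(0, max_height_m * 0.8))
        hi = lo + float(rng.uniform(0, max_height_m - lo))
        period_set = _PERIOD_SETS[rng.choice(len(_PERIOD_SETS),
                                             p=spec.period_probs)]
        months = int(rng.integers(1, 13))
        if period_set == frozenset(PERIOD_ALL):
            months = 12
        species.append(SpeciesTraits(
            name=f"sp{i + 1:03d}",
            size_class=str(rng.choice(SIZE_CLASSES, p=spec.size_probs)),
            months_present=months,
            periods=period_set,
            flight_height_m=(round(lo, 1), round(hi, 1)),
            flight_type=str(rng.choice(("direct", "indirect"),
                                       p=spec.flight_type_probs)),
            flock_class=str(rng.choice(FLOCK_CLASSES, p=spec.flock_probs)),
            collision_record=str(rng.choice(COLLISION_RECORDS,
                                            p=spec.collision_probs)),
            strategy=str(rng.choice(STRATEGIES, p=spec.strategy_probs)),
            redbook=str(rng.choice(REDBOOK_CATEGORIES,
                                   p=spec.redbook_probs)),
            socioeconomic=bool(rng.random() < spec.socioeconomic_prob),
        ))
    return species


PERIOD_ALL = ("breeding", "winter", "passage")


def generate_survey(spec: FixtureSpec, species,
                    rng: np.random.Generator) -> CommunitySurvey:
    """Draw a survey covering every species (at least one presence each)."""
    presences = {}
    individuals = {}
    for s in species:
        p = int(rng.integers(spec.presences_per_species[0],
                             spec.presences_per_species[1] + 1))
        k = int(rng.integers(spec.individuals_per_presence[0],
                             spec.individuals_per_presence[1] + 1))
        presences[s.name] = p
        individuals[s.name] = p * k
    return CommunitySurvey(presence_counts=presences,
                           individual_counts=individuals)


def generate_community(spec: FixtureSpec):
    """One complete synthetic study: (farm, context, species, survey)."""
    rng = np.random.default_rng(spec.seed)
    farm, context = generate_farm(spec, rng)
    species = generate_species(spec, rng)
    survey = generate_survey(spec, species, rng)
    return farm, context, species, survey


def write_fixtures(spec: FixtureSpec, out_dir) -> dict[str, Path]:
    """Generate a study and write farm.yaml, species.csv and survey.csv.

    Returns the paths written; a fixed :class:`FixtureSpec` produces
    byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    farm, context, species, survey = generate_community(spec)
    paths = {
        "farm": out / "farm.yaml",
        "species": out / "species.csv",
        "survey": out / "survey.csv",
    }
    save_farm(farm, context, paths["farm"])
    save_species_table(species, paths["species"])
    save_survey(survey, paths["survey"])
    return paths
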