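"""Shared fixtures: the worked-example farm, community and survey."""

from importlib import resources

import pytest

from windfauna import (CommunitySurvey, FarmDescriptor, LocationContext,
                       SpeciesTraits, TurbineSpec, risk_zones)

DATA = resources.files("windfauna").joinpath("data")


@pytest.fixture
def turbine():
    """Worked-example turbine: 40 m blades, 80 m tower, 10 rpm."""
    return TurbineSpec(blade_length_m=40, tower_height_m=80,
                       rotor_speed_rpm=10)


@pytest.fixture
def zones(turbine):
    return risk_zones(turbine)


@pytest.fixture
def farm(turbine):
    """Ten worked-example turbines in one 2000 m row (AWF = 240000 m2)."""
    return FarmDescriptor(turbines=((turbine, 10),), rows=1,
                          frontal_area_m2=240_000)


@pytest.fixture
def context():
    """36/360 fog days, sensitive area at 30 km, on a migratory pass,
    one neighbouring farm at 7 km: UF = 0.10 + 0.15 + 0.25 + 0.10."""
    return LocationContext(
        low_visibility_days=36,
        observation_days=360,
        sensitive_area_distance_km=30,
        on_migratory_pass=True,
        neighbour_farm_distances_km=(7.0,),
    )


@pytest.fixture
def kestrel():
    """Worked-example species: every subscore known in closed form."""
    return SpeciesTraits(
        name="Falco naumanni",
        size_class="small",
        months_present=6,
        periods=frozenset({"breeding"}),
        flight_height_m=(50.0, 90.0),
        flight_type="indirect",
        flock_class="2-5",
        collision_record="scarce",
        strategy="K",
        redbook="V",
        socioeconomic=True,
    )


@pytest.fixture
def survey():
    """Community totals of 100 presences / 100 individuals; the worked
    species holds shares 0.3 and 0.2."""
    return CommunitySurvey(
        presence_counts={"Falco naumanni": 30, "Gyps fulvus": 50,
                         "Turdus merula": 20},
        individual_counts={"Falco naumanni": 20, "Gyps fulvus": 30,
                           "Turdus merula": 50},
    )


def maximal_species(name="maximal", survey_name=None):
    """A species with every sensitivity and value component at its
    category maximum (used by several test modules)."""
    return SpeciesTraits(
        name=survey_name or name,
        size_class="small",
        months_present=12,
        periods=frozenset({"breeding", "winter"}),
        flight_height_m=(60.0, 60.0),   # rotor-swept for the fixture turbine
        flight_type="indirect",
        flock_class=">10",
        collision_record="usual",
        strategy="K",
        redbook="CR",
        socioeconomic=True,
    )


def solo_survey(name):
    """A survey in which ``name`` is the only species (both shares = 1)."""
    return CommunitySurvey(presence_counts={name: 10},
                           individual_counts={name: 40})
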