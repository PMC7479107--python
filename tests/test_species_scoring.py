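"""Species sensitivity subscores, their ceilings, and the value score."""

import dataclasses

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from windfauna import (CommunitySurvey, DomainError, RiskZones,
                       SpeciesTraits, ValidationError, demographic_score,
                       ethological_score, flight_height_score,
                       flight_type_score, flock_score, historical_score,
                       morphological_score, phenology_score,
                       seasonality_score, sensitivity, species_value,
                       subscores)
from conftest import maximal_species, solo_survey


def make_species(**overrides):
    base = dict(
        name="sp", size_class="small", months_present=6,
        periods=frozenset({"breeding"}), flight_height_m=(50.0, 90.0),
        flight_type="indirect", flock_class="2-5",
        collision_record="scarce", strategy="K", redbook="V",
        socioeconomic=False,
    )
    base.update(overrides)
    return SpeciesTraits(**base)


species_strategy = st.builds(
    make_species,
    size_class=st.sampled_from(["small", "medium", "large"]),
    months_present=st.integers(min_value=0, max_value=12),
    periods=st.sets(st.sampled_from(["breeding", "winter", "passage"])).map(
        frozenset),
    flight_height_m=st.tuples(
        st.floats(min_value=0, max_value=300),
        st.floats(min_value=0, max_value=300),
    ).map(lambda p: (min(p), max(p))),
    flight_type=st.sampled_from(["direct", "indirect"]),
    flock_class=st.sampled_from(["1", "2-5", "6-10", ">10"]),
    collision_record=st.sampled_from(["usual", "medium", "scarce", "none"]),
    strategy=st.sampled_from(["K", "R"]),
    redbook=st.sampled_from(["CR", "E", "V", "NT", "DD", "LC", "NE", "NC"]),
    socioeconomic=st.booleans(),
)


class TestCategoricalSubscores:
    @pytest.mark.parametrize("size, expected", [
        ("small", 1.0), ("medium", 0.75), ("large", 0.5)])
    def test_morphology(self, size, expected):
        assert morphological_score(make_species(size_class=size)) == expected

    def test_unknown_size_rejected(self):
        with pytest.raises(ValidationError):
            make_species(size_class="enormous")

    @pytest.mark.parametrize("months, expected", [
        (0, 0.0), (1, 0.083), (6, 0.498), (11, 0.913), (12, 1.0)])
    def test_seasonality(self, months, expected):
        assert seasonality_score(
            make_species(months_present=months)) == pytest.approx(expected)

    def test_sedentary_special_case_beats_per_month_rate(self):
        """12 x 0.083 would be 0.996; the sedentary case is exactly 1."""
        assert seasonality_score(make_species(months_present=12)) == 1.0

    @pytest.mark.parametrize("periods, expected", [
        (frozenset(), 0.0),
        (frozenset({"breeding"}), 0.75),
        (frozenset({"passage"}), 0.5),
        (frozenset({"winter"}), 0.25),
        (frozenset({"breeding", "winter"}), 1.0),
        (frozenset({"winter", "passage"}), 1.0),
        (frozenset({"breeding", "winter", "passage"}), 1.0),
    ])
    def test_phenology(self, periods, expected):
        assert phenology_score(make_species(periods=periods)) == expected

    @pytest.mark.parametrize("ftype, expected", [
        ("direct", 0.25), ("indirect", 0.5)])
    def test_flight_type(self, ftype, expected):
        assert flight_type_score(make_species(flight_type=ftype)) == expected

    @pytest.mark.parametrize("flock, expected", [
        ("1", 0.25), ("2-5", 0.5), ("6-10", 0.75), (">10", 1.0)])
    def test_flock(self, flock, expected):
        assert flock_score(make_species(flock_class=flock)) == expected

    @pytest.mark.parametrize("record, expected", [
        ("usual", 2.0), ("medium", 1.0), ("scarce", 0.5), ("none", 0.0)])
    def test_historical_categorical(self, record, expected):
        assert historical_score(
            make_species(collision_record=record)) == expected

    @pytest.mark.parametrize("pct, expected", [
        (40, 2.0), (30.01, 2.0), (30, 1.0), (20, 1.0), (15, 0.5),
        (5, 0.5), (1, 0.5), (0.5, 0.0), (0, 0.0)])
    def test_historical_percentage_bins(self, pct, expected):
        s = make_species(collision_record=None, collision_study_pct=pct)
        assert historical_score(s) == expected

    def test_historical_categorical_overrides_percentage(self):
        s = make_species(collision_record="usual", collision_study_pct=2)
        assert historical_score(s) == 2.0

    def test_historical_percentage_out_of_range(self):
        with pytest.raises(DomainError):
            make_species(collision_record=None, collision_study_pct=120)


class TestFlightHeight:
    @pytest.mark.parametrize("height, expected", [
        ((60, 60), 1.0),    # rotor-swept
        ((10, 10), 0.5),    # below the rotor
        ((200, 200), 0.0),  # above the rotor
        ((40, 40), 1.0),    # bottom of the rotor band belongs to Zone II
        ((120, 120), 1.0),  # top of the band too
    ])
    def test_point_heights(self, zones, height, expected):
        s = make_species(flight_height_m=height)
        assert flight_height_score(s, zones) == expected

    @pytest.mark.parametrize("interval, expected", [
        ((0, 30), 0.5),      # entirely in Zone I
        ((0, 50), 1.0),      # spans into the rotor band: riskiest wins
        ((130, 400), 0.0),   # entirely above
        ((10, 400), 1.0),    # spans all three zones
    ])
    def test_interval_takes_riskiest_zone(self, zones, interval, expected):
        s = make_species(flight_height_m=interval)
        assert flight_height_score(s, zones) == expected

    def test_modal_height_overrides_interval(self, zones):
        s = make_species(flight_height_m=(0.0, 400.0),
                         modal_flight_height_m=10.0)
        assert flight_height_score(s, zones) == 0.5

    def test_negative_height_rejected(self):
        with pytest.raises(ValidationError):
            make_species(flight_height_m=(-5.0, 10.0))


class TestDemographic:
    def test_sole_species_reaches_ceiling(self):
        s = make_species(strategy="K")
        assert demographic_score(s, solo_survey("sp")) == pytest.approx(2.5)

    def test_share_arithmetic(self, survey):
        s = make_species(name="Falco naumanni", strategy="R")
        assert demographic_score(s, survey) == pytest.approx(
            0.2 + 0.3 + 0.2)

    def test_symmetric_species_score_equally(self):
        sv = CommunitySurvey(presence_counts={"a": 5, "b": 5},
                             individual_counts={"a": 7, "b": 7})
        sa = make_species(name="a")
        sb = make_species(name="b")
        assert demographic_score(sa, sv) == demographic_score(sb, sv)

    def test_absent_species_rejected(self, survey):
        with pytest.raises(ValidationError):
            demographic_score(make_species(name="ghost"), survey)

    def test_shares_sum_to_one(self, survey):
        assert sum(survey.presence_share(n)
                   for n in survey.presence_counts) == pytest.approx(1.0)
        assert sum(survey.individual_share(n)
                   for n in survey.individual_counts) == pytest.approx(1.0)


class TestSensitivity:
    def test_worked_example(self, zones, survey):
        """Componentwise: 1 + 0.498 + 0.75 + 1 + 0.5 + 0.5 + 0.5 +
        (0.5 + 0.3 + 0.2) = 5.748."""
        s = make_species(name="Falco naumanni")
        assert sensitivity(s, zones, survey) == pytest.approx(5.748)

    def test_maximal_species_reaches_ten(self, zones):
        s = maximal_species()
        assert sensitivity(s, zones, solo_survey(s.name)) == pytest.approx(
            10.0)

    def test_ethological_ceiling(self, zones):
        assert ethological_score(maximal_species(), zones) == pytest.approx(
            4.5)

    def test_subscores_sum_to_sensitivity(self, zones, survey):
        s = make_species(name="Falco naumanni")
        parts = subscores(s, zones, survey)
        assert len(parts) == 8
        assert sum(parts.values()) == pytest.approx(
            sensitivity(s, zones, survey))

    @given(species_strategy)
    @settings(max_examples=1000, deadline=None)
    def test_random_species_respect_ceilings(self, s):
        zones = RiskZones(40, 120)
        survey = solo_survey(s.name)
        parts = subscores(s, zones, survey)
        assert 0.5 <= parts["morphological"] <= 1
        assert 0 <= parts["seasonality"] <= 1
        assert 0 <= parts["phenology"] <= 1
        assert parts["flight_height"] in (0.0, 0.5, 1.0)
        assert parts["flight_type"] in (0.25, 0.5)
        assert 0.25 <= parts["flock"] <= 1
        assert 0 <= parts["historical"] <= 2
        assert 0 < parts["demographic"] <= 2.5
        assert sensitivity(s, zones, survey) <= 10
        assert 1 <= species_value(s) <= 10

    @pytest.mark.parametrize("field, worse", [
        ("size_class", "small"),
        ("flight_type", "indirect"),
        ("flock_class", ">10"),
        ("collision_record", "usual"),
        ("strategy", "K"),
        ("months_present", 12),
        ("periods", frozenset({"breeding", "winter"})),
    ])
    def test_monotone_in_risk_direction(self, zones, field, worse):
        """Moving any one trait to its highest-risk category never
        lowers the sensitivity score."""
        mid = make_species()
        bumped = dataclasses.replace(mid, **{field: worse})
        sv = solo_survey("sp")
        assert sensitivity(bumped, zones, sv) >= sensitivity(mid, zones, sv)


class TestSpeciesValue:
    @pytest.mark.parametrize("cat, expected", [
        ("CR", 9), ("E", 8), ("V", 6), ("NT", 4), ("DD", 2),
        ("LC", 1), ("NE", 1), ("NC", 1)])
    def test_redbook_table(self, cat, expected):
        assert species_value(make_species(redbook=cat)) == expected

    def test_socioeconomic_adds_one(self):
        assert species_value(
            make_species(redbook="V", socioeconomic=True)) == 7

    def test_unknown_category_rejected(self):
        with pytest.raises(ValidationError):
            make_species(redbook="EX")
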