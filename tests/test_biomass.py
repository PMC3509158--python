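import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_survey
from fallowfun import biomass
from fallowfun.errors import (
    InvalidArgumentError,
    MissingTraitError,
    UndefinedRatioError,
)


class TestAllometry:
    @pytest.mark.parametrize("dbh", [2.5, 5.0, 10.0, 25.0, 50.0])
    def test_matches_closed_form(self, dbh):
        expected = math.exp(-2.134 + 2.53 * math.log(dbh))
        got = biomass.allometric_tree_biomass_kg(dbh)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_intercept_isolated_at_unit_dbh(self):
        # ln(1) = 0 isolates the intercept; formula evaluated below its domain
        got = biomass.allometric_tree_biomass_kg(1.0, enforce_min=False)
        assert got == pytest.approx(math.exp(-2.134), rel=1e-12)

    def test_small_stems_rejected(self):
        with pytest.raises(InvalidArgumentError):
            biomass.allometric_tree_biomass_kg(1.0)
        with pytest.raises(InvalidArgumentError):
            biomass.allometric_tree_biomass_kg(-3.0, enforce_min=False)

    @given(st.floats(min_value=2.5, max_value=49.0), st.floats(min_value=0.01, max_value=1.0))
    @settings(max_examples=50, deadline=None)
    def test_strictly_increasing(self, dbh, step):
        assert biomass.allometric_tree_biomass_kg(dbh + step) > biomass.allometric_tree_biomass_kg(dbh)


class TestCoverClass:
    @pytest.mark.parametrize(
        "cls,mid", [(1, 0.025), (2, 0.095), (3, 0.275), (4, 0.525), (5, 0.825)]
    )
    def test_midpoints(self, cls, mid):
        assert biomass.cover_class_midpoint(cls) == pytest.approx(mid)

    @pytest.mark.parametrize("bad", [0, 6, -1, "a"])
    def test_out_of_scale(self, bad):
        with pytest.raises(InvalidArgumentError):
            biomass.cover_class_midpoint(bad)


class TestBiovolumePath:
    def test_unit_arithmetic(self, simple_traits):
        # 10 m^3 x 2 kg/m^3 on a 100 m^2 plot = 20 kg/plot = 2.0 t/ha
        rec = pd.Series({"species_id": "grass1", "biovolume_m3": 10.0})
        out = biomass.biovolume_to_biomass(rec, simple_traits)
        assert out["aboveground_t_ha"] == pytest.approx(2.0)
        assert out["green_t_ha"] == pytest.approx(2.0 * 0.85)

    def test_zero_biovolume(self, simple_traits):
        rec = pd.Series({"species_id": "grass1", "biovolume_m3": 0.0})
        assert biomass.biovolume_to_biomass(rec, simple_traits).sum() == 0.0

    def test_unknown_species_named(self, simple_traits):
        rec = pd.Series({"species_id": "ghost", "biovolume_m3": 1.0})
        with pytest.raises(MissingTraitError, match="ghost"):
            biomass.biovolume_to_biomass(rec, simple_traits)


class TestForageQuality:
    def test_ratio_rule(self, simple_traits):
        # N=2, lignin=10: CP = 12.5, ratio 1.25
        assert biomass.is_quality_forage(simple_traits.loc["grass1"])
        # N=0.8, lignin=10: ratio 0.5
        assert not biomass.is_quality_forage(simple_traits.loc["poorgrass"])

    def test_boundary_inclusive(self):
        row = pd.Series({"n_pct": 1.28, "lignin_pct": 10.0}, name="edge")
        assert 6.25 * 1.28 / 10.0 == pytest.approx(0.8)
        assert biomass.is_quality_forage(row)

    def test_zero_lignin(self):
        row = pd.Series({"n_pct": 1.0, "lignin_pct": 0.0}, name="x")
        with pytest.raises(UndefinedRatioError):
            biomass.is_quality_forage(row)


class TestWoodAndForageFunctions:
    def test_herb_only_plot_has_no_wood(self, simple_traits):
        survey = make_survey([("p", "grass1", "herb", 0.4, 2, [], 5.0)])
        assert biomass.wood_biomass(survey, simple_traits) == 0.0

    def test_single_tree_chain(self, simple_traits):
        survey = make_survey([("p", "tree1", "tree", 5.0, 3, [10.0], 0.0)])
        expected = math.exp(-2.134 + 2.53 * math.log(10.0)) * 0.65 * 0.1
        assert biomass.wood_biomass(survey, simple_traits) == pytest.approx(expected)

    def test_short_woody_excluded_from_wood(self, simple_traits):
        survey = make_survey([("p", "shrub1", "shrub", 0.5, 2, [], 4.0)])
        assert biomass.wood_biomass(survey, simple_traits) == 0.0
        # ...but its green biomass is forage (shrub1 qualifies: ratio 0.94)
        assert biomass.forage_biomass(survey, simple_traits) > 0.0

    def test_forage_quality_filter(self, simple_traits):
        good = make_survey([("p", "grass1", "herb", 0.4, 2, [], 10.0)])
        bad = make_survey([("p", "poorgrass", "herb", 0.4, 2, [], 10.0)])
        assert biomass.forage_biomass(good, simple_traits) == pytest.approx(2.0 * 0.85)
        assert biomass.forage_biomass(bad, simple_traits) == 0.0

    def test_tall_tree_never_forage(self, simple_traits):
        survey = make_survey(
            [
                ("p", "grass1", "herb", 0.4, 2, [], 10.0 / (2.0 * 0.85)),  # 1.0 t/ha green... scaled below
                ("p", "tree1", "tree", 6.0, 3, [15.0], 2.0),
            ]
        )
        forage = biomass.forage_biomass(survey, simple_traits)
        grass_only = biomass.forage_biomass(survey.iloc[[0]], simple_traits)
        assert forage == pytest.approx(grass_only)

    def test_wood_forage_partition(self, default_dataset):
        """No species' biomass is counted in both functions within a plot."""
        traits = default_dataset.traits
        for _, grp in default_dataset.survey.groupby("plot_id"):
            for _, rec in grp.iterrows():
                wood_side = biomass._is_wood_esp(rec["growth_form"], rec["avg_height_m"])
                forage_side = biomass._is_forage_candidate(rec["growth_form"], rec["avg_height_m"])
                assert not (wood_side and forage_side)

    def test_permutation_invariance_and_scaling(self, simple_traits):
        survey = make_survey(
            [
                ("p", "tree1", "tree", 5.0, 3, [10.0, 12.0], 1.0),
                ("p", "shrub1", "shrub", 1.5, 2, [], 4.0),
                ("p", "grass1", "herb", 0.4, 2, [], 6.0),
            ]
        )
        shuffled = survey.iloc[[2, 0, 1]].reset_index(drop=True)
        assert biomass.wood_biomass(survey, simple_traits) == pytest.approx(
            biomass.wood_biomass(shuffled, simple_traits)
        )
        scaled = survey.copy()
        scaled["biovolume_m3"] = scaled["biovolume_m3"] * 3.0
        no_stems = survey.copy()
        no_stems["dbh_cm"] = [[] for _ in range(3)]
        no_stems_scaled = scaled.copy()
        no_stems_scaled["dbh_cm"] = [[] for _ in range(3)]
        assert biomass.wood_biomass(no_stems_scaled, simple_traits) == pytest.approx(
            3.0 * biomass.wood_biomass(no_stems, simple_traits)
        )

    def test_green_plus_woody_bounded_by_aboveground(self, default_dataset):
        per = biomass.species_biomass(default_dataset.survey, default_dataset.traits)
        assert (
            per["green_t_ha"] + per["woody_t_ha"] <= per["aboveground_t_ha"] + 1e-9
        ).all()
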