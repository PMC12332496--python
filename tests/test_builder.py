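"""The unit-construction cascade and the end-to-end build."""

import pytest
from shapely.geometry import LineString, MultiPolygon, box

from geoschemes.builder import (
    BuildConfig,
    EEZClaim,
    ProvinceTemplate,
    SourceLayers,
    adjust_higher_levels,
    build_highseas_units,
    build_world,
    choose_rule,
    draft_regions_from_boundaries,
    split_discontinuous,
)
from geoschemes.geometry import DepthField, GeoConfig, geodesic_area
from geoschemes.registry import ancestor_chain, level_counts, validate_registry
from geoschemes.synthworld import world_build_config


def _layers(threshold=2_000_000.0, regional=None):
    ocean = box(-60, -90, 120, 90)
    return SourceLayers(
        oceans=[("A", "Ocean", ocean)],
        eez_units=[],
        sea_areas=[("South Sea", ocean.intersection(box(-180, -90, 180, 20))),
                   ("North Sea", ocean.intersection(box(-180, 20, 180, 90)))],
        regional_schemes=regional or {},
        size_threshold_km2=threshold,
    )


class TestChooseRule:
    def test_small_single_sea_keeps_eez(self):
        d = choose_rule(box(0, 0, 5, 5), "BE", _layers())
        assert d.rule == "KEEP_EEZ"

    def test_small_two_sea_eez_splits_by_sea_area(self):
        d = choose_rule(box(0, 17, 6, 23), "CR", _layers())
        assert d.rule == "SPLIT_IHO"

    def test_oversized_single_sea_defaults_to_ecoregions(self):
        d = choose_rule(box(0, -45, 40, -20), "BR", _layers())
        assert d.rule == "SPLIT_MEOW"

    def test_oversized_with_regional_scheme_adopts_it(self):
        from geoschemes.builder import RegionalScheme

        regional = {"AU": RegionalScheme("IMCRA", [])}
        d = choose_rule(box(0, -45, 40, -20), "AU", _layers(regional=regional))
        assert d.rule == "SPLIT_REGIONAL"

    def test_unwanted_iho_flag_skips_the_sea_split(self):
        cfg = BuildConfig(unwanted_iho_split=frozenset({"EG"}))
        d = choose_rule(box(0, 17, 6, 23), "EG", _layers(), cfg)
        assert d.rule == "SPLIT_MEOW"

    def test_shrinking_threshold_never_restores_keep_eez(self):
        """Rule monotonicity: a smaller size threshold cannot turn any
        SPLIT_* decision back into KEEP_EEZ."""
        geoms = [box(0, 0, 5, 5), box(0, 17, 6, 23), box(0, -45, 40, -20)]
        for g in geoms:
            big = choose_rule(g, "XX", _layers(threshold=5e6)).rule
            small = choose_rule(g, "XX", _layers(threshold=5e5)).rule
            if big != "KEEP_EEZ":
                assert small != "KEEP_EEZ"


class TestSplitDiscontinuous:
    def test_single_part_is_identity(self):
        g = box(0, 0, 1, 1)
        assert split_discontinuous(g) == [g]

    def test_two_islands_give_two_parts(self):
        g = MultiPolygon([box(0, 0, 1, 1), box(5, 0, 6, 1)])
        parts = split_discontinuous(g)
        assert len(parts) == 2
        assert sum(geodesic_area(p) for p in parts) == pytest.approx(
            geodesic_area(g), rel=1e-12)

    def test_three_components_sorted_west_to_east(self):
        g = MultiPolygon([box(10, 0, 11, 1), box(0, 0, 1, 1), box(5, 0, 6, 1)])
        parts = split_discontinuous(g)
        assert [p.centroid.x for p in parts] == sorted(
            p.centroid.x for p in parts)
        assert len(parts) == 3

    def test_antimeridian_parts_are_one_component(self):
        g = MultiPolygon([box(176, -20, 180, -12), box(-180, -20, -176, -12)])
        assert len(split_discontinuous(g)) == 1


class TestHighSeas:
    def test_uniform_deep_world_yields_only_abyssal_units(self):
        hs = box(0, 0, 20, 10)
        units = build_highseas_units(
            hs, DepthField.uniform(5000.0),
            [ProvinceTemplate("West", box(0, 0, 10, 10)),
             ProvinceTemplate("East", box(10, 0, 20, 10))],
            {}, ocean_letter="A")
        assert [u.depth_class for u in units] == ["deep", "deep"]
        assert [u.sector_tag for u in units] == ["AB1", "AB2"]

    def test_ridge_splits_one_template_into_two_units(self):
        import numpy as np

        hs = box(0, 0, 20, 10)
        field = DepthField(lambda lon, lat: np.where(
            (np.asarray(lon) >= 4) & (np.asarray(lon) < 8), 2000.0, 5000.0))
        units = build_highseas_units(
            hs, field, [ProvinceTemplate("Only", box(0, 0, 20, 10))], {},
            ocean_letter="A")
        assert sorted(u.depth_class for u in units) == ["deep", "shallow"]

    def test_template_clipped_to_high_seas(self):
        hs = box(0, 0, 10, 10)        # EEZ occupies lon 10..20
        units = build_highseas_units(
            hs, DepthField.uniform(5000.0),
            [ProvinceTemplate("Wide", box(0, 0, 20, 10))], {},
            ocean_letter="A")
        assert len(units) == 1
        assert geodesic_area(units[0].geometry) == pytest.approx(
            geodesic_area(hs), rel=1e-9)

    def test_template_gap_is_an_error(self):
        from geoschemes.geometry import GeometryError

        with pytest.raises(GeometryError, match="tile"):
            build_highseas_units(
                box(0, 0, 20, 10), DepthField.uniform(5000.0),
                [ProvinceTemplate("Half", box(0, 0, 10, 10))], {},
                ocean_letter="A")


class TestAdjustHigherLevels:
    def test_majority_overlap_assigns_whole_unit(self):
        # draft boundary bisects the unit with 70% of its area on side A
        regions = [("RA", box(0, 0, 7, 10)), ("RB", box(7, 0, 20, 10))]
        keys, snapped = adjust_higher_levels([box(0, 0, 10, 10)], regions)
        assert keys == ["RA"]
        assert geodesic_area(snapped["RA"]) == pytest.approx(
            geodesic_area(box(0, 0, 10, 10)), rel=1e-9)

    def test_boundary_already_on_unit_edges_is_identity(self):
        regions = [("RA", box(0, 0, 1, 1)), ("RB", box(1, 0, 2, 1))]
        keys, snapped = adjust_higher_levels(
            [box(0, 0, 1, 1), box(1, 0, 2, 1)], regions)
        assert keys == ["RA", "RB"]

    def test_draft_regions_from_polylines(self):
        regions = draft_regions_from_boundaries(
            box(0, 0, 2, 2), [LineString([(1, -1), (1, 3)])])
        assert len(regions) == 2


class TestEndToEnd:
    def test_built_registry_matches_manifest_rows(self, world, built):
        _, _, manifest = world
        expected = manifest.registry()
        reg = built.registry
        assert sorted(reg.units) == sorted(expected.units)
        for code in expected.units:
            e, b = expected[code], reg[code]
            assert (e.label, e.level, e.parent_code, e.category,
                    e.source_scheme, e.country_iso) == \
                   (b.label, b.level, b.parent_code, b.category,
                    b.source_scheme, b.country_iso), code

    def test_built_geometry_matches_manifest_within_tolerance(self, world, built):
        _, _, manifest = world
        for code, expected_geom in manifest.expected_geometries.items():
            got = built.registry[code].geometry
            diff = geodesic_area(expected_geom.symmetric_difference(got))
            assert diff <= 1e-6 * max(manifest.expected_areas_km2[code], 1.0), code

    def test_built_registry_validates(self, built):
        report = validate_registry(built.registry)
        assert report.passed, [f.message for f in report.errors()]

    def test_decisions_match_manifest(self, world, built):
        _, _, manifest = world
        got = {}
        for d in built.decisions:
            got.setdefault(d.country_iso, set()).add(d.rule)
        for iso, rule in manifest.decisions.items():
            if iso == "ZZ":
                continue
            assert got[iso] == {rule}, iso

    def test_nesting_holds_at_every_level(self, built):
        from geoschemes.geometry import validate_nesting

        reg = built.registry
        for level in (1, 2, 3):
            for code in reg.codes(level):
                kids = reg.children_of(code)
                assert kids, code
                report = validate_nesting(
                    reg[code].geometry,
                    [reg[k].geometry for k in kids])
                assert report.passed, (code, report.findings)

    def test_census_identities(self, built):
        census = level_counts(built.registry)
        assert (census.coincident_pairs + census.l4_in_multi_child_l3
                == census.by_level[4])
        assert census.coincident_pairs + census.grouping_l3 == census.by_level[3]

    def test_build_is_deterministic(self, world, built):
        spec, layers, _ = world
        again = build_world(layers, world_build_config(spec))
        assert sorted(again.registry.units) == sorted(built.registry.units)
        for code in again.registry.units:
            a, b = again.registry[code], built.registry[code]
            assert a.label == b.label
            assert a.geometry.equals(b.geometry), code

    def test_overlap_claim_emits_exactly_one_extra_unit(self, built):
        overlap = [c for c in built.registry.codes(4)
                   if built.registry[c].category == "overlap_claim"]
        assert len(overlap) == 1
        assert built.registry[overlap[0]].country_iso == "ZZ"

    def test_two_ocean_country_has_one_unit_per_ocean(self, built):
        reg = built.registry
        tc = [c for c in reg.codes(4) if reg[c].country_iso == "TC"]
        oceans = {ancestor_chain(reg, c)[0] for c in tc}
        assert len(tc) == 2
        assert oceans == {"A", "P"}

    def test_empty_layers_build_empty_unit_list(self):
        from geoschemes.builder import build_coastal_units

        pieces, decisions = build_coastal_units(_layers())
        assert pieces == [] and decisions == []
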