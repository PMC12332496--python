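"""Registry loading, validation, census, queries and serialization."""

import pytest

from geoschemes.registry import (
    GeoUnit,
    RegistryError,
    ancestor_chain,
    level_counts,
    load_registry,
    query_units,
    read_csv,
    read_excel,
    read_json,
    validate_registry,
    write_csv,
    write_json,
)


def _rows(*tuples):
    cols = ("code", "label", "level", "parent", "category", "source_scheme",
            "country_iso")
    return [dict(zip(cols, t)) for t in tuples]


# A toy registry modelling the Costa-Rica situation: one country, one unit
# on each of two coasts.
CR_ROWS = _rows(
    ("A", "Atlantic Ocean", 1, None, "coastal", "ADHOC", None),
    ("P", "Pacific Ocean", 1, None, "coastal", "ADHOC", None),
    ("A1", "Atlantic – Caribbean coastal", 2, "A", "coastal", "ADHOC", None),
    ("P1", "Pacific – Eastern coastal", 2, "P", "coastal", "ADHOC", None),
    ("CR1", "Costa Rica (Caribbean)", 3, "A1", "coastal", "EEZ_IHO", None),
    ("CR2", "Costa Rica (Pacific)", 3, "P1", "coastal", "EEZ_IHO", None),
    ("CR1-OO", "Costa Rica – Caribbean Sea", 4, "CR1", "coastal", "EEZ_IHO", "CR"),
    ("CR2-OO", "Costa Rica – Pacific Ocean", 4, "CR2", "coastal", "EEZ_IHO", "CR"),
)


class TestLoad:
    def test_empty_rows_give_empty_registry(self):
        reg = load_registry([])
        assert len(reg) == 0
        assert level_counts(reg).by_level == {1: 0, 2: 0, 3: 0, 4: 0}

    def test_duplicate_code_is_a_hard_error(self):
        rows = _rows(("A", "x", 1, None, "coastal", "ADHOC", None),
                     ("A", "y", 1, None, "coastal", "ADHOC", None))
        with pytest.raises(RegistryError, match="duplicate.*'A'"):
            load_registry(rows)

    def test_missing_parent_is_a_hard_error(self):
        rows = _rows(("FR1", "France", 3, "A1", "coastal", "EEZ", "FR"))
        with pytest.raises(RegistryError, match="FR1.*A1"):
            load_registry(rows)

    def test_unparseable_code_names_the_row(self):
        rows = _rows(("A", "ok", 1, None, "coastal", "ADHOC", None),
                     ("NOT-A-CODE!", "bad", 4, None, "coastal", "EEZ", "XX"))
        with pytest.raises(RegistryError, match="row 1"):
            load_registry(rows)

    def test_column_mapping(self):
        rows = [{"Code": "A", "Name": "Atlantic", "Lvl": 1, "Above": None}]
        reg = load_registry(rows, column_map={"code": "Code", "label": "Name",
                                              "level": "Lvl", "parent": "Above"})
        assert reg["A"].label == "Atlantic"


class TestValidate:
    def test_clean_registry_passes(self):
        assert validate_registry(load_registry(CR_ROWS)).passed

    def test_single_child_without_oo_suffix_fails(self):
        rows = _rows(
            ("A", "x", 1, None, "coastal", "ADHOC", None),
            ("A1", "x", 2, "A", "coastal", "ADHOC", None),
            ("FR1", "France", 3, "A1", "coastal", "EEZ", "FR"),
            ("FR1-AA", "France – EEZ", 4, "FR1", "coastal", "EEZ", "FR"))
        report = validate_registry(load_registry(rows))
        assert not report.passed
        assert any(f.rule == "coincident-oo" and "-OO" in f.message
                   for f in report.errors())

    def test_oo_in_multi_child_group_fails(self):
        rows = _rows(
            ("A", "x", 1, None, "coastal", "ADHOC", None),
            ("A1", "x", 2, "A", "coastal", "ADHOC", None),
            ("FR1", "France", 3, "A1", "coastal", "EEZ", "FR"),
            ("FR1-OO", "a", 4, "FR1", "coastal", "EEZ", "FR"),
            ("FR1-AB", "b", 4, "FR1", "coastal", "EEZ", "FR"))
        assert not validate_registry(load_registry(rows)).passed

    def test_high_seas_unit_must_carry_qp(self):
        rows = _rows(
            ("A", "x", 1, None, "coastal", "ADHOC", None),
            ("A9", "High Seas", 2, "A", "high_seas", "GOODS", "QP"),
            ("A9A", "Province", 3, "A9", "high_seas", "GOODS", "QP"),
            ("A9A-OO", "AB1 – Basin", 4, "A9A", "high_seas", "GOODS", "FR"))
        report = validate_registry(load_registry(rows))
        assert any(f.rule == "high-seas-qp" and "QP" in f.message
                   for f in report.errors())

    def test_parent_level_mismatch_is_reported(self):
        rows = _rows(
            ("A", "x", 1, None, "coastal", "ADHOC", None),
            ("FR1", "France", 3, "A", "coastal", "EEZ", "FR"),
            ("FR1-OO", "u", 4, "FR1", "coastal", "EEZ", "FR"))
        report = validate_registry(load_registry(rows))
        assert any(f.rule == "parent-level" for f in report.errors())

    def test_terrestrial_collision_detected(self):
        report = validate_registry(load_registry(CR_ROWS),
                                   terrestrial_codes=["CR1", "FRA"])
        assert any(f.rule == "terrestrial-collision" for f in report.errors())


class TestCensus:
    def test_costa_rica_counts(self):
        census = level_counts(load_registry(CR_ROWS))
        assert census.by_level == {1: 2, 2: 2, 3: 2, 4: 2}
        assert census.coincident_pairs == 2
        assert census.l4_in_multi_child_l3 == 0

    def test_minimal_world_counts_match_manifest(self, minimal_world):
        _, _, manifest = minimal_world
        census = level_counts(manifest.registry())
        assert census.by_level == {1: 2, 2: 3, 3: 4, 4: 6}
        assert census.coincident_pairs == 2
        assert census.grouping_l3 == 2
        assert census.l4_in_multi_child_l3 == 4
        assert census.coincident_pairs + census.l4_in_multi_child_l3 == 6

    def test_default_world_census_is_consistent(self, world):
        _, _, manifest = world
        census = level_counts(manifest.registry())
        assert census.by_level == manifest.counts["by_level"]
        assert (census.coincident_pairs + census.l4_in_multi_child_l3
                == census.by_level[4])
        assert census.coincident_pairs + census.grouping_l3 == census.by_level[3]


class TestQuery:
    def test_country_filter_costa_rica(self):
        reg = load_registry(CR_ROWS)
        units = query_units(reg, country_iso="CR")
        assert [u.code for u in units] == ["CR1-OO", "CR2-OO"]

    def test_empty_filter_returns_all_sorted(self):
        reg = load_registry(CR_ROWS)
        assert [u.code for u in query_units(reg)] == sorted(
            r["code"] for r in CR_ROWS)

    def test_ancestor_filter_walks_primary_chain(self, world):
        _, _, manifest = world
        reg = manifest.registry()
        subtree = {u.code for u in query_units(reg, ancestor_code="A1")}
        assert subtree == {c for c in reg.units
                           if c != "A1" and "A1" in ancestor_chain(reg, c)}

    def test_unknown_ancestor_raises(self):
        with pytest.raises(KeyError):
            query_units(load_registry(CR_ROWS), ancestor_code="Z9")

    def test_unknown_filter_key_raises(self):
        with pytest.raises(ValueError):
            query_units(load_registry(CR_ROWS), colour="blue")


class TestAncestorChain:
    def test_level1_chain_is_single_element(self):
        assert ancestor_chain(load_registry(CR_ROWS), "A") == ["A"]

    def test_level4_chain_has_four_elements(self):
        assert ancestor_chain(load_registry(CR_ROWS), "CR1-OO") == \
            ["A", "A1", "CR1", "CR1-OO"]

    def test_chain_uses_primary_parent_only(self):
        rows = list(CR_ROWS)
        reg = load_registry(rows)
        reg["CR1-OO"].alt_parent_codes = ("P1",)
        assert ancestor_chain(reg, "CR1-OO") == ["A", "A1", "CR1", "CR1-OO"]

    def test_unknown_code_raises(self):
        with pytest.raises(KeyError):
            ancestor_chain(load_registry(CR_ROWS), "XX1")


class TestSerialization:
    def test_csv_roundtrip(self, tmp_path, world):
        _, _, manifest = world
        reg = manifest.registry()
        path = tmp_path / "registry.csv"
        write_csv(reg, path)
        back = read_csv(path)
        assert sorted(back.units) == sorted(reg.units)
        for code in reg.units:
            a, b = reg[code], back[code]
            assert (a.label, a.level, a.parent_code, a.category,
                    a.source_scheme, a.country_iso) == \
                   (b.label, b.level, b.parent_code, b.category,
                    b.source_scheme, b.country_iso)

    def test_json_roundtrip(self, tmp_path):
        reg = load_registry(CR_ROWS)
        path = tmp_path / "registry.json"
        write_json(reg, path)
        back = read_json(path)
        assert sorted(back.units) == sorted(reg.units)

    def test_excel_reader_with_column_map(self, tmp_path):
        import pandas as pd

        df = pd.DataFrame([
            {"Code": "A", "Label": "Atlantic", "Level": 1, "Parent": None},
            {"Code": "A1", "Label": "Sub", "Level": 2, "Parent": "A"},
        ])
        path = tmp_path / "table.xlsx"
        df.to_excel(path, index=False)
        reg = read_excel(path, column_map={"code": "Code", "label": "Label",
                                           "level": "Level", "parent": "Parent"})
        assert sorted(reg.units) == ["A", "A1"]


def test_geounit_rejects_unknown_category():
    with pytest.raises(RegistryError):
        GeoUnit(code="A", label="x", level=1, category="pelagic")
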