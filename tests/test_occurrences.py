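"""Occurrence reading, assignment and checklist roll-up."""

import io

import pytest

from geoschemes.occurrences import (
    assign,
    assign_all,
    build_checklist,
    checklist_report,
    checklist_report_csv,
    read_occurrences,
)
from geoschemes.registry import ancestor_chain
from geoschemes.synthworld import generate_occurrences


def _csv(text: str) -> io.StringIO:
    return io.StringIO(text.strip() + "\n")


HEADER = "occurrenceID,scientificName,decimalLatitude,decimalLongitude,countryCode,locality"


class TestReader:
    def test_mixed_rows_with_warning(self):
        records, issues = read_occurrences(_csv(f"""
{HEADER}
o1,Abyssina vulgaris,10.5,-127.0,,
o2,Abyssina vulgaris,,,AA,off Alphia
o3,Benthodora communis,,,,somewhere
"""))
        assert len(records) == 3
        assert len(issues.warnings) == 1 and "o3" in issues.warnings[0]
        assert issues.n_skipped == 0

    def test_out_of_range_latitude_rejected(self):
        records, issues = read_occurrences(_csv(f"""
{HEADER}
o1,Abyssina vulgaris,95.0,0.0,,
"""))
        assert records == []
        assert any("out of range" in e for e in issues.errors)

    def test_missing_name_skipped_and_counted(self):
        records, issues = read_occurrences(_csv(f"""
{HEADER}
o1,,10.0,0.0,,
o2,Abyssina vulgaris,15.0,-127.0,,
"""))
        assert [r.source_id for r in records] == ["o2"]
        assert issues.n_skipped == 1

    def test_generated_file_roundtrips(self, world):
        _, _, manifest = world
        occ, _ = generate_occurrences(manifest, 200, seed=7)
        buf = io.StringIO()
        occ.to_csv(buf, index=False)
        buf.seek(0)
        records, issues = read_occurrences(buf)
        assert len(records) == 200
        assert not issues.errors


@pytest.fixture(scope="module")
def reg(built):
    return built.registry


@pytest.fixture(scope="module")
def pipeline(built, world):
    _, _, manifest = world
    registry = built.registry
    occ, truth = generate_occurrences(manifest, 400, point_fraction=0.6,
                                      seed=3)
    buf = io.StringIO()
    occ.to_csv(buf, index=False)
    buf.seek(0)
    records, _ = read_occurrences(buf)
    lookup = {v: k for k, v in manifest.country_names.items()}
    return registry, assign_all(records, registry, lookup), truth, records


class TestAssign:
    def test_point_record_gets_unit_and_chain(self, reg):
        records, _ = read_occurrences(_csv(f"""
{HEADER}
o1,Abyssina vulgaris,15.0,-127.0,,
"""))
        a = assign(records[0], reg)
        assert a.kind == "point"
        assert a.l4_codes == ("AA1-OO",)
        assert len(a.chain) == 4
        assert a.chain == tuple(ancestor_chain(reg, "AA1-OO"))

    def test_country_record_is_imprecise_with_all_units(self, reg, world):
        _, _, manifest = world
        records, _ = read_occurrences(_csv(f"""
{HEADER}
o1,Abyssina vulgaris,,,TC,
"""))
        a = assign(records[0], reg)
        assert a.kind == "country_level"
        assert a.imprecise
        assert sorted(a.l4_codes) == manifest.country_l4["TC"]

    def test_country_name_resolves_through_lookup(self, reg, world):
        _, _, manifest = world
        records, _ = read_occurrences(_csv(f"""
{HEADER}
o1,Abyssina vulgaris,,,Twocean,
"""))
        lookup = {v: k for k, v in manifest.country_names.items()}
        a = assign(records[0], reg, lookup)
        assert a.kind == "country_level"
        a2 = assign(records[0], reg)    # no lookup: name cannot resolve
        assert a2.kind == "unresolvable"

    def test_coordinates_win_and_conflicts_are_flagged(self, reg):
        records, _ = read_occurrences(_csv(f"""
{HEADER}
o1,Abyssina vulgaris,15.0,-127.0,TC,
"""))
        a = assign(records[0], reg)
        assert a.kind == "point"
        assert "country_conflict" in a.flags

    def test_point_on_land_with_country_falls_back(self, reg):
        # inside a Scatteria island (a hole in the unit)
        records, _ = read_occurrences(_csv(f"""
{HEADER}
o1,Abyssina vulgaris,-7.0,3.0,SC,
o2,Abyssina vulgaris,-7.0,3.0,,
"""))
        a1, a2 = (assign(r, reg) for r in records)
        assert a1.kind == "country_level"
        assert "point_outside_units" in a1.flags
        assert a2.kind == "unresolvable"

    def test_seeded_records_reproduce_ground_truth(self, reg, world):
        """Mixed point/text records: assignments equal the generator's
        ground truth with zero mismatches."""
        _, _, manifest = world
        occ, truth = generate_occurrences(manifest, 500, point_fraction=0.7,
                                          seed=11)
        buf = io.StringIO()
        occ.to_csv(buf, index=False)
        buf.seek(0)
        records, _ = read_occurrences(buf)
        lookup = {v: k for k, v in manifest.country_names.items()}
        assignments = assign_all(records, reg, lookup)
        for a, (_, t) in zip(assignments, truth.iterrows()):
            want = tuple(sorted(t["codes"].split(";"))) if t["codes"] else ()
            assert a.kind == t["kind"], a.record.source_id
            assert tuple(sorted(a.l4_codes)) == want, a.record.source_id


class TestChecklist:
    def test_point_record_lists_taxon_once_per_level(self, built):
        reg = built.registry
        records, _ = read_occurrences(_csv(f"""
{HEADER}
o1,Abyssina vulgaris,15.0,-127.0,,
"""))
        assignments = assign_all(records, reg)
        for level in (1, 2, 3, 4):
            cl = build_checklist(assignments, reg, level)
            units = [c for c in cl if cl.taxa(c)]
            assert len(units) == 1
            assert cl[units[0]]["Abyssina vulgaris"].status == "confirmed"

    def test_country_record_is_imprecise_in_every_candidate(self, built):
        reg = built.registry
        records, _ = read_occurrences(_csv(f"""
{HEADER}
o1,Abyssina vulgaris,,,TC,
"""))
        cl = build_checklist(assign_all(records, reg), reg, 4)
        statuses = {c: cl[c]["Abyssina vulgaris"].status for c in cl}
        assert len(statuses) == 2
        assert set(statuses.values()) == {"imprecise"}

    def test_confirmed_wins_over_imprecise(self, built):
        reg = built.registry
        records, _ = read_occurrences(_csv(f"""
{HEADER}
o1,Abyssina vulgaris,15.0,-127.0,,
o2,Abyssina vulgaris,,,AA,
"""))
        cl = build_checklist(assign_all(records, reg), reg, 4)
        assert cl["AA1-OO"]["Abyssina vulgaris"].status == "confirmed"

    def test_rollup_equals_independent_set_union_oracle(self, pipeline, world):
        """Level-2 confirmed sets equal a union computed directly from the
        generator's truth table and the manifest's parent mapping."""
        _, _, manifest = world
        reg, assignments, truth, records = pipeline
        cl = build_checklist(assignments, reg, 2)
        parents = {r["code"]: r["parent"] for r in manifest.registry_rows}
        up = {c: parents[parents[c]] for c in manifest.l4_geometries}
        taxa_by_id = {r.source_id: r.taxon for r in records}
        expected: dict[str, set] = {}
        for _, t in truth.iterrows():
            if t["kind"] != "point":
                continue
            expected.setdefault(up[t["codes"]], set()).add(
                taxa_by_id[t["source_id"]])
        got = {c: cl.taxa(c, "confirmed") for c in cl}
        got = {c: s for c, s in got.items() if s}
        assert got == expected

    def test_rollup_monotonicity(self, pipeline):
        """For every taxon the number of listing units never grows when
        moving up a level, and each listing unit is an ancestor of a
        listing level-4 unit."""
        reg, assignments, _, _ = pipeline
        per_level = {lv: build_checklist(assignments, reg, lv)
                     for lv in (1, 2, 3, 4)}
        taxa = {t for cl in per_level.values() for c in cl for t in cl.taxa(c)}
        for taxon in taxa:
            counts = {}
            for lv in (1, 2, 3, 4):
                cl = per_level[lv]
                units = {c for c in cl
                         if taxon in cl.taxa(c, "confirmed")}
                counts[lv] = units
            for lv in (1, 2, 3):
                assert len(counts[lv]) <= len(counts[lv + 1])
                for unit in counts[lv]:
                    assert any(unit in ancestor_chain(reg, l4)
                               for l4 in counts[4])

    def test_permutation_invariance(self, pipeline):
        reg, assignments, _, _ = pipeline
        cl_fwd = build_checklist(assignments, reg, 3)
        cl_rev = build_checklist(list(reversed(assignments)), reg, 3)
        for code in set(cl_fwd) | set(cl_rev):
            assert checklist_report_csv(cl_fwd, code) == \
                checklist_report_csv(cl_rev, code)

    def test_report_is_sorted_and_deterministic(self, built):
        reg = built.registry
        records, _ = read_occurrences(_csv(f"""
{HEADER}
o1,Corallina profunda,15.0,-127.0,,
o2,Abyssina vulgaris,15.1,-127.1,,
o3,Benthodora communis,15.2,-127.2,,
"""))
        cl = build_checklist(assign_all(records, reg), reg, 4)
        df = checklist_report(cl, "AA1-OO")
        assert list(df["taxon"]) == sorted(df["taxon"])
        assert len(df) == 3

    def test_report_unknown_code_raises(self, built):
        cl = build_checklist([], built.registry, 4)
        with pytest.raises(KeyError):
            checklist_report(cl, "XX1-OO")

    def test_bad_level_raises(self, built):
        with pytest.raises(ValueError):
            build_checklist([], built.registry, 5)
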