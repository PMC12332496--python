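"""Assigning occurrence records to geounits and rolling up checklists.

Presence in a recording unit is existential, never universal: a taxon
listed for a unit occurs *somewhere* therein.  Coordinate records resolve
to a single basic recording unit (level 4) plus its ancestor chain; records
carrying only a country — the imprecise country-level data of the older
literature — resolve to the full set of that country's level-4 units and
are flagged imprecise.  Depth is carried through but deliberately not used
for assignment: the scheme records geography, not habitat.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import pandas as pd

from .geometry import locate_point
from .registry import Registry, ancestor_chain, query_units

_COLUMNS = ("occurrenceID", "scientificName", "decimalLatitude",
            "decimalLongitude", "countryCode", "locality")


@dataclass
class OccurrenceRecord:
    taxon: str
    lon: Optional[float] = None
    lat: Optional[float] = None
    depth_m: Optional[float] = None
    country_text: Optional[str] = None
    locality: Optional[str] = None
    source_id: str = ""


@dataclass
class ReadIssues:
    warnings: list[str] = field(default_factory=list)
    errors: list[str] = field(default_factory=list)

    @property
    def n_skipped(self) -> int:
        return len(self.errors)


def read_occurrences(path_or_buf) -> tuple[list[OccurrenceRecord], ReadIssues]:
    """Read Darwin Core-style occurrence rows from CSV.

    Rows without a scientific name, or with out-of-range coordinates, are
    skipped and counted as errors.  Rows with neither coordinates nor a
    country are kept with a warning (they will be unresolvable).
    """
    df = pd.read_csv(path_or_buf, dtype=str, keep_default_na=False)
    issues = ReadIssues()
    records: list[OccurrenceRecord] = []
    for i, row in enumerate(df.to_dict("records")):
        sid = str(row.get("occurrenceID", "") or f"row-{i}")
        taxon = str(row.get("scientificName", "")).strip()
        if not taxon:
            issues.errors.append(f"{sid}: missing scientificName, row skipped")
            continue
        lat_s = str(row.get("decimalLatitude", "")).strip()
        lon_s = str(row.get("decimalLongitude", "")).strip()
        lat = lon = None
        if lat_s or lon_s:
            try:
                lat = float(lat_s)
                lon = float(lon_s)
            except ValueError:
                issues.errors.append(f"{sid}: unparseable coordinates, row skipped")
                continue
            if abs(lat) > 90.0 or abs(lon) > 180.0:
                issues.errors.append(
                    f"{sid}: coordinates out of range ({lat}, {lon}), row skipped")
                continue
        country = str(row.get("countryCode", "")).strip() or None
        depth_s = str(row.get("minimumDepthInMeters", "")).strip()
        depth = float(depth_s) if depth_s else None
        if lat is None and country is None:
            issues.warnings.append(
                f"{sid}: neither coordinates nor country; will be unresolvable")
        records.append(OccurrenceRecord(
            taxon=taxon, lon=lon, lat=lat, depth_m=depth,
            country_text=country,
            locality=str(row.get("locality", "")).strip() or None,
            source_id=sid))
    return records, issues


@dataclass
class Assignment:
    record: OccurrenceRecord
    kind: str                       # "point" | "country_level" | "unresolvable"
    l4_codes: tuple[str, ...] = ()
    chain: tuple[str, ...] = ()     # ancestor chain for point assignments
    imprecise: bool = False
    flags: tuple[str, ...] = ()


def resolve_country(text: Optional[str],
                    lookup: Optional[Mapping[str, str]] = None) -> Optional[str]:
    """Country text to ISO alpha-2 via an explicit lookup table.

    A bare two-letter code passes through; names resolve only through the
    supplied table (no fuzzy matching — silent misassignment of historical
    names is worse than an unresolved record).
    """
    if not text:
        return None
    t = text.strip()
    if len(t) == 2 and t.isalpha():
        return t.upper()
    if lookup:
        hit = {k.strip().casefold(): v for k, v in lookup.items()}.get(t.casefold())
        if hit:
            return hit.upper()
    return None


def assign(record: OccurrenceRecord, reg: Registry,
           country_lookup: Optional[Mapping[str, str]] = None) -> Assignment:
    """Assign one record to geounits.

    Coordinates win over country text; a point outside every unit falls
    back to the country (flagged), and a point located in a unit of a
    different country than the named one is flagged as a conflict.
    """
    iso = resolve_country(record.country_text, country_lookup)
    if record.lat is not None and record.lon is not None:
        code = locate_point(record.lon, record.lat, reg.l4_layer())
        if code is not None:
            flags = ()
            if iso is not None and reg[code].country_iso != iso:
                flags = ("country_conflict",)
            return Assignment(record, "point", (code,),
                              tuple(ancestor_chain(reg, code)), False, flags)
        if iso is None:
            return Assignment(record, "unresolvable",
                              flags=("point_outside_units",))
        codes = tuple(u.code for u in query_units(reg, level=4, country_iso=iso))
        if not codes:
            return Assignment(record, "unresolvable",
                              flags=("point_outside_units", "unknown_country"))
        return Assignment(record, "country_level", codes, imprecise=True,
                          flags=("point_outside_units",))
    if iso is not None:
        codes = tuple(u.code for u in query_units(reg, level=4, country_iso=iso))
        if codes:
            return Assignment(record, "country_level", codes, imprecise=True)
        return Assignment(record, "unresolvable", flags=("unknown_country",))
    return Assignment(record, "unresolvable")


def assign_all(records: Iterable[OccurrenceRecord], reg: Registry,
               country_lookup: Optional[Mapping[str, str]] = None) -> list[Assignment]:
    return [assign(r, reg, country_lookup) for r in records]


# ---------------------------------------------------------------------------
# Checklists

@dataclass
class ChecklistEntry:
    status: str                     # "confirmed" | "imprecise"
    source_ids: set[str] = field(default_factory=set)


class Checklist(dict):
    """unit code -> {taxon -> ChecklistEntry}; ``level`` is the roll-up level."""

    def __init__(self, level: int):
        super().__init__()
        self.level = level

    def taxa(self, code: str, status: Optional[str] = None) -> set[str]:
        entries = self.get(code.strip().upper(), {})
        if status is None:
            return set(entries)
        return {t for t, e in entries.items() if e.status == status}


def build_checklist(assignments: Iterable[Assignment], reg: Registry,
                    level: int) -> Checklist:
    """Roll taxa up the primary hierarchy to the requested level.

    Point assignments contribute confirmed presences; country-level
    assignments contribute imprecise-only presences to every candidate
    unit.  A taxon both confirmed and imprecise in a unit reports as
    confirmed.  The result is independent of input order.
    """
    if not 1 <= level <= 4:
        raise ValueError("level must be 1..4")
    cl = Checklist(level)

    def bump(code: str, taxon: str, status: str, sid: str) -> None:
        entries = cl.setdefault(code, {})
        entry = entries.setdefault(taxon, ChecklistEntry(status))
        if status == "confirmed":
            entry.status = "confirmed"
        entry.source_ids.add(sid)

    for a in assignments:
        if a.kind == "unresolvable":
            continue
        status = "imprecise" if a.imprecise else "confirmed"
        for l4 in a.l4_codes:
            chain = ancestor_chain(reg, l4)
            bump(chain[level - 1], a.record.taxon, status, a.record.source_id)
    return cl


def checklist_report(cl: Checklist, code: str) -> pd.DataFrame:
    """Deterministic tabular export for one unit: taxon, status, n_sources."""
    key = code.strip().upper()
    if key not in cl:
        raise KeyError(f"unit {code!r} not present in the checklist")
    rows = [{"taxon": t, "status": e.status, "n_sources": len(e.source_ids)}
            for t, e in cl[key].items()]
    rows.sort(key=lambda r: r["taxon"])
    return pd.DataFrame(rows, columns=["taxon", "status", "n_sources"])


def checklist_report_csv(cl: Checklist, code: str) -> str:
    buf = io.StringIO()
    checklist_report(cl, code).to_csv(buf, index=False, lineterminator="\n")
    return buf.getvalue()


def assignment_log(assignments: Iterable[Assignment]) -> pd.DataFrame:
    """Flat log of assignments (record id, kind, codes, flags), code-sorted."""
    rows = [{"source_id": a.record.source_id, "taxon": a.record.taxon,
             "kind": a.kind, "codes": ";".join(sorted(a.l4_codes)),
             "imprecise": a.imprecise, "flags": ";".join(a.flags)}
            for a in assignments]
    rows.sort(key=lambda r: r["source_id"])
    return pd.DataFrame(rows, columns=["source_id", "taxon", "kind", "codes",
                                       "imprecise", "flags"])
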