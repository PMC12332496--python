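"""The four-level geounit registry: loading, indexing, validation, queries.

A registry holds one :class:`GeoUnit` per code and maintains two indexes:
codes by level and children by parent code.  The hierarchy is strict — every
unit above level 1 has exactly one primary parent one level up, and parent
chains always terminate at a level-1 unit.  Alternative parents (the
Marine-Regions-style multi-parent hierarchies) are stored but never used for
nesting validation or roll-up.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import pandas as pd

from .codes import COINCIDENT_SUFFIX, CodeError, HIGH_SEAS_ISO, parse_code

CATEGORIES = frozenset({"coastal", "high_seas", "overlap_claim"})
SOURCE_SCHEMES = frozenset({"EEZ", "EEZ_IHO", "MEOW_SPLIT", "MSFD", "IMCRA",
                            "GOODS", "ADHOC"})

#: Canonical column schema of the registry table.
CANONICAL_COLUMNS = ("code", "label", "level", "parent", "category",
                     "source_scheme", "country_iso")


class RegistryError(ValueError):
    """Structural problem that prevents a registry from being built."""


@dataclass
class GeoUnit:
    """One recording unit of the hierarchical scheme."""

    code: str
    label: str
    level: int
    parent_code: Optional[str] = None
    alt_parent_codes: tuple[str, ...] = ()
    category: str = "coastal"
    source_scheme: str = "EEZ"
    country_iso: Optional[str] = None
    geometry: object = None
    area_km2: Optional[float] = None

    def __post_init__(self) -> None:
        self.code = self.code.strip().upper()
        self.level = int(self.level)
        if self.parent_code is not None:
            self.parent_code = str(self.parent_code).strip().upper() or None
        if self.category not in CATEGORIES:
            raise RegistryError(f"{self.code}: unknown category {self.category!r}")
        if self.source_scheme not in SOURCE_SCHEMES:
            raise RegistryError(
                f"{self.code}: unknown source scheme {self.source_scheme!r}")
        if self.area_km2 is not None and self.area_km2 < 0:
            raise RegistryError(f"{self.code}: negative area")


@dataclass
class Finding:
    severity: str   # "error" | "warning" | "info"
    subject: str    # code or "code1/code2"
    rule: str
    message: str


@dataclass
class ValidationReport:
    findings: list[Finding] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return not any(f.severity == "error" for f in self.findings)

    def errors(self) -> list[Finding]:
        return [f for f in self.findings if f.severity == "error"]


class Registry:
    """Validated, indexed collection of geounits."""

    def __init__(self) -> None:
        self.units: dict[str, GeoUnit] = {}
        self.by_level: dict[int, set[str]] = {1: set(), 2: set(), 3: set(), 4: set()}
        self.children: dict[str, set[str]] = {}

    def __len__(self) -> int:
        return len(self.units)

    def __contains__(self, code: str) -> bool:
        return code.strip().upper() in self.units

    def __getitem__(self, code: str) -> GeoUnit:
        key = code.strip().upper()
        if key not in self.units:
            raise KeyError(f"unknown geounit code {code!r}")
        return self.units[key]

    def add(self, unit: GeoUnit) -> None:
        if unit.code in self.units:
            raise RegistryError(f"duplicate geounit code {unit.code!r}")
        self.units[unit.code] = unit
        self.by_level.setdefault(unit.level, set()).add(unit.code)
        if unit.parent_code:
            self.children.setdefault(unit.parent_code, set()).add(unit.code)

    def codes(self, level: Optional[int] = None) -> list[str]:
        if level is None:
            return sorted(self.units)
        return sorted(self.by_level.get(level, ()))

    def children_of(self, code: str) -> list[str]:
        return sorted(self.children.get(code.strip().upper(), ()))

    def l4_layer(self) -> list[tuple[str, object]]:
        """(code, geometry) pairs for all level-4 units carrying geometry."""
        return [(c, self.units[c].geometry) for c in self.codes(4)
                if self.units[c].geometry is not None]


def load_registry(rows: Iterable[Mapping] | pd.DataFrame,
                  column_map: Optional[Mapping[str, str]] = None) -> Registry:
    """Build a registry from table rows.

    ``rows`` may be a DataFrame or an iterable of mappings with at least the
    columns code, label, level and parent (canonical names, or any names via
    ``column_map`` mapping canonical -> actual).  Duplicate codes, missing
    parents and unparseable codes are hard errors.
    """
    if isinstance(rows, pd.DataFrame):
        records = rows.to_dict("records")
    else:
        records = [dict(r) for r in rows]
    cmap = dict(column_map or {})

    def get(rec, name, default=None):
        key = cmap.get(name, name)
        val = rec.get(key, default)
        if val is None or (isinstance(val, float) and pd.isna(val)):
            return default
        if isinstance(val, str) and not val.strip():
            return default
        return val

    reg = Registry()
    for i, rec in enumerate(records):
        code = get(rec, "code")
        if code is None:
            raise RegistryError(f"row {i}: missing code")
        try:
            parsed = parse_code(str(code))
        except CodeError as exc:
            raise RegistryError(f"row {i}: {exc}") from exc
        level = get(rec, "level", parsed.level)
        alt = get(rec, "alt_parents", "") or ""
        if isinstance(alt, str):
            alt_codes = tuple(a.strip().upper() for a in alt.split(";") if a.strip())
        else:
            alt_codes = tuple(alt)
        area = get(rec, "area_km2")
        unit = GeoUnit(
            code=str(code),
            label=str(get(rec, "label", "")),
            level=int(level),
            parent_code=get(rec, "parent"),
            alt_parent_codes=alt_codes,
            category=str(get(rec, "category", "coastal")),
            source_scheme=str(get(rec, "source_scheme", "EEZ")),
            country_iso=get(rec, "country_iso"),
            area_km2=float(area) if area is not None else None,
        )
        if unit.code in reg.units:
            raise RegistryError(f"duplicate geounit code {unit.code!r}")
        reg.add(unit)
    for unit in reg.units.values():
        if unit.parent_code and unit.parent_code not in reg.units:
            raise RegistryError(
                f"unit {unit.code!r} names missing parent {unit.parent_code!r}")
    return reg


def validate_registry(reg: Registry,
                      terrestrial_codes: Optional[Iterable[str]] = None) -> ValidationReport:
    """Run the structural rules of the standard over a loaded registry.

    All problems are findings, never exceptions: code/level agreement,
    parent one level up, chains ending at level 1, the ``-OO`` convention
    (mandatory for, and restricted to, a level-3 unit's single child),
    high-seas units carrying QP, level-4 units carrying exactly one country
    code, and no collisions with a terrestrial code list.
    """
    rep = ValidationReport()
    terrestrial = {c.strip().upper() for c in (terrestrial_codes or ())}
    for code in sorted(reg.units):
        u = reg.units[code]
        try:
            parsed = parse_code(code)
        except CodeError as exc:
            rep.findings.append(Finding("error", code, "code-grammar", str(exc)))
            continue
        if parsed.level != u.level:
            rep.findings.append(Finding(
                "error", code, "code-level",
                f"code parses to level {parsed.level} but unit declares {u.level}"))
        if u.level > 1:
            if not u.parent_code:
                rep.findings.append(Finding(
                    "error", code, "parent-missing",
                    "units above level 1 need a parent"))
            elif u.parent_code in reg.units:
                pl = reg.units[u.parent_code].level
                if pl != u.level - 1:
                    rep.findings.append(Finding(
                        "error", f"{code}/{u.parent_code}", "parent-level",
                        f"parent is level {pl}, expected {u.level - 1}"))
        elif u.parent_code:
            rep.findings.append(Finding(
                "error", code, "parent-level",
                "level-1 units have no parent"))
        if u.category == "high_seas" and u.country_iso != HIGH_SEAS_ISO:
            rep.findings.append(Finding(
                "error", code, "high-seas-qp",
                f"high-seas units carry the reserved code {HIGH_SEAS_ISO!r}, "
                f"found {u.country_iso!r}"))
        if u.level == 4:
            iso = u.country_iso or ""
            if not iso or any(sep in iso for sep in ",;/ "):
                rep.findings.append(Finding(
                    "error", code, "single-country",
                    f"level-4 units carry exactly one country code, found {iso!r}"))
        if code in terrestrial:
            rep.findings.append(Finding(
                "error", code, "terrestrial-collision",
                "code collides with the terrestrial scheme"))
    # -OO convention, evaluated per level-3 parent
    for l3 in sorted(reg.by_level.get(3, ())):
        kids = reg.children_of(l3)
        if len(kids) == 1:
            kid = kids[0]
            if not kid.endswith("-" + COINCIDENT_SUFFIX):
                rep.findings.append(Finding(
                    "error", kid, "coincident-oo",
                    f"the single child of {l3} must use the -{COINCIDENT_SUFFIX} suffix"))
        else:
            for kid in kids:
                if kid.endswith("-" + COINCIDENT_SUFFIX):
                    rep.findings.append(Finding(
                        "error", kid, "coincident-oo",
                        f"-{COINCIDENT_SUFFIX} is reserved for a level-3 unit's "
                        f"single child; {l3} has {len(kids)} children"))
    # chains terminate at level 1 in level-1 steps
    for code in sorted(reg.units):
        u = reg.units[code]
        seen, cur = {code}, u
        steps = 0
        while cur.parent_code and cur.parent_code in reg.units:
            cur = reg.units[cur.parent_code]
            steps += 1
            if cur.code in seen or steps > 4:
                rep.findings.append(Finding(
                    "error", code, "chain-cycle", "parent chain does not terminate"))
                break
            seen.add(cur.code)
        else:
            if u.parent_code and cur.level != 1:
                rep.findings.append(Finding(
                    "error", code, "chain-root",
                    f"parent chain ends at level {cur.level}, not 1"))
    return rep


@dataclass(frozen=True)
class LevelCensus:
    by_level: dict[int, int]
    coincident_pairs: int       # level-3 units identical to their single level-4 child
    grouping_l3: int            # level-3 units with more than one child
    l4_in_multi_child_l3: int   # level-4 units sitting in grouping level-3 units


def level_counts(reg: Registry) -> LevelCensus:
    """Census of the registry: per-level counts and the coincidence split."""
    by_level = {lv: len(reg.by_level.get(lv, ())) for lv in (1, 2, 3, 4)}
    coincident = sum(1 for l3 in reg.by_level.get(3, ())
                     if len(reg.children.get(l3, ())) == 1)
    grouping = by_level[3] - coincident
    multi = sum(len(reg.children.get(l3, ()))
                for l3 in reg.by_level.get(3, ())
                if len(reg.children.get(l3, ())) > 1)
    return LevelCensus(by_level, coincident, grouping, multi)


_QUERY_KEYS = {"level", "country_iso", "category", "ancestor_code", "source_scheme"}


def query_units(reg: Registry, **filters) -> list[GeoUnit]:
    """Units matching the conjunction of filters, sorted by code.

    ``ancestor_code`` matches through the primary hierarchy only.
    """
    unknown = set(filters) - _QUERY_KEYS
    if unknown:
        raise ValueError(f"unknown query filter(s): {sorted(unknown)}")
    ancestor = filters.get("ancestor_code")
    if ancestor is not None:
        ancestor = ancestor.strip().upper()
        if ancestor not in reg.units:
            raise KeyError(f"unknown ancestor code {ancestor!r}")
    out = []
    for code in sorted(reg.units):
        u = reg.units[code]
        if filters.get("level") is not None and u.level != filters["level"]:
            continue
        if filters.get("country_iso") is not None and u.country_iso != filters["country_iso"]:
            continue
        if filters.get("category") is not None and u.category != filters["category"]:
            continue
        if filters.get("source_scheme") is not None and u.source_scheme != filters["source_scheme"]:
            continue
        if ancestor is not None:
            chain = ancestor_chain(reg, code)
            if ancestor not in chain[:-1]:
                continue
        out.append(u)
    return out


def ancestor_chain(reg: Registry, code: str) -> list[str]:
    """Codes from the level-1 root down to ``code`` itself (primary parents)."""
    u = reg[code]
    chain = [u.code]
    while u.parent_code:
        u = reg[u.parent_code]
        chain.append(u.code)
        if len(chain) > 4:
            raise RegistryError(f"parent chain of {code!r} does not terminate")
    return list(reversed(chain))


# ---------------------------------------------------------------------------
# Serialization

def to_dataframe(reg: Registry) -> pd.DataFrame:
    rows = []
    for code in sorted(reg.units):
        u = reg.units[code]
        rows.append({
            "code": u.code, "label": u.label, "level": u.level,
            "parent": u.parent_code or "",
            "alt_parents": ";".join(u.alt_parent_codes),
            "category": u.category, "source_scheme": u.source_scheme,
            "country_iso": u.country_iso or "",
            "area_km2": "" if u.area_km2 is None else u.area_km2,
        })
    return pd.DataFrame(rows, columns=[*CANONICAL_COLUMNS[:4], "alt_parents",
                                       *CANONICAL_COLUMNS[4:], "area_km2"])


def write_csv(reg: Registry, path) -> None:
    to_dataframe(reg).to_csv(path, index=False)


def read_csv(path, column_map: Optional[Mapping[str, str]] = None) -> Registry:
    return load_registry(pd.read_csv(path, dtype={"code": str, "parent": str}),
                         column_map)


def write_json(reg: Registry, path) -> None:
    recs = to_dataframe(reg).to_dict("records")
    with open(path, "w") as fh:
        json.dump(recs, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_json(path, column_map: Optional[Mapping[str, str]] = None) -> Registry:
    with open(path) as fh:
        return load_registry(json.load(fh), column_map)


def read_excel(path, column_map: Optional[Mapping[str, str]] = None,
               sheet=0) -> Registry:
    """Read a geounit table from a spreadsheet via a column-mapping config.

    ``column_map`` maps the canonical schema names (code, label, level,
    parent, category, source_scheme, country_iso) to the spreadsheet's
    actual headers; it is configuration, shipped alongside the data file it
    describes.
    """
    df = pd.read_excel(path, sheet_name=sheet)
    return load_registry(df, column_map)


def attach_geometry(reg: Registry, geoms: Mapping[str, object],
                    compute_areas: bool = True) -> Registry:
    """Attach geometries (code -> shapely geometry) to registry units."""
    from .geometry import geodesic_area

    for code, geom in geoms.items():
        u = reg[code]
        u.geometry = geom
        if compute_areas:
            u.area_km2 = geodesic_area(geom)
    return reg
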