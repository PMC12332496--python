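"""Deterministic toy planet for exercising the whole pipeline.

The world is rectilinear in lon/lat so every expected area has a closed
form.  Two (optionally three) oceans are separated at the 120°E and 60°W
meridians; each ocean is tiled by two sea areas split at 20°N.  A fixed cast
of fictional coastal states exercises every structural case the scheme must
handle:

========  ============  =====================================================
iso       name          case
========  ============  =====================================================
DP        Duoporto      small EEZ straddling two sea areas (Costa-Rica-like)
AG        Aegyptis      sea-area split flagged unwanted (Egypt-like), so the
                        ecoregion dividers are used instead
SC        Scatteria     discontinuous EEZ (two islands, with land holes)
GR        Grandia       oversized single-sea EEZ split by ecoregion lines
TC        Twocean       EEZ spanning two oceans (South-Africa-like)
RG        Regionis      oversized EEZ with an adopted regional (MSFD-style)
                        scheme
AA / BB   Alphia/Betia  overlapping claim pair (plus the ZZ overlap unit)
TM        Transmeridia  EEZ crossing the antimeridian
MM        Meridia       simple two-ecoregion EEZ (minimal preset only)
========  ============  =====================================================

The high seas of each ocean are covered by province templates and split at
the 3500 m depth contour of a synthetic field (uniform, east-west ramp, or a
shallow meridional ridge at 85–95°E).  The generator emits both the source
layers and a manifest holding the expected registry, builder decisions,
analytic unit geometries and areas — the ground truth the builder and the
occurrence pipeline are tested against.  All geometry is deterministic; the
seed only drives occurrence sampling.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from shapely.geometry import LineString, MultiPolygon, box
from shapely.ops import unary_union

from .builder import (
    OVERLAP_ISO,
    BuildConfig,
    EEZClaim,
    HIGH_SEAS_DIGIT,
    ProvinceTemplate,
    RegionalScheme,
    SourceLayers,
)
from .codes import HIGH_SEAS_ISO, make_code
from .geometry import (
    DepthField,
    GeoConfig,
    geodesic_area,
    normalize_antimeridian,
    write_geojson,
)
from .registry import Registry, load_registry

OCEAN_DIVIDE_E = 120.0
OCEAN_DIVIDE_W = -60.0
SEA_DIVIDE_LAT = 20.0
AUSTRAL_LAT = -70.0          # southern ocean boundary when n_oceans = 3
RIDGE_LON = (85.0, 95.0)     # shallow band of the "ridge" depth profile
SIZE_THRESHOLD_KM2 = 2_000_000.0


@dataclass(frozen=True)
class WorldFlags:
    two_ocean_country: bool = True
    discontinuous_eez: bool = True
    overlapping_claim: bool = True
    antimeridian_unit: bool = True
    oversized_eez_with_ecoregions: bool = True
    regional_scheme_country: bool = True
    costa_rica_mimic: bool = True
    egypt_mimic: bool = True
    high_seas: bool = True
    simple_meow_country: bool = False


@dataclass(frozen=True)
class WorldSpec:
    """Parameters of the toy planet.

    ``n_countries`` must equal the number of coastal states implied by the
    include flags (an overlapping claim contributes two states).  The same
    spec always produces byte-identical outputs; ``seed`` enters only
    through occurrence sampling.
    """

    seed: int = 42
    n_oceans: int = 2
    n_countries: int = 9
    include: WorldFlags = field(default_factory=WorldFlags)
    depth_profile: str = "ridge"      # "uniform" | "ramp" | "ridge"
    grid_resolution_deg: float = 1.0

    @classmethod
    def default(cls, seed: int = 42) -> "WorldSpec":
        return cls(seed=seed)

    @classmethod
    def minimal(cls, seed: int = 42) -> "WorldSpec":
        """Three countries, six basic recording units, no high seas."""
        return cls(seed=seed, n_countries=3, include=WorldFlags(
            two_ocean_country=False, discontinuous_eez=True,
            overlapping_claim=False, antimeridian_unit=False,
            oversized_eez_with_ecoregions=False,
            regional_scheme_country=False, costa_rica_mimic=True,
            egypt_mimic=False, high_seas=False, simple_meow_country=True))


# ---------------------------------------------------------------------------
# Static country definitions: geometry plus the expected build outcome.
# Pieces within a group and groups within a country are listed in the
# deterministic build order (west-to-east, then south-to-north).

@dataclass(frozen=True)
class _Piece:
    boxes: tuple[tuple[float, float, float, float], ...]
    holes: tuple[tuple[float, float, float, float], ...] = ()
    qualifier: Optional[str] = None
    scheme: str = "EEZ"
    label: str = ""

    def geometry(self):
        g = unary_union([box(*b) for b in self.boxes])
        if self.holes:
            g = g.difference(unary_union([box(*b) for b in self.holes]))
        return normalize_antimeridian(g)


@dataclass(frozen=True)
class _Group:
    ocean: str
    sea: str
    pieces: tuple[_Piece, ...]


@dataclass(frozen=True)
class _Country:
    flag: str
    iso: str
    name: str
    eez_boxes: tuple[tuple[float, float, float, float], ...]
    land_boxes: tuple[tuple[float, float, float, float], ...]
    island_boxes: tuple[tuple[float, float, float, float], ...]
    rule: str
    groups: tuple[_Group, ...]
    own_iso: bool = False


_COUNTRIES: tuple[_Country, ...] = (
    _Country(
        flag="costa_rica_mimic", iso="DP", name="Duoporto",
        eez_boxes=((-40, 17, -34, 23),), land_boxes=((-34, 17, -32, 23),),
        island_boxes=(), rule="SPLIT_IHO",
        groups=(
            _Group("A", "Azure Sea", (_Piece(((-40, 17, -34, 20),),
                                             qualifier="Azure Sea",
                                             scheme="EEZ_IHO",
                                             label="Duoporto – Azure Sea"),)),
            _Group("A", "Boreal Sea", (_Piece(((-40, 20, -34, 23),),
                                              qualifier="Boreal Sea",
                                              scheme="EEZ_IHO",
                                              label="Duoporto – Boreal Sea"),)),
        )),
    _Country(
        flag="egypt_mimic", iso="AG", name="Aegyptis",
        eez_boxes=((-20, 15, -10, 23),), land_boxes=((-20, 23, -10, 25),),
        island_boxes=(), rule="SPLIT_MEOW",
        groups=(
            _Group("A", "Azure Sea", (
                _Piece(((-20, 15, -15, 23),), qualifier="Sector 1",
                       scheme="MEOW_SPLIT", label="Aegyptis – Sector 1 EEZ"),
                _Piece(((-15, 15, -10, 23),), qualifier="Sector 2",
                       scheme="MEOW_SPLIT", label="Aegyptis – Sector 2 EEZ"))),
        )),
    _Country(
        flag="discontinuous_eez", iso="SC", name="Scatteria",
        eez_boxes=((0, -10, 6, -4), (10, -10, 16, -4)),
        land_boxes=(), island_boxes=((2, -8, 4, -6), (12, -8, 14, -6)),
        rule="KEEP_EEZ",
        groups=(
            _Group("A", "Azure Sea", (
                _Piece(((0, -10, 6, -4),), holes=((2, -8, 4, -6),),
                       qualifier="Part 1", label="Scatteria – Part 1 EEZ"),
                _Piece(((10, -10, 16, -4),), holes=((12, -8, 14, -6),),
                       qualifier="Part 2", label="Scatteria – Part 2 EEZ"))),
        )),
    _Country(
        flag="oversized_eez_with_ecoregions", iso="GR", name="Grandia",
        eez_boxes=((20, -45, 50, -25),), land_boxes=((20, -25, 50, -23),),
        island_boxes=(), rule="SPLIT_MEOW",
        groups=(
            _Group("A", "Azure Sea", (
                _Piece(((20, -45, 30, -25),), qualifier="Sector 1",
                       scheme="MEOW_SPLIT", label="Grandia – Sector 1 EEZ"),
                _Piece(((30, -45, 40, -25),), qualifier="Sector 2",
                       scheme="MEOW_SPLIT", label="Grandia – Sector 2 EEZ"),
                _Piece(((40, -45, 50, -25),), qualifier="Sector 3",
                       scheme="MEOW_SPLIT", label="Grandia – Sector 3 EEZ"))),
        )),
    _Country(
        flag="two_ocean_country", iso="TC", name="Twocean",
        eez_boxes=((114, -40, 126, -30),), land_boxes=((114, -30, 126, -28),),
        island_boxes=(), rule="SPLIT_IHO",
        groups=(
            _Group("A", "Azure Sea", (_Piece(((114, -40, 120, -30),),
                                             qualifier="Azure Sea",
                                             scheme="EEZ_IHO",
                                             label="Twocean – Azure Sea"),)),
            _Group("P", "Meridian Sea", (_Piece(((120, -40, 126, -30),),
                                                qualifier="Meridian Sea",
                                                scheme="EEZ_IHO",
                                                label="Twocean – Meridian Sea"),)),
        )),
    _Country(
        flag="regional_scheme_country", iso="RG", name="Regionis",
        eez_boxes=((70, 25, 100, 45),), land_boxes=((100, 25, 102, 45),),
        island_boxes=(), rule="SPLIT_REGIONAL",
        groups=(
            _Group("A", "Boreal Sea", (
                _Piece(((70, 25, 100, 35),), qualifier="Regionis South",
                       scheme="MSFD", label="Regionis – Regionis South"),
                _Piece(((70, 35, 100, 45),), qualifier="Regionis North",
                       scheme="MSFD", label="Regionis – Regionis North"))),
        )),
    _Country(
        flag="overlapping_claim", iso="AA", name="Alphia",
        eez_boxes=((-130, 10, -118, 20),), land_boxes=((-130, 20, -125, 22),),
        island_boxes=(), rule="KEEP_EEZ", own_iso=True,
        groups=(
            _Group("P", "Meridian Sea", (_Piece(((-130, 10, -124, 20),),
                                                label="Alphia EEZ"),)),
        )),
    _Country(
        flag="overlapping_claim", iso="BB", name="Betia",
        eez_boxes=((-124, 10, -112, 20),), land_boxes=((-117, 8, -112, 10),),
        island_boxes=(), rule="KEEP_EEZ",
        groups=(
            _Group("P", "Meridian Sea", (_Piece(((-118, 10, -112, 20),),
                                                label="Betia – EEZ"),)),
        )),
    _Country(
        flag="antimeridian_unit", iso="TM", name="Transmeridia",
        eez_boxes=((176, -20, 184, -12),), land_boxes=((176, -12, 184, -10),),
        island_boxes=(), rule="KEEP_EEZ",
        groups=(
            _Group("P", "Meridian Sea", (_Piece(((176, -20, 184, -12),),
                                                label="Transmeridia – EEZ"),)),
        )),
    _Country(
        flag="simple_meow_country", iso="MM", name="Meridia",
        eez_boxes=((-110, -40, -80, -20),), land_boxes=((-110, -20, -80, -18),),
        island_boxes=(), rule="SPLIT_MEOW",
        groups=(
            _Group("P", "Meridian Sea", (
                _Piece(((-110, -40, -95, -20),), qualifier="Sector 1",
                       scheme="MEOW_SPLIT", label="Meridia – Sector 1 EEZ"),
                _Piece(((-95, -40, -80, -20),), qualifier="Sector 2",
                       scheme="MEOW_SPLIT", label="Meridia – Sector 2 EEZ"))),
        )),
)

# the overlap unit emitted alongside the AA/BB pair
_OVERLAP_GROUP = _Group("P", "Meridian Sea", (
    _Piece(((-124, 10, -118, 20),), scheme="ADHOC",
           label="Alphia / Betia – overlapping claim"),))

_DIVIDERS = {
    "AG": (LineString([(-15, 14), (-15, 24)]),),
    "GR": (LineString([(30, -46), (30, -24)]), LineString([(40, -46), (40, -24)])),
    "MM": (LineString([(-95, -41), (-95, -19)]),),
}

# province templates: (name, west, east); latitude span follows the oceans
_TEMPLATES_A = (("Occident Province", -60.0, 20.0), ("Orient Province", 20.0, 120.0))
_FEATURE_NAMES = {
    ("Occident Province", "deep"): "Occident Abyssal Plain",
    ("Occident Province", "shallow"): "Occident Rise",
    ("Orient Province", "deep"): "Orient Abyssal Plain",
    ("Orient Province", "shallow"): "Central Atlantis Ridge",
    ("Meridian Province", "deep"): "Meridian Abyssal Plain",
    ("Meridian Province", "shallow"): "Meridian Rise",
    ("Austral Province", "deep"): "Austral Abyssal Plain",
    ("Austral Province", "shallow"): "Austral Rise",
}

_TAXA = tuple(
    f"{genus} {epithet}"
    for genus in ("Abyssina", "Benthodora", "Corallina", "Dorsalia",
                  "Eurybia", "Fundicola")
    for epithet in ("australis", "borealis", "communis", "profunda", "vulgaris")
)


@dataclass
class WorldManifest:
    """Ground truth emitted alongside the source layers."""

    spec: WorldSpec
    registry_rows: Optional[list[dict]]
    counts: dict
    decisions: dict[str, str]
    l4_geometries: dict[str, object]
    expected_geometries: dict[str, object]
    expected_areas_km2: dict[str, float]
    country_names: dict[str, str]
    country_l4: dict[str, list[str]]
    land: object
    build_config: BuildConfig
    analytic_contour_lon: Optional[float] = None

    def registry(self) -> Registry:
        if self.registry_rows is None:
            raise ValueError("no expected registry for this world spec")
        return load_registry(self.registry_rows)


def _enabled_countries(flags: WorldFlags) -> list[_Country]:
    return [c for c in _COUNTRIES if getattr(flags, c.flag)]


def _depth_field(spec: WorldSpec) -> DepthField:
    if spec.depth_profile == "uniform":
        return DepthField.uniform(5000.0, spec.grid_resolution_deg)
    if spec.depth_profile == "ramp":
        def ramp(lon, lat):
            return 1000.0 + 12.4 * (np.asarray(lon, dtype=float) + 180.0)
        return DepthField(ramp, spec.grid_resolution_deg,
                          note="east-west linear ramp, 1000-5464 m")
    if spec.depth_profile == "ridge":
        def ridge(lon, lat):
            lon = np.asarray(lon, dtype=float)
            return np.where((lon >= RIDGE_LON[0]) & (lon < RIDGE_LON[1]),
                            2000.0, 5000.0)
        return DepthField(ridge, spec.grid_resolution_deg,
                          note="5000 m abyssal plain with a 2000 m ridge")
    raise ValueError(f"unknown depth profile {spec.depth_profile!r}")


def generate_world(spec: WorldSpec = WorldSpec()) -> tuple[SourceLayers, WorldManifest]:
    """Build the toy planet's source layers and its ground-truth manifest."""
    if spec.n_oceans not in (2, 3):
        raise ValueError("n_oceans must be 2 or 3")
    countries = _enabled_countries(spec.include)
    if spec.n_countries != len(countries):
        raise ValueError(
            f"spec declares {spec.n_countries} countries but the include "
            f"flags imply {len(countries)}; a spec too small to host its "
            "flags is invalid")
    lat_min = AUSTRAL_LAT if spec.n_oceans == 3 else -90.0

    land = unary_union(
        [normalize_antimeridian(box(*b))
         for c in countries for b in (*c.land_boxes, *c.island_boxes)])
    ocean_a = box(OCEAN_DIVIDE_W, lat_min, OCEAN_DIVIDE_E, 90).difference(land)
    ocean_p = unary_union([box(OCEAN_DIVIDE_E, lat_min, 180, 90),
                           box(-180, lat_min, OCEAN_DIVIDE_W, 90)]).difference(land)
    oceans = [("A", "Atlantis Ocean", ocean_a), ("P", "Pacifis Ocean", ocean_p)]
    if spec.n_oceans == 3:
        ocean_s = box(-180, -90, 180, AUSTRAL_LAT).difference(land)
        oceans.append(("S", "Austral Ocean", ocean_s))

    south = box(-180, -90, 180, SEA_DIVIDE_LAT)
    north = box(-180, SEA_DIVIDE_LAT, 180, 90)
    seas = [("Azure Sea", ocean_a.intersection(south)),
            ("Boreal Sea", ocean_a.intersection(north)),
            ("Meridian Sea", ocean_p.intersection(south)),
            ("Corona Sea", ocean_p.intersection(north))]
    if spec.n_oceans == 3:
        seas.append(("Austral Sea", oceans[2][2]))

    eez_units = []
    for c in countries:
        geom = unary_union([normalize_antimeridian(box(*b))
                            for b in c.eez_boxes]).difference(land)
        eez_units.append(EEZClaim(c.iso, c.name, geom, c.own_iso))

    dividers = [d for c in countries for d in _DIVIDERS.get(c.iso, ())]
    regional = {}
    if spec.include.regional_scheme_country:
        regional["RG"] = RegionalScheme("MSFD", [
            ("Regionis South", box(70, 25, 100, 35)),
            ("Regionis North", box(70, 35, 100, 45))])

    templates: list[ProvinceTemplate] = []
    if spec.include.high_seas:
        for name, w, e in _TEMPLATES_A:
            templates.append(ProvinceTemplate(name, box(w, lat_min, e, 90)))
        templates.append(ProvinceTemplate("Meridian Province", MultiPolygon([
            box(OCEAN_DIVIDE_E, lat_min, 180, 90),
            box(-180, lat_min, OCEAN_DIVIDE_W, 90)])))
        if spec.n_oceans == 3:
            templates.append(ProvinceTemplate("Austral Province",
                                              box(-180, -90, 180, AUSTRAL_LAT)))

    layers = SourceLayers(
        oceans=oceans, eez_units=eez_units, sea_areas=seas,
        ecoregion_dividers=dividers, regional_schemes=regional,
        depth=_depth_field(spec), province_templates=templates,
        feature_names=dict(_FEATURE_NAMES),
        size_threshold_km2=SIZE_THRESHOLD_KM2,
        overlapping_claims=([("AA", "BB")]
                            if spec.include.overlapping_claim else []))

    manifest = _build_manifest(spec, countries, layers, land, oceans, seas)
    return layers, manifest


def world_build_config(spec: WorldSpec,
                       geo: Optional[GeoConfig] = None) -> BuildConfig:
    """Builder configuration matching the toy world's judgement calls."""
    unwanted = frozenset({"AG"}) if spec.include.egypt_mimic else frozenset()
    return BuildConfig(geo=geo or GeoConfig(), unwanted_iho_split=unwanted)


def _build_manifest(spec, countries, layers, land, oceans, seas):
    flags = spec.include
    # level-2 code allocation mirrors the published convention: digits per
    # ocean in sea-name order, 9 reserved for the high seas
    cells = sorted({(g.ocean, g.sea) for c in countries for g in c.groups}
                   | ({(_OVERLAP_GROUP.ocean, _OVERLAP_GROUP.sea)}
                      if flags.overlapping_claim else set()))
    l2_codes = {}
    for letter in sorted({o for o, _ in cells}):
        for digit, sea in enumerate(sorted(s for o, s in cells if o == letter),
                                    start=1):
            l2_codes[(letter, sea)] = make_code(2, ocean=letter, digit=digit)

    ocean_names = {letter: name for letter, name, _ in oceans}
    rows: list[dict] = []
    geoms: dict[str, object] = {}
    decisions: dict[str, str] = {}
    country_names: dict[str, str] = {}
    country_l4: dict[str, list[str]] = {}

    def add(code, label, level, parent, category, scheme, iso, geom):
        rows.append({"code": code, "label": label, "level": level,
                     "parent": parent, "category": category,
                     "source_scheme": scheme, "country_iso": iso})
        geoms[code] = geom

    entries = list(countries)
    overlap_entry = None
    if flags.overlapping_claim:
        overlap_entry = _Country(
            flag="overlapping_claim", iso=OVERLAP_ISO, name="Alphia / Betia",
            eez_boxes=(), land_boxes=(), island_boxes=(), rule="",
            groups=(_OVERLAP_GROUP,))
        entries.append(overlap_entry)
    for c in entries:
        if c.rule:
            decisions[c.iso] = c.rule
        if c is not overlap_entry:
            country_names[c.iso] = c.name
        for digit, g in enumerate(c.groups, start=1):
            l2 = l2_codes[(g.ocean, g.sea)]
            l3 = make_code(3, letters=c.iso, digit=digit)
            suffixes = (["OO"] if len(g.pieces) == 1
                        else [chr(ord("A")) + chr(ord("A") + i)
                              for i in range(len(g.pieces))])
            child_geoms = []
            for sfx, piece in zip(suffixes, g.pieces):
                code = make_code(4, l3=l3, suffix=sfx)
                category = ("overlap_claim" if c is overlap_entry else "coastal")
                iso = OVERLAP_ISO if c is overlap_entry else c.iso
                geom = piece.geometry()
                add(code, piece.label, 4, l3, category, piece.scheme, iso, geom)
                child_geoms.append(geom)
                country_l4.setdefault(iso, []).append(code)
            if c is overlap_entry:
                l3_label = _OVERLAP_GROUP.pieces[0].label
            elif len(c.groups) == 1:
                l3_label = c.name
            else:
                l3_label = f"{c.name} ({g.sea})"
            schemes = {p.scheme for p in g.pieces}
            add(l3, l3_label, 3, l2,
                "overlap_claim" if c is overlap_entry else "coastal",
                schemes.pop() if len(schemes) == 1 else "ADHOC",
                OVERLAP_ISO if c is overlap_entry else c.iso,
                unary_union(child_geoms))

    # high-seas expectations (exact for the grid-aligned profiles)
    contour = None
    if spec.depth_profile == "ramp":
        contour = 2500.0 / 12.4 - 180.0   # depth(lon) = 3500 m
    hs_exact = flags.high_seas and spec.depth_profile in ("uniform", "ridge")
    if hs_exact:
        eez_all = unary_union([e.geometry for e in layers.eez_units])
        ridge = box(*[RIDGE_LON[0], -90, RIDGE_LON[1], 90])
        ab = by = 0
        for letter, _, ocean_geom in sorted(oceans, key=lambda o: o[0]):
            hs = ocean_geom.difference(eez_all)
            if hs.is_empty:
                continue
            l2 = make_code(2, ocean=letter, digit=HIGH_SEAS_DIGIT)
            tpls = [(t.name, t.geometry.intersection(hs))
                    for t in layers.province_templates]
            tpls = [(n, g) for n, g in tpls
                    if not g.is_empty and geodesic_area(g) > 1.0]
            tpls.sort(key=lambda ng: (round(ng[1].centroid.x, 9),
                                      round(ng[1].centroid.y, 9)))
            for i, (tname, region) in enumerate(tpls):
                l3 = make_code(3, high_seas=True, l2=l2,
                               discriminator=chr(ord("A") + i))
                if spec.depth_profile == "uniform":
                    parts = [("deep", region)]
                else:
                    deep = region.difference(ridge)
                    shallow = region.intersection(ridge)
                    parts = [(cls, g) for cls, g in
                             (("deep", deep), ("shallow", shallow))
                             if not g.is_empty and geodesic_area(g) > 1.0]
                    parts.sort(key=lambda cg: (round(cg[1].centroid.x, 9),
                                               round(cg[1].centroid.y, 9)))
                child_geoms = []
                suffixes = (["OO"] if len(parts) == 1
                            else ["A" + chr(ord("A") + k)
                                  for k in range(len(parts))])
                for sfx, (cls, g) in zip(suffixes, parts):
                    if cls == "deep":
                        ab += 1
                        tag = f"AB{ab}"
                    else:
                        by += 1
                        tag = f"BY{by}"
                    code = make_code(4, l3=l3, suffix=sfx)
                    feature = _FEATURE_NAMES[(tname, cls)]
                    add(code, f"{tag} – {feature}", 4, l3, "high_seas",
                        "GOODS", HIGH_SEAS_ISO, g)
                    child_geoms.append(g)
                    country_l4.setdefault(HIGH_SEAS_ISO, []).append(code)
                add(l3, tname, 3, l2, "high_seas", "GOODS", HIGH_SEAS_ISO,
                    unary_union(child_geoms))

    # levels 2 and 1 as unions of members
    l3_rows = [r for r in rows if r["level"] == 3]
    l2_parents = sorted({r["parent"] for r in l3_rows})
    for l2 in l2_parents:
        members = [geoms[r["code"]] for r in l3_rows if r["parent"] == l2]
        letter = l2[0]
        digit = int(l2[1])
        if digit == HIGH_SEAS_DIGIT:
            add(l2, f"{ocean_names[letter]} – High Seas", 2, letter,
                "high_seas", "GOODS", HIGH_SEAS_ISO, unary_union(members))
        else:
            sea = next(s for (o, s), code in l2_codes.items() if code == l2)
            add(l2, f"{ocean_names[letter]} – {sea} coastal", 2, letter,
                "coastal", "ADHOC", None, unary_union(members))
    l2_rows = [r for r in rows if r["level"] == 2]
    for letter, name, _ in sorted(oceans, key=lambda o: o[0]):
        members = [geoms[r["code"]] for r in l2_rows if r["parent"] == letter]
        if not members:
            continue
        add(letter, name, 1, None, "coastal", "ADHOC", None,
            unary_union(members))

    rows.sort(key=lambda r: (r["level"], r["code"]))
    registry_rows = rows if (hs_exact or not flags.high_seas) else None
    by_level = {lv: sum(1 for r in rows if r["level"] == lv)
                for lv in (1, 2, 3, 4)}
    l3_children = {}
    for r in rows:
        if r["level"] == 4:
            l3_children.setdefault(r["parent"], []).append(r["code"])
    coincident = sum(1 for kids in l3_children.values() if len(kids) == 1)
    counts = {
        "by_level": by_level,
        "coincident_pairs": coincident,
        "grouping_l3": by_level[3] - coincident,
        "l4_in_multi_child_l3": sum(len(k) for k in l3_children.values()
                                    if len(k) > 1),
    }
    l4_geoms = {r["code"]: geoms[r["code"]] for r in rows if r["level"] == 4}
    areas = {code: geodesic_area(g) for code, g in sorted(geoms.items())}
    for lst in country_l4.values():
        lst.sort()
    return WorldManifest(
        spec=spec, registry_rows=registry_rows, counts=counts,
        decisions=decisions, l4_geometries=l4_geoms,
        expected_geometries=geoms, expected_areas_km2=areas,
        country_names=country_names, country_l4=country_l4, land=land,
        build_config=world_build_config(spec),
        analytic_contour_lon=contour)


# ---------------------------------------------------------------------------
# Occurrence sampling

def _sample_point(geom, rng: np.random.Generator):
    """Uniform point strictly inside a (multi)polygon."""
    from shapely.geometry import Point

    parts = list(geom.geoms) if geom.geom_type.startswith("Multi") else [geom]
    weights = np.array([p.area for p in parts])
    part = parts[rng.choice(len(parts), p=weights / weights.sum())]
    minx, miny, maxx, maxy = part.bounds
    for _ in range(10_000):
        x = rng.uniform(minx, maxx)
        y = rng.uniform(miny, maxy)
        if part.contains(Point(x, y)):
            return x, y
    raise RuntimeError("rejection sampling failed")  # pragma: no cover


def generate_occurrences(manifest: WorldManifest, n: int,
                         point_fraction: float = 0.7, seed: int = 0,
                         broken_fraction: float = 0.0
                         ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sample Darwin Core-style occurrence rows with ground truth.

    Point records are drawn uniformly inside a randomly chosen basic
    recording unit (recorded as the truth); text records carry only a
    country (ISO code or full name, alternating).  ``broken_fraction`` of
    rows are deliberately defective (out-of-range latitude or a missing
    scientific name) to exercise the reader.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    if not (0.0 <= point_fraction <= 1.0):
        raise ValueError("point_fraction must be within [0, 1]")
    rng = np.random.default_rng(seed)
    codes = sorted(manifest.l4_geometries)
    isos = sorted(manifest.country_names)
    recs, truths = [], []
    for i in range(n):
        rec = {"occurrenceID": f"occ-{i:05d}",
               "scientificName": _TAXA[rng.integers(len(_TAXA))],
               "decimalLatitude": "", "decimalLongitude": "",
               "countryCode": "", "locality": "",
               "minimumDepthInMeters": ""}
        truth = {"source_id": rec["occurrenceID"], "kind": "", "codes": ""}
        broken = rng.random() < broken_fraction
        if broken and i % 2 == 0:
            code = codes[rng.integers(len(codes))]
            _, lat = _sample_point(manifest.l4_geometries[code], rng)
            rec["decimalLatitude"] = 95.0
            rec["decimalLongitude"] = 0.0
            truth["kind"] = "rejected"
        elif broken:
            rec["scientificName"] = ""
            rec["countryCode"] = isos[rng.integers(len(isos))]
            truth["kind"] = "skipped"
        elif rng.random() < point_fraction:
            code = codes[rng.integers(len(codes))]
            lon, lat = _sample_point(manifest.l4_geometries[code], rng)
            rec["decimalLatitude"] = round(lat, 6)
            rec["decimalLongitude"] = round(lon, 6)
            truth["kind"] = "point"
            truth["codes"] = code
        else:
            iso = isos[rng.integers(len(isos))]
            rec["countryCode"] = (iso if rng.random() < 0.5
                                  else manifest.country_names[iso])
            rec["locality"] = f"off {manifest.country_names[iso]}"
            truth["kind"] = "country_level"
            truth["codes"] = ";".join(manifest.country_l4.get(iso, []))
        recs.append(rec)
        truths.append(truth)
    columns = ["occurrenceID", "scientificName", "decimalLatitude",
               "decimalLongitude", "countryCode", "locality",
               "minimumDepthInMeters"]
    return (pd.DataFrame(recs, columns=columns),
            pd.DataFrame(truths, columns=["source_id", "kind", "codes"]))


# ---------------------------------------------------------------------------
# On-disk form

def write_world(layers: SourceLayers, manifest: WorldManifest, outdir,
                n_occurrences: int = 500, include_depth_raster: bool = True) -> None:
    """Write layers (GeoJSON), depth raster (CSV), expected registry (CSV),
    occurrences (CSV) and the manifest (JSON) to a directory."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_geojson(out / "oceans.geojson",
                  [({"letter": l, "name": n}, g) for l, n, g in layers.oceans])
    write_geojson(out / "sea_areas.geojson",
                  [({"name": n}, g) for n, g in layers.sea_areas])
    write_geojson(out / "eez.geojson",
                  [({"country_iso": e.country_iso, "name": e.country_name,
                     "own_iso": e.own_iso}, e.geometry)
                   for e in layers.eez_units])
    write_geojson(out / "ecoregion_dividers.geojson",
                  [({}, d) for d in layers.ecoregion_dividers])
    write_geojson(out / "province_templates.geojson",
                  [({"name": t.name}, t.geometry)
                   for t in layers.province_templates])
    write_geojson(out / "regional_schemes.geojson",
                  [({"country_iso": iso, "scheme": rs.scheme, "name": name}, g)
                   for iso, rs in sorted(layers.regional_schemes.items())
                   for name, g in rs.subunits])
    write_geojson(out / "land.geojson", [({}, manifest.land)])
    if include_depth_raster and layers.depth is not None:
        layers.depth.to_grid_csv(out / "depth.csv", (-180, -90, 180, 90))
    if manifest.registry_rows is not None:
        pd.DataFrame(manifest.registry_rows).to_csv(
            out / "registry_expected.csv", index=False)
    occ, truth = generate_occurrences(manifest, n_occurrences,
                                      seed=manifest.spec.seed)
    occ.to_csv(out / "occurrences.csv", index=False)
    truth.to_csv(out / "occurrences_truth.csv", index=False)
    meta = {
        "spec": dataclasses.asdict(manifest.spec),
        "counts": manifest.counts,
        "decisions": manifest.decisions,
        "expected_areas_km2": {k: round(v, 6)
                               for k, v in manifest.expected_areas_km2.items()},
        "country_names": manifest.country_names,
        "country_l4": manifest.country_l4,
        "size_threshold_km2": layers.size_threshold_km2,
        "overlapping_claims": layers.overlapping_claims,
        "feature_names": {f"{t}|{c}": v
                          for (t, c), v in sorted(layers.feature_names.items())},
        "unwanted_iho_split": sorted(manifest.build_config.unwanted_iho_split),
        "analytic_contour_lon": manifest.analytic_contour_lon,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True)
        fh.write("\n")


def load_world(indir) -> tuple[SourceLayers, dict]:
    """Read back the layers written by :func:`write_world`.

    Returns the layers and the manifest metadata dict (counts, decisions,
    expected areas); the full geometric manifest is only available from
    :func:`generate_world`.
    """
    from .geometry import read_geojson

    d = Path(indir)
    with open(d / "manifest.json") as fh:
        meta = json.load(fh)
    if "by_level" in meta.get("counts", {}):
        meta["counts"]["by_level"] = {int(k): v for k, v
                                      in meta["counts"]["by_level"].items()}
    oceans = [(p["letter"], p["name"], g)
              for p, g in read_geojson(d / "oceans.geojson")]
    seas = [(p["name"], g) for p, g in read_geojson(d / "sea_areas.geojson")]
    eez = [EEZClaim(p["country_iso"], p["name"], g, p["own_iso"])
           for p, g in read_geojson(d / "eez.geojson")]
    dividers = [g for _, g in read_geojson(d / "ecoregion_dividers.geojson")]
    templates = [ProvinceTemplate(p["name"], g)
                 for p, g in read_geojson(d / "province_templates.geojson")]
    regional: dict[str, RegionalScheme] = {}
    for p, g in read_geojson(d / "regional_schemes.geojson"):
        rs = regional.setdefault(p["country_iso"],
                                 RegionalScheme(p["scheme"], []))
        rs.subunits.append((p["name"], g))
    depth = (DepthField.from_grid_csv(d / "depth.csv")
             if (d / "depth.csv").exists() else None)
    feature_names = {tuple(k.split("|")): v
                     for k, v in meta.get("feature_names", {}).items()}
    layers = SourceLayers(
        oceans=oceans, eez_units=eez, sea_areas=seas,
        ecoregion_dividers=dividers, regional_schemes=regional, depth=depth,
        province_templates=templates, feature_names=feature_names,
        size_threshold_km2=meta["size_threshold_km2"],
        overlapping_claims=[tuple(p) for p in meta["overlapping_claims"]])
    return layers, meta
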