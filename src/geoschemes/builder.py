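"""Construction of recording units from source layers.

The coastal decision cascade, applied to each (discontinuity-split) EEZ
part:

1. keep the EEZ whole when it is not too large and lies within a single
   sea area;
2. otherwise split it by the sea-area (IHO-style) layer, provided every
   resulting piece is acceptable and the country is not flagged as
   unwantedly split by that layer (the Gulf-of-Suez type of problem);
3. otherwise adopt an existing regional scheme (MSFD/IMCRA-style) where one
   exists for the country;
4. otherwise split along the ecoregion (MEOW-style) divider lines.

Overlapping claims are resolved first into three disjoint units (each
claimant's exclusive part plus a separate overlap unit), so that the levels
tile without double counting.  High-seas units are built per ocean by
intersecting province templates with the high-seas polygon and partitioning
at the 3500 m depth contour: basins below the threshold ("AB" sectors) and
seafloor elevations above it ("BY" sectors).

Code assignment during the build is deterministic: level-2 digits per ocean
follow sea-area name order (the high-seas level 2 takes the reserved digit
9), level-3 digits per country and level-4 suffixes follow west-to-east then
south-to-north centroid order, with ``-OO`` for a level-3 unit's single
child.  Real-standard codes are data in the registry table, never computed;
the builder's allocation only serves desk-scale worlds.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from shapely.geometry import LineString, MultiPolygon, Polygon
from shapely.ops import unary_union
from shapely.affinity import translate

from .codes import HIGH_SEAS_ISO, LabelSpec, format_label, make_code
from .geometry import (
    DepthField,
    GeoConfig,
    GeometryError,
    _as_polys,
    clip_by_depth,
    geodesic_area,
    normalize_antimeridian,
    split_polygon,
    trifurcate_overlap,
)
from .registry import Registry, attach_geometry, load_registry

RULES = ("KEEP_EEZ", "SPLIT_IHO", "SPLIT_REGIONAL", "SPLIT_MEOW", "ADHOC")

#: Reserved (user-assignable) ISO value carried by overlap-claim units.
OVERLAP_ISO = "ZZ"

#: Reserved level-2 digit for each ocean's high-seas unit.
HIGH_SEAS_DIGIT = 9


@dataclass
class EEZClaim:
    country_iso: str
    country_name: str
    geometry: Polygon | MultiPolygon
    own_iso: bool = False


@dataclass
class RegionalScheme:
    scheme: str                                  # "MSFD" | "IMCRA"
    subunits: list[tuple[str, Polygon | MultiPolygon]]


@dataclass
class ProvinceTemplate:
    name: str
    geometry: Polygon | MultiPolygon


@dataclass
class SourceLayers:
    """Inputs of the builder (EEZs, boundary layers, depth, templates)."""

    oceans: list[tuple[str, str, Polygon | MultiPolygon]]   # (letter, name, geometry)
    eez_units: list[EEZClaim]
    sea_areas: list[tuple[str, Polygon | MultiPolygon]]
    ecoregion_dividers: list[LineString] = field(default_factory=list)
    regional_schemes: dict[str, RegionalScheme] = field(default_factory=dict)
    depth: Optional[DepthField] = None
    province_templates: list[ProvinceTemplate] = field(default_factory=list)
    feature_names: dict[tuple[str, str], str] = field(default_factory=dict)
    size_threshold_km2: float = 2_000_000.0
    overlapping_claims: list[tuple[str, str]] = field(default_factory=list)


@dataclass
class BuildConfig:
    geo: GeoConfig = field(default_factory=GeoConfig)
    unwanted_iho_split: frozenset[str] = frozenset()
    adhoc_overrides: dict[str, list[tuple[str, Polygon | MultiPolygon]]] = field(
        default_factory=dict)


@dataclass(frozen=True)
class BuildDecision:
    country_iso: str
    rule: str
    rationale: str


@dataclass
class CoastalPiece:
    geometry: Polygon | MultiPolygon
    country_iso: str
    country_name: str
    own_iso: bool
    source_scheme: str
    category: str = "coastal"
    qualifier: Optional[str] = None
    label: Optional[str] = None


@dataclass
class HighSeasPiece:
    geometry: Polygon | MultiPolygon
    template_name: str
    sector_tag: str
    feature_name: str
    depth_class: str            # "deep" | "shallow"
    ocean_letter: str


def _material_pieces(geom, regions, tol_km2):
    """(name, intersection) for regions overlapping ``geom`` beyond slivers."""
    out = []
    for name, rg in regions:
        inter = geom.intersection(rg)
        if not inter.is_empty and geodesic_area(inter) > tol_km2:
            out.append((name, inter))
    return out


def choose_rule(eez_geom, country_iso: str, layers: SourceLayers,
                cfg: BuildConfig = BuildConfig()) -> BuildDecision:
    """Apply the decision cascade to one (already connected) EEZ part."""
    if country_iso in cfg.adhoc_overrides:
        return BuildDecision(country_iso, "ADHOC",
                             "explicit override subdivision configured")
    area = geodesic_area(eez_geom)
    thr = layers.size_threshold_km2
    tol = cfg.geo.nesting_area_tolerance * max(area, 1.0)
    seas = _material_pieces(eez_geom, layers.sea_areas, tol)
    if area <= thr and len(seas) == 1:
        return BuildDecision(
            country_iso, "KEEP_EEZ",
            f"area {area:.0f} km² within threshold, single sea area")
    if (all(geodesic_area(p) <= thr for _, p in seas)
            and country_iso not in cfg.unwanted_iho_split):
        return BuildDecision(
            country_iso, "SPLIT_IHO",
            f"{len(seas)} sea-area pieces, all within threshold")
    if country_iso in layers.regional_schemes:
        return BuildDecision(
            country_iso, "SPLIT_REGIONAL",
            f"adopted {layers.regional_schemes[country_iso].scheme} scheme")
    return BuildDecision(country_iso, "SPLIT_MEOW",
                         "default ecoregion-boundary subdivision")


def split_discontinuous(geom) -> list[Polygon | MultiPolygon]:
    """Connected components of a (multi)polygon EEZ.

    Parts that touch across the antimeridian (one part ending at +180°, the
    other starting at −180°) belong to the same component: they are one
    contiguous unit on the sphere, stored split.  Components are returned
    west-to-east then south-to-north.
    """
    parts = _as_polys(geom)
    n = len(parts)
    if n <= 1:
        return [geom] if not geom.is_empty else []
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            a, b = parts[i], parts[j]
            adjacent = a.intersects(b)
            if not adjacent and (abs(a.bounds[2] - 180.0) < 1e-9
                                 or abs(a.bounds[0] + 180.0) < 1e-9):
                adjacent = (translate(a, xoff=360.0).intersects(b)
                            or translate(a, xoff=-360.0).intersects(b))
            if adjacent:
                parent[find(i)] = find(j)
    groups: dict[int, list[Polygon]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(parts[i])
    comps = [unary_union(g) for g in groups.values()]
    return sorted(comps, key=lambda g: (round(g.centroid.x, 9),
                                        round(g.centroid.y, 9)))


def _expand_part(part, claim: EEZClaim, decision: BuildDecision,
                 layers: SourceLayers, cfg: BuildConfig,
                 part_qualifier: Optional[str]) -> list[CoastalPiece]:
    iso, name, own = claim.country_iso, claim.country_name, claim.own_iso
    tol = cfg.geo.nesting_area_tolerance * max(geodesic_area(part), 1.0)
    pieces: list[CoastalPiece] = []
    if decision.rule == "KEEP_EEZ":
        pieces.append(CoastalPiece(part, iso, name, own, "EEZ",
                                   qualifier=part_qualifier))
    elif decision.rule == "SPLIT_IHO":
        for sea, geom in _material_pieces(part, layers.sea_areas, tol):
            pieces.append(CoastalPiece(geom, iso, name, own, "EEZ_IHO",
                                       qualifier=sea))
    elif decision.rule == "SPLIT_REGIONAL":
        scheme = layers.regional_schemes[iso]
        for sub, geom in _material_pieces(part, scheme.subunits, tol):
            pieces.append(CoastalPiece(geom, iso, name, own, scheme.scheme,
                                       qualifier=sub))
    elif decision.rule == "ADHOC":
        for sub, geom in _material_pieces(part, cfg.adhoc_overrides[iso], tol):
            pieces.append(CoastalPiece(geom, iso, name, own, "ADHOC",
                                       qualifier=sub))
    elif decision.rule == "SPLIT_MEOW":
        dividers = [d for d in layers.ecoregion_dividers if d.intersects(part)]
        parts = split_polygon(part, dividers, cfg.geo)
        for i, geom in enumerate(parts, start=1):
            pieces.append(CoastalPiece(geom, iso, name, own, "MEOW_SPLIT",
                                       qualifier=f"Sector {i}"))
    else:  # pragma: no cover
        raise AssertionError(decision.rule)
    return pieces


def _label_coastal(piece: CoastalPiece) -> str:
    if piece.category == "overlap_claim":
        return piece.label or f"{piece.country_name} – overlapping claim"
    style = {"EEZ": "EEZ", "EEZ_IHO": "SEA_AREA", "MEOW_SPLIT": "EEZ",
             "MSFD": "MSFD", "IMCRA": "IMCRA", "ADHOC": "EEZ"}[piece.source_scheme]
    return format_label(LabelSpec(style=style, country_name=piece.country_name,
                                  own_iso=piece.own_iso,
                                  qualifier=piece.qualifier))


def build_coastal_units(layers: SourceLayers, cfg: BuildConfig = BuildConfig()
                        ) -> tuple[list[CoastalPiece], list[BuildDecision]]:
    """Coastal pieces (with geometry and label metadata) plus the decisions.

    Every output piece lies within exactly one country's jurisdiction; each
    overlapping claim contributes one extra unit; together the pieces tile
    the union of all claims (a violation is a hard error).
    """
    claims = {c.country_iso: EEZClaim(c.country_iso, c.country_name,
                                      normalize_antimeridian(c.geometry),
                                      c.own_iso)
              for c in layers.eez_units}
    total = unary_union([c.geometry for c in claims.values()])
    pieces: list[CoastalPiece] = []
    decisions: list[BuildDecision] = []
    # resolve declared overlapping claims first
    for iso_a, iso_b in layers.overlapping_claims:
        a, b = claims[iso_a], claims[iso_b]
        a_only, b_only, joint = trifurcate_overlap(a.geometry, b.geometry,
                                                   cfg.geo)
        if not joint.is_empty:
            name = f"{a.country_name} / {b.country_name}"
            pieces.append(CoastalPiece(
                joint, OVERLAP_ISO, name, False, "ADHOC",
                category="overlap_claim",
                label=f"{name} – overlapping claim"))
        claims[iso_a] = EEZClaim(iso_a, a.country_name, a_only, a.own_iso)
        claims[iso_b] = EEZClaim(iso_b, b.country_name, b_only, b.own_iso)
    for iso in sorted(claims):
        claim = claims[iso]
        parts = split_discontinuous(claim.geometry)
        multi = len(parts) > 1
        for i, part in enumerate(parts, start=1):
            decision = choose_rule(part, iso, layers, cfg)
            decisions.append(decision)
            qual = f"Part {i}" if multi else None
            pieces.extend(_expand_part(part, claim, decision, layers, cfg, qual))
    for p in pieces:
        if p.label is None:
            p.label = _label_coastal(p)
    built = unary_union([p.geometry for p in pieces]) if pieces else total
    a0, a1 = geodesic_area(total), geodesic_area(built)
    if abs(a0 - a1) > cfg.geo.nesting_area_tolerance * max(a0, 1.0):
        raise GeometryError(
            f"coastal units do not tile the claims: {a1:.6g} vs {a0:.6g} km²")
    return pieces, decisions


def build_highseas_units(highseas, depth: DepthField,
                         templates: Sequence[ProvinceTemplate],
                         feature_names: Mapping[tuple[str, str], str],
                         cfg: BuildConfig = BuildConfig(),
                         ocean_letter: str = "",
                         tag_counters: Optional[dict[str, int]] = None
                         ) -> list[HighSeasPiece]:
    """High-seas units of one ocean: template ∩ depth class.

    Templates are clipped to the high-seas polygon (removing parts of the
    deep sea comprised in the EEZs); each template contributes a deep unit
    (depth beyond the threshold, "AB" sector) and/or a shallow unit ("BY"
    sector).  Templates must cover the high-seas polygon without material
    overlap, otherwise a hard error is raised.
    """
    if highseas.is_empty:
        return []
    counters = tag_counters if tag_counters is not None else {"AB": 0, "BY": 0}
    hs_area = geodesic_area(highseas)
    tol = cfg.geo.nesting_area_tolerance * max(hs_area, 1.0)
    regions = []
    for t in sorted(templates, key=lambda t: (round(t.geometry.centroid.x, 9),
                                              round(t.geometry.centroid.y, 9))):
        region = t.geometry.intersection(highseas)
        if region.is_empty or geodesic_area(region) <= tol:
            continue
        regions.append((t.name, region))
    covered = sum(geodesic_area(r) for _, r in regions)
    overlap = 0.0
    for i in range(len(regions)):
        for j in range(i + 1, len(regions)):
            inter = regions[i][1].intersection(regions[j][1])
            if not inter.is_empty:
                overlap += geodesic_area(inter)
    if abs(covered - overlap - hs_area) > tol or overlap > tol:
        raise GeometryError(
            f"province templates do not tile the high seas: cover "
            f"{covered:.6g} km² (overlap {overlap:.6g}) of {hs_area:.6g}")
    out: list[HighSeasPiece] = []
    for tname, region in regions:
        shallow, deep = clip_by_depth(region, depth, cfg.geo)
        for cls, geom, prefix in (("deep", deep, "AB"), ("shallow", shallow, "BY")):
            if geom.is_empty or geodesic_area(geom) <= tol:
                continue
            counters[prefix] += 1
            tag = f"{prefix}{counters[prefix]}"
            default = f"{tname} {'Basin' if cls == 'deep' else 'Rise'}"
            out.append(HighSeasPiece(geom, tname, tag,
                                     feature_names.get((tname, cls), default),
                                     cls, ocean_letter))
    return out


def adjust_higher_levels(l4_geoms: Sequence, draft_regions: Sequence[tuple[str, object]]
                         ) -> tuple[list[str], dict[str, object]]:
    """Assign level-4 geometries wholly to draft higher-level regions.

    Each unit goes, undivided, to the draft region holding the largest share
    of its area (the higher-level limit is adjusted to the nearest level-4
    limit rather than splitting the unit).  Ties break to the
    lexicographically smallest region key.  Returns the per-unit keys and
    the snapped region polygons (union of assigned units).
    """
    keys: list[str] = []
    members: dict[str, list] = {k: [] for k, _ in draft_regions}
    for geom in l4_geoms:
        best_key, best_area = None, -1.0
        for key, region in sorted(draft_regions, key=lambda kr: kr[0]):
            inter = geom.intersection(region)
            a = 0.0 if inter.is_empty else geodesic_area(inter)
            if a > best_area + 1e-9 * max(best_area, 1.0):
                best_key, best_area = key, a
        if best_key is None or best_area <= 0.0:
            raise GeometryError("level-4 unit overlaps no draft region")
        keys.append(best_key)
        members[best_key].append(geom)
    snapped = {k: unary_union(g) for k, g in members.items() if g}
    return keys, snapped


def draft_regions_from_boundaries(domain, boundaries: Sequence[LineString],
                                  cfg: GeoConfig = GeoConfig()
                                  ) -> list[tuple[str, object]]:
    """Polygonize draft boundary polylines over a domain into keyed regions."""
    parts = split_polygon(domain, list(boundaries), cfg)
    return [(f"R{i + 1}", p) for i, p in enumerate(parts)]


# ---------------------------------------------------------------------------
# End-to-end build

_SUFFIX_LETTERS = string.ascii_uppercase


def _l4_suffixes(n: int) -> list[str]:
    """AA, AB, AC, ... skipping the reserved OO."""
    out = []
    i = 0
    while len(out) < n:
        s = _SUFFIX_LETTERS[i // 26] + _SUFFIX_LETTERS[i % 26]
        i += 1
        if s == "OO":
            continue
        out.append(s)
    return out


def _centroid_key(geom):
    return (round(geom.centroid.x, 9), round(geom.centroid.y, 9))


@dataclass
class BuildResult:
    registry: Registry
    decisions: list[BuildDecision]


def build_world(layers: SourceLayers, cfg: BuildConfig = BuildConfig()
                ) -> BuildResult:
    """Run the full pipeline: coastal cascade, high seas, level assembly.

    Returns a geometry-carrying registry whose level 1/2/3 units are unions
    of their children (higher-level limits adjusted to the nearest level-4
    limit), with deterministic code allocation throughout.
    """
    coastal, decisions = build_coastal_units(layers, cfg)
    oceans = sorted(layers.oceans, key=lambda o: o[0])
    ocean_names = {letter: name for letter, name, _ in oceans}
    eez_union = unary_union([normalize_antimeridian(c.geometry)
                             for c in layers.eez_units])

    # assign each coastal piece to (ocean, sea) by majority overlap
    ocean_regions = [(letter, geom) for letter, _, geom in oceans]
    sea_regions = [(name, geom) for name, geom in layers.sea_areas]
    ocean_keys, _ = adjust_higher_levels([p.geometry for p in coastal],
                                         ocean_regions)
    sea_keys, _ = adjust_higher_levels([p.geometry for p in coastal],
                                       sea_regions)

    # level-2 coastal cells: digits per ocean in sea-name order
    cells = sorted({(ok, sk) for ok, sk in zip(ocean_keys, sea_keys)})
    l2_codes: dict[tuple[str, str], str] = {}
    for letter in sorted({ok for ok, _ in cells}):
        seas = sorted(sk for ok, sk in cells if ok == letter)
        for digit, sea in enumerate(seas, start=1):
            l2_codes[(letter, sea)] = make_code(2, ocean=letter, digit=digit)

    # high seas per ocean
    hs_pieces: list[HighSeasPiece] = []
    hs_l2: dict[str, str] = {}
    counters = {"AB": 0, "BY": 0}
    for letter, _, ocean_geom in oceans:
        hs = ocean_geom.difference(eez_union)
        if hs.is_empty or layers.depth is None or not layers.province_templates:
            continue
        units = build_highseas_units(hs, layers.depth,
                                     layers.province_templates,
                                     layers.feature_names, cfg,
                                     ocean_letter=letter,
                                     tag_counters=counters)
        if units:
            hs_l2[letter] = make_code(2, ocean=letter, digit=HIGH_SEAS_DIGIT)
            hs_pieces.extend(units)

    # level-3 grouping
    coastal_groups: dict[tuple[str, str], list[CoastalPiece]] = {}
    for piece, ok, sk in zip(coastal, ocean_keys, sea_keys):
        coastal_groups.setdefault((l2_codes[(ok, sk)], piece.country_iso),
                                  []).append(piece)
    # per-country digit order: group centroid west-to-east, south-to-north
    country_groups: dict[str, list[tuple[tuple, tuple[str, str]]]] = {}
    for (l2, iso), members in coastal_groups.items():
        key = _centroid_key(unary_union([m.geometry for m in members]))
        country_groups.setdefault(iso, []).append((key, (l2, iso)))
    l3_codes: dict[tuple[str, str], str] = {}
    for iso, lst in country_groups.items():
        for digit, (_, gkey) in enumerate(sorted(lst), start=1):
            l3_codes[gkey] = make_code(3, letters=iso, digit=digit)

    hs_groups: dict[tuple[str, str], list[HighSeasPiece]] = {}
    for piece in hs_pieces:
        hs_groups.setdefault((hs_l2[piece.ocean_letter], piece.template_name),
                             []).append(piece)
    hs_l3_codes: dict[tuple[str, str], str] = {}
    for l2 in sorted({k for k, _ in hs_groups}):
        tnames = [(_centroid_key(unary_union([m.geometry for m in members])), t)
                  for (l2c, t), members in hs_groups.items() if l2c == l2]
        for i, (_, t) in enumerate(sorted(tnames)):
            hs_l3_codes[(l2, t)] = make_code(3, high_seas=True, l2=l2,
                                             discriminator=_SUFFIX_LETTERS[i])

    # assemble rows and geometries
    rows: list[dict] = []
    geoms: dict[str, object] = {}

    def add_row(code, label, level, parent, category, scheme, iso, geom):
        rows.append({"code": code, "label": label, "level": level,
                     "parent": parent, "category": category,
                     "source_scheme": scheme, "country_iso": iso})
        geoms[code] = geom

    sea_names = {}
    for (letter, sea), l2 in l2_codes.items():
        sea_names[l2] = sea

    l3_children: dict[str, list] = {}
    for (l2, iso), members in coastal_groups.items():
        l3 = l3_codes[(l2, iso)]
        ordered = sorted(members, key=lambda m: _centroid_key(m.geometry))
        suffixes = (["OO"] if len(ordered) == 1 else _l4_suffixes(len(ordered)))
        for sfx, piece in zip(suffixes, ordered):
            code = make_code(4, l3=l3, suffix=sfx)
            add_row(code, piece.label, 4, l3, piece.category,
                    piece.source_scheme, piece.country_iso, piece.geometry)
            l3_children.setdefault(l3, []).append(piece)
        schemes = {m.source_scheme for m in members}
        n_groups = len(country_groups[iso])
        sample = members[0]
        if sample.category == "overlap_claim":
            l3_label = sample.label
        elif n_groups == 1:
            l3_label = sample.country_name
        else:
            l3_label = f"{sample.country_name} ({sea_names[l2]})"
        add_row(l3, l3_label, 3, l2,
                sample.category if len(members) == 1 else "coastal",
                schemes.pop() if len(schemes) == 1 else "ADHOC",
                sample.country_iso,
                unary_union([m.geometry for m in members]))
    for (l2, tname), members in hs_groups.items():
        l3 = hs_l3_codes[(l2, tname)]
        ordered = sorted(members, key=lambda m: _centroid_key(m.geometry))
        suffixes = (["OO"] if len(ordered) == 1 else _l4_suffixes(len(ordered)))
        for sfx, piece in zip(suffixes, ordered):
            code = make_code(4, l3=l3, suffix=sfx)
            label = format_label(LabelSpec(style="HIGH_SEAS",
                                           sector_tag=piece.sector_tag,
                                           feature_name=piece.feature_name))
            add_row(code, label, 4, l3, "high_seas", "GOODS",
                    HIGH_SEAS_ISO, piece.geometry)
        add_row(l3, tname, 3, l2, "high_seas", "GOODS", HIGH_SEAS_ISO,
                unary_union([m.geometry for m in members]))

    # level 2 and level 1 as unions of members
    l2_members: dict[str, list] = {}
    for row in [r for r in rows if r["level"] == 3]:
        l2_members.setdefault(row["parent"], []).append(geoms[row["code"]])
    for (letter, sea), l2 in sorted(l2_codes.items(), key=lambda kv: kv[1]):
        add_row(l2, f"{ocean_names[letter]} – {sea} coastal", 2, letter,
                "coastal", "ADHOC", None, unary_union(l2_members[l2]))
    for letter, l2 in sorted(hs_l2.items()):
        add_row(l2, f"{ocean_names[letter]} – High Seas", 2, letter,
                "high_seas", "GOODS", HIGH_SEAS_ISO, unary_union(l2_members[l2]))
    l1_members: dict[str, list] = {}
    for row in [r for r in rows if r["level"] == 2]:
        l1_members.setdefault(row["parent"], []).append(geoms[row["code"]])
    for letter, name, _ in oceans:
        if letter not in l1_members:
            continue
        add_row(letter, name, 1, None, "coastal", "ADHOC", None,
                unary_union(l1_members[letter]))

    rows.sort(key=lambda r: (r["level"], r["code"]))
    reg = load_registry(rows)
    attach_geometry(reg, geoms)
    return BuildResult(registry=reg, decisions=decisions)
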