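"""Polygon services on the WGS84 ellipsoid.

Topology (intersection, containment, splitting) is planar in lon/lat — the
recording-unit boundaries are defined in coordinate space, so plate-carrée
topology keeps the splits exact — while all *measurement* (areas, arc
lengths) is ellipsoidal.

The area of a region bounded by edges that are straight in lon/lat is

    A = ∮ G(φ) dλ,     G(φ) = ∫₀^φ M(φ') N(φ') cos φ' dφ'

with M, N the meridional and prime-vertical radii of curvature.  G has the
closed form

    G(φ) = a²(1−e²)/2 · [ sinφ/(1−e²sin²φ) + (1/2e)·ln((1+e sinφ)/(1−e sinφ)) ]

and the line integral along each edge (φ linear in λ) is evaluated by
Gauss–Legendre quadrature on sub-edges of at most one degree, which is exact
to machine precision for this smooth integrand.

Polygons crossing the antimeridian are stored split at ±180° into parts;
unit geometries are the union of their parts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
from scipy.integrate import quad
from shapely.geometry import (
    GeometryCollection,
    LineString,
    MultiPolygon,
    Point,
    Polygon,
    box,
    mapping,
    shape,
)
from shapely.geometry.polygon import orient
from shapely.ops import polygonize, unary_union
from shapely.affinity import translate

# WGS84 defining constants
WGS84_A = 6_378_137.0                 # equatorial radius, m
WGS84_F = 1.0 / 298.257223563         # flattening
WGS84_E2 = WGS84_F * (2.0 - WGS84_F)  # first eccentricity squared
_E = np.sqrt(WGS84_E2)


class GeometryError(ValueError):
    """Invalid geometry or violated geometric precondition."""


@dataclass(frozen=True)
class GeoConfig:
    """Geometric conventions of the scheme.

    depth_threshold_m
        Depth separating abyssal from bathyal high-seas units (positive
        metres downward; "deep" means depth strictly greater).
    nesting_area_tolerance
        Relative area tolerance for nesting/partition checks.
    eez_width_nm
        Nominal EEZ breadth, used when constructing synthetic worlds.
    """

    depth_threshold_m: float = 3500.0
    nesting_area_tolerance: float = 1e-6
    eez_width_nm: float = 200.0

    def __post_init__(self) -> None:
        for name in ("depth_threshold_m", "nesting_area_tolerance", "eez_width_nm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


# ---------------------------------------------------------------------------
# Ellipsoidal measurement

def _area_primitive(lat_rad: np.ndarray | float) -> np.ndarray | float:
    """G(φ): ellipsoid area between equator and φ per radian of longitude (m²)."""
    s = np.sin(lat_rad)
    return (WGS84_A**2 * (1.0 - WGS84_E2) / 2.0) * (
        s / (1.0 - WGS84_E2 * s * s)
        + (1.0 / (2.0 * _E)) * np.log((1.0 + _E * s) / (1.0 - _E * s))
    )


# 8-point Gauss–Legendre nodes/weights on [0, 1]
_GL_X, _GL_W = np.polynomial.legendre.leggauss(8)
_GL_X = 0.5 * (_GL_X + 1.0)
_GL_W = 0.5 * _GL_W


def _ring_signed_area_m2(coords: Sequence[tuple[float, float]]) -> float:
    """Signed ellipsoidal area of a closed lon/lat ring (CCW positive)."""
    pts = np.asarray(coords, dtype=float)
    if len(pts) < 4 or not np.allclose(pts[0], pts[-1]):
        raise GeometryError("ring must be closed with at least 3 distinct vertices")
    total = 0.0
    for (lon1, lat1), (lon2, lat2) in zip(pts[:-1], pts[1:]):
        dlon = lon2 - lon1
        if dlon == 0.0:
            continue
        # subdivide long edges so GL-8 stays exact to machine precision
        n = max(1, int(np.ceil(max(abs(dlon), abs(lat2 - lat1)))))
        t = (np.arange(n)[:, None] + _GL_X[None, :]) / n   # (n, 8) in [0,1]
        lat = np.radians(lat1 + (lat2 - lat1) * t)
        g = _area_primitive(lat)
        total += np.radians(dlon) / n * float(np.sum(g * _GL_W[None, :]))
    # Green's theorem: ∬ g(φ) dφ dλ = −∮ G(φ) dλ for a CCW boundary
    return -total


def geodesic_area(geom: Polygon | MultiPolygon) -> float:
    """Area of a lon/lat polygon on the WGS84 ellipsoid, in km².

    Holes are subtracted; multi-part geometries (e.g. antimeridian-split
    units) are summed.  Raises :class:`GeometryError` on invalid rings.
    """
    if geom.is_empty:
        return 0.0
    if isinstance(geom, MultiPolygon):
        return sum(geodesic_area(p) for p in geom.geoms)
    if isinstance(geom, GeometryCollection):
        return sum(geodesic_area(p) for p in geom.geoms
                   if isinstance(p, (Polygon, MultiPolygon)))
    if not isinstance(geom, Polygon):
        # lower-dimensional intersection products (shared edges, points)
        if geom.geom_type in ("LineString", "MultiLineString", "LinearRing",
                              "Point", "MultiPoint"):
            return 0.0
        raise GeometryError(f"expected a polygon, got {geom.geom_type}")
    if not geom.is_valid:
        raise GeometryError("invalid polygon ring")
    p = orient(geom, sign=1.0)  # CCW exterior, CW holes -> signed sum
    area = _ring_signed_area_m2(list(p.exterior.coords))
    for ring in p.interiors:
        area += _ring_signed_area_m2(list(ring.coords))
    return area / 1e6


def _meridian_arc_m(lat_deg: float) -> float:
    """Meridian arc length from the equator to ``lat_deg``, in metres."""
    integrand = lambda t: (1.0 - WGS84_E2 * np.sin(t) ** 2) ** -1.5
    val, _ = quad(integrand, 0.0, np.radians(lat_deg), epsabs=1e-12, epsrel=1e-12)
    return WGS84_A * (1.0 - WGS84_E2) * val


def arc_lengths(degrees: float) -> tuple[float, float]:
    """WGS84 lengths, in km, of ``degrees`` of longitude along the equator
    and of the meridian arc from the equator to latitude ``degrees``.
    """
    if not (0.0 < degrees <= 90.0):
        raise ValueError("degrees must be in (0, 90]")
    equatorial = WGS84_A * np.radians(degrees) / 1e3
    meridian = _meridian_arc_m(degrees) / 1e3
    return float(equatorial), float(meridian)


def cell_dimensions_km(degrees: float) -> tuple[float, float]:
    """East-west and north-south extent, in km, of a ``degrees``-sized
    grid cell resting on the equator.

    The north-south extent is the meridian arc from 0° to ``degrees``; the
    east-west extent is the arc of the parallel at the cell's mid-latitude
    (``degrees``/2), the natural single figure for a cell's width.  For 5°
    this yields the familiar "556 × 553 km" cell.
    """
    if not (0.0 < degrees <= 90.0):
        raise ValueError("degrees must be in (0, 90]")
    mid = np.radians(degrees / 2.0)
    n_rad = WGS84_A / np.sqrt(1.0 - WGS84_E2 * np.sin(mid) ** 2)
    width = np.radians(degrees) * n_rad * np.cos(mid) / 1e3
    height = _meridian_arc_m(degrees) / 1e3
    return float(width), float(height)


# ---------------------------------------------------------------------------
# Depth field

@dataclass
class DepthField:
    """Scalar depth field, positive metres downward.

    ``evaluator`` maps arrays of (lon, lat) to depths; ``resolution_deg`` is
    the grid step used when the field must be rasterised (contouring).
    """

    evaluator: Callable[[np.ndarray, np.ndarray], np.ndarray]
    resolution_deg: float = 1.0
    note: str = ""

    @classmethod
    def uniform(cls, depth_m: float, resolution_deg: float = 1.0) -> "DepthField":
        return cls(lambda lon, lat: np.full_like(np.asarray(lon, dtype=float), depth_m),
                   resolution_deg, note=f"uniform {depth_m} m")

    @classmethod
    def from_grid_csv(cls, path) -> "DepthField":
        """Nearest-neighbour field backed by a (lon, lat, depth_m) CSV raster."""
        import pandas as pd

        df = pd.read_csv(path)
        lons = np.sort(df["lon"].unique())
        lats = np.sort(df["lat"].unique())
        grid = (df.pivot_table(index="lat", columns="lon", values="depth_m")
                .reindex(index=lats, columns=lons).to_numpy())
        step = float(np.min(np.diff(lons))) if len(lons) > 1 else 1.0

        def evaluator(lon, lat, _lons=lons, _lats=lats, _grid=grid):
            i = np.clip(np.abs(_lats[None, :] - np.asarray(lat, dtype=float).reshape(-1, 1)).argmin(axis=1), 0, len(_lats) - 1)
            j = np.clip(np.abs(_lons[None, :] - np.asarray(lon, dtype=float).reshape(-1, 1)).argmin(axis=1), 0, len(_lons) - 1)
            return _grid[i, j].reshape(np.shape(lon))

        return cls(evaluator, resolution_deg=step, note=f"raster {path}")

    def to_grid_csv(self, path, bounds: tuple[float, float, float, float],
                    resolution_deg: Optional[float] = None) -> None:
        import pandas as pd

        r = resolution_deg or self.resolution_deg
        minx, miny, maxx, maxy = bounds
        lons = np.arange(minx + r / 2, maxx, r)
        lats = np.arange(miny + r / 2, maxy, r)
        gx, gy = np.meshgrid(lons, lats)
        depth = self.evaluator(gx, gy)
        pd.DataFrame({"lon": gx.ravel(), "lat": gy.ravel(),
                      "depth_m": np.asarray(depth).ravel()}).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Nesting / partition validation

@dataclass
class NestingReport:
    findings: list[tuple[str, str, str]] = field(default_factory=list)  # (severity, rule, message)

    @property
    def passed(self) -> bool:
        return not any(sev == "error" for sev, _, _ in self.findings)


def validate_nesting(parent: Polygon | MultiPolygon,
                     children: Sequence[Polygon | MultiPolygon],
                     cfg: GeoConfig = GeoConfig()) -> NestingReport:
    """Check that ``children`` exactly tile ``parent``.

    Reports (never raises): each child inside the parent, pairwise child
    overlaps below tolerance, and total child area equal to the parent's,
    all relative to the parent's ellipsoidal area.
    """
    if not children:
        raise ValueError("at least one child required")
    rep = NestingReport()
    parent_area = geodesic_area(parent)
    tol = cfg.nesting_area_tolerance * max(parent_area, 1e-12)
    child_areas = []
    for i, ch in enumerate(children):
        child_areas.append(geodesic_area(ch))
        outside = ch.difference(parent)
        if not outside.is_empty and geodesic_area(outside) > tol:
            rep.findings.append(
                ("error", "child-outside-parent",
                 f"child {i} extends {geodesic_area(outside):.6g} km² beyond parent"))
    for i in range(len(children)):
        for j in range(i + 1, len(children)):
            inter = children[i].intersection(children[j])
            if not inter.is_empty:
                a = geodesic_area(inter)
                if a > tol:
                    rep.findings.append(
                        ("error", "child-overlap",
                         f"children {i} and {j} overlap by {a:.6g} km²"))
    gap = abs(parent_area - sum(child_areas))
    if gap > tol:
        rep.findings.append(
            ("error", "coverage",
             f"children cover {sum(child_areas):.6g} of {parent_area:.6g} km²"))
    return rep


# ---------------------------------------------------------------------------
# Splitting and partitioning

def _as_polys(geom) -> list[Polygon]:
    if geom.is_empty:
        return []
    if isinstance(geom, Polygon):
        return [geom]
    if isinstance(geom, (MultiPolygon, GeometryCollection)):
        out: list[Polygon] = []
        for g in geom.geoms:
            out.extend(_as_polys(g))
        return out
    return []


def _sorted_parts(parts: Iterable[Polygon | MultiPolygon]):
    return sorted(parts, key=lambda g: (round(g.centroid.x, 9), round(g.centroid.y, 9)))


def _check_conservation(original, parts, cfg: GeoConfig, what: str) -> None:
    a0 = geodesic_area(original)
    a1 = sum(geodesic_area(p) for p in parts)
    if abs(a0 - a1) > cfg.nesting_area_tolerance * max(a0, 1e-12):
        raise GeometryError(
            f"{what} does not conserve area: {a1:.9g} vs {a0:.9g} km²")


def split_polygon(p: Polygon | MultiPolygon,
                  dividers: Sequence[LineString],
                  cfg: GeoConfig = GeoConfig()) -> list[Polygon | MultiPolygon]:
    """Split ``p`` along dividing polylines.

    Dividers must cut clear through: an endpoint strictly inside ``p`` is an
    error.  Parts are returned west-to-east then south-to-north by centroid,
    and the split is checked to conserve ellipsoidal area.
    """
    relevant = []
    for d in dividers:
        if not d.intersects(p):
            continue
        for end in (Point(d.coords[0]), Point(d.coords[-1])):
            if p.contains(end):
                raise GeometryError(
                    f"divider endpoint {end.wkt} dangles inside the polygon")
        relevant.append(d)
    if not relevant:
        return [p]
    lines = unary_union([p.boundary, *relevant])
    faces = [f for f in polygonize(lines)
             if f.representative_point().within(p)]
    # reattach any holes of p: polygonize produces faces of the line
    # arrangement, holes are excluded by the representative-point test
    parts = _sorted_parts(faces)
    _check_conservation(p, parts, cfg, "split_polygon")
    return parts


def clip_by_depth(p: Polygon | MultiPolygon, depth: DepthField,
                  cfg: GeoConfig = GeoConfig()):
    """Partition ``p`` at the configured depth threshold.

    Returns ``(shallow, deep)`` where "deep" means depth strictly greater
    than ``cfg.depth_threshold_m``.  The threshold contour is taken from the
    field rasterised at its own resolution, so the dividing line is accurate
    to one grid cell; the two parts always union exactly to ``p``.
    """
    if p.is_empty:
        return p, p
    r = depth.resolution_deg
    minx, miny, maxx, maxy = p.bounds
    # snap outward to the raster lattice
    x0 = np.floor(minx / r) * r
    y0 = np.floor(miny / r) * r
    nx = int(np.ceil((maxx - x0) / r))
    ny = int(np.ceil((maxy - y0) / r))
    xs = x0 + (np.arange(nx) + 0.5) * r
    ys = y0 + (np.arange(ny) + 0.5) * r
    gx, gy = np.meshgrid(xs, ys)
    deep_mask = np.asarray(depth.evaluator(gx, gy)) > cfg.depth_threshold_m
    strips = []
    for iy in range(ny):
        row = deep_mask[iy]
        ix = 0
        while ix < nx:
            if row[ix]:
                j = ix
                while j + 1 < nx and row[j + 1]:
                    j += 1
                strips.append(box(x0 + ix * r, y0 + iy * r,
                                  x0 + (j + 1) * r, y0 + (iy + 1) * r))
                ix = j + 1
            else:
                ix += 1
    if not strips:
        return p, Polygon()
    deep_region = unary_union(strips)
    deep = p.intersection(deep_region)
    shallow = p.difference(deep_region)
    _check_conservation(p, [shallow, deep], cfg, "clip_by_depth")
    return shallow, deep


def trifurcate_overlap(claim_a: Polygon | MultiPolygon,
                       claim_b: Polygon | MultiPolygon,
                       cfg: GeoConfig = GeoConfig()):
    """Resolve two overlapping claims into (a_only, b_only, joint).

    The three parts are disjoint and together cover the union of the claims;
    ``joint`` is empty iff the claims are disjoint.
    """
    joint = claim_a.intersection(claim_b)
    a_only = claim_a.difference(claim_b)
    b_only = claim_b.difference(claim_a)
    _check_conservation(claim_a.union(claim_b), [a_only, b_only, joint],
                        cfg, "trifurcate_overlap")
    return a_only, b_only, joint


# ---------------------------------------------------------------------------
# Point location

def locate_point(lon: float, lat: float,
                 l4_layer: Sequence[tuple[str, Polygon | MultiPolygon]]) -> Optional[str]:
    """Code of the basic recording unit containing a point, or None.

    Units must be pairwise disjoint (validated upstream).  Points exactly on
    a shared boundary are assigned to the lexicographically smallest code,
    so iteration is in code order and ``covers`` (boundary inclusive) is
    used.
    """
    if lon > 180.0:
        lon -= 360.0
    elif lon < -180.0:
        lon += 360.0
    pt = Point(lon, lat)
    for code, geom in sorted(l4_layer, key=lambda cg: cg[0]):
        if geom.covers(pt):
            return code
    return None


# ---------------------------------------------------------------------------
# Antimeridian handling

_WEST = box(-540.0, -90.0, -180.0, 90.0)
_MAIN = box(-180.0, -90.0, 180.0, 90.0)
_EAST = box(180.0, -90.0, 540.0, 90.0)


def normalize_antimeridian(geom: Polygon | MultiPolygon) -> Polygon | MultiPolygon:
    """Normalize a polygon drawn past ±180° into parts within [−180, 180].

    A unit crossing the antimeridian may be drawn with longitudes beyond the
    legal range (e.g. 176..184); it is stored split at ±180° and the unit's
    geometry is the union of the parts.
    """
    minx, _, maxx, _ = geom.bounds
    if minx >= -180.0 and maxx <= 180.0:
        return geom
    parts = _as_polys(geom.intersection(_MAIN))
    parts += [translate(g, xoff=-360.0) for g in _as_polys(geom.intersection(_EAST))]
    parts += [translate(g, xoff=360.0) for g in _as_polys(geom.intersection(_WEST))]
    merged = unary_union(parts)
    return merged


def unsplit_antimeridian(geom: Polygon | MultiPolygon) -> Polygon | MultiPolygon:
    """Shift western parts by +360° and re-merge an antimeridian-split unit."""
    parts = _as_polys(geom)
    shifted = [translate(g, xoff=360.0) if g.bounds[2] <= 0.0 else g for g in parts]
    return unary_union(shifted)


# ---------------------------------------------------------------------------
# GeoJSON I/O (RFC 7946)

def read_geojson(path) -> list[tuple[dict, Polygon | MultiPolygon]]:
    """Read a GeoJSON FeatureCollection into (properties, geometry) pairs."""
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("type") != "FeatureCollection":
        raise GeometryError(f"{path}: not a GeoJSON FeatureCollection")
    return [(f.get("properties") or {}, shape(f["geometry"]))
            for f in doc["features"]]


def write_geojson(path, features: Iterable[tuple[dict, Polygon | MultiPolygon]]) -> None:
    doc = {
        "type": "FeatureCollection",
        "features": [
            {"type": "Feature", "properties": props, "geometry": mapping(geom)}
            for props, geom in features
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)
        fh.write("\n")
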