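"""Independent oracles used by the tests.

The triangulation oracle computes ellipsoidal polygon area by a route
deliberately different from the library's boundary-integral method: fan
triangulation in lon/lat, recursive 4-way subdivision of each triangle, and
a midpoint rule applying the local ellipsoid area element at each tiny
triangle's centroid.  Second-order convergence makes depth-6 subdivision
(4096 sub-triangles per triangle) accurate far beyond the 0.01% comparison
tolerance for degree-scale polygons.
"""

from __future__ import annotations

import numpy as np

WGS84_A = 6_378_137.0
WGS84_F = 1.0 / 298.257223563
WGS84_E2 = WGS84_F * (2.0 - WGS84_F)


def _area_element(lat_deg: float) -> float:
    """Ellipsoid surface area per square radian of (lon, lat) at a latitude."""
    s = np.sin(np.radians(lat_deg))
    return WGS84_A**2 * (1.0 - WGS84_E2) * np.cos(np.radians(lat_deg)) \
        / (1.0 - WGS84_E2 * s * s) ** 2


def _tri_area(tri: np.ndarray, depth: int) -> float:
    if depth == 0:
        (x1, y1), (x2, y2), (x3, y3) = tri
        planar = 0.5 * abs((x2 - x1) * (y3 - y1) - (x3 - x1) * (y2 - y1))
        return planar * np.radians(1.0) ** 2 * _area_element(tri[:, 1].mean())
    m12 = (tri[0] + tri[1]) / 2
    m23 = (tri[1] + tri[2]) / 2
    m31 = (tri[2] + tri[0]) / 2
    return (_tri_area(np.array([tri[0], m12, m31]), depth - 1)
            + _tri_area(np.array([m12, tri[1], m23]), depth - 1)
            + _tri_area(np.array([m31, m23, tri[2]]), depth - 1)
            + _tri_area(np.array([m12, m23, m31]), depth - 1))


def triangulation_area_km2(exterior_coords, depth: int = 6) -> float:
    """Ellipsoidal area of a convex lon/lat polygon by dense triangulation."""
    pts = np.asarray(exterior_coords, dtype=float)
    if np.allclose(pts[0], pts[-1]):
        pts = pts[:-1]
    total = 0.0
    for i in range(1, len(pts) - 1):
        total += _tri_area(np.array([pts[0], pts[i], pts[i + 1]]), depth)
    return total / 1e6


def random_convex_polygon(rng: np.random.Generator, max_extent_deg: float = 2.0):
    """Random small convex polygon away from the poles (returns coords)."""
    from scipy.spatial import ConvexHull

    lon0 = rng.uniform(-170, 170)
    lat0 = rng.uniform(-65, 65)
    pts = np.column_stack([
        lon0 + rng.uniform(0, max_extent_deg, 8),
        lat0 + rng.uniform(0, max_extent_deg, 8),
    ])
    hull = ConvexHull(pts)
    return pts[hull.vertices]
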