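"""Division-of-labor statistic: alpha-shape search areas and their overlap.

Each ground player's trajectory (downsampled to 5 Hz, first second trimmed)
is wrapped in the tightest single bounding polygon obtainable from its
Delaunay alpha complex: triangles are admitted by circumradius threshold (the
rolling-circle radius), and the smallest threshold whose triangle set covers
every point and is edge-connected is found by bisection over the sorted
circumradii.  If no threshold improves on keeping every triangle, the shape
is the convex hull and is flagged as such.  Interior holes are filled
(outer boundary only) and flagged.

The team's overlap proportion is area(union of the three pairwise polygon
intersections) / area(union of the three polygons): 0 means a cleanly
partitioned search, 1 identical coverage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np
from scipy.spatial import Delaunay, QhullError
from shapely.geometry import MultiPoint, Polygon
from shapely.ops import unary_union

__all__ = [
    "DegenerateGeometryError",
    "SearchPolygon",
    "OverlapResult",
    "preprocess_trajectory",
    "search_polygon",
    "proportion_overlap",
]


class DegenerateGeometryError(ValueError):
    """Raised when a point set cannot support a 2-D bounding polygon."""


@dataclass
class SearchPolygon:
    """A player's bounding search polygon."""

    polygon: Polygon
    method: str  # "alpha_shape" | "convex_hull_fallback"
    alpha_radius: float  # rolling-circle radius actually used
    has_holes: bool = False

    @property
    def area(self) -> float:
        return float(self.polygon.area)

    def exterior_coords(self) -> list[tuple[float, float]]:
        """Outer vertex ring, GeoJSON-style (closed, counter-clockwise)."""
        ring = self.polygon.exterior
        coords = list(ring.coords)
        return coords if ring.is_ccw else coords[::-1]


@dataclass
class OverlapResult:
    overlap_area: float
    total_area: float

    @property
    def proportion(self) -> float:
        return self.overlap_area / self.total_area


def preprocess_trajectory(
    traj: np.ndarray,
    tick_rate: float,
    sample_rate: float = 5.0,
    trim_seconds: float = 1.0,
) -> np.ndarray:
    """Trim the first second and downsample a (T, 2) trajectory to 5 Hz.

    When ``tick_rate`` is not an integer multiple of ``sample_rate`` the
    nearest sample is taken.  A trajectory no longer than the trimmed period
    is rejected; exactly the trimmed length yields an empty point set (which
    downstream polygon construction will reject).
    """
    traj = np.asarray(traj, dtype=float)
    if traj.ndim != 2 or traj.shape[1] != 2:
        raise ValueError("trajectory must have shape (T, 2)")
    n_trim = int(round(trim_seconds * tick_rate))
    if len(traj) < n_trim:
        raise ValueError(
            f"trajectory shorter than the {trim_seconds} s transient trim"
        )
    rest = traj[n_trim:]
    if len(rest) == 0:
        return rest.reshape(0, 2)
    step = tick_rate / sample_rate
    if abs(step - round(step)) < 1e-9:
        return rest[:: int(round(step))]
    idx = np.round(np.arange(0, len(rest) - 0.5, step)).astype(int)
    return rest[np.clip(idx, 0, len(rest) - 1)]


def _circumradii(pts: np.ndarray, simplices: np.ndarray) -> np.ndarray:
    a, b, c = pts[simplices[:, 0]], pts[simplices[:, 1]], pts[simplices[:, 2]]
    la = np.hypot(*(b - c).T)
    lb = np.hypot(*(c - a).T)
    lc = np.hypot(*(a - b).T)
    cross = (b[:, 0] - a[:, 0]) * (c[:, 1] - a[:, 1]) - (b[:, 1] - a[:, 1]) * (
        c[:, 0] - a[:, 0]
    )
    area2 = np.abs(cross)  # 2 * triangle area
    with np.errstate(divide="ignore", invalid="ignore"):
        r = la * lb * lc / (2.0 * area2)
    r[area2 < 1e-300] = np.inf
    return r


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def _feasible(
    keep: np.ndarray, simplices: np.ndarray, n_points: int
) -> bool:
    """Do the kept triangles cover every point and form one edge-connected piece?"""
    kept = np.flatnonzero(keep)
    if len(kept) == 0:
        return False
    if len(np.unique(simplices[kept])) != n_points:
        return False
    uf = _UnionFind(len(kept))
    edge_owner: dict[tuple[int, int], int] = {}
    for local, tri_idx in enumerate(kept):
        s = simplices[tri_idx]
        for e in ((s[0], s[1]), (s[1], s[2]), (s[0], s[2])):
            key = (min(e), max(e))
            other = edge_owner.get(key)
            if other is None:
                edge_owner[key] = local
            else:
                uf.union(local, other)
    root = uf.find(0)
    return all(uf.find(i) == root for i in range(len(kept)))


def _hull_fallback(pts: np.ndarray) -> SearchPolygon:
    hull = MultiPoint([tuple(p) for p in pts]).convex_hull
    if not isinstance(hull, Polygon):
        raise DegenerateGeometryError("points are collinear; no bounding polygon")
    return SearchPolygon(hull, "convex_hull_fallback", alpha_radius=float("inf"))


def search_polygon(points: np.ndarray) -> SearchPolygon:
    """Tightest single bounding polygon of a 2-D point set.

    Requires at least three non-collinear (distinct) points; degenerate
    inputs raise :class:`DegenerateGeometryError`.
    """
    pts = np.unique(np.asarray(points, dtype=float), axis=0)
    if pts.ndim != 2 or pts.shape[0] < 3 or pts.shape[1] != 2:
        raise DegenerateGeometryError("need at least 3 distinct 2-D points")
    try:
        tri = Delaunay(pts)
    except QhullError as exc:
        raise DegenerateGeometryError(f"degenerate point set: {exc}") from exc
    simplices = tri.simplices
    radii = _circumradii(pts, simplices)
    thresholds = np.unique(radii)
    n_points = len(pts)

    def feasible_at(i: int) -> bool:
        return _feasible(radii <= thresholds[i], simplices, n_points)

    lo, hi = 0, len(thresholds) - 1
    if not feasible_at(hi):  # full triangulation should always work
        return _hull_fallback(pts)
    while lo < hi:
        mid = (lo + hi) // 2
        if feasible_at(mid):
            hi = mid
        else:
            lo = mid + 1
    chosen = thresholds[lo]
    if lo == len(thresholds) - 1 or not np.isfinite(chosen):
        # alpha could not improve on the full triangulation: convex hull
        return _hull_fallback(pts)

    keep = radii <= chosen
    shape = unary_union(
        [Polygon(pts[s]) for s in simplices[keep]]
    )
    if not isinstance(shape, Polygon) or shape.is_empty:
        return _hull_fallback(pts)
    has_holes = len(shape.interiors) > 0
    if has_holes:
        shape = Polygon(shape.exterior)
    return SearchPolygon(
        shape, "alpha_shape", alpha_radius=float(chosen), has_holes=has_holes
    )


def proportion_overlap(
    polygons: Sequence[Union[SearchPolygon, Polygon]],
) -> OverlapResult:
    """Fraction of the team's total search area covered by >= 2 players.

    The overlap region is the union of the three pairwise intersections, so
    triple overlap is counted once; the total is the union of all three.
    """
    if len(polygons) != 3:
        raise ValueError("proportion_overlap expects exactly 3 polygons")
    geoms = [p.polygon if isinstance(p, SearchPolygon) else p for p in polygons]
    for g in geoms:
        if g.is_empty or not g.is_valid:
            raise ValueError("all polygons must be valid and non-empty")
    pairs = [
        geoms[0].intersection(geoms[1]),
        geoms[0].intersection(geoms[2]),
        geoms[1].intersection(geoms[2]),
    ]
    overlap = unary_union(pairs)
    total = unary_union(geoms)
    if total.area <= 0.0:
        raise ValueError("total search area is zero")
    return OverlapResult(
        overlap_area=float(overlap.area), total_area=float(total.area)
    )
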