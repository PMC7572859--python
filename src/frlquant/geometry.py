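"""Calibrated 2-D geometry for replica quantification.

All lengths are in nanometres internally; areas cross to square
micrometres only at reporting/I-O boundaries (1 um^2 = 1e6 nm^2).
Coordinates follow the image convention: origin top-left, y increasing
downward, which matches how micrograph pixels are indexed.

The postsynaptic specialization on a replica is demarcated by connecting
the outermost intramembrane particles (IMPs); here that outline is the
convex hull of the IMP point set.  Membership of a gold particle in a
demarcated cluster uses an inclusive dilation rule: a particle belongs
to the cluster if it lies inside the hull or within ``d`` nm of its edge
(default 30 nm, the nominal reach of the primary/secondary antibody
bridge between a gold particle and its antigen).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import shapely
from scipy.spatial import ConvexHull, QhullError
from shapely.geometry import Point as _ShapelyPoint
from shapely.geometry import Polygon as _ShapelyPolygon

NM_PER_UM = 1.0e3
NM2_PER_UM2 = 1.0e6

__all__ = [
    "Point",
    "Polygon",
    "DilationRadius",
    "DegenerateGeometryError",
    "convex_hull",
    "polygon_area",
    "distance_to_boundary",
    "within_dilation",
    "rasterize_mask",
    "rasterized_area",
    "rasterized_dilation_mask",
]


class DegenerateGeometryError(ValueError):
    """Raised when a point set or polygon cannot support a 2-D demarcation."""


@dataclass(frozen=True)
class Point:
    """A planar location in nm (image convention: y grows downward)."""

    x: float
    y: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.x) and np.isfinite(self.y)):
            raise ValueError(f"non-finite coordinate: ({self.x}, {self.y})")

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y], dtype=float)


@dataclass(frozen=True)
class DilationRadius:
    """Dilation distance in nm for cluster-membership tests (default 30)."""

    d: float = 30.0

    def __post_init__(self) -> None:
        if self.d < 0:
            raise ValueError(f"dilation radius must be >= 0, got {self.d}")


class Polygon:
    """A simple polygon with vertices in nm, counter-clockwise.

    "Counter-clockwise" is taken in the image coordinate frame (y down),
    i.e. positive signed area under the shoelace formula with y negated.
    Vertices are stored without the closing repeat.
    """

    def __init__(self, vertices: Iterable[Point] | np.ndarray):
        arr = _as_xy_array(vertices)
        if arr.shape[0] < 3:
            raise DegenerateGeometryError(
                f"polygon needs >= 3 vertices, got {arr.shape[0]}"
            )
        poly = _ShapelyPolygon(arr)
        if not poly.is_valid:
            raise DegenerateGeometryError("polygon is self-intersecting or invalid")
        if poly.area <= 0.0:
            raise DegenerateGeometryError("polygon has zero area")
        # normalize orientation: shapely's ccw in a y-up frame is cw in the
        # image frame; store so that signed shoelace area (y down) > 0
        if _signed_area_image(arr) < 0:
            arr = arr[::-1].copy()
        self._xy = arr
        self._shapely = _ShapelyPolygon(arr)

    # -- accessors -------------------------------------------------------
    @property
    def vertices(self) -> tuple[Point, ...]:
        return tuple(Point(float(x), float(y)) for x, y in self._xy)

    @property
    def xy(self) -> np.ndarray:
        """Vertex array of shape (n, 2), nm."""
        return self._xy.copy()

    @property
    def shapely(self) -> _ShapelyPolygon:
        return self._shapely

    @property
    def area_nm2(self) -> float:
        return float(self._shapely.area)

    @property
    def centroid(self) -> Point:
        c = self._shapely.centroid
        return Point(float(c.x), float(c.y))

    def __len__(self) -> int:
        return self._xy.shape[0]

    def __repr__(self) -> str:  # pragma: no cover
        return f"Polygon({len(self)} vertices, {self.area_nm2:.1f} nm^2)"

    def __geo_interface__(self):  # pragma: no cover
        return self._shapely.__geo_interface__

    def contains_xy(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Vectorized inside-or-on-boundary test."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        inside = shapely.contains_xy(self._shapely, x, y)
        if np.all(inside):
            return inside
        # contains_xy excludes the boundary; pull boundary points back in
        on_edge = shapely.intersects_xy(self._shapely.exterior, x, y)
        return inside | on_edge


def _as_xy_array(points: Iterable[Point] | np.ndarray) -> np.ndarray:
    if isinstance(points, np.ndarray):
        arr = np.asarray(points, dtype=float)
    else:
        pts = list(points)
        if pts and isinstance(pts[0], Point):
            arr = np.array([[p.x, p.y] for p in pts], dtype=float)
        else:
            arr = np.asarray(pts, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError(f"expected an (n, 2) coordinate array, got {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite coordinates")
    return arr


def _signed_area_image(xy: np.ndarray) -> float:
    """Shoelace signed area in the image frame (positive == ccw, y down)."""
    x, y = xy[:, 0], xy[:, 1]
    # negate because y grows downward
    return -0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def convex_hull(points: Iterable[Point] | np.ndarray) -> Polygon:
    """Demarcate a point set by its convex hull.

    This is the package's reading of "connecting the outermost IMP
    particles": the smallest convex outline enclosing every IMP.

    Raises
    ------
    DegenerateGeometryError
        for fewer than 3 points or an (all-)collinear set.
    """
    arr = _as_xy_array(points)
    if arr.shape[0] < 3:
        raise DegenerateGeometryError(
            f"convex hull needs >= 3 points, got {arr.shape[0]}"
        )
    try:
        hull = ConvexHull(arr)
    except QhullError as exc:
        raise DegenerateGeometryError(f"degenerate point set: {exc}") from exc
    return Polygon(arr[hull.vertices])


def polygon_area(poly: Polygon) -> float:
    """Polygon area in um^2 (shoelace, converted at 1 um^2 = 1e6 nm^2)."""
    return poly.area_nm2 / NM2_PER_UM2


def distance_to_boundary(p: Point | Sequence[float], poly: Polygon) -> float:
    """Distance (nm) from a point to the polygon: 0 inside or on boundary,
    otherwise the minimum Euclidean distance to any edge segment."""
    if isinstance(p, Point):
        g = _ShapelyPoint(p.x, p.y)
    else:
        g = _ShapelyPoint(float(p[0]), float(p[1]))
    return float(poly.shapely.distance(g))


def distances_to_boundary(xy: np.ndarray, poly: Polygon) -> np.ndarray:
    """Vectorized :func:`distance_to_boundary` for an (n, 2) array."""
    xy = np.asarray(xy, dtype=float)
    if xy.size == 0:
        return np.zeros(0)
    pts = shapely.points(xy)
    return shapely.distance(pts, poly.shapely)


def within_dilation(
    p: Point | Sequence[float], poly: Polygon, r: DilationRadius | float = DilationRadius()
) -> bool:
    """Inclusive dilation membership: True iff the point is inside the
    polygon or within ``r`` nm of its boundary (<=, so a point exactly at
    the dilation distance is accepted)."""
    d = r.d if isinstance(r, DilationRadius) else float(r)
    if d < 0:
        raise ValueError("dilation radius must be >= 0")
    return distance_to_boundary(p, poly) <= d


def within_dilation_mask(
    xy: np.ndarray, poly: Polygon, r: DilationRadius | float = DilationRadius()
) -> np.ndarray:
    """Vectorized dilation membership for an (n, 2) array of nm coords."""
    d = r.d if isinstance(r, DilationRadius) else float(r)
    return distances_to_boundary(xy, poly) <= d


# ---------------------------------------------------------------------------
# Rasterization oracle
# ---------------------------------------------------------------------------

def _pixel_grid(bounds: tuple[float, float, float, float], px: float):
    x0, y0, x1, y1 = bounds
    nx = max(1, int(np.ceil((x1 - x0) / px)))
    ny = max(1, int(np.ceil((y1 - y0) / px)))
    xs = x0 + (np.arange(nx) + 0.5) * px
    ys = y0 + (np.arange(ny) + 0.5) * px
    return xs, ys


def rasterize_mask(poly: Polygon, px: float = 0.25, pad: float = 0.0):
    """Boolean pixel mask of the polygon sampled at pixel centers.

    Returns ``(mask, (x0, y0))`` where pixel (i, j) covers the nm square
    with center ``(x0 + (j + 0.5) px, y0 + (i + 0.5) px)``; 0-based
    indices, row i along y (down).  Intended as an independent check of
    the analytic geometry, not for production use.
    """
    minx, miny, maxx, maxy = poly.shapely.bounds
    x0, y0 = minx - pad, miny - pad
    xs, ys = _pixel_grid((x0, y0, maxx + pad, maxy + pad), px)
    gx, gy = np.meshgrid(xs, ys)
    mask = shapely.contains_xy(poly.shapely, gx.ravel(), gy.ravel()).reshape(gx.shape)
    return mask, (x0, y0)


def rasterized_area(poly: Polygon, px: float = 0.25) -> float:
    """Monte-Carlo-free pixel-count area estimate in um^2 at ``px`` nm/px."""
    mask, _ = rasterize_mask(poly, px=px)
    return float(mask.sum()) * px * px / NM2_PER_UM2


def rasterized_dilation_mask(poly: Polygon, d: float, px: float = 0.25):
    """Pixel mask of the polygon dilated by ``d`` nm (rounded corners),
    the brute-force counterpart of :func:`within_dilation`."""
    dil = poly.shapely.buffer(d, quad_segs=64)
    minx, miny, maxx, maxy = dil.bounds
    x0, y0 = minx - px, miny - px
    xs, ys = _pixel_grid((x0, y0, maxx + px, maxy + px), px)
    gx, gy = np.meshgrid(xs, ys)
    mask = shapely.contains_xy(dil, gx.ravel(), gy.ravel()).reshape(gx.shape)
    return mask, (x0, y0)
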