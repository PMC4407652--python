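"""Arc-length polyline geometry and spatial-distribution measures.

Everything here works in the image frame: pixel units, x rightward,
y *downward*.  Three measures carry the scientific load:

* the centre of mass of the root material, computed as the mean of points
  sampled at regular arc-length intervals along every root — equivalent to a
  length-weighted mean position under the assumption of uniform linear
  density;
* the convex hull of all sampled points (Andrew's monotone chain), whose
  area |A| is the root-system spread;
* the hull centroid via the shoelace identities

      A  = 1/2 Σ (x_i y_{i+1} − x_{i+1} y_i)
      C_x = 1/(6A) Σ (x_i + x_{i+1})(x_i y_{i+1} − x_{i+1} y_i)
      C_y = 1/(6A) Σ (y_i + y_{i+1})(x_i y_{i+1} − x_{i+1} y_i)

  with the wrap-around convention (x_{n+1}, y_{n+1}) = (x_1, y_1).

Single-root seedlings produce degenerate (collinear) hulls; these are
represented explicitly and flagged rather than raising, so a one-seminal
plant flows through the trait pipeline.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .architecture import Point2D, as_point_array
from .errors import DegenerateInputError

#: area below which a hull is treated as collinear/degenerate (px^2)
DEGENERATE_AREA_TOL = 1e-9


@dataclass
class Polygon:
    """A closed polygon ring (last vertex implicitly joins the first).

    ``degenerate`` marks hulls with fewer than 3 vertices (collinear input);
    such polygons have zero area and no shoelace centroid.
    """

    vertices: np.ndarray
    degenerate: bool = False

    def __post_init__(self) -> None:
        self.vertices = as_point_array(self.vertices)

    def __len__(self) -> int:
        return len(self.vertices)

    def contains(self, point, atol: float = 1e-9) -> bool:
        """Point-in-convex-polygon test (boundary counts as inside)."""
        if self.degenerate or len(self.vertices) < 3:
            return False
        p = np.asarray(point, dtype=float)
        v = self.vertices
        w = np.roll(v, -1, axis=0)
        cross = (w[:, 0] - v[:, 0]) * (p[1] - v[:, 1]) \
            - (w[:, 1] - v[:, 1]) * (p[0] - v[:, 0])
        return bool(np.all(cross >= -atol) or np.all(cross <= atol))


@dataclass
class SampledRoot:
    """A root resampled at regular arc-length steps.

    Points sit at arc lengths 0, interval, 2*interval, ...; the terminal
    polyline endpoint is always appended so total length is preserved.
    """

    points: np.ndarray
    interval: float
    source_root_id: str | None = None


def polyline_length(points) -> float:
    """Total Euclidean length of an ordered polyline (0 for a single point)."""
    pts = as_point_array(points)
    if len(pts) < 2:
        return 0.0
    seg = np.diff(pts, axis=0)
    return float(np.hypot(seg[:, 0], seg[:, 1]).sum())


def cumulative_arclength(points) -> np.ndarray:
    """Arc length from the first vertex to each vertex."""
    pts = as_point_array(points)
    seg = np.diff(pts, axis=0)
    return np.concatenate([[0.0], np.cumsum(np.hypot(seg[:, 0], seg[:, 1]))])


def _interp_at(pts: np.ndarray, cum: np.ndarray, s) -> np.ndarray:
    x = np.interp(s, cum, pts[:, 0])
    y = np.interp(s, cum, pts[:, 1])
    return np.column_stack([x, y])


def resample(points, interval: float,
             source_root_id: str | None = None) -> SampledRoot:
    """Resample a polyline at regular arc-length intervals.

    Linear interpolation within segments; the terminal point is retained even
    when the final step is shorter than ``interval``.
    """
    if interval <= 0:
        raise ValueError(f"interval must be positive, got {interval}")
    pts = as_point_array(points)
    cum = cumulative_arclength(pts)
    total = float(cum[-1])
    if total <= 0.0:
        raise DegenerateInputError("cannot resample a zero-length polyline")
    stations = np.arange(0.0, total, interval)
    if total - stations[-1] > 1e-12 * max(1.0, total):
        stations = np.concatenate([stations, [total]])
    else:
        stations[-1] = total
    return SampledRoot(points=_interp_at(pts, cum, stations),
                       interval=float(interval),
                       source_root_id=source_root_id)


def point_at_arclength(points, s: float, clamp: bool = False) -> Point2D:
    """The point at arc length ``s`` along the polyline.

    With ``clamp=True`` an ``s`` beyond the total length returns the tip
    (and a negative ``s`` the base) instead of raising.
    """
    pts = as_point_array(points)
    cum = cumulative_arclength(pts)
    total = float(cum[-1])
    if total <= 0.0:
        raise DegenerateInputError("polyline has zero length")
    if not clamp and not (0.0 <= s <= total):
        raise ValueError(f"arc length {s} outside [0, {total}]")
    s = min(max(s, 0.0), total)
    p = _interp_at(pts, cum, s)[0]
    return Point2D(float(p[0]), float(p[1]))


def point_at_fraction(points, f: float) -> Point2D:
    """The point at fraction ``f`` of the polyline's own length (f in [0,1])."""
    if not (0.0 <= f <= 1.0):
        raise ValueError(f"fraction must lie in [0, 1], got {f}")
    pts = as_point_array(points)
    cum = cumulative_arclength(pts)
    total = float(cum[-1])
    if total <= 0.0:
        raise DegenerateInputError("polyline has zero length")
    p = _interp_at(pts, cum, f * total)[0]
    return Point2D(float(p[0]), float(p[1]))


def center_of_mass(polylines, interval: float = 1.0) -> Point2D:
    """Centre of mass of root material under uniform linear density.

    Each root is sampled at regular ``interval`` arc-length steps and the
    plain mean of all samples is returned; with a common interval every
    root's influence is proportional to its length.
    """
    if interval <= 0:
        raise ValueError(f"interval must be positive, got {interval}")
    chunks = []
    for poly in polylines:
        pts = as_point_array(poly)
        if polyline_length(pts) <= 0.0:
            continue
        chunks.append(resample(pts, interval).points)
    if not chunks:
        raise DegenerateInputError("no root with nonzero length")
    samples = np.vstack(chunks)
    m = samples.mean(axis=0)
    return Point2D(float(m[0]), float(m[1]))


def _cross(o, a, b) -> float:
    return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])


def convex_hull(points) -> Polygon:
    """Convex hull by Andrew's monotone chain.

    Vertices are returned counter-clockwise in the mathematical (y-up) sense
    with collinear interior vertices removed; sorting ties break by (x, y).
    All-collinear input yields a degenerate 2-vertex (or 1-vertex) polygon.
    """
    pts = np.unique(as_point_array(points), axis=0)  # sorts lexicographically
    if len(pts) == 1:
        return Polygon(vertices=pts, degenerate=True)

    def half(iterable):
        chain: list[np.ndarray] = []
        for p in iterable:
            while len(chain) >= 2 and _cross(chain[-2], chain[-1], p) <= 0:
                chain.pop()
            chain.append(p)
        return chain

    lower = half(pts)
    upper = half(pts[::-1])
    hull = np.array(lower[:-1] + upper[:-1])
    if len(hull) < 3:
        extremes = np.array([pts[0], pts[-1]])
        return Polygon(vertices=extremes, degenerate=True)
    return Polygon(vertices=hull, degenerate=False)


def signed_area(polygon) -> float:
    """Shoelace signed area; positive for counter-clockwise (y-up) rings.

    Polygons with fewer than 3 vertices are degenerate and return 0.
    """
    v = polygon.vertices if isinstance(polygon, Polygon) else as_point_array(polygon)
    if len(v) < 3:
        return 0.0
    w = np.roll(v, -1, axis=0)
    return float(0.5 * np.sum(v[:, 0] * w[:, 1] - w[:, 0] * v[:, 1]))


def hull_centroid(polygon, area_tol: float = DEGENERATE_AREA_TOL) -> Point2D:
    """Centroid of a polygon via the shoelace identities.

    For degenerate polygons (|A| <= ``area_tol``) the arithmetic mean of the
    vertices is returned; callers should propagate the degeneracy flag.
    """
    v = polygon.vertices if isinstance(polygon, Polygon) else as_point_array(polygon)
    a = signed_area(v)
    if len(v) < 3 or abs(a) <= area_tol:
        m = v.mean(axis=0)
        return Point2D(float(m[0]), float(m[1]))
    w = np.roll(v, -1, axis=0)
    cross = v[:, 0] * w[:, 1] - w[:, 0] * v[:, 1]
    cx = float(np.sum((v[:, 0] + w[:, 0]) * cross) / (6.0 * a))
    cy = float(np.sum((v[:, 1] + w[:, 1]) * cross) / (6.0 * a))
    return Point2D(cx, cy)


def extent(points, origin) -> tuple[float, float]:
    """(width, depth) of a point set: width = max(x)−min(x); depth is the
    deepest point below the origin (y-down frame), floored at 0."""
    pts = as_point_array(points)
    width = float(pts[:, 0].max() - pts[:, 0].min())
    depth = float(max(pts[:, 1].max() - float(origin[1]), 0.0))
    return width, depth
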