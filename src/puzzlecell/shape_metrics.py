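"""Per-cell shape descriptors for pavement-cell contours.

The descriptors quantify how a cell accommodates growth-induced wall stress:

* **area / perimeter** — basic size measures (um^2, um).
* **lobeyness** — perimeter divided by convex-hull perimeter.  Exactly 1 for
  convex outlines, larger for lobed (jigsaw) cells; an inverse measure of
  convexity that separates lobed cells from smoothly curved elongated ones.
* **min-axis** — the width of the narrowest rectangle that encloses the cell,
  i.e. its shortest dimension.  Long thin cells have small min-axis even when
  their area is large.
* **largest empty circle (LEC)** — the biggest circle fitting inside the
  outline; a 2D proxy for the maximal unsupported wall span and hence for
  turgor-driven tensile stress.
"""

from __future__ import annotations

import heapq
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon

from . import _geom
from .contour_io import Contour, ContourSet
from .errors import MetricError


@dataclass(frozen=True)
class ShapeMetrics:
    """Bundle of per-cell descriptors (lengths in um, areas in um^2)."""

    area: float
    perimeter: float
    hull_perimeter: float
    lobeyness: float
    min_axis: float
    lec_center: tuple[float, float]
    lec_radius: float

    @property
    def lec_diameter(self) -> float:
        return 2.0 * self.lec_radius

    @property
    def lec_area(self) -> float:
        return math.pi * self.lec_radius**2


def _pts(c: Contour | np.ndarray) -> np.ndarray:
    if isinstance(c, Contour):
        return np.asarray(c.vertices, dtype=float)
    return np.asarray(c, dtype=float)


def polygon_area(c: Contour | np.ndarray) -> float:
    """Unsigned shoelace area, independent of orientation and start vertex."""
    a = abs(_geom.signed_area(_pts(c)))
    if a <= 0.0:
        raise MetricError("degenerate (zero-area) polygon")
    return a


def perimeter(c: Contour | np.ndarray) -> float:
    return _geom.perimeter(_pts(c))


def convex_hull(c: Contour | np.ndarray) -> np.ndarray:
    hull = _geom.convex_hull(_pts(c))
    if len(hull) < 3:
        raise MetricError("convex hull is degenerate (collinear contour)")
    return hull


def _lobeyness_ratio(peri: float, hull_peri: float) -> float:
    ratio = peri / hull_peri
    # convex contours must score exactly 1; summation order across the hull
    # cycle can differ from the contour cycle by a few ulp
    if abs(ratio - 1.0) < 1e-12:
        return 1.0
    return ratio


def lobeyness(c: Contour | np.ndarray) -> float:
    """Perimeter / convex-hull perimeter; >= 1, equality iff convex."""
    hull = convex_hull(c)
    return _lobeyness_ratio(perimeter(c), _geom.perimeter(hull))


def min_axis(c: Contour | np.ndarray, n_angles: int = 3600,
             method: str = "sampled") -> tuple[float, np.ndarray]:
    """Smallest width of the contour and the direction along which it occurs.

    Widths are measured by projecting the convex hull onto candidate axes,
    which leaves the width unchanged while shrinking the vertex count.  The
    default densely samples orientations over [0, pi) (projection width is
    invariant under a half-turn, so the half range covers all axes);
    ``method="exact"`` instead evaluates only the hull-edge orientations,
    one of which always attains the true minimum width (rotating-calipers
    argument).  Ties are broken toward the smallest angle.
    """
    hull = convex_hull(c)
    if method == "sampled":
        if n_angles < 2:
            raise ValueError("n_angles must be >= 2")
        angles = np.linspace(0.0, np.pi, n_angles, endpoint=False)
    elif method == "exact":
        # the min width is attained perpendicular to a hull edge, so the
        # candidate measurement axes are the edge normals
        edges = np.roll(hull, -1, axis=0) - hull
        angles = np.sort((np.arctan2(edges[:, 1], edges[:, 0]) + np.pi / 2) % np.pi)
    else:
        raise ValueError(f"unknown method {method!r}")
    dirs = np.column_stack([np.cos(angles), np.sin(angles)])
    proj = hull @ dirs.T  # (n_hull, n_angles)
    widths = proj.max(axis=0) - proj.min(axis=0)
    i = int(np.argmin(widths))
    return float(widths[i]), dirs[i]


def largest_empty_circle(c: Contour | np.ndarray,
                         tolerance: float | None = None) -> tuple[np.ndarray, float]:
    """Center and radius of the largest circle inscribed in the contour.

    Quadtree-style refinement of the signed distance to the boundary (the
    pole-of-inaccessibility search): square cells are scored by the largest
    inscribed radius they could contain and split best-first until the bound
    is within ``tolerance`` of the incumbent.  Robust on noisy outlines where
    a boundary-Voronoi construction is brittle.  Ties are resolved toward
    the lexicographically smallest (x, y) center.  Default tolerance is 0.5%
    of the min-axis width.
    """
    pts = _pts(c)
    if tolerance is None:
        tolerance = 0.005 * min_axis(pts, method="exact")[0]
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    poly = Polygon(pts)
    if not poly.is_valid:
        poly = poly.buffer(0)
    boundary = poly.exterior if hasattr(poly, "exterior") else poly.boundary

    def score(x: float, y: float) -> float:
        d = boundary.distance(Point(x, y))
        return d if poly.contains(Point(x, y)) else -d

    minx, miny, maxx, maxy = poly.bounds
    w, hgt = maxx - minx, maxy - miny
    if min(w, hgt) < tolerance:
        warnings.warn("contour thinner than LEC tolerance; radius is tolerance-limited",
                      stacklevel=2)
    cell = max(min(w, hgt), tolerance)
    sqrt2 = math.sqrt(2.0)
    # seed with square cells tiling the bounding box, best-first refine
    heap: list[tuple[float, float, float, float]] = []

    def push(x: float, y: float, half: float) -> None:
        heapq.heappush(heap, (-(score(x, y) + half * sqrt2), x, y, half))

    y0 = miny
    while y0 < maxy:
        x0 = minx
        while x0 < maxx:
            push(x0 + cell / 2, y0 + cell / 2, cell / 2)
            x0 += cell
        y0 += cell
    cx, cy = _geom.centroid(pts)
    best_r = score(cx, cy)
    best = (cx, cy)
    while heap:
        neg_bound, x, y, half = heapq.heappop(heap)
        bound = -neg_bound
        if bound <= best_r + tolerance:
            break
        d = score(x, y)
        if d > best_r + 1e-15 or (abs(d - best_r) <= 1e-15 and (x, y) < best):
            best_r, best = d, (x, y)
        q = half / 2.0
        for dx in (-q, q):
            for dy in (-q, q):
                push(x + dx, y + dy, q)
    if best_r < 0:
        raise MetricError("failed to locate an interior point for the LEC")
    return np.array(best), float(best_r)


_NEUTRAL_FLOOR = 1e-9


def directional_lobe_bias(c: Contour | np.ndarray) -> float | None:
    """Ratio of vertical to horizontal boundary excursion in excess of the hull.

    ``Ey`` sums |dy| over contour edges minus |dy| over hull edges; ``Ex``
    analogously for |dx|.  The ratio ``Ey / Ex`` exceeds 1 when lobes
    protrude predominantly vertically and is below 1 for horizontal lobes.
    Convex outlines have no excess excursion in either axis and return
    ``None`` (the neutral flag) rather than a ratio.
    """
    pts = _pts(c)
    hull = convex_hull(pts)
    d = np.abs(np.roll(pts, -1, axis=0) - pts).sum(axis=0)
    dh = np.abs(np.roll(hull, -1, axis=0) - hull).sum(axis=0)
    ex, ey = d[0] - dh[0], d[1] - dh[1]
    scale = max(d[0], d[1], 1.0)
    if ex < _NEUTRAL_FLOOR * scale and ey < _NEUTRAL_FLOOR * scale:
        return None
    ex = max(ex, _NEUTRAL_FLOOR * scale)
    ey = max(ey, _NEUTRAL_FLOOR * scale)
    return float(ey / ex)


def compute_metrics(c: Contour | np.ndarray, n_angles: int = 3600,
                    lec_tolerance: float | None = None) -> ShapeMetrics:
    """All descriptors for one contour."""
    width, _ = min_axis(c, n_angles=n_angles)
    center, radius = largest_empty_circle(c, tolerance=lec_tolerance)
    hull = convex_hull(c)
    return ShapeMetrics(
        area=polygon_area(c),
        perimeter=perimeter(c),
        hull_perimeter=_geom.perimeter(hull),
        lobeyness=_lobeyness_ratio(perimeter(c), _geom.perimeter(hull)),
        min_axis=width,
        lec_center=(float(center[0]), float(center[1])),
        lec_radius=radius,
    )


METRIC_COLUMNS = [
    "clade", "species", "organ", "sample", "label",
    "area_um2", "perimeter_um", "hull_perimeter_um", "lobeyness",
    "min_axis_um", "lec_radius_um", "lec_x", "lec_y", "failed",
]


def metrics_table(cs: ContourSet, n_angles: int = 3600,
                  lec_tolerance: float | None = None) -> pd.DataFrame:
    """One row of descriptors per contour, ordered by group then label.

    A contour whose metrics cannot be computed is kept as a flagged row
    (``failed=True``) with NaN metrics so the pipeline never drops cells
    silently.
    """
    rows = []
    for c in sorted(cs, key=lambda c: (c.group, c.label)):
        row = {"clade": c.clade, "species": c.species, "organ": c.organ,
               "sample": c.sample, "label": c.label, "failed": False}
        try:
            m = compute_metrics(c, n_angles=n_angles, lec_tolerance=lec_tolerance)
            row.update(area_um2=m.area, perimeter_um=m.perimeter,
                       hull_perimeter_um=m.hull_perimeter, lobeyness=m.lobeyness,
                       min_axis_um=m.min_axis, lec_radius_um=m.lec_radius,
                       lec_x=m.lec_center[0], lec_y=m.lec_center[1])
        except Exception as exc:  # noqa: BLE001 - flagged, not dropped
            warnings.warn(f"metrics failed for contour {c.label}: {exc}", stacklevel=2)
            row.update(area_um2=np.nan, perimeter_um=np.nan, hull_perimeter_um=np.nan,
                       lobeyness=np.nan, min_axis_um=np.nan, lec_radius_um=np.nan,
                       lec_x=np.nan, lec_y=np.nan, failed=True)
        rows.append(row)
    return pd.DataFrame(rows, columns=METRIC_COLUMNS)
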