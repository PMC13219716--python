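"""Independent brute-force reference implementations used only by tests.

These deliberately use different algorithms from the package (gift-wrapping
instead of monotone chain, exhaustive edge-normal widths instead of sampled
projections, dense grids instead of best-first refinement) so agreement is
evidence of correctness rather than shared bugs.
"""

from __future__ import annotations

import numpy as np


def gift_wrap_hull(pts: np.ndarray) -> np.ndarray:
    """Jarvis-march convex hull, CCW."""
    pts = np.unique(np.asarray(pts, dtype=float), axis=0)
    start = min(range(len(pts)), key=lambda i: (pts[i, 0], pts[i, 1]))
    hull = [start]
    while True:
        p = hull[-1]
        q = (p + 1) % len(pts)
        for r in range(len(pts)):
            if r == p:
                continue
            u = pts[q] - pts[p]
            v = pts[r] - pts[p]
            cross = u[0] * v[1] - u[1] * v[0]
            if cross < 0 or (cross == 0
                             and np.linalg.norm(pts[r] - pts[p])
                             > np.linalg.norm(pts[q] - pts[p])):
                q = r
        if q == start:
            break
        hull.append(q)
    return pts[hull]


def perimeter(pts: np.ndarray) -> float:
    d = np.roll(pts, -1, axis=0) - pts
    return float(np.sum(np.hypot(d[:, 0], d[:, 1])))


def lobeyness(pts: np.ndarray) -> float:
    return perimeter(pts) / perimeter(gift_wrap_hull(pts))


def min_width(pts: np.ndarray) -> float:
    """Exact minimum width: for every hull edge, the farthest-vertex distance.

    The minimum width of a convex polygon is attained perpendicular to one
    of its edges, so checking each edge against all (antipodal) vertices is
    exhaustive and exact.
    """
    hull = gift_wrap_hull(pts)
    n = len(hull)
    best = np.inf
    for i in range(n):
        a, b = hull[i], hull[(i + 1) % n]
        e = b - a
        ln = np.linalg.norm(e)
        if ln == 0:
            continue
        u = e / ln
        w = hull - a
        d = np.abs(w[:, 0] * u[1] - w[:, 1] * u[0])
        best = min(best, float(d.max()))
    return best


def dist_to_boundary(points: np.ndarray, poly: np.ndarray) -> np.ndarray:
    """Distance from each query point to the closed polyline boundary."""
    a = poly
    b = np.roll(poly, -1, axis=0)
    e = b - a                                    # (m, 2)
    ee = np.einsum("ij,ij->i", e, e)
    w = points[:, None, :] - a[None, :, :]       # (n, m, 2)
    t = np.clip(np.einsum("nmj,mj->nm", w, e) / np.maximum(ee, 1e-300), 0, 1)
    proj = a[None, :, :] + t[..., None] * e[None, :, :]
    d = np.linalg.norm(points[:, None, :] - proj, axis=2)
    return d.min(axis=1)


def points_inside(points: np.ndarray, poly: np.ndarray) -> np.ndarray:
    """Vectorized even-odd point-in-polygon test."""
    x, y = points[:, 0], points[:, 1]
    vx, vy = poly[:, 0], poly[:, 1]
    wx, wy = np.roll(vx, -1), np.roll(vy, -1)
    inside = np.zeros(len(points), dtype=bool)
    for i in range(len(poly)):
        cond = (vy[i] > y) != (wy[i] > y)
        with np.errstate(divide="ignore", invalid="ignore"):
            xin = vx[i] + (y - vy[i]) * (wx[i] - vx[i]) / (wy[i] - vy[i])
        inside ^= cond & (x < xin)
    return inside


def grid_lec_radius(poly: np.ndarray, cell: float) -> float:
    """Dense-grid inscribed-circle radius at grid pitch ``cell``."""
    minx, miny = poly.min(axis=0)
    maxx, maxy = poly.max(axis=0)
    xs = np.arange(minx, maxx + cell, cell)
    ys = np.arange(miny, maxy + cell, cell)
    gx, gy = np.meshgrid(xs, ys)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    mask = points_inside(pts, poly)
    if not mask.any():
        return 0.0
    return float(dist_to_boundary(pts[mask], poly).max())


def monte_carlo_area(poly: np.ndarray, n: int, seed: int) -> float:
    rng = np.random.default_rng(seed)
    lo = poly.min(axis=0)
    hi = poly.max(axis=0)
    pts = rng.uniform(lo, hi, size=(n, 2))
    frac = points_inside(pts, poly).mean()
    return float(frac * np.prod(hi - lo))


def quadratic_origin_normal_equations(x: np.ndarray, y: np.ndarray):
    """Solve the origin-constrained quadratic fit via explicit normal equations."""
    s2, s3, s4 = (x**2).sum(), (x**3).sum(), (x**4).sum()
    sxy, sx2y = (x * y).sum(), (x**2 * y).sum()
    mat = np.array([[s2, s3], [s3, s4]])
    rhs = np.array([sxy, sx2y])
    beta, alpha = np.linalg.solve(mat, rhs)
    return float(beta), float(alpha)
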