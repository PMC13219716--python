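"""Low-level planar geometry shared across modules.

All routines operate on (n, 2) float arrays of polygon vertices, closed
implicitly (the last vertex is joined back to the first).
"""

from __future__ import annotations

import numpy as np


def signed_area(pts: np.ndarray) -> float:
    """Shoelace signed area; positive for counter-clockwise orientation."""
    x, y = pts[:, 0], pts[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def perimeter(pts: np.ndarray) -> float:
    d = np.roll(pts, -1, axis=0) - pts
    return float(np.sum(np.hypot(d[:, 0], d[:, 1])))


def centroid(pts: np.ndarray) -> np.ndarray:
    """Area-weighted polygon centroid (falls back to vertex mean if degenerate)."""
    x, y = pts[:, 0], pts[:, 1]
    xr, yr = np.roll(x, -1), np.roll(y, -1)
    cross = x * yr - xr * y
    a = 0.5 * np.sum(cross)
    if abs(a) < 1e-300:
        return pts.mean(axis=0)
    cx = np.sum((x + xr) * cross) / (6.0 * a)
    cy = np.sum((y + yr) * cross) / (6.0 * a)
    return np.array([cx, cy])


def _orient(p: np.ndarray, q: np.ndarray, r: np.ndarray) -> np.ndarray:
    return (q[..., 0] - p[..., 0]) * (r[..., 1] - p[..., 1]) - (
        q[..., 1] - p[..., 1]
    ) * (r[..., 0] - p[..., 0])


def segments_cross(p1, p2, q1, q2) -> bool:
    """True if open segments (p1,p2) and (q1,q2) properly intersect."""
    d1 = _orient(q1, q2, p1)
    d2 = _orient(q1, q2, p2)
    d3 = _orient(p1, p2, q1)
    d4 = _orient(p1, p2, q2)
    return bool((d1 * d2 < 0) and (d3 * d4 < 0))


def crossing_edge_pairs(pts: np.ndarray) -> list[tuple[int, int]]:
    """Brute-force O(n^2) list of properly crossing edge index pairs.

    Edge i runs from vertex i to vertex (i+1) % n.  Adjacent edges share a
    vertex and are never reported.
    """
    n = len(pts)
    a = pts
    b = np.roll(pts, -1, axis=0)
    out = []
    for i in range(n):
        # skip neighbours of i (share a vertex)
        js = [j for j in range(i + 2, n) if not (i == 0 and j == n - 1)]
        if not js:
            continue
        j = np.array(js)
        d1 = _orient(a[j], b[j], a[i])
        d2 = _orient(a[j], b[j], b[i])
        d3 = _orient(a[i][None, :], b[i][None, :], a[j])
        d4 = _orient(a[i][None, :], b[i][None, :], b[j])
        hit = (d1 * d2 < 0) & (d3 * d4 < 0)
        for jj in j[hit]:
            out.append((i, int(jj)))
    return out


def is_simple(pts: np.ndarray) -> bool:
    """Brute-force simplicity check (no properly crossing edge pair)."""
    return len(crossing_edge_pairs(pts)) == 0


def convex_hull(pts: np.ndarray) -> np.ndarray:
    """Monotone-chain convex hull, CCW, collinear points dropped."""
    p = np.unique(np.asarray(pts, dtype=float), axis=0)
    if len(p) < 3:
        return p
    order = np.lexsort((p[:, 1], p[:, 0]))
    p = p[order]

    def half(points):
        h: list[np.ndarray] = []
        for pt in points:
            while len(h) >= 2 and _orient(h[-2], h[-1], pt) <= 0:
                h.pop()
            h.append(pt)
        return h

    lower = half(p)
    upper = half(p[::-1])
    return np.array(lower[:-1] + upper[:-1])


def point_in_polygon(pt: np.ndarray, pts: np.ndarray) -> bool:
    """Even-odd ray-casting test."""
    x, y = pt
    vx, vy = pts[:, 0], pts[:, 1]
    wx, wy = np.roll(vx, -1), np.roll(vy, -1)
    cond = (vy > y) != (wy > y)
    with np.errstate(divide="ignore", invalid="ignore"):
        xin = vx + (y - vy) * (wx - vx) / (wy - vy)
    return bool(np.count_nonzero(cond & (x < xin)) % 2)


def rotation_matrix(theta: float) -> np.ndarray:
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s], [s, c]])


def turn_signs(pts: np.ndarray) -> np.ndarray:
    """Cross product of successive edge vectors at each vertex.

    For a CCW simple polygon, positive values mark convex vertices and
    negative values mark concave (indented) ones.
    """
    prev = pts - np.roll(pts, 1, axis=0)
    nxt = np.roll(pts, -1, axis=0) - pts
    return prev[:, 0] * nxt[:, 1] - prev[:, 1] * nxt[:, 0]
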