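"""Fully damped mass-spring model of puzzle-cell emergence.

Cells are polygons of point masses joined by linear wall springs.  Growth is
boundary-driven: the outermost rim of the tissue template is displaced
outward each step by prescribed per-axis factors, while the rest lengths of
interior wall springs follow the same affine growth, so a tissue free of
other constraints would simply scale.  The constraint comes from
*connections*: stiff intracellular springs, the geometric proxy for
microtubule-guided cellulose reinforcement, placed across a cell wherever a
free span falls inside a target window and the local wall geometry (chord
angle, concavity) permits; each wall vertex anchors at most one connection
per cell.  A connection's rest length is frozen at
placement, so it resists further expansion of that span; wall material that
keeps growing around a clamped span has nowhere to go but outward, producing
the lobes-and-necks (jigsaw) morphology.  Because clamping happens where
spans are small and growth is frustrated along the currently fast axis, the
orientation of lobes records the temporal order of growth anisotropy.

After every growth increment the interior vertices are relaxed to mechanical
equilibrium (energy minimum of all springs) with the rim held fixed — the
fully damped limit in which inertia plays no role.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.optimize import minimize

from . import _geom
from .contour_io import Contour, ContourSet
from .errors import FuncFormatError, SimulationError

# --------------------------------------------------------------------------
# growth curves and schedules
# --------------------------------------------------------------------------


def load_func(path: str | Path):
    """Load a growth-rate curve from a control-point (.func) file.

    The dialect is a plain list of ``t value`` control points with
    piecewise-linear interpolation; header lines that do not parse as two
    numbers (as written by the upstream curve-editing tool) are skipped.
    Evaluation clamps to the endpoint values outside [0, 1].
    """
    pts = []
    for raw in Path(path).read_text().splitlines():
        tokens = raw.replace(",", " ").split()
        if len(tokens) < 2:
            continue
        try:
            pts.append((float(tokens[0]), float(tokens[1])))
        except ValueError:
            continue
    if len(pts) < 2:
        raise FuncFormatError(f"{path}: need at least 2 control points")
    t = np.array([p[0] for p in pts])
    v = np.array([p[1] for p in pts])
    if np.any(np.diff(t) < 0):
        raise FuncFormatError(f"{path}: control-point times must be non-decreasing")

    def f(x):
        return np.interp(np.clip(x, t[0], t[-1]), t, v)

    return f


@dataclass(frozen=True)
class GrowthSchedule:
    """Per-step multiplicative growth factors for the x and y axes.

    ``factors_x[i]`` scales the rim (and interior rest lengths) along x
    during step ``i``; the cumulative per-axis scale is the running product
    of the factors, which is exactly reproducible.
    """

    factors_x: np.ndarray
    factors_y: np.ndarray

    def __post_init__(self):
        fx = np.asarray(self.factors_x, dtype=float)
        fy = np.asarray(self.factors_y, dtype=float)
        if len(fx) != len(fy) or len(fx) == 0:
            raise ValueError("schedules need equal, nonzero step counts")
        if np.any(fx < 0) or np.any(fy < 0):
            raise ValueError("growth factors must be non-negative")
        object.__setattr__(self, "factors_x", fx)
        object.__setattr__(self, "factors_y", fy)

    @property
    def n_steps(self) -> int:
        return len(self.factors_x)

    def cumulative_scale(self) -> tuple[float, float]:
        return float(np.prod(self.factors_x)), float(np.prod(self.factors_y))

    def reversed(self) -> "GrowthSchedule":
        return GrowthSchedule(self.factors_x[::-1].copy(), self.factors_y[::-1].copy())

    @classmethod
    def from_rate_functions(cls, gx, gy, n_steps: int) -> "GrowthSchedule":
        """Discretize per-axis rate functions of normalized time.

        The step factor is ``1 + g(t_mid) * dt`` with ``dt = 1 / n_steps``,
        evaluated at mid-step times.
        """
        t = (np.arange(n_steps) + 0.5) / n_steps
        dt = 1.0 / n_steps
        return cls(1.0 + np.asarray(gx(t), dtype=float) * dt,
                   1.0 + np.asarray(gy(t), dtype=float) * dt)

    @classmethod
    def two_phase(cls, n_steps: int, split: float,
                  scale1: tuple[float, float],
                  scale2: tuple[float, float]) -> "GrowthSchedule":
        """Constant-rate phases reaching exact cumulative per-axis scales.

        Phase 1 covers the first ``round(split * n_steps)`` steps and scales
        the axes by ``scale1``; phase 2 covers the rest and adds ``scale2``.
        Within each phase the per-step factor is the appropriate root of the
        phase scale, so the product telescopes to the target exactly.
        """
        n1 = int(round(split * n_steps))
        n2 = n_steps - n1
        fx = np.concatenate([
            np.full(n1, scale1[0] ** (1.0 / n1) if n1 else 1.0),
            np.full(n2, scale2[0] ** (1.0 / n2) if n2 else 1.0)])
        fy = np.concatenate([
            np.full(n1, scale1[1] ** (1.0 / n1) if n1 else 1.0),
            np.full(n2, scale2[1] ** (1.0 / n2) if n2 else 1.0)])
        return cls(fx, fy)


# --------------------------------------------------------------------------
# mesh state
# --------------------------------------------------------------------------


@dataclass
class SimConfig:
    """Mechanical and rule parameters of the model.

    Stiffnesses are per unit strain-length; lengths are in template units
    (the initial cell size is ~1).  The connection window is expressed in
    multiples of the target free-span diameter ``2 * lec_target``: a chord is
    eligible when its length is between ``chord_min_factor`` and
    ``chord_max_factor`` times that diameter, roughly aligned with the
    inward wall normal at both ends (``theta_max_deg``) and anchored at an
    indentation when ``require_concave`` is set.
    """

    k_wall: float = 1.0
    k_conn: float = 10.0
    relax_tolerance: float = 1e-5      # x k_wall x mean rest length
    max_relax_iters: int = 1500
    lec_target: float = 0.8            # target free-span radius (length units)
    chord_min_factor: float = 0.9
    chord_max_factor: float = 1.4
    theta_max_deg: float = 25.0
    require_concave: bool = True
    concave_tol: float = 1e-9
    max_edge_length: float = 0.45      # walls longer than this are subdivided
    compress_yield: float = 1.0        # per-step yielding of compressed walls
    conn_break_strain: float = 0.5     # connections rupture beyond this strain
    connections_enabled: bool = True
    divisions_enabled: bool = False
    f_div: float = 0.2                 # division phase as fraction of run time
    area_div: float = 2.0              # split cells above this area
    n_div_directions: int = 60
    untangle_every: int = 3            # untangling cadence, in steps (0 = off)
    max_failed_relax_frac: float = 0.5
    rng_seed: int = 0


@dataclass
class ConvergenceReport:
    iterations: int
    residual: float
    converged: bool


class CellMesh:
    """Tissue state: vertex positions, springs, connections and cell cycles."""

    def __init__(self, positions, is_boundary, walls, cells,
                 connections=None, growth_center=None):
        self.positions = np.asarray(positions, dtype=float)
        self.is_boundary = np.asarray(is_boundary, dtype=bool)
        # walls: {frozen (i, j) with i < j: [rest_length, stiffness]}
        self.walls: dict[tuple[int, int], list[float]] = dict(walls)
        # connections: {(i, j): [rest_length, stiffness, owner cell]}
        self.connections: dict[tuple[int, int], list] = dict(connections or {})
        self.cells: dict[int, list[int]] = {k: list(v) for k, v in cells.items()}
        self.growth_center = (np.asarray(growth_center, dtype=float)
                              if growth_center is not None
                              else self.positions[self.is_boundary].mean(axis=0))
        self.next_label = max(self.cells, default=-1) + 1

    # -- bookkeeping -------------------------------------------------------

    def copy(self) -> "CellMesh":
        m = CellMesh(self.positions.copy(), self.is_boundary.copy(),
                     {k: list(v) for k, v in self.walls.items()},
                     {k: list(v) for k, v in self.cells.items()},
                     {k: list(v) for k, v in self.connections.items()},
                     self.growth_center.copy())
        m.next_label = self.next_label
        return m

    @property
    def n_vertices(self) -> int:
        return len(self.positions)

    def cell_polygon(self, label: int) -> np.ndarray:
        return self.positions[self.cells[label]]

    def cell_contours(self, group=("sim", "run", "final", "")) -> ContourSet:
        out = []
        for label in sorted(self.cells):
            pts = self.cell_polygon(label)
            if _geom.signed_area(pts) < 0:
                pts = pts[::-1]
            out.append(Contour(vertices=pts.copy(), label=label,
                               group=(group[0], group[1], group[2], f"cell_{label:04d}")))
        return ContourSet(out)

    def total_cell_area(self) -> float:
        return float(sum(abs(_geom.signed_area(self.cell_polygon(c)))
                         for c in self.cells))

    def rim_polygon(self) -> np.ndarray:
        """Outer rim traced by walking boundary-boundary wall edges."""
        adj: dict[int, list[int]] = {}
        for (i, j) in self.walls:
            if self.is_boundary[i] and self.is_boundary[j]:
                adj.setdefault(i, []).append(j)
                adj.setdefault(j, []).append(i)
        start = min(adj)
        loop = [start]
        prev = None
        while True:
            nxts = [v for v in adj[loop[-1]] if v != prev]
            prev = loop[-1]
            loop.append(nxts[0])
            if loop[-1] == start:
                break
        return self.positions[loop[:-1]]

    def mean_rest_length(self) -> float:
        return float(np.mean([w[0] for w in self.walls.values()]))

    def add_vertex(self, pos, boundary: bool) -> int:
        self.positions = np.vstack([self.positions, np.asarray(pos, dtype=float)])
        self.is_boundary = np.append(self.is_boundary, boundary)
        return len(self.positions) - 1

    def split_wall(self, i: int, j: int) -> int:
        """Insert the midpoint vertex of wall (i, j) into springs and cycles."""
        key = (min(i, j), max(i, j))
        rest, k = self.walls.pop(key)
        mid = self.add_vertex((self.positions[i] + self.positions[j]) / 2.0,
                              bool(self.is_boundary[i] and self.is_boundary[j]))
        self.walls[(min(i, mid), max(i, mid))] = [rest / 2.0, k]
        self.walls[(min(j, mid), max(j, mid))] = [rest / 2.0, k]
        for cyc in self.cells.values():
            n = len(cyc)
            for a in range(n):
                b = (a + 1) % n
                if {cyc[a], cyc[b]} == {i, j}:
                    cyc.insert(a + 1, mid)
                    break
        return mid


# --------------------------------------------------------------------------
# template generation
# --------------------------------------------------------------------------


def make_template(kind: str, n_cells: int = 36, cell_size: float = 1.0,
                  rng_seed: int = 0, segments_per_edge: int = 4,
                  maize_aspect: int = 6, jitter: float = 0.18) -> CellMesh:
    """Build a starting tissue of polygonal cells on a grid.

    ``isodiametric_grid`` gives near-square cells with seeded interior
    jitter (the only stochastic element of a run); ``maize_elongated`` gives
    cells stretched ``maize_aspect``-fold along y, the idealized geometry of
    young cells displaced from an intercalary meristem.  Cell walls are
    pre-subdivided into ``segments_per_edge`` springs per edge so they can
    buckle.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if cell_size <= 0:
        raise ValueError("cell_size must be positive")
    if kind not in ("isodiametric_grid", "maize_elongated"):
        raise ValueError(f"unknown template kind {kind!r}")
    nx = max(int(round(math.sqrt(n_cells))), 1)
    ny = max(int(math.ceil(n_cells / nx)), 1)
    w = cell_size
    h = cell_size * (maize_aspect if kind == "maize_elongated" else 1)
    seg_y = segments_per_edge * (maize_aspect if kind == "maize_elongated" else 1)
    seg_x = segments_per_edge
    rng = np.random.default_rng(rng_seed)

    index: dict[tuple[int, int], int] = {}
    positions: list[np.ndarray] = []

    def vid(ix: int, iy: int) -> int:
        # lattice coordinates in units of (w/seg_x, h/seg_y)
        key = (ix, iy)
        if key not in index:
            index[key] = len(positions)
            positions.append(np.array([ix * w / seg_x, iy * h / seg_y]))
        return index[key]

    cells: dict[int, list[int]] = {}
    walls: dict[tuple[int, int], list[float]] = {}
    label = 0
    for cy in range(ny):
        for cx in range(nx):
            x0, y0 = cx * seg_x, cy * seg_y
            cyc = []
            cyc += [vid(x0 + s, y0) for s in range(seg_x)]
            cyc += [vid(x0 + seg_x, y0 + s) for s in range(seg_y)]
            cyc += [vid(x0 + seg_x - s, y0 + seg_y) for s in range(seg_x)]
            cyc += [vid(x0, y0 + seg_y - s) for s in range(seg_y)]
            cells[label] = cyc
            label += 1
    pos = np.array(positions)
    xmax, ymax = nx * w, ny * h
    on_rim = (np.isclose(pos[:, 0], 0) | np.isclose(pos[:, 0], xmax)
              | np.isclose(pos[:, 1], 0) | np.isclose(pos[:, 1], ymax))
    # seeded jitter on interior vertices only; rim stays rectangular
    amp = jitter * min(w / seg_x, h / seg_y)
    pos = pos + np.where(on_rim[:, None], 0.0,
                         rng.uniform(-amp, amp, size=pos.shape))
    for cyc in cells.values():
        n = len(cyc)
        for a in range(n):
            i, j = cyc[a], cyc[(a + 1) % n]
            key = (min(i, j), max(i, j))
            if key not in walls:
                walls[key] = [float(np.linalg.norm(pos[i] - pos[j])), 1.0]
    mesh = CellMesh(pos, on_rim, walls, cells,
                    growth_center=np.array([xmax / 2.0, ymax / 2.0]))
    return mesh


# --------------------------------------------------------------------------
# per-step operations
# --------------------------------------------------------------------------


def apply_boundary_growth(mesh: CellMesh, gx_step: float, gy_step: float) -> CellMesh:
    """Scale rim vertices about the template center; growth is imposed.

    Rim positions are multiplied by ``(1 + gx_step, 1 + gy_step)`` per axis;
    interior vertices are untouched here (they move during relaxation).
    Rest lengths of rim-rim walls are reset to their imposed lengths, so the
    rim carries no elastic energy of its own.
    """
    if gx_step < -1 or gy_step < -1:
        raise ValueError("per-step growth factors must be >= 0")
    scale = np.array([1.0 + gx_step, 1.0 + gy_step])
    b = mesh.is_boundary
    mesh.positions[b] = mesh.growth_center + (mesh.positions[b] - mesh.growth_center) * scale
    for (i, j), spring in mesh.walls.items():
        if b[i] and b[j]:
            spring[0] = float(np.linalg.norm(mesh.positions[i] - mesh.positions[j]))
    return mesh


def grow_rest_lengths(mesh: CellMesh, gx_step: float, gy_step: float) -> None:
    """Grow interior wall rest lengths by the affine image of the step.

    Each wall's rest length is multiplied by the factor by which the growth
    tensor ``diag(1 + gx, 1 + gy)`` stretches a segment of its current
    orientation.  With no connections this keeps the uniformly scaled tissue
    at zero energy; connections frustrate it, and the surplus wall length
    they trap is what buckles into lobes.
    """
    scale = np.array([1.0 + gx_step, 1.0 + gy_step])
    b = mesh.is_boundary
    pos = mesh.positions
    for (i, j), spring in mesh.walls.items():
        if b[i] and b[j]:
            continue
        e = pos[j] - pos[i]
        norm = np.linalg.norm(e)
        if norm < 1e-12:
            spring[0] *= float(scale.mean())
            continue
        spring[0] *= float(np.linalg.norm(e / norm * scale))


def yield_compressed_walls(mesh: CellMesh, rate: float) -> None:
    """Shrink the rest length of compressed walls toward their actual length.

    Plant walls buckle rather than bear compression; without this yielding,
    surplus rest length stored in a buckled wall keeps pushing and folds
    lobes over themselves.  ``rate`` is the per-step fraction of the
    compression relieved (0 disables, 1 removes it entirely).
    """
    if rate <= 0:
        return
    pos = mesh.positions
    for (i, j), spring in mesh.walls.items():
        length = float(np.linalg.norm(pos[i] - pos[j]))
        if length < spring[0]:
            spring[0] += rate * (length - spring[0])


def break_overstretched_connections(mesh: CellMesh, max_strain: float) -> int:
    """Remove connections stretched beyond ``max_strain``; returns count.

    A clamp that the surrounding tissue has overpowered is mechanically
    failed; removing it mimics rupture of the reinforcing bundle and stops
    far-stretched springs from dragging distant tissue together.
    """
    if max_strain <= 0:
        return 0
    pos = mesh.positions
    doomed = [key for key, (rest, _k, _c) in mesh.connections.items()
              if np.linalg.norm(pos[key[0]] - pos[key[1]]) > (1 + max_strain) * rest]
    for key in doomed:
        del mesh.connections[key]
    return len(doomed)


def untangle_mesh(mesh: CellMesh, cfg: SimConfig, rounds: int = 8) -> int:
    """Resolve rare local wall pierce-throughs by neighborhood smoothing.

    The spring energy has no contact term, so a deeply pinched neck can
    locally push one wall through another.  Vertices on crossing edges are
    moved toward the average of their wall neighborhood (the same local rule
    used to repair traced contours), incident rest lengths are reset to the
    new geometry, and the tissue is re-relaxed.  Returns the number of
    crossing vertices found initially (0 means the mesh was already clean).
    """
    adj: dict[int, list[int]] = {}
    for (i, j) in mesh.walls:
        adj.setdefault(i, []).append(j)
        adj.setdefault(j, []).append(i)
    n_initial = -1
    # first half: smooth + re-relax; second half: smoothing only, so a
    # crossing that re-forms at the energy minimum is still removed
    for round_i in range(2 * rounds):
        bad: set[int] = set()
        for cyc in mesh.cells.values():
            poly = mesh.positions[cyc]
            for (a, b) in _geom.crossing_edge_pairs(poly):
                n = len(cyc)
                bad.update({cyc[a], cyc[(a + 1) % n], cyc[b], cyc[(b + 1) % n]})
        bad = {v for v in bad if not mesh.is_boundary[v]}
        if n_initial < 0:
            n_initial = len(bad)
        if not bad:
            return max(n_initial, 0)
        new_pos = mesh.positions.copy()
        for v in bad:
            nbrs = adj.get(v, [])
            new_pos[v] = (mesh.positions[v] + mesh.positions[nbrs].sum(axis=0)) / (
                1 + len(nbrs))
        mesh.positions = new_pos
        for (i, j), spring in mesh.walls.items():
            if i in bad or j in bad:
                spring[0] = float(np.linalg.norm(mesh.positions[i] - mesh.positions[j]))
        if round_i < rounds:
            relax(mesh, cfg)
    return n_initial


def subdivide_long_edges(mesh: CellMesh, max_length: float) -> int:
    """Split walls whose current length exceeds ``max_length``; returns count."""
    n_split = 0
    for (i, j) in list(mesh.walls):
        if np.linalg.norm(mesh.positions[i] - mesh.positions[j]) > max_length:
            mesh.split_wall(i, j)
            n_split += 1
    return n_split


def _spring_arrays(mesh: CellMesh, k_wall: float, k_conn: float):
    pairs, rest, k = [], [], []
    for (i, j), (r, kk) in mesh.walls.items():
        pairs.append((i, j))
        rest.append(r)
        k.append(kk * k_wall)
    for (i, j), (r, kk, _cell) in mesh.connections.items():
        pairs.append((i, j))
        rest.append(r)
        k.append(kk * k_conn)
    return (np.array(pairs, dtype=int), np.array(rest, dtype=float),
            np.array(k, dtype=float))


def relax(mesh: CellMesh, cfg: SimConfig) -> ConvergenceReport:
    """Move interior vertices to the spring-energy minimum (rim fixed).

    Quasi-Newton descent on the total elastic energy — the stationary state
    of a fully damped system.  Convergence is declared when the largest
    residual force component on any free vertex falls below
    ``relax_tolerance * k_wall * mean rest length``.
    """
    pairs, rest, ks = _spring_arrays(mesh, cfg.k_wall, cfg.k_conn)
    free = ~mesh.is_boundary
    free_idx = np.flatnonzero(free)
    if len(free_idx) == 0 or len(pairs) == 0:
        return ConvergenceReport(0, 0.0, True)
    tol = cfg.relax_tolerance * cfg.k_wall * float(np.mean(rest))
    pos0 = mesh.positions
    ii, jj = pairs[:, 0], pairs[:, 1]

    def energy_grad(x):
        p = pos0.copy()
        p[free_idx] = x.reshape(-1, 2)
        d = p[jj] - p[ii]
        length = np.sqrt(np.einsum("ij,ij->i", d, d)) + 1e-300
        stretch = length - rest
        e = 0.5 * np.sum(ks * stretch**2)
        f = (ks * stretch / length)[:, None] * d  # force on i toward j
        grad = np.zeros_like(p)
        np.add.at(grad, ii, -f)
        np.add.at(grad, jj, f)
        return e, grad[free_idx].ravel()

    x0 = pos0[free_idx].ravel()
    e0, g0 = energy_grad(x0)
    if np.max(np.abs(g0)) < tol:
        return ConvergenceReport(0, float(np.max(np.abs(g0))), True)
    res = minimize(energy_grad, x0, jac=True, method="L-BFGS-B",
                   options={"maxiter": cfg.max_relax_iters, "gtol": tol,
                            "ftol": 1e-16, "maxls": 40})
    mesh.positions = pos0.copy()
    mesh.positions[free_idx] = res.x.reshape(-1, 2)
    _e, g = energy_grad(res.x)
    residual = float(np.max(np.abs(g)))
    return ConvergenceReport(int(res.nit), residual, residual < tol * 1.5)


def _chord_admissible(poly: np.ndarray, a: int, b: int) -> bool:
    """Does the open chord a-b of the cell polygon stay strictly inside?"""
    pa, pb = poly[a], poly[b]
    # shrink slightly so edges incident to the endpoints don't count as hits
    eps = 1e-6
    qa = pa + (pb - pa) * eps
    qb = pb - (pb - pa) * eps
    n = len(poly)
    e1 = poly
    e2 = np.roll(poly, -1, axis=0)
    d1 = (e2[:, 0] - e1[:, 0]) * (qa[1] - e1[:, 1]) - (e2[:, 1] - e1[:, 1]) * (qa[0] - e1[:, 0])
    d2 = (e2[:, 0] - e1[:, 0]) * (qb[1] - e1[:, 1]) - (e2[:, 1] - e1[:, 1]) * (qb[0] - e1[:, 0])
    d3 = (qb[0] - qa[0]) * (e1[:, 1] - qa[1]) - (qb[1] - qa[1]) * (e1[:, 0] - qa[0])
    d4 = (qb[0] - qa[0]) * (e2[:, 1] - qa[1]) - (qb[1] - qa[1]) * (e2[:, 0] - qa[0])
    if np.any((d1 * d2 < 0) & (d3 * d4 < 0)):
        return False
    mid = (pa + pb) / 2.0
    return _geom.point_in_polygon(mid, poly)


def place_connections(mesh: CellMesh, cfg: SimConfig) -> int:
    """Place intracellular connection springs; returns how many were added.

    For every cell, chords between wall vertices are admitted when they
    (i) lie inside the cell, (ii) have length inside the span window
    ``[chord_min_factor, chord_max_factor] * 2 * lec_target``, (iii) are
    aligned with the inward wall normal at both endpoints to within
    ``theta_max_deg``, and (iv) have at least one endpoint at a concave
    (indented) vertex when the concavity rule is active.  Admitted chords
    become springs frozen at their current length; each vertex anchors at
    most one connection per cell, so a clamped span is not re-clamped by
    near-parallel duplicates.  Existing connections whose chord has left
    the interior of its cell are removed; the rest persist (they are the
    memory of past clamping).
    """
    if not cfg.connections_enabled:
        return 0
    lo = cfg.chord_min_factor * 2.0 * cfg.lec_target
    hi = cfg.chord_max_factor * 2.0 * cfg.lec_target
    cos_max = math.cos(math.radians(cfg.theta_max_deg))
    added = 0
    # prune connections that no longer lie inside their owner cell
    for key in list(mesh.connections):
        i, j, cell = key[0], key[1], mesh.connections[key][2]
        cyc = mesh.cells.get(cell)
        if cyc is None or i not in cyc or j not in cyc:
            del mesh.connections[key]
            continue
        poly = mesh.positions[cyc]
        if not _chord_admissible(poly, cyc.index(i), cyc.index(j)):
            del mesh.connections[key]
    busy: dict[int, set[int]] = {}
    for (i, j), (_r, _k, cell) in mesh.connections.items():
        busy.setdefault(cell, set()).update((i, j))
    for cell, cyc in mesh.cells.items():
        poly = mesh.positions[cyc]
        n = len(poly)
        if n < 4:
            continue
        cell_busy = busy.setdefault(cell, set())
        turns = _geom.turn_signs(poly)
        orient = 1.0 if _geom.signed_area(poly) > 0 else -1.0
        concave = (turns * orient) < -cfg.concave_tol
        prev = poly - np.roll(poly, 1, axis=0)
        nxt = np.roll(poly, -1, axis=0) - poly
        tang = prev + nxt
        tang /= (np.linalg.norm(tang, axis=1, keepdims=True) + 1e-300)
        inward = orient * np.column_stack([-tang[:, 1], tang[:, 0]])
        if cfg.require_concave:
            seeds = np.flatnonzero(concave)
        else:
            seeds = np.arange(n)
        if len(seeds) == 0:
            continue
        diff = poly[seeds][:, None, :] - poly[None, :, :]
        dist = np.hypot(diff[:, :, 0], diff[:, :, 1])
        for si, a in enumerate(seeds):
            cand = np.flatnonzero((dist[si] >= lo) & (dist[si] <= hi))
            for b in cand:
                if min(abs(a - b), n - abs(a - b)) <= 1:
                    continue
                ga, gb = cyc[a], cyc[b]
                if ga in cell_busy or gb in cell_busy:
                    continue
                key = (min(ga, gb), max(ga, gb))
                if key in mesh.connections or key in mesh.walls:
                    continue
                u = (poly[b] - poly[a]) / dist[si, b]
                if float(u @ inward[a]) < cos_max or float(-u @ inward[b]) < cos_max:
                    continue
                if not _chord_admissible(poly, a, b):
                    continue
                mesh.connections[key] = [float(dist[si, b]), 1.0, cell]
                cell_busy.update((ga, gb))
                added += 1
    return added


def _shortest_centroid_chord(poly: np.ndarray, n_directions: int):
    """Shortest straight chord through the polygon centroid.

    Returns ((edge_a, point_a), (edge_b, point_b)) — the boundary edges hit
    and the crossing points — or None if no direction yields a clean
    two-point crossing.
    """
    ctr = _geom.centroid(poly)
    n = len(poly)
    e1 = poly
    e2 = np.roll(poly, -1, axis=0)
    best = None
    best_len = np.inf
    for t in np.linspace(0.0, np.pi, n_directions, endpoint=False):
        d = np.array([math.cos(t), math.sin(t)])
        # intersect the line ctr + s d with every edge
        de = e2 - e1
        denom = de[:, 0] * d[1] - de[:, 1] * d[0]
        with np.errstate(divide="ignore", invalid="ignore"):
            s = ((ctr[0] - e1[:, 0]) * d[1] - (ctr[1] - e1[:, 1]) * d[0]) / denom
            u = (de[:, 0] * (ctr[1] - e1[:, 1]) - de[:, 1] * (ctr[0] - e1[:, 0])) / (-denom)
        ok = np.isfinite(s) & (s >= 1e-9) & (s < 1 - 1e-9)
        if np.count_nonzero(ok) != 2:
            continue
        idx = np.flatnonzero(ok)
        p = e1[idx] + de[idx] * s[idx][:, None]
        if np.sign(u[idx[0]]) == np.sign(u[idx[1]]):
            continue  # both hits on the same side of the centroid
        length = float(np.linalg.norm(p[0] - p[1]))
        if length < best_len:
            best_len = length
            best = ((int(idx[0]), p[0]), (int(idx[1]), p[1]))
    return best


def divide_cells(mesh: CellMesh, t: float, cfg: SimConfig) -> int:
    """Split oversized cells during the division phase; returns split count.

    Active only while ``t <= f_div``.  Each cell with area above
    ``area_div`` is cut by the shortest straight wall through its centroid
    (an Errera-style plane rule); daughters keep the parent label and the
    next fresh label.  A cut that fails to produce two simple polygons is
    skipped and logged.
    """
    if not cfg.divisions_enabled or t > cfg.f_div:
        return 0
    n_divided = 0
    for label in sorted(mesh.cells):
        cyc = mesh.cells[label]
        poly = mesh.positions[cyc]
        if abs(_geom.signed_area(poly)) <= cfg.area_div:
            continue
        chord = _shortest_centroid_chord(poly, cfg.n_div_directions)
        if chord is None:
            warnings.warn(f"division skipped for cell {label}: no clean chord",
                          stacklevel=2)
            continue
        (ea, pa), (eb, pb) = chord
        n = len(cyc)
        # split the two boundary edges at the crossing points
        va = _insert_on_edge(mesh, cyc, ea, pa)
        cyc = mesh.cells[label]
        # edge indices may have shifted by the first insertion
        poly = mesh.positions[cyc]
        eb2 = _locate_edge(mesh, cyc, pb)
        if eb2 is None:
            warnings.warn(f"division skipped for cell {label}: edge lookup failed",
                          stacklevel=2)
            continue
        vb = _insert_on_edge(mesh, cyc, eb2, pb)
        cyc = mesh.cells[label]
        ia, ib = cyc.index(va), cyc.index(vb)
        if ia > ib:
            ia, ib = ib, ia
        half1 = cyc[ia:ib + 1]
        half2 = cyc[ib:] + cyc[:ia + 1]
        if len(half1) < 3 or len(half2) < 3:
            continue
        if not (_geom.is_simple(mesh.positions[half1])
                and _geom.is_simple(mesh.positions[half2])):
            warnings.warn(f"division skipped for cell {label}: non-simple daughters",
                          stacklevel=2)
            continue
        # the new wall, subdivided to match the local spring scale
        wall_len = float(np.linalg.norm(mesh.positions[va] - mesh.positions[vb]))
        nseg = max(int(math.ceil(wall_len / cfg.max_edge_length)), 1)
        chain = [va]
        for s in range(1, nseg):
            p = mesh.positions[va] + (mesh.positions[vb] - mesh.positions[va]) * s / nseg
            chain.append(mesh.add_vertex(p, False))
        chain.append(vb)
        for a, b in zip(chain[:-1], chain[1:]):
            key = (min(a, b), max(a, b))
            mesh.walls[key] = [wall_len / nseg, 1.0]
        new_label = mesh.next_label
        mesh.next_label += 1
        mesh.cells[label] = half1 + chain[::-1][1:-1]
        mesh.cells[new_label] = half2 + chain[1:-1]
        # re-home connections of the parent to whichever daughter holds them
        for key in list(mesh.connections):
            if mesh.connections[key][2] == label:
                i, j = key
                if i in mesh.cells[new_label] and j in mesh.cells[new_label]:
                    mesh.connections[key][2] = new_label
                elif not (i in mesh.cells[label] and j in mesh.cells[label]):
                    del mesh.connections[key]
        n_divided += 1
    return n_divided


def _insert_on_edge(mesh: CellMesh, cyc: list[int], edge: int, point: np.ndarray) -> int:
    """Split the wall under cycle edge ``edge`` at ``point``; return the new id."""
    i, j = cyc[edge], cyc[(edge + 1) % len(cyc)]
    key = (min(i, j), max(i, j))
    rest, k = mesh.walls.pop(key)
    frac = (np.linalg.norm(point - mesh.positions[i])
            / max(np.linalg.norm(mesh.positions[j] - mesh.positions[i]), 1e-300))
    mid = mesh.add_vertex(point, bool(mesh.is_boundary[i] and mesh.is_boundary[j]))
    mesh.walls[(min(i, mid), max(i, mid))] = [rest * frac, k]
    mesh.walls[(min(j, mid), max(j, mid))] = [rest * (1 - frac), k]
    for cyc2 in mesh.cells.values():
        n = len(cyc2)
        for a in range(n):
            if {cyc2[a], cyc2[(a + 1) % n]} == {i, j}:
                cyc2.insert(a + 1, mid)
                break
    return mid


def _locate_edge(mesh: CellMesh, cyc: list[int], point: np.ndarray):
    """Cycle edge index whose segment passes through ``point`` (within tol)."""
    poly = mesh.positions[cyc]
    n = len(poly)
    e2 = np.roll(poly, -1, axis=0)
    d = e2 - poly
    seg_len = np.linalg.norm(d, axis=1) + 1e-300
    tpar = np.einsum("ij,ij->i", point - poly, d) / seg_len**2
    tpar = np.clip(tpar, 0.0, 1.0)
    proj = poly + d * tpar[:, None]
    dist = np.linalg.norm(proj - point, axis=1)
    e = int(np.argmin(dist))
    if dist[e] > 1e-6 * max(seg_len.max(), 1.0):
        return None
    return e


# --------------------------------------------------------------------------
# the simulation loop
# --------------------------------------------------------------------------


@dataclass
class Trajectory:
    """Result of a run: snapshots, convergence reports and final metrics."""

    final_mesh: CellMesh
    snapshots: list[tuple[int, CellMesh]] = field(default_factory=list)
    reports: list[ConvergenceReport] = field(default_factory=list)
    n_connections: int = 0
    n_divisions: int = 0

    def final_contours(self, run_name: str = "run") -> ContourSet:
        return self.final_mesh.cell_contours(group=("sim", run_name, "final", ""))

    def final_metrics(self, run_name: str = "run", n_angles: int = 720):
        from .shape_metrics import metrics_table

        return metrics_table(self.final_contours(run_name), n_angles=n_angles)


def run_simulation(template: CellMesh, schedule: GrowthSchedule,
                   cfg: SimConfig, snapshot_every: int | None = None) -> Trajectory:
    """Run the growth loop: boundary growth, relaxation, connection placement
    and (optionally) division, once per schedule step.

    The run is fully deterministic given the template (whose seeded jitter
    is the only randomness) and the configuration.  It aborts if more than
    ``max_failed_relax_frac`` of the relaxations fail to converge.
    """
    mesh = template.copy()
    traj = Trajectory(final_mesh=mesh)
    n_steps = schedule.n_steps
    n_div_total = 0
    for step in range(n_steps):
        fx = float(schedule.factors_x[step])
        fy = float(schedule.factors_y[step])
        t = (step + 1) / n_steps
        apply_boundary_growth(mesh, fx - 1.0, fy - 1.0)
        grow_rest_lengths(mesh, fx - 1.0, fy - 1.0)
        subdivide_long_edges(mesh, cfg.max_edge_length)
        rep = relax(mesh, cfg)
        traj.reports.append(rep)
        yield_compressed_walls(mesh, cfg.compress_yield)
        break_overstretched_connections(mesh, cfg.conn_break_strain)
        place_connections(mesh, cfg)
        if cfg.divisions_enabled:
            n_div_total += divide_cells(mesh, t, cfg)
        if cfg.untangle_every and (step + 1) % cfg.untangle_every == 0:
            untangle_mesh(mesh, cfg)
        if snapshot_every and (step + 1) % snapshot_every == 0:
            traj.snapshots.append((step + 1, mesh.copy()))
        failed = sum(1 for r in traj.reports if not r.converged)
        if failed > cfg.max_failed_relax_frac * n_steps:
            raise SimulationError(
                f"{failed} of {step + 1} relaxations failed to converge")
    if cfg.untangle_every:
        untangle_mesh(mesh, cfg)
    traj.final_mesh = mesh
    traj.n_connections = len(mesh.connections)
    traj.n_divisions = n_div_total
    return traj


# --------------------------------------------------------------------------
# preset scenarios
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class Scenario:
    """A named (template recipe, schedule, config) bundle."""

    name: str
    template_kind: str
    n_cells: int
    schedule: GrowthSchedule
    config: SimConfig
    template_kwargs: dict = field(default_factory=dict)

    def make_template(self, rng_seed: int = 0) -> CellMesh:
        return make_template(self.template_kind, n_cells=self.n_cells,
                             rng_seed=rng_seed, **self.template_kwargs)

    def run(self, rng_seed: int = 0, snapshot_every: int | None = None) -> Trajectory:
        cfg = replace(self.config, rng_seed=rng_seed)
        return run_simulation(self.make_template(rng_seed), self.schedule, cfg,
                              snapshot_every=snapshot_every)


def preset_scenarios(n_steps: int = 300, n_cells: int = 36,
                     scale_x: float = 10.0, scale_y: float = 16.0,
                     divisions_area: float = 2.0,
                     reduced: bool = False) -> dict[str, Scenario]:
    """The named growth scenarios of the study, at configurable size.

    The isodiametric family reaches cumulative per-axis scales of exactly
    ``(scale_x, scale_y)`` = (10, 16) by default under three time courses:

    * ``uniform_weak_aniso`` — constant rates, 1.6:1 final anisotropy;
    * ``iso_then_aniso`` — isotropic for 5/6 of the run (to 10x, 10x), then
      y-only growth for the final 1/6 (vertically oriented lobes);
    * ``aniso_then_iso`` — the exact time-reversal (horizontal lobe bias);
    * ``*_div`` variants of the three with divisions during the first 20%.

    The maize family starts from elongated cells and runs a longitudinal
    (y) growth phase and a transverse-widening phase in either order
    (``maize_ordered`` vs ``maize_reversed``), both to the same cumulative
    scale.

    ``reduced=True`` returns the same scenario family at desk scale —
    smaller templates, fewer steps and smaller cumulative growth — with all
    of the qualitative contrasts (lobe-bias orderings, division effects)
    intact.  The reduced family is what the test-suite property checks run.
    """
    if reduced:
        n_steps = min(n_steps, 50)
        n_cells = min(n_cells, 16)
        scale_x, scale_y = 5.0, 8.0
        maize_s1, maize_s2 = (1.2, 3.5), (2.5, 10.0 / 7.0)
        maize_kwargs = {"maize_aspect": 3}
        maize_cells = min(n_cells, 9)
    else:
        maize_s1, maize_s2 = (1.5, 8.0), (4.0, 2.0)
        maize_kwargs = {"maize_aspect": 6}
        maize_cells = n_cells
    base = SimConfig(divisions_enabled=False, area_div=divisions_area)
    div = replace(base, divisions_enabled=True, f_div=0.2)
    uniform = GrowthSchedule(
        np.full(n_steps, scale_x ** (1.0 / n_steps)),
        np.full(n_steps, scale_y ** (1.0 / n_steps)))
    iso_then = GrowthSchedule.two_phase(
        n_steps, 5.0 / 6.0,
        (scale_x, scale_x),                 # isotropic phase
        (1.0, scale_y / scale_x))           # then y-only growth
    aniso_then = iso_then.reversed()
    maize_ordered = GrowthSchedule.two_phase(n_steps, 0.5, maize_s1, maize_s2)
    maize_reversed = GrowthSchedule.two_phase(n_steps, 0.5, maize_s2, maize_s1)
    out = {
        "uniform_weak_aniso": Scenario("uniform_weak_aniso", "isodiametric_grid",
                                       n_cells, uniform, base),
        "iso_then_aniso": Scenario("iso_then_aniso", "isodiametric_grid",
                                   n_cells, iso_then, base),
        "aniso_then_iso": Scenario("aniso_then_iso", "isodiametric_grid",
                                   n_cells, aniso_then, base),
        "uniform_weak_aniso_div": Scenario("uniform_weak_aniso_div",
                                           "isodiametric_grid", n_cells, uniform, div),
        "iso_then_aniso_div": Scenario("iso_then_aniso_div", "isodiametric_grid",
                                       n_cells, iso_then, div),
        "aniso_then_iso_div": Scenario("aniso_then_iso_div", "isodiametric_grid",
                                       n_cells, aniso_then, div),
        "maize_ordered": Scenario("maize_ordered", "maize_elongated",
                                  maize_cells, maize_ordered, base, maize_kwargs),
        "maize_reversed": Scenario("maize_reversed", "maize_elongated",
                                   maize_cells, maize_reversed, base, maize_kwargs),
    }
    return out


# --------------------------------------------------------------------------
# rendering
# --------------------------------------------------------------------------


def render_mesh_svg(mesh: CellMesh, path: str | Path, scale: float = 20.0) -> None:
    """Write a minimal SVG of cell outlines (black) and connections (red)."""
    pts = mesh.positions
    minx, miny = pts.min(axis=0)
    maxx, maxy = pts.max(axis=0)
    w = (maxx - minx) * scale + 20
    h = (maxy - miny) * scale + 20

    def sx(p):
        return 10 + (p[0] - minx) * scale

    def sy(p):
        return h - 10 - (p[1] - miny) * scale

    parts = [f'<svg xmlns="http://www.w3.org/2000/svg" width="{w:.0f}" height="{h:.0f}">']
    for label in sorted(mesh.cells):
        poly = mesh.cell_polygon(label)
        d = " ".join(f"{sx(p):.2f},{sy(p):.2f}" for p in poly)
        parts.append(f'<polygon points="{d}" fill="none" stroke="black" stroke-width="1"/>')
    for (i, j) in mesh.connections:
        parts.append(
            f'<line x1="{sx(pts[i]):.2f}" y1="{sy(pts[i]):.2f}" '
            f'x2="{sx(pts[j]):.2f}" y2="{sy(pts[j]):.2f}" '
            f'stroke="red" stroke-width="0.5"/>')
    parts.append("</svg>")
    Path(path).write_text("\n".join(parts))
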