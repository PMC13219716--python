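"""Reading, writing, cleaning and organizing polygonal cell contours.

A contour is a closed 2D polygon in microns, stored as a plain text file with
one ``x y`` pair per line.  Surveys organize many such files in a labeled
directory tree ``root/clade/species/organ/sample.txt``; the loader preserves
those path components as group labels so downstream statistics can aggregate
per clade, per species, or per species-organ.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import _geom
from .errors import (
    ContourParseError,
    DegenerateContourError,
    MalformedContourError,
    MultiPieceError,
    UnrepairableContourError,
)

log = logging.getLogger(__name__)

# Two consecutive vertices closer than this (microns) are treated as
# coincident and collapsed on load.  Implementation-chosen threshold.
COINCIDENT_TOL = 1e-9


@dataclass(frozen=True)
class Contour:
    """A simple closed polygon (microns) with survey labels.

    ``vertices`` excludes the implicit closure edge: the last vertex connects
    back to the first.  Orientation is normalized counter-clockwise.
    """

    vertices: np.ndarray
    label: int = 0
    group: tuple[str, str, str, str] = ("", "", "", "")  # clade, species, organ, sample

    @property
    def clade(self) -> str:
        return self.group[0]

    @property
    def species(self) -> str:
        return self.group[1]

    @property
    def organ(self) -> str:
        return self.group[2]

    @property
    def sample(self) -> str:
        return self.group[3]

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def with_vertices(self, vertices: np.ndarray) -> "Contour":
        return replace(self, vertices=np.asarray(vertices, dtype=float))


@dataclass
class ContourSet:
    """A collection of contours with unique labels and group mappings."""

    contours: list[Contour] = field(default_factory=list)

    def __post_init__(self) -> None:
        labels = [c.label for c in self.contours]
        if len(labels) != len(set(labels)):
            raise MultiPieceError("duplicate contour labels within one set")

    def __len__(self) -> int:
        return len(self.contours)

    def __iter__(self):
        return iter(self.contours)

    def grouping(self, level: str) -> dict:
        """Map a grouping key to member labels.

        ``level`` is one of ``"clade"``, ``"species"`` or ``"species-organ"``.
        """
        out: dict = {}
        for c in self.contours:
            if level == "clade":
                key = c.clade
            elif level == "species":
                key = c.species
            elif level == "species-organ":
                key = (c.species, c.organ)
            else:
                raise ValueError(f"unknown grouping level {level!r}")
            out.setdefault(key, []).append(c.label)
        return out

    def metadata_table(self) -> pd.DataFrame:
        rows = [
            {
                "label": c.label,
                "clade": c.clade,
                "species": c.species,
                "organ": c.organ,
                "sample": c.sample,
                "n_vertices": c.n_vertices,
            }
            for c in sorted(self.contours, key=lambda c: (c.group, c.label))
        ]
        return pd.DataFrame(
            rows, columns=["label", "clade", "species", "organ", "sample", "n_vertices"]
        )


def _clean_vertices(pts: np.ndarray, where: str) -> np.ndarray:
    """Drop an explicit closure point and coincident consecutive vertices."""
    pts = np.asarray(pts, dtype=float)
    if len(pts) >= 2 and np.hypot(*(pts[-1] - pts[0])) <= COINCIDENT_TOL:
        pts = pts[:-1]
    if len(pts) >= 2:
        d = np.hypot(*(pts - np.roll(pts, 1, axis=0)).T)
        keep = d > COINCIDENT_TOL
        keep[0] = True  # roll made index 0 compare to the last vertex; closure handled above
        pts = pts[keep]
    if len(pts) < 3:
        raise MalformedContourError(f"{where}: fewer than 3 distinct vertices")
    return pts


def normalize_ccw(pts: np.ndarray) -> np.ndarray:
    if _geom.signed_area(pts) < 0:
        return pts[::-1].copy()
    return pts


def parse_contour_text(text: str, where: str = "<string>") -> np.ndarray:
    """Parse the one-point-per-line contour dialect.

    Coordinates may be separated by whitespace or commas; lines starting with
    ``#`` are comments.  A blank line splitting the points into several blocks
    marks a multi-piece cell, which is rejected.
    """
    blocks: list[list[list[float]]] = [[]]
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if line.startswith("#"):
            continue
        if not line:
            if blocks[-1]:
                blocks.append([])
            continue
        tokens = line.replace(",", " ").split()
        if len(tokens) < 2:
            raise ContourParseError(f"{where}, line {lineno}: expected two coordinates")
        try:
            x, y = float(tokens[0]), float(tokens[1])
        except ValueError as exc:
            raise ContourParseError(f"{where}, line {lineno}: {raw.strip()!r}") from exc
        if not (np.isfinite(x) and np.isfinite(y)):
            raise ContourParseError(f"{where}, line {lineno}: non-finite coordinate")
        blocks[-1].append([x, y])
    blocks = [b for b in blocks if b]
    if not blocks:
        raise MalformedContourError(f"{where}: no points")
    if len(blocks) > 1:
        raise MultiPieceError(f"{where}: {len(blocks)} disconnected loops under one label")
    return np.array(blocks[0], dtype=float)


def read_contour_file(path: str | Path, label: int = 0,
                      group: tuple[str, str, str, str] = ("", "", "", "")) -> Contour:
    """Read one contour file (microns, one 2D point per line), CCW-normalized."""
    path = Path(path)
    pts = parse_contour_text(path.read_text(), where=str(path))
    pts = _clean_vertices(pts, where=str(path))
    return Contour(vertices=normalize_ccw(pts), label=label, group=group)


def write_contour_file(c: Contour, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = [f"{x:.9g} {y:.9g}" for x, y in c.vertices]
    path.write_text("\n".join(lines) + "\n")


def load_labeled_tree(root: str | Path) -> ContourSet:
    """Load every ``*.txt`` under ``root/clade/species/organ/`` as a contour.

    Files at other depths are skipped and logged.  Labels are assigned
    sequentially in sorted path order, so loading is deterministic.
    """
    root = Path(root)
    if not root.is_dir():
        raise FileNotFoundError(f"contour tree root {root} does not exist")
    contours: list[Contour] = []
    label = 0
    found_any = False
    for path in sorted(root.rglob("*.txt")):
        found_any = True
        rel = path.relative_to(root)
        if len(rel.parts) != 4:
            log.warning("skipping %s: not at root/clade/species/organ depth", path)
            continue
        clade, species, organ = rel.parts[:3]
        sample = rel.stem
        contours.append(read_contour_file(path, label=label,
                                          group=(clade, species, organ, sample)))
        label += 1
    if not found_any:
        warnings.warn(f"no contour files found under {root}", stacklevel=2)
    return ContourSet(contours)


def save_labeled_tree(cs: ContourSet, root: str | Path) -> None:
    """Mirror of :func:`load_labeled_tree`; empty group parts become ``unlabeled``."""
    root = Path(root)
    for c in cs:
        clade, species, organ, sample = (p or "unlabeled" for p in c.group)
        write_contour_file(c, root / clade / species / organ / f"{sample}.txt")


def smooth_contour(c: Contour, passes: int = 1) -> Contour:
    """Cyclic 1-neighborhood position average, applied ``passes`` times.

    Each output vertex is the unweighted mean of the vertex and its two
    cyclic neighbours.  Repeated application contracts toward the centroid;
    a triangle collapses to its centroid in a single pass, which is reported.
    """
    if passes < 1:
        raise ValueError("passes must be >= 1")
    pts = np.asarray(c.vertices, dtype=float)
    if len(pts) == 3:
        warnings.warn("smoothing a triangle maps all vertices to the centroid",
                      stacklevel=2)
    for _ in range(passes):
        pts = (np.roll(pts, 1, axis=0) + pts + np.roll(pts, -1, axis=0)) / 3.0
    distinct = np.unique(np.round(pts / max(COINCIDENT_TOL, 1e-12)), axis=0)
    if len(distinct) < 3:
        raise DegenerateContourError("smoothing collapsed the contour below 3 distinct points")
    return c.with_vertices(pts)


def _flagged_vertices(pts: np.ndarray) -> list[int]:
    """Vertices incident to an edge that properly crosses another edge."""
    n = len(pts)
    flagged: set[int] = set()
    for i, j in _geom.crossing_edge_pairs(pts):
        flagged.update({i, (i + 1) % n, j, (j + 1) % n})
    return sorted(flagged)


def repair_contour(c: Contour, max_rounds: int = 25) -> Contour:
    """Resolve self-intersections by locally re-smoothing out-of-order vertices.

    Vertices on crossing edges are replaced by their 1-neighborhood average;
    the detection/smoothing cycle repeats until the polygon is simple or the
    round budget is exhausted.  If a round fails to reduce the number of
    crossings (smoothing alone cannot uncross a symmetric bowtie, which it
    maps to a smaller bowtie), the vertex run between the first crossing
    edge pair is reversed — the classic 2-opt move that reorders
    out-of-sequence vertices directly.
    """
    pts = np.asarray(c.vertices, dtype=float)
    if len(pts) < 3:
        raise MalformedContourError("repair needs at least 3 vertices")
    # exact duplicate of a non-adjacent vertex pinches the loop into pieces
    _, counts = np.unique(pts, axis=0, return_counts=True)
    if np.any(counts > 1):
        raise MultiPieceError("contour revisits a vertex: cell in multiple pieces")
    n_prev = np.inf
    for _ in range(max_rounds):
        crossings = _geom.crossing_edge_pairs(pts)
        if not crossings:
            return c.with_vertices(normalize_ccw(pts)) if pts is not c.vertices else c
        if len(crossings) >= n_prev:
            i, j = crossings[0]
            pts = pts.copy()
            pts[i + 1:j + 1] = pts[i + 1:j + 1][::-1]
            n_prev = np.inf
            continue
        n_prev = len(crossings)
        n = len(pts)
        flagged = sorted({v for i, j in crossings
                          for v in (i, (i + 1) % n, j, (j + 1) % n)})
        new = pts.copy()
        for i in flagged:
            new[i] = (pts[i - 1] + pts[i] + pts[(i + 1) % len(pts)]) / 3.0
        pts = new
    raise UnrepairableContourError(
        f"contour still self-intersects after {max_rounds} repair rounds",
        flagged=_flagged_vertices(pts),
    )


def rotate_to_min_axis(c: Contour, n_angles: int = 3600) -> Contour:
    """Rigidly rotate about the centroid so the min-axis lies along +x.

    Width is invariant under a half-turn, so among tied minimizing
    orientations the smallest angle in [0, pi) is chosen.
    """
    from .shape_metrics import min_axis  # local import to avoid a cycle

    _, direction = min_axis(c, n_angles=n_angles, method="exact")
    theta = float(np.arctan2(direction[1], direction[0])) % np.pi
    ctr = _geom.centroid(c.vertices)
    rot = _geom.rotation_matrix(-theta)
    return c.with_vertices((c.vertices - ctr) @ rot.T + ctr)
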