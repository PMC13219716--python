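"""Synthetic contour populations with controlled statistical structure.

The survey pipeline needs per-species populations of simple-to-lobed cells
whose width (min-axis) and lobing can be coupled or decoupled at will.  The
generator uses a star-polygon family, r(theta) = R (1 + a cos k theta),
anisotropically scaled and rotated: the amplitude ``a`` controls lobing, the
lobe count ``k`` the spatial frequency, and the base width the min-axis.
The family is convenient because its simplicity boundary is analytic (any
a < 0.5 keeps the sampled polygon simple) and lobeyness grows monotonically
with ``a``, so ground truth is known exactly for every generated cell.

A species couples width to lobing through an amplitude law
``a(w) = a0 + s (w - w0) + noise`` clipped to [0, a_max]: a positive slope
``s`` with small noise plants a strong min-axis-lobeyness correlation, while
``s = 0`` with larger noise plants a null species.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import _geom
from .contour_io import Contour, ContourSet, save_labeled_tree

CLADES = ("fern", "gymnosperm", "basal_angiosperm", "monocot", "eudicot")


def make_lobed_contour(R: float, a: float, k: int, aspect: float = 1.0,
                       angle: float = 0.0, n_points: int = 128,
                       rng_seed: int | None = None,
                       jitter: float = 0.0) -> Contour:
    """Star polygon r(theta) = R (1 + a cos k theta), scaled and rotated.

    ``aspect >= 1`` stretches the x axis before rotation, so the min-axis of
    the unrotated shape stays near ``2 R``.  ``a = 0`` gives an ellipse.
    Optional radial jitter (fraction of R) roughens the outline.
    """
    if not 0 <= a < 0.5:
        raise ValueError("lobe amplitude must satisfy 0 <= a < 0.5")
    if k < 0 or n_points < 32:
        raise ValueError("need k >= 0 and n_points >= 32")
    if aspect < 1:
        raise ValueError("aspect must be >= 1")
    theta = np.linspace(0.0, 2 * np.pi, n_points, endpoint=False)
    r = R * (1.0 + a * np.cos(k * theta))
    if jitter > 0:
        rng = np.random.default_rng(rng_seed)
        r = r * (1.0 + jitter * rng.uniform(-1, 1, size=n_points))
    pts = np.column_stack([aspect * r * np.cos(theta), r * np.sin(theta)])
    if angle:
        pts = pts @ _geom.rotation_matrix(angle).T
    return Contour(vertices=pts)


@dataclass(frozen=True)
class SpeciesSpec:
    """Recipe for one synthetic species population."""

    n_cells: int = 150
    width_range: tuple[float, float] = (10.0, 40.0)   # log-uniform min-axis, um
    aspect_range: tuple[float, float] = (1.0, 2.5)
    amp_intercept: float = 0.12       # a0 at reference width w0
    amp_slope: float = 0.01           # s, per um of width: the coupling dial
    amp_noise: float = 0.03           # sigma_a
    amp_max: float = 0.45             # keeps star polygons simple (< 0.5)
    ref_width: float | None = None    # w0; geometric mean of range if None
    lobe_counts: tuple[int, ...] = (4, 5, 6, 7, 8)
    n_points: int = 96
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.amp_max >= 0.5 or min(self.width_range) <= 0:
            raise ValueError("invalid species spec: amp_max < 0.5, widths > 0")


def make_species(spec: SpeciesSpec, species: str = "species",
                 clade: str = "", organ: str = "leaf") -> tuple[ContourSet, pd.DataFrame]:
    """Generate one species population plus its ground-truth table.

    Widths are log-uniform over ``width_range``; the amplitude law turns the
    width into a lobe amplitude, so ``amp_slope > 0`` with small noise plants
    a positive min-axis-lobeyness correlation and ``amp_slope = 0`` with
    larger noise plants an (approximately) uncorrelated species.
    """
    rng = np.random.default_rng(spec.rng_seed)
    lo, hi = spec.width_range
    w0 = spec.ref_width if spec.ref_width is not None else float(np.sqrt(lo * hi))
    w = np.exp(rng.uniform(np.log(lo), np.log(hi), size=spec.n_cells))
    a = np.clip(spec.amp_intercept + spec.amp_slope * (w - w0)
                + rng.normal(0.0, spec.amp_noise, size=spec.n_cells),
                0.0, spec.amp_max)
    k = rng.choice(spec.lobe_counts, size=spec.n_cells)
    aspect = rng.uniform(*spec.aspect_range, size=spec.n_cells)
    angle = rng.uniform(0.0, np.pi, size=spec.n_cells)
    contours, rows = [], []
    for i in range(spec.n_cells):
        c = make_lobed_contour(R=w[i] / 2.0, a=float(a[i]), k=int(k[i]),
                               aspect=float(aspect[i]), angle=float(angle[i]),
                               n_points=spec.n_points)
        contours.append(Contour(vertices=c.vertices, label=i,
                                group=(clade, species, organ, f"cell_{i:04d}")))
        rows.append({"label": i, "true_width_um": w[i], "true_amplitude": a[i],
                     "true_lobe_count": int(k[i]), "true_aspect": aspect[i],
                     "true_angle": angle[i]})
    return ContourSet(contours), pd.DataFrame(rows)


def coupled_spec(rng_seed: int, width_center: float = 20.0) -> SpeciesSpec:
    """Species with a planted positive width-lobing coupling (r >= 0.3)."""
    return SpeciesSpec(width_range=(width_center / 2, width_center * 2),
                       amp_slope=0.30 / width_center, amp_noise=0.02,
                       rng_seed=rng_seed)


def null_spec(rng_seed: int, width_center: float = 20.0) -> SpeciesSpec:
    """Size-neutral species: amplitude independent of width (|r| < 0.3)."""
    return SpeciesSpec(width_range=(width_center / 2, width_center * 2),
                       amp_slope=0.0, amp_intercept=0.15, amp_noise=0.08,
                       rng_seed=rng_seed)


def make_survey(root: str | Path, n_species: int = 40,
                fraction_coupled: float = 0.75, rng_seed: int = 0,
                n_cells: int = 80, force: bool = False) -> pd.DataFrame:
    """Write a labeled survey tree plus a truth manifest.

    Species width centers span 1.5 orders of magnitude (log-uniform) across
    the survey, mimicking the size range of real cross-species collections.
    The manifest records, per species, whether the coupling was planted, so
    recovery of the planted fraction can be checked against binomial error.
    """
    if not 0 <= fraction_coupled <= 1:
        raise ValueError("fraction_coupled must be in [0, 1]")
    root = Path(root)
    if root.exists() and any(root.iterdir()) and not force:
        raise FileExistsError(f"{root} is not empty; pass force=True to overwrite")
    rng = np.random.default_rng(rng_seed)
    n_coupled = int(round(fraction_coupled * n_species))
    coupled_flags = np.zeros(n_species, dtype=bool)
    coupled_flags[:n_coupled] = True
    rng.shuffle(coupled_flags)
    centers = np.exp(rng.uniform(np.log(8.0), np.log(8.0 * 10**1.5), n_species))
    manifest = []
    all_contours = []
    label = 0
    for i in range(n_species):
        seed = int(rng.integers(0, 2**31 - 1))
        make = coupled_spec if coupled_flags[i] else null_spec
        spec = make(rng_seed=seed, width_center=float(centers[i]))
        spec = SpeciesSpec(**{**asdict(spec), "n_cells": n_cells})
        name = f"species_{i:03d}"
        clade = CLADES[i % len(CLADES)]
        cs, _truth = make_species(spec, species=name, clade=clade)
        for c in cs:
            all_contours.append(Contour(vertices=c.vertices, label=label,
                                        group=c.group))
            label += 1
        manifest.append({"species": name, "clade": clade,
                         "coupled": bool(coupled_flags[i]),
                         "width_center_um": float(centers[i]), "rng_seed": seed})
    save_labeled_tree(ContourSet(all_contours), root)
    mdf = pd.DataFrame(manifest)
    mdf.to_csv(root / "truth_manifest.csv", index=False)
    (root / "truth_manifest.json").write_text(json.dumps(manifest, indent=1))
    return mdf


def make_degenerate_fixtures(outdir: str | Path) -> list[tuple[Path, str]]:
    """Write raw contour files exercising the error/repair paths.

    Returns (path, expected-behavior tag) pairs; tags are one of
    ``repairable`` (self-intersecting but fixable), ``duplicate-vertices``
    (cleanable), ``malformed`` (too few points) and ``multi-piece``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fixtures: list[tuple[Path, str]] = []

    def emit(name: str, lines: list[str], tag: str) -> None:
        p = outdir / name
        p.write_text("\n".join(lines) + "\n")
        fixtures.append((p, tag))

    emit("bowtie.txt", ["0 0", "2 2", "2 0", "0 2"], "repairable")
    emit("duplicate_vertices.txt",
         ["0 0", "0 0", "1 0", "1 0", "1 1", "0 1"], "duplicate-vertices")
    emit("two_points.txt", ["0 0", "1 1"], "malformed")
    emit("two_loops.txt",
         ["0 0", "1 0", "1 1", "0 1", "", "5 5", "6 5", "6 6", "5 6"],
         "multi-piece")
    return fixtures
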