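# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `puzzlecell`, in the order a user meets them: contour
handling, shape descriptors, the mass-spring tissue model, the survey
statistics, and the synthetic data that drives the tests.

## Contours

A contour is a closed simple polygon in microns, one `x y` pair per line in
its text form (whitespace or comma separated, `#` comments ignored). The
closure edge is implicit — the last vertex is *not* repeated — so
perimeters never double-count an edge. Orientation is normalized
counter-clockwise on load using the shoelace sign. Consecutive vertices
closer than 1e-9 um are collapsed (an implementation-chosen threshold; the
traced data the format mimics carries far coarser precision). A blank line
splitting a file's points into two runs marks a cell in multiple pieces and
is rejected rather than silently merged.

Smoothing replaces each vertex by the unweighted mean of its closed
1-neighborhood (weights 1/3, 1/3, 1/3 — the plainest reading of a
"position average"). It commutes with rigid motions and contracts toward
the centroid; a triangle collapses in one pass, which raises a warning and
then an error if the result is degenerate.

Repair of self-intersecting ("vertices out of order") contours iterates:
find properly crossing edge pairs by an exhaustive O(n^2) segment test,
re-smooth the four incident vertices, repeat. Pure local smoothing has a
blind spot: a symmetric bowtie maps to a smaller symmetric bowtie and never
uncrosses. When a round fails to reduce the crossing count, the vertex run
between the first crossing pair is therefore reversed — the classic 2-opt
move, which directly reorders out-of-sequence vertices. Repair fails
loudly (with the offending vertex indices) if crossings survive the round
budget.

## Shape descriptors

* **Area, perimeter**: shoelace and summed edge lengths with implicit
  closure.
* **Convex hull**: monotone chain on exact coordinates; collinear hull
  points are dropped (neither hull perimeter nor widths change).
* **Lobeyness** `L = P / P_hull`. Ratios within 1e-12 of 1 are snapped to
  exactly 1 so convex polygons score 1.0 regardless of summation order;
  1e-12 is orders of magnitude below any measurable lobing.
* **Min-axis**: widths are projections of the hull onto candidate axes.
  The default samples 3600 orientations over [0, pi) — projection width is
  pi-periodic, so the half range covers every axis of the full circle.
  An exact mode evaluates only hull-edge normals, one of which always
  attains the minimum (rotating-calipers argument); it is the reference
  for tests and for rotating contours onto their min-axis (ties broken
  toward the smallest angle).
* **Largest empty circle**: best-first quadtree refinement of the signed
  distance to the boundary (the pole-of-inaccessibility search). Square
  cells are scored by the largest radius they could contain
  (`d + h*sqrt(2)`) and split until the bound is within tolerance of the
  incumbent. Default tolerance is 0.5% of the min-axis. Chosen over a
  boundary-Voronoi construction for robustness on noisy traced outlines.
  For shapes with non-unique centers (e.g. rectangles) the search returns
  one maximizing point deterministically, preferring the lexicographically
  smaller (x, y) among numerically tied candidates.
* **Directional lobe bias** `B = E_y / E_x`, where `E_y` is the summed
  |dy| over contour edges minus the same over hull edges, and `E_x`
  analogously. Convex contours have no excess in either axis and return a
  neutral flag (`None`), not a number; otherwise each excess is floored at
  a 1e-9 fraction of the total excursion so the ratio stays finite.

The LEC is reported as a radius; diameter and area are derived properties,
since downstream fits use both (area against cell area, diameter against
min-axis).

## The mass-spring tissue model

**State.** Vertices (point masses) with positions and a rim flag; wall
springs (vertex pair, rest length, stiffness) shared between adjacent
cells; connection springs owned by exactly one cell; cells as vertex
cycles. Templates are grids of near-square cells (`isodiametric_grid`) or
cells stretched 3-6x along y (`maize_elongated`), with walls pre-subdivided
(4 springs per cell edge) so they can buckle, and seeded uniform jitter
(0.18 of a segment length) on interior vertices — the only randomness in a
run.

**Growth.** Each step multiplies rim positions about the template center
by per-axis factors `(f_x, f_y)` from the growth schedule, and multiplies
every interior wall's rest length by the factor by which
`diag(f_x, f_y)` stretches a segment of its current orientation. With no
connections, the uniformly scaled tissue is therefore a zero-energy
equilibrium and cells simply enlarge — growth is imposed, not elastic.
Schedules are arrays of per-step factors; preset phases use the exact
per-phase root so cumulative scales telescope to their targets to
floating-point accuracy (the full-size preset family reaches exactly 10x
in x and 16x in y). A piecewise-linear `.func` control-point dialect is
supported for custom curves; true B-spline semantics of the upstream curve
editor are not reproduced (documented deviation).

**Relaxation.** Interior vertices are moved to the minimum of total
spring energy with the rim fixed — the stationary state of a fully damped
system — by quasi-Newton descent (L-BFGS with analytic gradients, i.e.
damped gradient flow with curvature acceleration). Convergence: largest
residual force component below `1e-5 * k_wall * mean rest length`, capped
at 1500 iterations; non-convergence is recorded per step, and a run aborts
if more than half its relaxations fail.

**Connections** (the microtubule/cellulose proxy). Candidate chords
between wall vertices of one cell are admitted when they (i) lie inside
the cell, (ii) have length within `[0.9, 1.4] * 2 * lec_target`
(`lec_target = 0.8` length units, the target free-span radius: spans are
clamped as they grow through this window), (iii) align with the inward
wall normal at both endpoints to within 25 degrees, and (iv) anchor at a
concave (indented) vertex — concavity read from the discrete turn sign
over a 3-vertex window. Admitted chords become springs 10x stiffer than
walls, frozen at their current length; each vertex anchors at most one
connection per cell. Connections are re-audited every step: chords that
leave their cell's interior are removed, and connections stretched beyond
50% strain rupture (a clamp the tissue has overpowered is mechanically
failed). These constants are implementation defaults chosen to give
robust lobing and clean geometry at desk scale; the admission *rules* are
the model, the constants are tunable via `SimConfig`.

**Why lobes form and remember growth history.** A clamped span cannot
widen, but the wall material around it keeps growing; the surplus buckles
outward, seeded by template jitter. Buckling is largest along whichever
axis growth is currently frustrated, so late-phase anisotropy imprints its
direction on the lobes: isotropic-then-vertical growth ends with
vertically biased lobes (median `B > 1`), the reversed schedule with
horizontally biased ones, and the maize-like longitudinal-then-transverse
sequence with transverse lobes despite the elongated organ axis.

**Numerical safeguards.** Wall springs under compression yield: each step
the rest length of a compressed wall relaxes fully to its actual length
(`compress_yield = 1`), because real walls buckle rather than push;
without this, stored compression folds lobes over themselves. Walls
longer than 0.45 units are split at their midpoint (daughters inherit half
the rest length) to keep the buckling wavelength resolved. The spring
energy has no contact term, so a deeply pinched neck can occasionally push
one wall through its neighbour; every 3 steps, and at the end of a run,
vertices on crossing edges are smoothed toward their wall neighborhood,
incident rest lengths are re-zeroed to the new geometry, and the tissue is
re-relaxed (with smoothing-only fallback rounds). On the tested
configurations this keeps every cell polygon simple and the cells tiling
the rim area to better than 1%.

**Division.** When enabled, cells above `area_div` (default 2x the
initial cell area) are split during the first `f_div = 20%` of the run by
the shortest straight chord through the centroid (an Errera-style plane
rule; the plane rule is an implementation choice, as is keeping the
original rim fixed after divisions of rim-adjacent cells). Daughters keep
the parent label plus a fresh label; a cut that fails to produce two
simple polygons is skipped and logged.

**Determinism.** Given template seed, schedule and config, runs are
bit-identical: jitter is the only stochastic element, and every
subsequent operation (L-BFGS, chord admission order, division order) is
deterministic.

**Preset sizes.** Full presets default to 36 cells, 300 steps and
cumulative (10, 16). The *reduced* family used by the property tests and
the acceptance script runs 16-cell templates (9 for maize, aspect 3) for
50 steps to cumulative (5, 8) — and (3, 5) for maize — which preserves
every qualitative contrast (bias orderings, division effects,
isotropy-lobeyness ordering) at desk scale.

## Survey statistics

* **Percentile selection** uses the nearest-rank convention (the
  `ceil(q/100 * n)`-th order statistic): a real cell is always selected,
  so its contour can be displayed; value-interpolating definitions would
  return values belonging to no cell. Ties resolve to the smallest label.
* **Correlation**: product-moment r between min-axis and lobeyness per
  species (n >= 3 required); zero-variance species are flagged undefined,
  kept in the denominator as "weak" by default, with an option to exclude
  them (both conventions are reported because survey denominators in the
  literature rarely state the choice).
* **Classification**: weak below 0.3, moderate-high at or above 0.3
  (boundary inclusive).
* **Curvature fits**: least squares for `y = beta*x + alpha*x^2` with no
  intercept, fitted per species on (cell area, LEC area) and on
  (min-axis, LEC diameter). The sign aggregation and binomial test use the
  area-area fit. Fitting is per species (the sign count requires it);
  pooled fits remain available by passing a pooled table.
* **Binomial sign test**: exact two-sided at null probability 1/2,
  doubling the smaller tail capped at 1 — which at p = 1/2 coincides with
  the minimum-likelihood definition by symmetry.
* **Areal strain**: `(A2 - A1) / A1`.
* Reported percentages are exact fractions; rounding to integers happens
  only in display strings.

## Synthetic data

The generator emulates the statistical structure of cross-species contour
collections: per-species populations of simple-to-lobed cells, widths
log-uniform within a species and species centers spanning 1.5 orders of
magnitude (8 um to ~250 um), lobe counts 4-8, aspect ratios 1-2.5, random
orientations. The star-polygon family is used because its geometry is
analytically controllable: any amplitude a < 0.5 keeps the sampled polygon
simple, and lobeyness is monotone in a, so each generated cell carries
exact ground truth.

Coupling between width and lobing enters through the amplitude law
`a(w) = a0 + s*(w - w0) + noise`, clipped to [0, 0.45]. "Coupled" species
use `s = 0.30 / w_center` with noise sd 0.02 (planting r well above the
0.3 threshold); "null" species use `s = 0` with noise sd 0.08. A planted
survey writes the labeled directory tree plus a manifest of which species
were coupled, so pipeline recovery can be checked against exact binomial
error. Note that even null species show a small positive correlation
(~0.15): deeper lobes slightly enlarge the convex hull and hence the
measured min-axis. This is a property of the measurement, not a bug, and
it stays safely below the 0.3 threshold.

What the generator does **not** emulate: wall waviness and tracing noise
spectra of real segmentations, within-organ spatial correlation of cell
shapes, multi-organ heterogeneity within a species, or any real taxon's
shape distribution. Passing the recovery tests therefore shows the
pipeline's statistics behave correctly under known structure — not that
real surveys would yield any particular percentage.

## Known limitations

* The mechanical model has no contact mechanics, turgor pressure term, 3D
  walls or explicit cytoskeleton dynamics; connections are a geometric
  proxy. Exact stiffnesses, angle caps and span windows used with the
  original modelling framework are not published, so the defaults here are
  the package's own and only qualitative orderings should be compared.
* The fully damped quasi-static assumption means trajectories have no
  time scale beyond "growth steps".
* The LEC search is tolerance-limited for slivers thinner than its
  tolerance (it warns).
* Survey statistics assume cells are independent within a species;
  no phylogenetic or within-organ correlation correction is applied.
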