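# puzzlecell

Quantification and mechanistic simulation of plant epidermal pavement-cell
shape.

## The problem

Pavement cells of plant aerial organs range from simple elongated bricks to
interlocking jigsaw ("puzzle") pieces. The puzzle morphology is understood
as a mechanical adaptation: lobes limit the largest unsupported span of the
outer wall — proxied in 2D by the **largest empty circle (LEC)**, the
biggest circle that fits inside the cell outline — and thereby cap
turgor-driven tensile stress as cells enlarge. Whether lobes form, and in
which direction they point, depends on the history of tissue growth
anisotropy, not just its cumulative amount.

`puzzlecell` provides three things:

1. **Shape descriptors** for polygonal cell contours (microns):
   area *A*, perimeter *P*, **lobeyness** `L = P / P_hull` (perimeter over
   convex-hull perimeter; `L = 1` iff convex), **min-axis** (width of the
   narrowest enclosing rectangle, i.e. the cell's shortest dimension), and
   the LEC center/radius. A directional lobe-bias ratio
   `B = E_y / E_x` (excess boundary excursion beyond the hull, per axis)
   quantifies whether lobes point vertically (`B > 1`) or horizontally.
2. **A fully damped mass-spring tissue model** of puzzle-cell emergence.
   Cells are polygons of point masses joined by linear wall springs; the
   tissue rim is displaced outward each step by per-axis growth factors
   while interior wall rest lengths follow the same growth. Stiff
   intracellular *connections* — the geometric proxy for microtubule-guided
   cellulose reinforcement — are placed across free spans that exceed a
   target width, freeze at their current length, and force subsequent wall
   growth to buckle outward into lobes. Preset scenarios contrast constant
   weak anisotropy, isotropic-then-anisotropic growth and its reversal
   (with and without an early division phase), and a maize-like sequence
   starting from elongated cells.
3. **Survey statistics** across species: per-species Pearson correlation
   between min-axis and lobeyness (classified weak vs moderate-high at
   `r >= 0.3`), nearest-rank 95th-percentile lobeyness, an
   origin-constrained quadratic fit `LEC_area = beta*A + alpha*A^2` whose
   curvature sign `alpha < 0` marks sub-linear LEC growth, and an exact
   two-sided binomial test on the sign counts across species.

A synthetic-data module generates star-polygon cell populations
(`r(theta) = R (1 + a cos k theta)`) with a tunable coupling between cell
width and lobe amplitude, so every pipeline stage can be exercised — and
its statistical power checked against planted ground truth — without any
imaging data.

## Worked example

```python
import numpy as np
from puzzlecell.synthetic_data import make_lobed_contour
from puzzlecell.shape_metrics import compute_metrics

cell = make_lobed_contour(R=20.0, a=0.3, k=6, n_points=256)  # lobed cell, ~40 um across
m = compute_metrics(cell)
print(f"area          = {m.area:8.1f} um^2")
print(f"perimeter     = {m.perimeter:8.1f} um")
print(f"lobeyness     = {m.lobeyness:8.3f}")
print(f"min-axis      = {m.min_axis:8.1f} um")
print(f"LEC radius    = {m.lec_radius:8.1f} um")
```

prints

```
area          =   1312.4 um^2
perimeter     =    198.6 um
lobeyness     =    1.267
min-axis      =     45.8 um
LEC radius    =     14.0 um
```

A six-lobed star of base radius 20 um is clearly lobed (`L = 1.27 > 1.1`),
and its maximal free span (LEC radius 14 um) is well below half its
min-axis (22.9 um) — the lobes are doing mechanical work.

The same pipeline from the shell, on a synthetic 4-species survey:

```bash
$ puzzlecell synth survey --out tree --n-species 4 --n-cells 30 --fraction-coupled 0.5 --seed 1
wrote 4 species (2 coupled) to tree
$ puzzlecell quantify --root tree --out metrics.csv
wrote 120 rows to metrics.csv (0 flagged failures)
$ puzzlecell survey --metrics metrics.csv --out survey.json
4 species: 50% with r >= 0.3, 100% concave (binomial p = 0.125)
```

The two species generated with width-lobing coupling are recovered as
moderate-high correlations (50% of 4), and all four concave LEC-area fits
give `alpha < 0` (with only 4 species the sign test is of course not yet
significant).

Simulations run from the same entry point, e.g.
`puzzlecell simulate --preset iso_then_aniso --steps 100 --cells 36 --out run/`
writes the final cell contours, their metrics table and an SVG rendering.

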