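import numpy as np
import pytest

from puzzlecell.contour_io import Contour
from puzzlecell.synthetic_data import make_lobed_contour


@pytest.fixture
def unit_square() -> Contour:
    return Contour(vertices=np.array([[0.0, 0], [1, 0], [1, 1], [0, 1]]))


@pytest.fixture
def rectangle_2x5() -> Contour:
    return Contour(vertices=np.array([[0.0, 0], [5, 0], [5, 2], [0, 2]]))


@pytest.fixture
def plus_shape() -> Contour:
    """Cross of five unit squares: perimeter 12, hull perimeter 4 + 4*sqrt(2)."""
    pts = np.array([
        [1.0, 0], [2, 0], [2, 1], [3, 1], [3, 2], [2, 2],
        [2, 3], [1, 3], [1, 2], [0, 2], [0, 1], [1, 1],
    ])
    return Contour(vertices=pts)


def random_star_polygons(n_shapes: int, seed: int, n_points: int = 180):
    """Deterministic family of star polygons spanning amplitudes and sizes."""
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_shapes):
        c = make_lobed_contour(
            R=float(rng.uniform(2.0, 60.0)),
            a=float(rng.uniform(0.0, 0.45)),
            k=int(rng.integers(3, 9)),
            aspect=float(rng.uniform(1.0, 3.0)),
            angle=float(rng.uniform(0, np.pi)),
            n_points=n_points,
        )
        out.append(c)
    return out
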