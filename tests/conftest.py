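import numpy as np
import pytest

from osteoquant.annotation import (
    BBox,
    CellAnnotation,
    CellType,
    Polygon,
    RegionAnnotation,
    WellAnnotation,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_simple_polygon(rng, n=12, cx=50.0, cy=50.0, r=20.0):
    """Star-convex polygon: radial samples at sorted angles are always simple."""
    theta = np.sort(rng.uniform(0, 2 * np.pi, size=n))
    rad = rng.uniform(0.4 * r, r, size=n)
    return Polygon(
        [(cx + ri * np.cos(t), cy + ri * np.sin(t)) for t, ri in zip(theta, rad)]
    )


@pytest.fixture
def square_polygon():
    return Polygon([(10.0, 10.0), (30.0, 10.0), (30.0, 20.0), (10.0, 20.0)])


@pytest.fixture
def tiny_well():
    """A 100x100 well with a 2x2 region grid and three annotated cells."""
    tri = Polygon([(5.0, 5.0), (25.0, 5.0), (5.0, 20.0)])
    quad = Polygon([(10.0, 10.0), (40.0, 12.0), (38.0, 40.0), (8.0, 35.0)])
    blob = Polygon([(20.0, 20.0), (45.0, 25.0), (40.0, 45.0), (15.0, 40.0)])
    regions = (
        RegionAnnotation(
            0, (0, 0), 50, 50,
            cells=(CellAnnotation(tri, CellType.PREOSTEOCLAST, 2),),
        ),
        RegionAnnotation(
            1, (50, 0), 50, 50,
            cells=(CellAnnotation(quad, CellType.OSTEOCLAST_I, 7),),
        ),
        RegionAnnotation(2, (0, 50), 50, 50, cells=()),
        RegionAnnotation(
            3, (50, 50), 50, 50,
            cells=(CellAnnotation(blob, CellType.GHOST, None),),
        ),
    )
    return WellAnnotation("w1", "w1.png", 100, 100, regions)


@pytest.fixture
def random_boxes(rng):
    def make(n, size=100.0, min_side=2.0, max_side=30.0):
        x0 = rng.uniform(0, size - max_side, size=n)
        y0 = rng.uniform(0, size - max_side, size=n)
        w = rng.uniform(min_side, max_side, size=n)
        h = rng.uniform(min_side, max_side, size=n)
        return np.stack([x0, y0, x0 + w, y0 + h], axis=1)

    return make
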