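import math

import numpy as np
import pytest

from wbcdetect.ellipse_geometry import EllipseParams, mea_rasterize
from wbcdetect.preprocess import edges_to_list


@pytest.fixture(scope="session")
def rendered_ellipse_edge_map():
    """Axis-aligned ellipse rasterized into an edge map plus its edge list."""
    e = EllipseParams(x0=48.0, y0=44.0, rmax=20.0, rmin=15.0, theta=0.0)
    size = 96
    shape = mea_rasterize(e, (size, size))
    edge = np.zeros((size, size), dtype=bool)
    edge[shape.pixels[:, 1], shape.pixels[:, 0]] = True
    return e, edge, edges_to_list(edge), shape


def quadrant_midpoint_oracle(ra: float, rb: float) -> set[tuple[int, int]]:
    """Exhaustive first-quadrant midpoint-test oracle for an axis-aligned ellipse.

    For every column in the shallow-slope region (up to the slope = -1 point)
    pick the largest row whose lower midpoint lies strictly inside the
    ellipse; symmetrically for rows in the steep region.  Entirely independent
    of the incremental walk it is used to check.
    """
    a2, b2 = ra * ra, rb * rb

    def fe(u: float, v: float) -> float:
        return b2 * u * u + a2 * v * v - a2 * b2

    denom = math.sqrt(a2 + b2)
    pts: set[tuple[int, int]] = set()
    for x in range(0, math.floor(a2 / denom) + 1):
        ys = [y for y in range(0, int(math.ceil(rb)) + 2) if fe(x, y - 0.5) < 0] + [0]
        pts.add((x, max(ys)))
    for y in range(0, math.floor(b2 / denom) + 1):
        xs = [x for x in range(0, int(math.ceil(ra)) + 2) if fe(x - 0.5, y) < 0] + [0]
        pts.add((max(xs), y))
    return pts


def full_midpoint_oracle(e: EllipseParams, bounds: tuple[int, int]) -> set[tuple[int, int]]:
    """Four-fold mirror of the quadrant oracle around an integer center."""
    assert e.theta == 0.0
    cx, cy = int(e.x0), int(e.y0)
    width, height = bounds
    out: set[tuple[int, int]] = set()
    for u, v in quadrant_midpoint_oracle(e.rmax, e.rmin):
        for sx in (1, -1):
            for sy in (1, -1):
                x, y = cx + sx * u, cy + sy * v
                if 0 <= x < width and 0 <= y < height:
                    out.add((x, y))
    return out
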