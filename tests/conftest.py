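import numpy as np
import pytest
from hypothesis import HealthCheck, settings
from shapely.geometry import Polygon

from carmap import generate_lattice

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=30,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def lattice_2x2():
    return generate_lattice(2, 2)


@pytest.fixture(scope="session")
def lattice_8x10():
    return generate_lattice(8, 10)


def rect(x0, y0, x1, y1):
    return Polygon([(x0, y0), (x1, y0), (x1, y1), (x0, y1)])


def random_rect_tiling(rng, n_target):
    """Tile the unit square by recursive random splits -> (ids, rectangles).

    Produces T-junctions, so contiguity cannot be read off shared vertices
    alone; used to exercise the Queen implementation against an exact
    interval-overlap oracle.
    """
    rects = [(0.0, 0.0, 1.0, 1.0)]
    while len(rects) < n_target:
        k = rng.integers(len(rects))
        x0, y0, x1, y1 = rects.pop(k)
        if rng.random() < 0.5 and (x1 - x0) > 0.05:
            xm = rng.uniform(x0 + 0.02, x1 - 0.02)
            rects += [(x0, y0, xm, y1), (xm, y0, x1, y1)]
        elif (y1 - y0) > 0.05:
            ym = rng.uniform(y0 + 0.02, y1 - 0.02)
            rects += [(x0, y0, x1, ym), (x0, ym, x1, y1)]
        else:
            rects.append((x0, y0, x1, y1))
    ids = [f"T{k:03d}" for k in range(len(rects))]
    return ids, rects


def interval_queen_oracle(rects, snap=1e-9):
    """Exact Queen adjacency for axis-aligned rectangles: two rectangles
    share a boundary point iff their closed x- and y-intervals both overlap."""
    def snapv(t):
        return tuple(round(c / snap) * snap for c in t)

    rects = [snapv(r) for r in rects]
    n = len(rects)
    nbrs = [set() for _ in range(n)]
    for i in range(n):
        ax0, ay0, ax1, ay1 = rects[i]
        for j in range(i + 1, n):
            bx0, by0, bx1, by1 = rects[j]
            if max(ax0, bx0) <= min(ax1, bx1) and max(ay0, by0) <= min(ay1, by1):
                nbrs[i].add(j)
                nbrs[j].add(i)
    return [np.array(sorted(s)) for s in nbrs]
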