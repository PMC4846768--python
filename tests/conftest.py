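import numpy as np
import pytest

from seedshape.geometry import Polygon, make_cardioid


@pytest.fixture
def unit_square() -> Polygon:
    return Polygon(np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]]))


@pytest.fixture
def cardioid_polygon() -> Polygon:
    return make_cardioid(1.0, 360).polygon


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def segments_intersect(p1, p2, q1, q2) -> bool:
    """Proper-intersection test for the brute-force simplicity oracle."""

    def orient(a, b, c):
        return np.sign((b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0]))

    return (
        orient(p1, p2, q1) != orient(p1, p2, q2)
        and orient(q1, q2, p1) != orient(q1, q2, p2)
    )


def brute_force_simple(poly: Polygon) -> bool:
    """O(n²) all-pairs edge-crossing check, independent of shapely."""
    v = poly.vertices
    n = len(v)
    edges = [(v[i], v[(i + 1) % n]) for i in range(n)]
    for i in range(n):
        for j in range(i + 2, n):
            if i == 0 and j == n - 1:
                continue  # adjacent around the wrap
            if segments_intersect(*edges[i], *edges[j]):
                return False
    return True
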