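import math

import numpy as np
import pytest

from celltda import PointCloud, RingSpec, make_infiltration_series, make_ring


@pytest.fixture
def acute_triangle() -> PointCloud:
    """Triangle with side lengths 1.0, 1.1, 1.2 (all angles acute).

    Analytic alpha filtration: edges at half-lengths 0.50/0.55/0.60,
    triangle at its circumradius abc/4K ~ 0.6405.
    """
    a, b, c = 1.0, 1.1, 1.2
    A = np.array([0.0, 0.0])
    B = np.array([c, 0.0])
    x = (c**2 + b**2 - a**2) / (2 * c)
    C = np.array([x, math.sqrt(b**2 - x**2)])
    return PointCloud(np.array([A, B, C]), "triangle", "cells")


@pytest.fixture
def triangle_circumradius() -> float:
    a, b, c = 1.0, 1.1, 1.2
    s = (a + b + c) / 2
    area = math.sqrt(s * (s - a) * (s - b) * (s - c))
    return a * b * c / (4 * area)


@pytest.fixture
def unit_ring() -> PointCloud:
    """40 points on the unit circle with the default tiny angular jitter."""
    return make_ring(RingSpec(n_points=40), seed=1)


@pytest.fixture
def infiltration_series() -> list[PointCloud]:
    """The fixed-seed infiltration fixture: a 60-point unit ring with
    0/10/40/160 interior noise points."""
    base = RingSpec(n_points=60, radial_jitter_sd=0.03)
    return make_infiltration_series(base, [0, 10, 40, 160], seed=11)


def random_cloud(seed: int, n: int | None = None) -> PointCloud:
    rng = np.random.default_rng(seed)
    if n is None:
        n = int(rng.integers(4, 26))
    return PointCloud(rng.uniform(0.0, 1.0, (n, 2)), f"rand{seed}", "cells")
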