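"""Synthetic point-cloud generators.

These generators reproduce the geometric motifs that drive the pipeline's
behaviour on tissue data, so every downstream stage is testable offline:

* a single ring of cells (one prominent loop),
* a ring with interior "infiltration" noise at increasing levels,
* several rings of different radius and point density in one cloud,
* dense blobs perforated by voids over a sparse background (tissue mimic),
* a labelled two-condition cohort for descriptor-clustering tests.

All generators are pure functions of ``(spec, seed)``: the same inputs give
byte-identical clouds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .data_io import PointCloud

__all__ = [
    "RingSpec",
    "make_ring",
    "make_multi_ring",
    "make_infiltration_series",
    "make_blob_with_voids",
    "make_two_condition_cohort",
]

#: default angular jitter (radians); exactly co-circular points are
#: non-generic for the Delaunay-based alpha construction.
DEFAULT_ANGULAR_JITTER = 0.01


@dataclass(frozen=True)
class RingSpec:
    """Parameters of one jittered ring of points with optional interior noise.

    ``n_points`` points are placed at evenly spaced angles on a circle of
    ``radius`` around ``centre``, each perturbed by Gaussian jitter in angle
    (sd ``angular_jitter_sd`` radians) and radius (sd ``radial_jitter_sd``,
    same units as radius).  ``n_interior_noise`` extra points are drawn
    uniformly in the open disc — the "infiltration" noise.
    """

    centre: tuple[float, float] = (0.0, 0.0)
    radius: float = 1.0
    n_points: int = 40
    angular_jitter_sd: float = DEFAULT_ANGULAR_JITTER
    radial_jitter_sd: float = 0.0
    n_interior_noise: int = 0

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.n_points < 3:
            raise ValueError("a ring needs at least 3 points")
        if self.angular_jitter_sd < 0 or self.radial_jitter_sd < 0:
            raise ValueError("jitter standard deviations must be non-negative")
        if self.n_interior_noise < 0:
            raise ValueError("n_interior_noise must be non-negative")


def _ring_points(spec: RingSpec, rng: np.random.Generator) -> np.ndarray:
    angles = 2 * np.pi * np.arange(spec.n_points) / spec.n_points
    if spec.angular_jitter_sd > 0:
        angles = angles + rng.normal(0.0, spec.angular_jitter_sd, spec.n_points)
    radii = np.full(spec.n_points, float(spec.radius))
    if spec.radial_jitter_sd > 0:
        radii = radii + rng.normal(0.0, spec.radial_jitter_sd, spec.n_points)
    cx, cy = spec.centre
    return np.column_stack([cx + radii * np.cos(angles), cy + radii * np.sin(angles)])


def _interior_noise(
    centre: tuple[float, float], radius: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    # uniform on the open disc via sqrt-radius sampling
    r = radius * np.sqrt(rng.uniform(0.0, 1.0, n))
    theta = rng.uniform(0.0, 2 * np.pi, n)
    cx, cy = centre
    return np.column_stack([cx + r * np.cos(theta), cy + r * np.sin(theta)])


def make_ring(
    spec: RingSpec,
    seed: int,
    sample_id: str = "ring",
    population: str = "cells",
    condition: str | None = None,
) -> PointCloud:
    """One jittered ring plus uniform interior noise; deterministic given seed.

    Ring points come first (indices ``0..n_points-1``), noise points after,
    so the ring part of the cloud is identical across noise levels when the
    same seed is used (see :func:`make_infiltration_series`).
    """
    rng = np.random.default_rng(seed)
    pts = _ring_points(spec, rng)
    if spec.n_interior_noise > 0:
        noise_rng = np.random.default_rng((seed, 0x9E3779B9))
        pts = np.vstack(
            [pts, _interior_noise(spec.centre, spec.radius, spec.n_interior_noise, noise_rng)]
        )
    return PointCloud(points=pts, sample_id=sample_id, population=population,
                      condition=condition)


def make_multi_ring(
    specs: list[RingSpec],
    seed: int,
    sample_id: str = "multi_ring",
    population: str = "cells",
    condition: str | None = None,
) -> PointCloud:
    """Concatenation of independent rings under one sample id.

    Ring centres should be pairwise farther apart than the sum of the two
    radii; overlap is only warned about, not rejected, because near-tangent
    arrangements are legitimate fixtures.
    """
    if not specs:
        raise ValueError("make_multi_ring needs at least one RingSpec")
    for i, a in enumerate(specs):
        for b in specs[i + 1:]:
            d = np.hypot(a.centre[0] - b.centre[0], a.centre[1] - b.centre[1])
            if d <= a.radius + b.radius:
                warnings.warn(
                    f"rings at {a.centre} and {b.centre} overlap "
                    f"(centre distance {d:.3g} <= radii sum {a.radius + b.radius:.3g})",
                    stacklevel=2,
                )
    parts = [
        make_ring(spec, seed=int(np.random.default_rng((seed, i)).integers(2**31)))
        for i, spec in enumerate(specs)
    ]
    pts = np.vstack([p.points for p in parts])
    return PointCloud(points=pts, sample_id=sample_id, population=population,
                      condition=condition)


def make_infiltration_series(
    base: RingSpec,
    noise_levels: list[int],
    seed: int,
    sample_prefix: str = "infiltration",
    population: str = "cells",
) -> list[PointCloud]:
    """A series of clouds sharing one ring, with increasing interior noise.

    The ring points are identical at every level and the noise points are
    nested (level ``k`` contains the noise of every smaller level), so any
    change in persistent homology along the series is attributable to the
    infiltration alone.
    """
    if list(noise_levels) != sorted(noise_levels):
        raise ValueError("noise_levels must be non-decreasing")
    rng_ring = np.random.default_rng(seed)
    ring = _ring_points(base, rng_ring)
    noise_rng = np.random.default_rng((seed, 0x9E3779B9))
    max_noise = max(noise_levels) if noise_levels else 0
    all_noise = _interior_noise(base.centre, base.radius, max_noise, noise_rng)
    clouds = []
    for level in noise_levels:
        pts = np.vstack([ring, all_noise[:level]]) if level else ring.copy()
        clouds.append(
            PointCloud(
                points=pts,
                sample_id=f"{sample_prefix}_{level:03d}",
                population=population,
            )
        )
    return clouds


def make_blob_with_voids(
    n_points: int,
    extent: float,
    voids: list[tuple[float, float, float]],
    seed: int,
    n_background: int = 0,
    background_extent: float | None = None,
    sample_id: str = "tissue",
    population: str = "cells",
    condition: str | None = None,
) -> PointCloud:
    """Tissue mimic: a dense uniform blob perforated by circular voids,
    plus an optional sparse uniform background.

    ``voids`` is a list of ``(cx, cy, r)`` discs from which dense points are
    rejected — the analogue of white-pulp holes in a red-pulp carpet.
    Background points (sparse, covering ``background_extent``) may fall
    anywhere, including inside voids: they emulate infiltration.
    """
    rng = np.random.default_rng(seed)
    pts: list[np.ndarray] = []
    kept = 0
    # rejection sampling; voids of plausible size leave plenty of room
    while kept < n_points:
        cand = rng.uniform(0.0, extent, size=(max(64, n_points), 2))
        inside_void = np.zeros(len(cand), dtype=bool)
        for cx, cy, r in voids:
            inside_void |= (cand[:, 0] - cx) ** 2 + (cand[:, 1] - cy) ** 2 < r**2
        keep = cand[~inside_void][: n_points - kept]
        pts.append(keep)
        kept += len(keep)
    if n_background > 0:
        be = extent if background_extent is None else background_extent
        pts.append(rng.uniform(0.0, be, size=(n_background, 2)))
    return PointCloud(points=np.vstack(pts), sample_id=sample_id,
                      population=population, condition=condition)


def make_two_condition_cohort(
    n_per_condition: int,
    params_healthy: RingSpec,
    params_diseased: RingSpec,
    seed: int,
    population: str = "cells",
    condition_names: tuple[str, str] = ("healthy", "diseased"),
) -> list[PointCloud]:
    """A labelled cohort: ``n_per_condition`` ring clouds per condition.

    Per-cloud seeds are derived from the master seed, so two calls with the
    same arguments produce byte-identical cohorts.  Identical parameter
    sets are allowed and give the negative-control cohort (no systematic
    difference between the condition labels).
    """
    clouds = []
    for cond_idx, (name, params) in enumerate(
        zip(condition_names, (params_healthy, params_diseased))
    ):
        for i in range(n_per_condition):
            sub = int(np.random.default_rng((seed, cond_idx, i)).integers(2**31))
            clouds.append(
                make_ring(
                    params,
                    seed=sub,
                    sample_id=f"{name}_{i:02d}",
                    population=population,
                    condition=name,
                )
            )
    return clouds
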