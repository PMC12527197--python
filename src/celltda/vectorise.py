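"""Fixed-length descriptors from persistence diagrams.

Three families of vectorisation are provided:

* **normalised Betti curves** — the number of features alive at each grid
  scale, divided by the total number of features in the diagram (all of
  them, including zero-persistence and essential features);
* **percentile statistics** — the 10/25/50/75/90th percentiles of the
  birth, death or persistence distribution, by linear interpolation
  between order statistics (essential features are excluded from death
  and persistence, included in birth);
* **persistence images** — the diagram in (birth, persistence)
  coordinates smoothed by an isotropic Gaussian per feature, weighted by
  one of five functions, and integrated over a pixel grid.  Box integrals
  are exact products of 1-D normal CDFs, so total image mass on a wide
  grid equals the summed weights.

The weightings are ``flat`` (linear ramp p/p0 plateauing at p0), ``w1`` =
p, ``w2`` = p², ``w3`` = bp, ``w4`` = bp².  All vanish at p = 0, the
stability requirement.  The plateau p0 derives from the typical
small scale s of the data — the average nearest-neighbour distance of the
all-cells clouds: p0 = s/2 in degree 0 (the scale at which neighbouring
cells connect) and p0 = (1/√3 − 1/2)·s in degree 1, the persistence of
the minimal loop — three cells at the corners of an equilateral triangle
of side s, born at s/2 and filled at its circumradius s/√3.  s and p0 are
fixed from the whole point clouds even when vectorising single-population
subsets, so descriptors of sparse populations stay on a common scale.

Degree-1 diagrams get all nine vectorisations.  In degree 0 every feature
is born at 0, so death equals persistence and only the persistence
percentiles and the flat/w1/w2 images are kept (birth percentiles are
identically zero and the birth-weighted images identically empty).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .data_io import PointCloud
from .persistence import PersistenceDiagram

logger = logging.getLogger(__name__)

__all__ = [
    "WeightingSpec",
    "ImageParams",
    "estimate_scale_s",
    "p0_for_degree",
    "betti_curve",
    "percentile_stats",
    "persistence_image",
    "default_registry",
    "build_descriptor_matrix",
]

PERCENTILES = (10, 25, 50, 75, 90)

#: persistence of the equilateral-triangle loop at unit side:
#: death 1/sqrt(3) (circumradius) minus birth 1/2 (half-side).
EQUILATERAL_LOOP_PERSISTENCE = 1.0 / math.sqrt(3.0) - 0.5

WEIGHTING_NAMES = ("flat", "w1", "w2", "w3", "w4")


@dataclass(frozen=True)
class WeightingSpec:
    """One of the five persistence-image weightings.

    ``p0`` (plateau of the flat ramp) is required for ``flat`` only.
    """

    name: str
    p0: float | None = None

    def __post_init__(self) -> None:
        if self.name not in WEIGHTING_NAMES:
            raise ValueError(f"unknown weighting {self.name!r}")
        if self.name == "flat" and (self.p0 is None or self.p0 <= 0):
            raise ValueError("flat weighting needs p0 > 0")

    def __call__(self, b: np.ndarray, p: np.ndarray) -> np.ndarray:
        b = np.asarray(b, dtype=float)
        p = np.asarray(p, dtype=float)
        if self.name == "flat":
            return np.clip(p / self.p0, 0.0, 1.0)
        if self.name == "w1":
            return p
        if self.name == "w2":
            return p**2
        if self.name == "w3":
            return b * p
        return b * p**2  # w4


@dataclass(frozen=True)
class ImageParams:
    """Persistence-image grid: resolution, Gaussian sd, axis ranges.

    ``birth_range`` and ``pers_range`` are (min, max) bounds of the
    birth and persistence axes.
    """

    resolution: tuple[int, int] = (20, 20)
    gaussian_sd: float = 1.0
    birth_range: tuple[float, float] = (0.0, 1.0)
    pers_range: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self) -> None:
        if self.resolution[0] < 1 or self.resolution[1] < 1:
            raise ValueError("resolution must be at least (1, 1)")
        if self.gaussian_sd <= 0:
            raise ValueError("gaussian_sd must be positive")
        for lo, hi in (self.birth_range, self.pers_range):
            if not (np.isfinite(lo) and np.isfinite(hi) and hi > lo):
                raise ValueError("axis ranges must be finite with max > min")


def estimate_scale_s(clouds: list[PointCloud]) -> float:
    """Typical small scale s: mean over samples of the within-sample mean
    nearest-neighbour distance, computed on the all-cells clouds.

    Clouds with fewer than two points are excluded with a warning.
    """
    from scipy.spatial import cKDTree

    per_sample = []
    for cloud in clouds:
        if len(cloud) < 2:
            logger.warning(
                "cloud (%s, %s) has < 2 points; excluded from scale estimate",
                cloud.sample_id, cloud.population,
            )
            continue
        tree = cKDTree(cloud.points)
        dists, _ = tree.query(cloud.points, k=2)
        per_sample.append(float(dists[:, 1].mean()))
    if not per_sample:
        raise ValueError("no cloud with >= 2 points; cannot estimate scale")
    return float(np.mean(per_sample))


def p0_for_degree(s: float, degree: int) -> float:
    """Minimal-feature persistence at scale s: s/2 in degree 0; the
    equilateral-triangle loop persistence (1/√3 − 1/2)·s in degree 1."""
    if s <= 0:
        raise ValueError("s must be positive")
    if degree == 0:
        return s / 2.0
    if degree == 1:
        return EQUILATERAL_LOOP_PERSISTENCE * s
    raise ValueError(f"degree must be 0 or 1, got {degree}")


def betti_curve(
    diagram: PersistenceDiagram, grid: np.ndarray, normalise: bool = True
) -> np.ndarray:
    """Proportion of the diagram's features alive at each grid scale.

    A feature (b, d) is alive at t when b <= t < d; essential features are
    alive forever.  The normaliser is the total feature count, so values
    lie in [0, 1]; the area under the unnormalised curve equals the summed
    persistence (the mean persistence, after normalising).
    """
    grid = np.asarray(grid, dtype=float)
    if np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing")
    total = len(diagram)
    if total == 0:
        logger.warning("empty diagram: zero Betti curve")
        return np.zeros_like(grid)
    births = diagram.births
    deaths = diagram.deaths
    alive = (births[None, :] <= grid[:, None]) & (grid[:, None] < deaths[None, :])
    counts = alive.sum(axis=1).astype(float)
    return counts / total if normalise else counts


def percentile_stats(diagram: PersistenceDiagram, of: str) -> np.ndarray:
    """(P10, P25, P50, P75, P90) of the birth, death or persistence values.

    Linear interpolation between order statistics.  Essential features are
    excluded from death/persistence and included in birth.  Returns an
    all-NaN vector (the missing-descriptor marker) when nothing remains.
    """
    if of == "birth":
        values = diagram.births
    elif of == "death":
        values = np.array([f.death for f in diagram.finite()])
    elif of == "persistence":
        values = np.array([f.persistence for f in diagram.finite()])
    else:
        raise ValueError(f"of must be birth|death|persistence, got {of!r}")
    if len(values) == 0:
        logger.warning("no %s values to summarise; descriptor marked missing", of)
        return np.full(len(PERCENTILES), np.nan)
    return np.percentile(values, PERCENTILES, method="linear")


def persistence_image(
    diagram: PersistenceDiagram,
    weighting: WeightingSpec,
    params: ImageParams,
) -> np.ndarray:
    """Weighted Gaussian rasterisation of the diagram in (birth, persistence)
    coordinates.

    Entry (r, c) sums, over finite features, the weight at (b, p) times the
    exact Gaussian mass of pixel (r, c) — the product of 1-D normal CDF
    differences.  Rows index persistence (bottom row = lowest persistence),
    columns index birth.  Essential features carry no finite coordinate
    and are excluded; zero-persistence features carry zero weight.
    """
    rows, cols = params.resolution
    out = np.zeros((rows, cols), dtype=float)
    finite = diagram.finite()
    if not finite:
        return out
    b = np.array([f.birth for f in finite])
    p = np.array([f.persistence for f in finite])
    w = weighting(b, p)
    keep = w > 0
    if not keep.any():
        return out
    b, p, w = b[keep], p[keep], w[keep]

    b_edges = np.linspace(*params.birth_range, cols + 1)
    p_edges = np.linspace(*params.pers_range, rows + 1)
    sd = params.gaussian_sd
    # CDF at every edge for every feature: (n_feat, edges)
    cdf_b = norm.cdf((b_edges[None, :] - b[:, None]) / sd)
    cdf_p = norm.cdf((p_edges[None, :] - p[:, None]) / sd)
    mass_b = np.diff(cdf_b, axis=1)  # (n_feat, cols)
    mass_p = np.diff(cdf_p, axis=1)  # (n_feat, rows)
    out = np.einsum("f,fr,fc->rc", w, mass_p, mass_b)
    return out


# ---------------------------------------------------------------------------
# descriptor registry and cohort matrices


@dataclass(frozen=True)
class DescriptorSpec:
    """One named vectorisation applied to one (degree, filtration) slot."""

    name: str
    degree: int
    vectorisation: str  # betti_curve | pct_birth | pct_death | pct_persistence
    #                   | image_flat | image_w1 | image_w2 | image_w3 | image_w4


def default_registry(degrees: tuple[int, ...] = (0, 1)) -> list[DescriptorSpec]:
    """The descriptor registry: nine vectorisations in degree 1; Betti
    curve, persistence percentiles and flat/w1/w2 images in degree 0."""
    specs: list[DescriptorSpec] = []
    for degree in degrees:
        if degree == 1:
            vecs = [
                "betti_curve", "pct_birth", "pct_death", "pct_persistence",
                "image_flat", "image_w1", "image_w2", "image_w3", "image_w4",
            ]
        elif degree == 0:
            vecs = ["betti_curve", "pct_persistence",
                    "image_flat", "image_w1", "image_w2"]
        else:
            raise ValueError(f"degree must be 0 or 1, got {degree}")
        specs.extend(
            DescriptorSpec(f"deg{degree}_{v}", degree, v) for v in vecs
        )
    return specs


def _image_params_for(
    diagrams: list[PersistenceDiagram],
    sd: float,
    resolution: tuple[int, int],
) -> ImageParams:
    """Shared image ranges across a cohort: [0, max + 3 sd] on both axes."""
    max_b = 0.0
    max_p = 0.0
    for dgm in diagrams:
        for f in dgm.finite():
            max_b = max(max_b, f.birth)
            max_p = max(max_p, f.persistence)
    return ImageParams(
        resolution=resolution,
        gaussian_sd=sd,
        birth_range=(0.0, max_b + 3 * sd),
        pers_range=(0.0, max_p + 3 * sd),
    )


def betti_grid(diagrams: list[PersistenceDiagram], n: int = 200) -> np.ndarray:
    """Shared Betti grid: ``n`` evenly spaced scales from 0 to the cohort
    maximum finite death, inclusive."""
    max_d = 0.0
    for dgm in diagrams:
        for f in dgm.finite():
            max_d = max(max_d, f.death)
    if max_d <= 0:
        max_d = 1.0
    return np.linspace(0.0, max_d, n)


def build_descriptor_matrix(
    cohort: dict[str, dict[int, PersistenceDiagram]],
    s: float,
    registry: list[DescriptorSpec] | None = None,
    resolution: tuple[int, int] = (20, 20),
    betti_grid_size: int = 200,
    gaussian_sd: dict[int, float] | None = None,
    drop_threshold: float = 0.5,
) -> dict[str, pd.DataFrame]:
    """Per-descriptor matrices (samples × vector entries) for one
    (population, filtration) slice of a cohort.

    ``cohort`` maps sample id → {degree: diagram}.  Grids and image ranges
    are shared across samples so rows are comparable; the Gaussian sd
    defaults to p0 for the degree.  A sample with nothing to summarise for
    a descriptor gets a NaN row; a descriptor missing for more than
    ``drop_threshold`` of the samples is dropped with a warning.
    """
    registry = registry if registry is not None else default_registry()
    samples = list(cohort)
    out: dict[str, pd.DataFrame] = {}
    for degree in sorted({spec.degree for spec in registry}):
        diagrams = [cohort[sid][degree] for sid in samples if degree in cohort[sid]]
        if not diagrams:
            continue
        p0 = p0_for_degree(s, degree)
        sd = (gaussian_sd or {}).get(degree, p0)
        grid = betti_grid(diagrams, betti_grid_size)
        params = _image_params_for(diagrams, sd, resolution)
        for spec in [r for r in registry if r.degree == degree]:
            rows = []
            for sid in samples:
                dgm = cohort[sid].get(degree)
                if dgm is None:
                    rows.append(None)
                    continue
                v = spec.vectorisation
                if v == "betti_curve":
                    vec = betti_curve(dgm, grid)
                elif v.startswith("pct_"):
                    vec = percentile_stats(dgm, v[4:])
                elif v.startswith("image_"):
                    wname = v[6:]
                    w = WeightingSpec(wname, p0=p0 if wname == "flat" else None)
                    vec = persistence_image(dgm, w, params).ravel()
                else:
                    raise ValueError(f"unknown vectorisation {v!r}")
                rows.append(vec)
            length = next(len(r) for r in rows if r is not None)
            mat = np.full((len(samples), length), np.nan)
            for i, r in enumerate(rows):
                if r is not None:
                    mat[i] = r
            df = pd.DataFrame(mat, index=samples)
            missing = df.isna().all(axis=1).sum()
            if missing > drop_threshold * len(samples):
                logger.warning(
                    "descriptor %s missing for %d/%d samples; dropped",
                    spec.name, missing, len(samples),
                )
                continue
            out[spec.name] = df
    return out
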