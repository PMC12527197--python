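"""Filtered simplicial complexes from planar point clouds.

Two constructions are provided.  The **alpha filtration** is supported on
the Delaunay triangulation: a simplex enters when the balls of radius ε
around its vertices, intersected with their Voronoi cells, meet.  Its
filtration values are reported on the **radius** scale (ε = ball radius),
so a Delaunay triangle enters at its circumradius and a Gabriel edge at
half its length; every downstream threshold (birth percentiles, the
typical-scale parameter s, the flat-weight plateau p0) lives on this same
distance scale.

The **witness filtration** is built on a random landmark subset: a simplex
σ on landmark vertices enters at the smallest ε at which some data point w
ε-witnesses it — there is a ball centred at w containing the vertices of σ
whose other enclosed landmarks all lie within ε of the ball's boundary.
For a witness w the smallest useful ball has radius m(w) = max distance
from w to a vertex of σ, so σ's raw entry value is

    min over data points w of  max(0, m(w) − min distance from w to a
                                      landmark outside σ),

after which upward closure (a simplex enters no earlier than its faces)
restores the filtration property, which witness complexes do not satisfy
by themselves.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import Delaunay, QhullError, cKDTree

from .data_io import PointCloud

__all__ = [
    "Simplex",
    "FilteredComplex",
    "LandmarkSet",
    "alpha_filtration",
    "choose_landmarks",
    "witness_filtration",
    "circumradius",
    "write_complex_tsv",
    "read_complex_tsv",
]

Simplex = tuple[int, ...]  # sorted vertex indices; dimension = len - 1


def simplex_dim(s: Simplex) -> int:
    return len(s) - 1


@dataclass(frozen=True)
class LandmarkSet:
    """A random subset of point indices acting as witness-complex vertices."""

    indices: tuple[int, ...]
    proportion: float
    seed: int

    def __post_init__(self) -> None:
        if len(self.indices) < 1:
            raise ValueError("a landmark set needs at least one index")
        if len(set(self.indices)) != len(self.indices):
            raise ValueError("landmark indices must be distinct")


@dataclass
class FilteredComplex:
    """Simplices with filtration values, the bridge from geometry to algebra.

    ``simplices`` maps each simplex (sorted vertex tuple) to its entry
    value ε ≥ 0.  ``kind`` is ``"alpha"`` or ``"witness"``.  For witness
    complexes ``landmark_map`` translates landmark vertex index → index in
    the original cloud.
    """

    simplices: dict[Simplex, float]
    kind: str
    landmark_map: dict[int, int] | None = None
    n_points: int = 0

    def items(self):
        return self.simplices.items()

    def __len__(self) -> int:
        return len(self.simplices)

    def check_filtration_property(self, atol: float = 1e-9) -> None:
        """Raise if some face enters later than its coface."""
        for simplex, value in self.simplices.items():
            if len(simplex) == 1:
                continue
            for face in itertools.combinations(simplex, len(simplex) - 1):
                if face not in self.simplices:
                    raise ValueError(f"face {face} of {simplex} missing")
                if self.simplices[face] > value + atol:
                    raise ValueError(
                        f"face {face} (ε={self.simplices[face]}) enters after "
                        f"coface {simplex} (ε={value})"
                    )

    def subcomplex(self, epsilon: float) -> list[Simplex]:
        """All simplices present at scale ``epsilon``."""
        return [s for s, v in self.simplices.items() if v <= epsilon]


def circumradius(p: np.ndarray, q: np.ndarray, r: np.ndarray) -> float:
    """Circumradius of a planar triangle: R = abc / 4K.

    Degenerate (collinear) triangles return +inf.
    """
    a = float(np.hypot(*(q - r)))
    b = float(np.hypot(*(p - r)))
    c = float(np.hypot(*(p - q)))
    cross = (q[0] - p[0]) * (r[1] - p[1]) - (q[1] - p[1]) * (r[0] - p[0])
    area2 = abs(cross)  # 2K
    if area2 == 0.0:
        return float("inf")
    return a * b * c / (2.0 * area2)


def _circumcentre(p: np.ndarray, q: np.ndarray, r: np.ndarray) -> np.ndarray:
    ax, ay = p
    bx, by = q
    cx, cy = r
    d = 2.0 * (ax * (by - cy) + bx * (cy - ay) + cx * (ay - by))
    ux = ((ax**2 + ay**2) * (by - cy) + (bx**2 + by**2) * (cy - ay)
          + (cx**2 + cy**2) * (ay - by)) / d
    uy = ((ax**2 + ay**2) * (cx - bx) + (bx**2 + by**2) * (ax - cx)
          + (cx**2 + cy**2) * (bx - ax)) / d
    return np.array([ux, uy])


def _collinear_skeleton(points: np.ndarray) -> FilteredComplex:
    """Degenerate fallback: vertices plus edges between consecutive points
    along the principal axis, each at half the inter-point distance."""
    n = len(points)
    simplices: dict[Simplex, float] = {(i,): 0.0 for i in range(n)}
    if n > 1:
        centred = points - points.mean(axis=0)
        # principal direction of the (possibly 1-D) scatter
        _, _, vt = np.linalg.svd(centred, full_matrices=False)
        t = centred @ vt[0]
        order = np.argsort(t, kind="stable")
        for a, b in zip(order[:-1], order[1:]):
            d = float(np.hypot(*(points[a] - points[b])))
            edge = tuple(sorted((int(a), int(b))))
            simplices[edge] = d / 2.0
    return FilteredComplex(simplices=simplices, kind="alpha", n_points=n)


def alpha_filtration(cloud: PointCloud) -> FilteredComplex:
    """Alpha filtration of a planar cloud, on the ball-radius scale.

    Vertices enter at ε = 0.  A Delaunay triangle enters at its
    circumradius.  An edge enters at half its length if it is Gabriel
    (its diametral disc is empty), otherwise at the smaller circumradius
    of its incident Delaunay triangles — the distance from an endpoint to
    the nearest point of the edge's Voronoi-dual segment.

    Fewer than three non-collinear points degenerate to the 1-skeleton
    (vertices, plus consecutive edges at half the inter-point distance)
    with a warning.
    """
    points = cloud.points
    n = len(points)
    if n == 1:
        return FilteredComplex(simplices={(0,): 0.0}, kind="alpha", n_points=1)
    try:
        if n < 3:
            raise QhullError("fewer than 3 points")
        tri = Delaunay(points)
    except QhullError:
        warnings.warn(
            f"cloud ({cloud.sample_id}, {cloud.population}): degenerate geometry; "
            "returning the 1-skeleton filtration",
            stacklevel=2,
        )
        return _collinear_skeleton(points)

    simplices: dict[Simplex, float] = {(i,): 0.0 for i in range(n)}

    tri_value: dict[Simplex, float] = {}
    # opposite vertices of each edge across its incident triangles
    edge_opposites: dict[Simplex, list[int]] = {}
    edge_triangles: dict[Simplex, list[Simplex]] = {}
    for simplex in tri.simplices:
        t: Simplex = tuple(sorted(int(v) for v in simplex))
        tri_value[t] = circumradius(points[t[0]], points[t[1]], points[t[2]])
        for k in range(3):
            edge = tuple(v for j, v in enumerate(t) if j != k)
            edge_opposites.setdefault(edge, []).append(t[k])
            edge_triangles.setdefault(edge, []).append(t)

    for edge, opposites in edge_opposites.items():
        a, b = points[edge[0]], points[edge[1]]
        mid = (a + b) / 2.0
        half = float(np.hypot(*(a - b))) / 2.0
        gabriel = all(
            float(np.hypot(*(points[v] - mid))) >= half for v in opposites
        )
        if gabriel:
            simplices[edge] = half
        else:
            simplices[edge] = min(tri_value[t] for t in edge_triangles[edge])

    simplices.update(tri_value)
    fc = FilteredComplex(simplices=simplices, kind="alpha", n_points=n)
    return fc


def choose_landmarks(cloud: PointCloud, proportion: float, seed: int) -> LandmarkSet:
    """Choose ⌈proportion·n⌉ landmark indices uniformly without replacement."""
    if not 0 < proportion <= 1:
        raise ValueError(f"proportion must be in (0, 1], got {proportion}")
    n = len(cloud)
    k = int(np.ceil(proportion * n))
    rng = np.random.default_rng(seed)
    idx = rng.choice(n, size=k, replace=False)
    return LandmarkSet(indices=tuple(sorted(int(i) for i in idx)),
                       proportion=proportion, seed=seed)


def witness_entry_value(
    points: np.ndarray,
    landmark_points: np.ndarray,
    simplex_local: Simplex,
) -> float:
    """Raw witness entry value of one simplex (landmark-local indices),
    minimised over all data points; no upward closure."""
    verts = landmark_points[list(simplex_local)]
    # m(w): smallest ball radius at w enclosing the simplex vertices
    m = np.sqrt(((points[:, None, :] - verts[None, :, :]) ** 2).sum(-1)).max(axis=1)
    others = np.delete(np.arange(len(landmark_points)), list(simplex_local))
    if len(others) == 0:
        return 0.0
    d_other = np.sqrt(
        ((points[:, None, :] - landmark_points[None, others, :]) ** 2).sum(-1)
    ).min(axis=1)
    return float(np.maximum(0.0, m - d_other).min())


def witness_filtration(
    cloud: PointCloud,
    landmarks: LandmarkSet,
    max_dimension: int = 2,
) -> FilteredComplex:
    """Relaxed witness filtration on a landmark subset (reference semantics).

    All landmark vertices enter at ε = 0; edges and triangles enter at the
    smallest relaxation at which some data point witnesses them, pushed up
    to their faces' entry values where needed.  Complexity is
    O(L^(d+1) · n) over landmark tuples and witnesses — intended for the
    moderate landmark counts (tens to low hundreds) the method uses.
    """
    if max_dimension > 2:
        raise ValueError("planar pipeline: max_dimension must be <= 2")
    points = cloud.points
    lm = list(landmarks.indices)
    if max(lm) >= len(points):
        raise ValueError("landmark indices outside the cloud")
    L = points[lm]
    nl = len(lm)

    simplices: dict[Simplex, float] = {(i,): 0.0 for i in range(nl)}
    if max_dimension >= 1 and nl >= 2:
        for e in itertools.combinations(range(nl), 2):
            simplices[e] = witness_entry_value(points, L, e)
    if max_dimension >= 2 and nl >= 3:
        for t in itertools.combinations(range(nl), 3):
            raw = witness_entry_value(points, L, t)
            faces = [tuple(v for j, v in enumerate(t) if j != k) for k in range(3)]
            simplices[t] = max(raw, max(simplices[f] for f in faces))

    return FilteredComplex(
        simplices=simplices,
        kind="witness",
        landmark_map={i: orig for i, orig in enumerate(lm)},
        n_points=len(points),
    )


def write_complex_tsv(fc: FilteredComplex, path: str | Path) -> None:
    """One simplex per line: space-joined vertices, value, kind."""
    with open(path, "w") as fh:
        fh.write("vertices\tvalue\tkind\n")
        for simplex, value in sorted(
            fc.simplices.items(), key=lambda kv: (kv[1], len(kv[0]), kv[0])
        ):
            fh.write(f"{' '.join(map(str, simplex))}\t{value:.12g}\t{fc.kind}\n")


def read_complex_tsv(path: str | Path) -> FilteredComplex:
    simplices: dict[Simplex, float] = {}
    kind = "alpha"
    with open(path) as fh:
        next(fh)
        for line in fh:
            verts, value, kind = line.rstrip("\n").split("\t")
            simplices[tuple(int(v) for v in verts.split())] = float(value)
    n = 1 + max(v for s in simplices for v in s)
    return FilteredComplex(simplices=simplices, kind=kind, n_points=n)
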