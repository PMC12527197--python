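"""Persistent homology by boundary-matrix reduction over GF(2).

The filtration is totally ordered (value, then dimension, then
lexicographic vertex tuple — a deterministic tie-break, since witness and
alpha complexes of generic points admit only one simplex per value but
degenerate inputs do not).  The standard column reduction pairs each
destroyer simplex with the youngest unpaired creator on its reduced
boundary; unpaired creators become features with infinite death.  The
destroyer ("death simplex") is retained on every finite feature: for a
loop it is the last triangle that fills the enclosed void, and it is what
the persistence-weighted death-simplex visualisation draws.

Zero-persistence pairs are kept in the diagrams: they carry no image or
visualisation weight, but they count toward the feature total used to
normalise Betti curves.

A brute-force Betti oracle (explicit GF(2) boundary ranks on the
subcomplex at a fixed scale) is provided for cross-checking the reduction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .filtration import FilteredComplex, Simplex

__all__ = [
    "PersistenceFeature",
    "PersistenceDiagram",
    "sort_filtration",
    "reduce_filtration",
    "compute_persistence",
    "betti_oracle",
    "diagrams_to_csv",
    "diagrams_from_csv",
]


@dataclass(frozen=True)
class PersistenceFeature:
    """One (birth, death) feature with its creator and destroyer simplices."""

    degree: int
    birth: float
    death: float  # math.inf for essential features
    birth_simplex: Simplex
    death_simplex: Simplex | None = None

    def __post_init__(self) -> None:
        if self.death < self.birth:
            raise ValueError(f"death {self.death} < birth {self.birth}")
        if (self.death_simplex is None) != math.isinf(self.death):
            raise ValueError("death_simplex must be present iff death is finite")

    @property
    def persistence(self) -> float:
        return self.death - self.birth

    @property
    def is_finite(self) -> bool:
        return math.isfinite(self.death)


@dataclass
class PersistenceDiagram:
    """Multiset of features of one homology degree from one filtration."""

    degree: int
    features: list[PersistenceFeature]
    source: tuple[str, str, str] = ("", "", "")  # (sample_id, population, kind)

    def __len__(self) -> int:
        return len(self.features)

    @property
    def births(self) -> np.ndarray:
        return np.array([f.birth for f in self.features], dtype=float)

    @property
    def deaths(self) -> np.ndarray:
        return np.array([f.death for f in self.features], dtype=float)

    def finite(self) -> list[PersistenceFeature]:
        return [f for f in self.features if f.is_finite]

    def n_alive(self, t: float) -> int:
        """Features alive at scale t: born at or before t, not yet dead."""
        return sum(1 for f in self.features if f.birth <= t < f.death)


def sort_filtration(fc: FilteredComplex) -> list[tuple[Simplex, float]]:
    """Total order by (value, dimension, lexicographic vertices).

    The order is a linear extension of the face poset whenever the
    filtration property holds, which is validated first.
    """
    fc.check_filtration_property()
    return sorted(fc.simplices.items(), key=lambda kv: (kv[1], len(kv[0]), kv[0]))


def reduce_filtration(
    ordered: list[tuple[Simplex, float]],
    source: tuple[str, str, str] = ("", "", ""),
) -> dict[int, PersistenceDiagram]:
    """Standard persistence pairing on a sorted filtration.

    Returns one diagram per degree in {0, 1} (degree 2 cannot occur for
    planar complexes of dimension <= 2 as there are no 3-simplices to pair
    2-cycles with, and planar alpha complexes have no 2-cycles).
    """
    index_of = {s: i for i, (s, _) in enumerate(ordered)}
    values = [v for _, v in ordered]

    # columns[j]: reduced boundary of simplex j as a set of row indices
    low_inv: dict[int, int] = {}  # pivot row -> column
    paired: set[int] = set()
    pairs: list[tuple[int, int]] = []  # (creator, destroyer)

    for j, (simplex, _) in enumerate(ordered):
        if len(simplex) == 1:
            continue
        col = set()
        for k in range(len(simplex)):
            face = simplex[:k] + simplex[k + 1:]
            col.add(index_of[face])
        while col:
            pivot = max(col)
            other = low_inv.get(pivot)
            if other is None:
                break
            col ^= other
        if col:
            pivot = max(col)
            low_inv[pivot] = col
            pairs.append((pivot, j))
            paired.add(pivot)
            paired.add(j)
        # else: j is a creator (its cycle may die later or never)

    # mark destroyers: columns that ended with non-empty reduced boundary
    destroyer_of = {creator: destroyer for creator, destroyer in pairs}
    destroyers = set(destroyer_of.values())

    diagrams: dict[int, list[PersistenceFeature]] = {0: [], 1: []}
    for i, (simplex, value) in enumerate(ordered):
        if i in destroyers:
            continue
        degree = len(simplex) - 1
        if degree > 1:
            continue  # a 2-simplex creator would start a 2-cycle: impossible here
        if i in destroyer_of:
            j = destroyer_of[i]
            feat = PersistenceFeature(
                degree=degree,
                birth=value,
                death=values[j],
                birth_simplex=simplex,
                death_simplex=ordered[j][0],
            )
        else:
            feat = PersistenceFeature(
                degree=degree, birth=value, death=math.inf, birth_simplex=simplex
            )
        diagrams[degree].append(feat)

    return {
        d: PersistenceDiagram(degree=d, features=feats, source=source)
        for d, feats in diagrams.items()
    }


def compute_persistence(
    fc: FilteredComplex,
    source: tuple[str, str, str] | None = None,
) -> dict[int, PersistenceDiagram]:
    """Sort a filtered complex and run the reduction; diagrams per degree."""
    if source is None:
        source = ("", "", fc.kind)
    return reduce_filtration(sort_filtration(fc), source=source)


def _gf2_rank(mat: np.ndarray) -> int:
    """Rank of a 0/1 matrix over GF(2) by Gaussian elimination."""
    m = mat.copy() % 2
    rank = 0
    rows, cols = m.shape
    for c in range(cols):
        pivot = None
        for r in range(rank, rows):
            if m[r, c]:
                pivot = r
                break
        if pivot is None:
            continue
        m[[rank, pivot]] = m[[pivot, rank]]
        for r in range(rows):
            if r != rank and m[r, c]:
                m[r] ^= m[rank]
        rank += 1
    return rank


def betti_oracle(fc: FilteredComplex, epsilon: float) -> tuple[int, int]:
    """(β0, β1) of the subcomplex at scale ε by explicit boundary ranks.

    βn = (#n-simplices − rank ∂n) − rank ∂n+1.  Exponential-free but dense:
    intended for small complexes as an independent check of the reduction.
    """
    present = [s for s, v in fc.simplices.items() if v <= epsilon]
    verts = sorted(s for s in present if len(s) == 1)
    edges = sorted(s for s in present if len(s) == 2)
    tris = sorted(s for s in present if len(s) == 3)
    vi = {v: i for i, v in enumerate(verts)}
    ei = {e: i for i, e in enumerate(edges)}

    d1 = np.zeros((len(verts), len(edges)), dtype=np.uint8)
    for j, (a, b) in enumerate(edges):
        d1[vi[(a,)], j] = 1
        d1[vi[(b,)], j] = 1
    d2 = np.zeros((len(edges), len(tris)), dtype=np.uint8)
    for j, t in enumerate(tris):
        for k in range(3):
            face = t[:k] + t[k + 1:]
            d2[ei[face], j] = 1

    r1 = _gf2_rank(d1) if d1.size else 0
    r2 = _gf2_rank(d2) if d2.size else 0
    beta0 = len(verts) - r1
    beta1 = (len(edges) - r1) - r2
    return beta0, beta1


def diagrams_to_csv(
    diagrams: dict[int, PersistenceDiagram] | list[PersistenceDiagram],
    path: str | Path,
) -> None:
    """Serialise diagrams: degree, birth, death ("inf" literal for essential
    features), death-simplex vertex indices (space-joined, empty if none)."""
    if isinstance(diagrams, dict):
        diagrams = [diagrams[k] for k in sorted(diagrams)]
    rows = []
    for dgm in diagrams:
        for f in dgm.features:
            rows.append(
                {
                    "degree": f.degree,
                    "birth": f.birth,
                    "death": "inf" if math.isinf(f.death) else f.death,
                    "death_simplex": ""
                    if f.death_simplex is None
                    else " ".join(map(str, f.death_simplex)),
                }
            )
    pd.DataFrame(rows, columns=["degree", "birth", "death", "death_simplex"]).to_csv(
        path, index=False
    )


def diagrams_from_csv(path: str | Path) -> dict[int, PersistenceDiagram]:
    df = pd.read_csv(path, keep_default_na=False)
    out: dict[int, list[PersistenceFeature]] = {0: [], 1: []}
    for _, row in df.iterrows():
        death = math.inf if str(row["death"]) == "inf" else float(row["death"])
        ds = (
            tuple(int(v) for v in str(row["death_simplex"]).split())
            if str(row["death_simplex"]).strip()
            else None
        )
        out[int(row["degree"])].append(
            PersistenceFeature(
                degree=int(row["degree"]),
                birth=float(row["birth"]),
                death=death,
                birth_simplex=(),
                death_simplex=ds,
            )
        )
    return {d: PersistenceDiagram(degree=d, features=f) for d, f in out.items()}
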