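"""Descriptor screening by k-means.

Each topological descriptor is clustered separately with k-means (best of
many restarts) and compared with the biological partition of the cohort:
a 2-clustering is *correct* if it exactly separates healthy from diseased
samples up to relabelling, a k-clustering if it matches the k-level stage
partition.  Correct clusterings are ranked by silhouette score; incorrect
ones additionally report the (unadjusted) Rand index — the fraction of
sample pairs on which the two partitions agree.  Descriptors are
clustered raw by default (each descriptor lives on its own scale and is
clustered alone, so per-feature standardisation is a choice, not a
requirement); pass ``standardise=True`` to z-score columns first.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import adjusted_rand_score, rand_score, silhouette_score

logger = logging.getLogger(__name__)

__all__ = [
    "ClusteringResult",
    "kmeans_cluster",
    "silhouette",
    "rand_index",
    "partitions_match",
    "evaluate_cohort",
    "pca_project",
]


@dataclass(frozen=True)
class ClusteringResult:
    descriptor: str
    k: int
    labels: tuple[int, ...]
    silhouette: float
    rand: float
    adjusted_rand: float
    correct: bool
    degenerate: bool = False


def kmeans_cluster(
    matrix: np.ndarray,
    k: int,
    n_restarts: int = 50,
    seed: int = 0,
) -> np.ndarray:
    """Best-of-restarts k-means labels (k-means++ seeding), deterministic
    given the seed."""
    matrix = np.asarray(matrix, dtype=float)
    if k < 2:
        raise ValueError("k must be at least 2")
    if k > len(matrix):
        raise ValueError(f"k={k} exceeds the {len(matrix)} samples")
    if np.isnan(matrix).any():
        raise ValueError("matrix contains missing rows; exclude them upstream")
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    return km.fit_predict(matrix)


def silhouette(matrix: np.ndarray, labels: np.ndarray) -> float:
    """Mean sample silhouette with Euclidean distance; NaN when fewer than
    two clusters are populated (undefined)."""
    labels = np.asarray(labels)
    n_labels = len(np.unique(labels))
    if n_labels < 2 or n_labels >= len(labels):
        logger.warning(
            "silhouette undefined for %d clusters on %d samples",
            n_labels, len(labels),
        )
        return float("nan")
    return float(silhouette_score(np.asarray(matrix, dtype=float), labels))


def rand_index(labels_a, labels_b) -> float:
    """Unadjusted Rand index: agreeing pairs / all pairs."""
    labels_a = np.asarray(labels_a)
    labels_b = np.asarray(labels_b)
    if labels_a.shape != labels_b.shape:
        raise ValueError("label vectors must have equal length")
    if len(labels_a) < 2:
        raise ValueError("need at least two samples")
    return float(rand_score(labels_a, labels_b))


def partitions_match(labels_a, labels_b) -> bool:
    """True when the two labelings induce the same partition (match up to
    a bijective relabelling)."""
    a = pd.factorize(np.asarray(labels_a))[0]
    b = pd.factorize(np.asarray(labels_b))[0]
    forward: dict[int, int] = {}
    backward: dict[int, int] = {}
    for x, y in zip(a, b):
        if forward.setdefault(x, y) != y or backward.setdefault(y, x) != x:
            return False
    return True


def evaluate_cohort(
    matrices: dict[str, pd.DataFrame],
    reference: dict[int, dict[str, str]],
    n_restarts: int = 50,
    seed: int = 0,
    standardise: bool = False,
) -> pd.DataFrame:
    """Screen every descriptor at every reference granularity.

    ``matrices`` maps descriptor name → (samples × features) frame;
    ``reference`` maps k → {sample id: partition label} (e.g. the 2-level
    healthy-vs-rest split and the 4-level stage split).  Samples with a
    missing (all-NaN) row for a descriptor are excluded from that
    descriptor's clustering with a warning.  Output rows are sorted by
    (correct desc, silhouette desc).
    """
    rows = []
    for name, df in matrices.items():
        valid = ~df.isna().any(axis=1)
        if (~valid).any():
            logger.warning(
                "descriptor %s: %d samples missing; excluded", name, (~valid).sum()
            )
        sub = df.loc[valid]
        for k, ref_map in sorted(reference.items()):
            if k < 2 or k > len(sub):
                continue
            ref = np.asarray([ref_map[s] for s in sub.index])
            mat = sub.to_numpy(dtype=float)
            if standardise:
                sdev = mat.std(axis=0)
                sdev[sdev == 0] = 1.0
                mat = (mat - mat.mean(axis=0)) / sdev
            degenerate = bool(np.allclose(mat, mat[0])) or len(sub) <= k
            labels = kmeans_cluster(mat, k, n_restarts=n_restarts, seed=seed)
            correct = partitions_match(labels, ref) and len(np.unique(labels)) == k
            rows.append(
                ClusteringResult(
                    descriptor=name,
                    k=k,
                    labels=tuple(int(x) for x in labels),
                    silhouette=silhouette(mat, labels),
                    rand=rand_index(labels, pd.factorize(ref)[0]),
                    adjusted_rand=float(
                        adjusted_rand_score(pd.factorize(ref)[0], labels)
                    ),
                    correct=correct,
                    degenerate=degenerate,
                )
            )
    out = pd.DataFrame(
        [
            {
                "descriptor": r.descriptor,
                "k": r.k,
                "correct": r.correct,
                "silhouette": r.silhouette,
                "rand": r.rand,
                "adjusted_rand": r.adjusted_rand,
                "degenerate": r.degenerate,
                "labels": " ".join(map(str, r.labels)),
            }
            for r in rows
        ]
    )
    if len(out):
        out = out.sort_values(
            ["correct", "silhouette"], ascending=[False, False], kind="stable"
        ).reset_index(drop=True)
    return out


def pca_project(matrix: np.ndarray, n_components: int = 2):
    """Centred PCA scores plus loadings and the explained-variance ratio.

    Returns ``(scores, components, explained_variance_ratio)``; the
    loadings let a clustering be attributed to specific vector entries
    (e.g. a principal component dominated by the 90th percentile).
    """
    matrix = np.asarray(matrix, dtype=float)
    if len(matrix) < 2:
        raise ValueError("PCA needs at least 2 samples")
    n_components = min(n_components, len(matrix) - 1, matrix.shape[1])
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(matrix)
    return scores, pca.components_, pca.explained_variance_ratio_
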