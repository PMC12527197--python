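"""Persistence weighted death simplices (PWDS).

Each finite degree-1 feature of an alpha filtration dies when a specific
triangle fills its void; drawing that triangle over the source points
localises the feature in the tissue.  Features are coloured by where they
sit in the birth distribution — red for loops formed by proximal cells
(birth below the ``bprox`` threshold), blue for loops formed by distal
cells (birth above ``bdist``), a continuous red→blue gradient in between —
and shaded by persistence, darker for more prominent loops.

The thresholds are the cohort averages of the per-sample 90th and 98th
birth percentiles, bprox = ⟨P90⟩ and bdist = ⟨P98⟩: most loops in cell
data are small voids between neighbouring cells, so the bulk of the birth
distribution is "proximal" and only the upper tail is "distal"; the 98th-
percentile cap keeps a few extreme births from flattening the gradient.

The death simplex is unique only when a single simplex enters the
filtration per value (generic positions); under ties the deterministic
simplex ordering decides, and which triangle of several near-equal
circumradii is chosen is not stable under perturbation — its filtration
value (the death) is.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data_io import PointCloud
from .persistence import PersistenceDiagram, PersistenceFeature

logger = logging.getLogger(__name__)

__all__ = [
    "PWDSConfig",
    "PWDSScene",
    "compute_thresholds",
    "classify_feature",
    "intensity",
    "build_scene",
    "render",
    "scene_to_csv",
]

#: floor for the intensity channel so weak features stay visible
MIN_INTENSITY = 0.05


@dataclass(frozen=True)
class PWDSConfig:
    """Birth thresholds and intensity-normalisation policy."""

    bprox: float
    bdist: float
    intensity_norm: str = "per-diagram"  # or "per-dataset"

    def __post_init__(self) -> None:
        if not 0 <= self.bprox <= self.bdist:
            raise ValueError(
                f"need 0 <= bprox <= bdist, got ({self.bprox}, {self.bdist})"
            )
        if self.intensity_norm not in ("per-diagram", "per-dataset"):
            raise ValueError(f"unknown intensity_norm {self.intensity_norm!r}")


@dataclass
class PWDSScene:
    """Renderable death triangles over their source cloud.

    ``triangles`` has shape (k, 3, 2); ``hue`` in [0, 1] (0 = red,
    1 = blue) and ``intensity`` in (0, 1] align with it.  Triangles are
    sorted by increasing persistence so prominent features draw on top.
    """

    triangles: np.ndarray
    hue: np.ndarray
    intensity: np.ndarray
    persistence: np.ndarray
    cloud: PointCloud

    def __len__(self) -> int:
        return len(self.triangles)


def compute_thresholds(
    diagrams: list[PersistenceDiagram],
    q_prox: float = 90.0,
    q_dist: float = 98.0,
    include_zero_persistence: bool = False,
) -> PWDSConfig:
    """bprox/bdist: mean across diagrams of the per-diagram birth
    percentiles (linear interpolation).

    Zero-persistence pairs are excluded by default: they are artefacts of
    a simplex entering together with its destroyer (e.g. a sliver
    triangle at the boundary of the cloud entering at the same value as
    its creating edge), they are never rendered, and their births — which
    can exceed the cloud diameter — would otherwise dominate the upper
    percentiles that define the red/blue gradient.
    """
    p_prox, p_dist = [], []
    for dgm in diagrams:
        if include_zero_persistence:
            births = dgm.births
        else:
            births = np.array([f.birth for f in dgm.features if f.persistence > 0])
        if len(births) == 0:
            continue
        p_prox.append(np.percentile(births, q_prox, method="linear"))
        p_dist.append(np.percentile(births, q_dist, method="linear"))
    if not p_prox:
        raise ValueError("all diagrams empty: cannot compute PWDS thresholds")
    return PWDSConfig(bprox=float(np.mean(p_prox)), bdist=float(np.mean(p_dist)))


def classify_feature(b: float, config: PWDSConfig) -> float:
    """Hue of a feature with birth b: 0 below bprox (red), 1 above bdist
    (blue), linear in between; a degenerate bprox = bdist splits at the
    shared threshold."""
    if b < 0:
        raise ValueError("birth must be non-negative")
    if config.bprox == config.bdist:
        return 0.0 if b <= config.bprox else 1.0
    if b < config.bprox:
        return 0.0
    if b > config.bdist:
        return 1.0
    return (b - config.bprox) / (config.bdist - config.bprox)


def intensity(p: float, pmax: float) -> float:
    """Persistence-proportional shade p/pmax, floored at the minimum
    visible value."""
    if p <= 0:
        raise ValueError("intensity is defined for positive persistence")
    if pmax <= 0:
        raise ValueError("pmax must be positive")
    return max(MIN_INTENSITY, min(1.0, p / pmax))


def _scene_features(diagram: PersistenceDiagram) -> list[PersistenceFeature]:
    return [f for f in diagram.features if f.is_finite and f.persistence > 0]


def build_scene(
    diagram: PersistenceDiagram,
    cloud: PointCloud,
    config: PWDSConfig,
    pmax_dataset: float | None = None,
) -> PWDSScene:
    """Assemble the PWDS scene for one degree-1 diagram over its cloud.

    Every finite positive-persistence feature appears exactly once.  The
    intensity normaliser is the diagram's own maximum persistence, or
    ``pmax_dataset`` under per-dataset normalisation.
    """
    if diagram.degree != 1:
        raise ValueError("PWDS renders degree-1 features only")
    feats = _scene_features(diagram)
    if not feats:
        logger.warning("empty degree-1 diagram: background-only PWDS scene")
        return PWDSScene(
            triangles=np.zeros((0, 3, 2)),
            hue=np.zeros(0),
            intensity=np.zeros(0),
            persistence=np.zeros(0),
            cloud=cloud,
        )
    if config.intensity_norm == "per-dataset":
        if pmax_dataset is None or pmax_dataset <= 0:
            raise ValueError("per-dataset normalisation needs pmax_dataset > 0")
        pmax = pmax_dataset
    else:
        pmax = max(f.persistence for f in feats)
    feats.sort(key=lambda f: f.persistence)
    tris, hues, inten, pers = [], [], [], []
    for f in feats:
        if f.death_simplex is None or len(f.death_simplex) != 3:
            raise ValueError("degree-1 death simplex must be a triangle")
        tris.append(cloud.points[list(f.death_simplex)])
        hues.append(classify_feature(f.birth, config))
        inten.append(intensity(f.persistence, pmax))
        pers.append(f.persistence)
    return PWDSScene(
        triangles=np.array(tris),
        hue=np.array(hues),
        intensity=np.array(inten),
        persistence=np.array(pers),
        cloud=cloud,
    )


def render(scene: PWDSScene, path: str | Path, dpi: int = 150) -> None:
    """Draw the scene: points in light grey, death triangles filled with a
    red→blue hue and persistence-proportional alpha, prominent on top,
    equal-aspect axes.  PNG or SVG by file extension."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    from matplotlib.patches import Polygon

    fig, ax = plt.subplots(figsize=(6, 6))
    ax.scatter(
        scene.cloud.points[:, 0], scene.cloud.points[:, 1],
        s=8, c="0.75", linewidths=0, zorder=1,
    )
    if len(scene) == 0:
        warnings.warn("rendering a background-only PWDS scene", stacklevel=2)
    for tri, h, i in zip(scene.triangles, scene.hue, scene.intensity):
        colour = (1.0 - h, 0.0, h)  # red (h=0) to blue (h=1)
        ax.add_patch(Polygon(tri, closed=True, facecolor=colour, alpha=float(i),
                             edgecolor="none", zorder=2))
    ax.set_aspect("equal")
    ax.set_xlabel("x")
    ax.set_ylabel("y")
    ax.set_title(f"PWDS: {scene.cloud.sample_id} / {scene.cloud.population}")
    fig.savefig(path, dpi=dpi, bbox_inches="tight")
    plt.close(fig)


def scene_to_csv(scene: PWDSScene, path: str | Path) -> None:
    """Headless serialisation: triangle vertex coordinates, hue, intensity,
    persistence — one feature per row."""
    rows = []
    for tri, h, i, p in zip(scene.triangles, scene.hue, scene.intensity,
                            scene.persistence):
        rows.append(
            {
                "x0": tri[0, 0], "y0": tri[0, 1],
                "x1": tri[1, 0], "y1": tri[1, 1],
                "x2": tri[2, 0], "y2": tri[2, 1],
                "hue": h, "intensity": i, "persistence": p,
            }
        )
    pd.DataFrame(
        rows,
        columns=["x0", "y0", "x1", "y1", "x2", "y2", "hue", "intensity",
                 "persistence"],
    ).to_csv(path, index=False)
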