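"""Reading and writing cell-centroid tables.

The unit of analysis is a :class:`PointCloud`: the 2-D centroid coordinates
of the cells of one population (a single annotated cell type, or a broader
group of types such as "red pulp") in one tissue sample.  Centroid tables
are plain CSV with one row per cell; a column mapping connects arbitrary
headers to the roles (sample id, x, y, cell type, optional condition).

Coordinates are treated as planar Euclidean in the file's own units
(typically micrometres); no unit conversion is performed.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "PointCloud",
    "GroupDefinition",
    "ColumnMapping",
    "read_centroids",
    "write_centroids",
    "read_groups",
    "apply_groups",
]


class CentroidFormatError(ValueError):
    """Raised when a centroid table cannot be mapped to the expected columns."""


@dataclass(frozen=True)
class PointCloud:
    """A labelled set of 2-D cell-centroid coordinates.

    Parameters
    ----------
    points : ndarray of shape (n, 2)
        Centroid coordinates.  Row order is stable: the row index
        identifies a cell throughout the pipeline.
    sample_id : str
        Tissue-sample identifier.
    population : str
        Cell type or group name the cloud represents.
    condition : str, optional
        Biological condition label (e.g. ``"healthy"`` / ``"diseased"``).
    """

    points: np.ndarray
    sample_id: str
    population: str
    condition: str | None = None

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError(f"points must have shape (n, 2), got {pts.shape}")
        if len(pts) < 1:
            raise ValueError("a PointCloud needs at least one point")
        if not np.all(np.isfinite(pts)):
            raise ValueError("all coordinates must be finite")
        object.__setattr__(self, "points", pts)
        pts.setflags(write=False)
        # Exact duplicates make positions non-generic for the Delaunay-based
        # alpha construction; keep them but warn.
        if len(pts) > 1 and len(np.unique(pts, axis=0)) < len(pts):
            warnings.warn(
                f"duplicate coordinates in cloud ({self.sample_id}, {self.population}); "
                "positions are non-generic",
                stacklevel=2,
            )

    def __len__(self) -> int:
        return len(self.points)

    def with_population(self, population: str) -> "PointCloud":
        return replace(self, population=population)


@dataclass(frozen=True)
class GroupDefinition:
    """A named union of cell-type labels (e.g. red pulp = {erythroblasts, ...})."""

    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", frozenset(self.members))
        if not self.members:
            raise ValueError(f"group {self.name!r} has no members")


@dataclass(frozen=True)
class ColumnMapping:
    sample: str = "sample"
    x: str = "x"
    y: str = "y"
    cell_type: str = "cell_type"
    condition: str | None = "condition"


def read_centroids(
    path: str | Path,
    mapping: ColumnMapping | Mapping[str, str] | None = None,
) -> dict[tuple[str, str], PointCloud]:
    """Read a centroid CSV into per-(sample, cell type) point clouds.

    Returns a dict keyed by ``(sample_id, cell_type)``.  Row order within
    each cloud follows file order.  A missing mapped column raises
    :class:`CentroidFormatError`; a non-numeric or non-finite coordinate
    raises a row-level error naming the offending line.
    """
    if mapping is None:
        mapping = ColumnMapping()
    elif isinstance(mapping, Mapping):
        mapping = ColumnMapping(**mapping)

    # round_trip parsing + %.17g writing make write/read lossless
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"sample": mapping.sample, "x": mapping.x, "y": mapping.y,
                "cell_type": mapping.cell_type}
    for role, col in required.items():
        if col not in df.columns:
            raise CentroidFormatError(
                f"{path}: missing column {col!r} (mapped to {role})"
            )
    has_condition = mapping.condition is not None and mapping.condition in df.columns

    if df.empty:
        logger.warning("%s: no data rows (header only)", path)
        return {}

    for axis in (mapping.x, mapping.y):
        coerced = pd.to_numeric(df[axis], errors="coerce")
        bad = ~np.isfinite(coerced.to_numpy(dtype=float))
        if bad.any():
            # +2: header line plus 1-based numbering.
            line = int(np.nonzero(bad)[0][0]) + 2
            raise CentroidFormatError(
                f"{path}: non-numeric or non-finite {axis!r} at line {line}"
            )
        df[axis] = coerced

    clouds: dict[tuple[str, str], PointCloud] = {}
    for (sample, ctype), grp in df.groupby(
        [mapping.sample, mapping.cell_type], sort=False
    ):
        condition = None
        if has_condition:
            vals = grp[mapping.condition].dropna().unique()
            condition = str(vals[0]) if len(vals) else None
        clouds[(str(sample), str(ctype))] = PointCloud(
            points=grp[[mapping.x, mapping.y]].to_numpy(dtype=float),
            sample_id=str(sample),
            population=str(ctype),
            condition=condition,
        )
    return clouds


def write_centroids(
    clouds: Iterable[PointCloud],
    path: str | Path,
    mapping: ColumnMapping | None = None,
) -> None:
    """Write clouds to the centroid CSV format (inverse of :func:`read_centroids`)."""
    mapping = mapping or ColumnMapping()
    frames = []
    any_condition = False
    for cloud in clouds:
        frame = pd.DataFrame(
            {
                mapping.sample: cloud.sample_id,
                mapping.x: cloud.points[:, 0],
                mapping.y: cloud.points[:, 1],
                mapping.cell_type: cloud.population,
            }
        )
        if cloud.condition is not None:
            frame[mapping.condition or "condition"] = cloud.condition
            any_condition = True
        frames.append(frame)
    out = pd.concat(frames, ignore_index=True)
    if any_condition:
        col = mapping.condition or "condition"
        out[col] = out.get(col)
    # %.17g round-trips IEEE doubles exactly
    out.to_csv(path, index=False, float_format="%.17g")


def read_groups(path: str | Path) -> list[GroupDefinition]:
    """Read group definitions from JSON ({name: [members]}) or CSV (group_name, member)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        data = json.loads(path.read_text())
        return [GroupDefinition(name, frozenset(members)) for name, members in data.items()]
    df = pd.read_csv(path)
    if not {"group_name", "member"} <= set(df.columns):
        raise CentroidFormatError(
            f"{path}: group CSV needs columns 'group_name' and 'member'"
        )
    return [
        GroupDefinition(str(name), frozenset(str(m) for m in grp["member"]))
        for name, grp in df.groupby("group_name", sort=False)
    ]


def apply_groups(
    clouds: Mapping[tuple[str, str], PointCloud],
    groups: Iterable[GroupDefinition],
) -> dict[tuple[str, str], PointCloud]:
    """Add per-(sample, group) clouds formed by concatenating member clouds.

    The original per-type clouds are retained.  Grouping is applied
    independently per sample; a group with no matching cells in a sample is
    omitted for that sample with a warning.  Group membership may overlap
    across groups (a cell type can feed several groups).
    """
    groups = list(groups)
    result = dict(clouds)
    vocabulary = {ctype for (_, ctype) in clouds}
    samples: dict[str, list[tuple[str, PointCloud]]] = {}
    for (sample, ctype), cloud in clouds.items():
        samples.setdefault(sample, []).append((ctype, cloud))

    seen: dict[str, set[str]] = {}
    for g in groups:
        for other in groups:
            if other.name != g.name and g.members & other.members:
                overlap = g.members & other.members
                key = "|".join(sorted((g.name, other.name)))
                if key not in seen:
                    seen[key] = overlap
                    logger.warning(
                        "groups %r and %r share members %s", g.name, other.name,
                        sorted(overlap),
                    )
        absent = g.members - vocabulary
        if absent:
            logger.warning(
                "group %r members %s absent from the cell-type vocabulary",
                g.name, sorted(absent),
            )

    for sample, typed in samples.items():
        for g in groups:
            member_clouds = [c for ctype, c in typed if ctype in g.members]
            if not member_clouds:
                logger.warning("sample %r: group %r matches no cells; omitted",
                               sample, g.name)
                continue
            pts = np.vstack([c.points for c in member_clouds])
            condition = member_clouds[0].condition
            result[(sample, g.name)] = PointCloud(
                points=pts, sample_id=sample, population=g.name, condition=condition
            )
    return result
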