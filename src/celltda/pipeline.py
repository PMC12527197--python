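"""End-to-end composition: clouds → diagrams → PWDS → descriptors → screen.

`run_pipeline` is the library entry point behind the ``celltda run``
command.  For every (population, filtration) it computes persistence
diagrams per sample, PWDS thresholds and scenes (alpha, degree 1),
cohort-aligned descriptor matrices, and — when condition labels are
present — the k-means descriptor screen.  A manifest records every
derived parameter (seed, typical scale s, p0 per degree, bprox/bdist) so
a run is reproducible from its inputs alone.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cluster import evaluate_cohort
from .data_io import PointCloud
from .filtration import alpha_filtration, choose_landmarks, witness_filtration
from .persistence import PersistenceDiagram, compute_persistence, diagrams_to_csv
from .pwds import build_scene, compute_thresholds, render, scene_to_csv
from .vectorise import (
    build_descriptor_matrix,
    default_registry,
    estimate_scale_s,
    p0_for_degree,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "compute_cohort_diagrams",
           "run_pipeline"]


@dataclass
class PipelineConfig:
    """Knobs of a full run; defaults follow the package-wide conventions."""

    filtrations: tuple[str, ...] = ("alpha",)
    degrees: tuple[int, ...] = (0, 1)
    witness_proportion: float = 0.2
    q_prox: float = 90.0
    q_dist: float = 98.0
    image_resolution: tuple[int, int] = (20, 20)
    betti_grid_size: int = 200
    clustering_ks: tuple[int, ...] = (2,)
    kmeans_restarts: int = 50
    healthy_label: str = "healthy"
    standardise: bool = False
    render_images: bool = True
    seed: int = 0


@dataclass
class PipelineResult:
    diagrams: dict[tuple[str, str, str], dict[int, PersistenceDiagram]]
    descriptors: dict[tuple[str, str], dict[str, pd.DataFrame]]
    thresholds: dict[tuple[str, str], tuple[float, float]]
    clustering: pd.DataFrame | None
    s: float
    manifest: dict


def _all_cells_clouds(
    clouds: dict[tuple[str, str], PointCloud]
) -> list[PointCloud]:
    """Per-sample concatenation of every population (the all-cells cloud)."""
    by_sample: dict[str, list[PointCloud]] = {}
    for (sample, _), cloud in clouds.items():
        by_sample.setdefault(sample, []).append(cloud)
    out = []
    for sample, parts in by_sample.items():
        pts = np.vstack([p.points for p in parts])
        out.append(
            PointCloud(points=pts, sample_id=sample, population="__all__",
                       condition=parts[0].condition)
        )
    return out


def compute_cohort_diagrams(
    clouds: dict[tuple[str, str], PointCloud],
    filtrations: tuple[str, ...] = ("alpha",),
    witness_proportion: float = 0.2,
    seed: int = 0,
) -> dict[tuple[str, str, str], dict[int, PersistenceDiagram]]:
    """Diagrams keyed by (sample, population, filtration kind)."""
    out: dict[tuple[str, str, str], dict[int, PersistenceDiagram]] = {}
    for (sample, population), cloud in clouds.items():
        for kind in filtrations:
            if kind == "alpha":
                fc = alpha_filtration(cloud)
            elif kind == "witness":
                lms = choose_landmarks(cloud, witness_proportion, seed)
                fc = witness_filtration(cloud, lms)
            else:
                raise ValueError(f"unknown filtration {kind!r}")
            out[(sample, population, kind)] = compute_persistence(
                fc, source=(sample, population, kind)
            )
    return out


def run_pipeline(
    clouds: dict[tuple[str, str], PointCloud],
    outdir: str | Path | None = None,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Run the full pipeline on a cohort of point clouds.

    When ``outdir`` is given, writes per-sample diagram CSVs, per-slot
    descriptor CSVs, PWDS images and CSVs, the clustering report and a
    manifest; with ``outdir=None`` everything stays in memory.
    """
    config = config or PipelineConfig()
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)

    s = estimate_scale_s(_all_cells_clouds(clouds))
    diagrams = compute_cohort_diagrams(
        clouds, config.filtrations, config.witness_proportion, config.seed
    )

    populations = sorted({pop for (_, pop) in clouds})
    samples = sorted({sid for (sid, _) in clouds})
    conditions = {
        sid: cloud.condition for (sid, _), cloud in clouds.items()
    }

    thresholds: dict[tuple[str, str], tuple[float, float]] = {}
    descriptors: dict[tuple[str, str], dict[str, pd.DataFrame]] = {}

    for population in populations:
        for kind in config.filtrations:
            slot = {
                sid: diagrams[(sid, population, kind)]
                for sid in samples
                if (sid, population, kind) in diagrams
            }
            if not slot:
                continue
            deg1 = [d[1] for d in slot.values() if len(d[1])]
            if deg1:
                cfg = compute_thresholds(deg1, config.q_prox, config.q_dist)
                thresholds[(population, kind)] = (cfg.bprox, cfg.bdist)
            descriptors[(population, kind)] = build_descriptor_matrix(
                slot,
                s,
                registry=default_registry(config.degrees),
                resolution=config.image_resolution,
                betti_grid_size=config.betti_grid_size,
            )
            if outdir is not None:
                for sid, dgms in slot.items():
                    diagrams_to_csv(
                        dgms, outdir / f"diagram_{sid}_{population}_{kind}.csv"
                    )
                for name, df in descriptors[(population, kind)].items():
                    df.to_csv(outdir / f"descriptor_{population}_{kind}_{name}.csv")
                if kind == "alpha" and 1 in config.degrees and deg1:
                    cfg = compute_thresholds(deg1, config.q_prox, config.q_dist)
                    for sid in slot:
                        dgm = slot[sid][1]
                        cloud = clouds[(sid, population)]
                        scene = build_scene(dgm, cloud, cfg)
                        scene_to_csv(
                            scene, outdir / f"pwds_{sid}_{population}.csv"
                        )
                        if config.render_images:
                            render(scene, outdir / f"pwds_{sid}_{population}.png")

    clustering = None
    if any(c is not None for c in conditions.values()):
        levels = sorted({c for c in conditions.values() if c is not None})
        reference: dict[int, dict[str, str]] = {}
        if 2 in config.clustering_ks:
            reference[2] = {
                sid: ("healthy" if conditions.get(sid) == config.healthy_label
                      else "rest")
                for sid in samples
            }
        for k in config.clustering_ks:
            if k != 2 and k == len(levels):
                reference[k] = {sid: str(conditions.get(sid)) for sid in samples}
        flat: dict[str, pd.DataFrame] = {}
        for (population, kind), mats in descriptors.items():
            for name, df in mats.items():
                flat[f"{population}|{kind}|{name}"] = df
        if reference and flat:
            clustering = evaluate_cohort(
                flat,
                reference,
                n_restarts=config.kmeans_restarts,
                seed=config.seed,
                standardise=config.standardise,
            )
            if outdir is not None:
                clustering.to_csv(outdir / "clustering_report.csv", index=False)

    manifest = {
        "seed": config.seed,
        "s": s,
        "p0": {str(d): p0_for_degree(s, d) for d in config.degrees},
        "thresholds": {
            f"{pop}|{kind}": {"bprox": b, "bdist": d}
            for (pop, kind), (b, d) in sorted(thresholds.items())
        },
        "filtrations": list(config.filtrations),
        "degrees": list(config.degrees),
        "samples": samples,
        "populations": populations,
    }
    if outdir is not None:
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                         sort_keys=True))

    return PipelineResult(
        diagrams=diagrams,
        descriptors=descriptors,
        thresholds=thresholds,
        clustering=clustering,
        s=s,
        manifest=manifest,
    )
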