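# celltda

Topological analysis of cell-centroid point clouds from multiplexed tissue
imaging (CODEX, IMC and similar technologies that yield annotated 2-D cell
positions). The package quantifies the *spatial arrangement* of cell
populations — rings, voids, dense carpets, infiltration — rather than their
counts, and screens which topological summaries separate biological
conditions.

## What it computes

For each sample and cell population the centroids form a point cloud
`X ⊂ ℝ²`. The multiscale shape of `X` is encoded by a filtration of
simplicial complexes indexed by a ball radius ε:

- the **alpha filtration** `A_ε`, supported on the Delaunay triangulation
  (a p-simplex enters when the ε-balls of its p+1 Voronoi-neighbour
  vertices share a point); values are reported on the radius scale, so a
  triangle enters at its circumradius;
- the **witness filtration** `W_ε` on a random landmark subset, for large
  clouds.

**Persistent homology** over GF(2) tracks connected components (degree 0)
and loops (degree 1) across ε, yielding a persistence diagram of
(birth, death) pairs; each finite pair retains its *death simplex* — for a
loop, the last triangle that fills the enclosed void.

**PWDS (persistence weighted death simplices)** draws those death
triangles over the cells: hue encodes where the birth sits between the
cohort thresholds `b_prox = ⟨P90⟩` and `b_dist = ⟨P98⟩` of the birth
distribution (red = loops of proximal cells, blue = loops of distal
cells), and opacity encodes persistence. The result localises loops in the
tissue and makes infiltration visually obvious.

**Vectorisations** turn each diagram into a fixed-length descriptor:
normalised Betti curves, percentiles (P10/P25/P50/P75/P90) of
birth/death/persistence, and persistence images under five weightings
`w_flat = min(p/p₀, 1)`, `w₁ = p`, `w₂ = p²`, `w₃ = bp`, `w₄ = bp²`,
with `p₀` tied to the typical cell spacing `s` (mean nearest-neighbour
distance of the all-cells clouds): `p₀ = s/2` in degree 0 and
`p₀ = (1/√3 − 1/2)s` — the persistence of a minimal three-cell loop — in
degree 1.

**Clustering** runs k-means on every descriptor separately and reports
which descriptors split the samples exactly along condition labels,
ranked by silhouette score, with the Rand index for imperfect splits.

## Worked example

```python
import celltda as ct

# a ring of 60 cells undergoing infiltration: 0 / 10 / 40 / 160 cells inside
base = ct.RingSpec(n_points=60, radial_jitter_sd=0.03)
series = ct.make_infiltration_series(base, [0, 10, 40, 160], seed=11)
diagrams = [ct.compute_persistence(ct.alpha_filtration(c))[1] for c in series]

cfg = ct.compute_thresholds(diagrams)          # bprox=0.183, bdist=0.204
for cloud, dgm in zip(series, diagrams):
    feats = [f for f in dgm.features if f.is_finite and f.persistence > 0]
    blue = sum(ct.classify_feature(f.birth, cfg) == 1.0 for f in feats)
    print(cloud.sample_id, len(feats), blue,
          round(max(f.persistence for f in feats), 3))
```

prints

```
infiltration_000 1 0 0.877
infiltration_010 16 11 0.424
infiltration_040 57 16 0.189
infiltration_160 182 2 0.167
```

The clean ring carries a single prominent loop (persistence 0.877 on a
unit-radius ring). Ten infiltrating cells split the void into 16 loops,
11 of them formed by distal points (blue), and the main loop's
persistence drops to 0.424; by 160 noise cells the large-scale structure
is gone. `ct.build_scene(...)` and `ct.render(...)` produce the
corresponding death-triangle overlays.

The same pipeline runs from the shell:

```
celltda synth cohort --n-per 3 --seed 7 --out cohort.csv
celltda run cohort.csv --seed 0 --outdir out/
```

which writes diagrams, PWDS images, descriptor matrices, the descriptor
screen (`clustering_report.csv`) and a manifest of all derived parameters.

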