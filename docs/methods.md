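# Methods

## Model and scope

The package treats the cell centroids of one population in one tissue
sample as a planar point cloud and summarises its multiscale shape with
persistent homology in degrees 0 (clusters of cells) and 1 (loops of
cells around voids). Everything downstream — the PWDS visualisation, the
descriptor vectorisations and the k-means screen — consumes the
persistence diagrams. Homology is computed over GF(2) by standard column
reduction of the boundary matrix; coefficients in other fields make no
difference for the planar complexes used here.

## Filtrations

**Alpha.** Built on the Delaunay triangulation (scipy). All values are on
the ball-*radius* scale: vertices at 0, a triangle at its circumradius, an
edge at half its length when its diametral disc is empty (Gabriel),
otherwise at the smaller circumradius of its incident Delaunay triangles —
the distance from an endpoint to the nearest point of the edge's dual
Voronoi segment. The radius convention keeps every derived threshold
(birth percentiles, the typical scale `s`, the plateau `p₀`) on one
distance scale. Degenerate inputs (fewer than three non-collinear points)
fall back to the 1-skeleton — consecutive points along the principal axis
joined at half their distance — with a warning; exactly co-circular or
duplicated positions are *not* perturbed silently: ties are resolved by
the deterministic simplex order below and a genericity warning is issued.

A consequence of exact alpha values worth knowing: three nearly collinear
boundary points form a "sliver" Delaunay triangle whose circumradius can
exceed the cloud's diameter. Such a triangle enters together with its
creating edge and produces a zero-persistence pair at a very large birth
value. These pairs are genuine elements of the filtration and are kept in
diagrams, but they carry no weight anywhere mass or colour is assigned
(see below).

**Witness.** A simplex on landmark vertices enters at the smallest
relaxation ε at which some data point witnesses it: a ball centred at the
witness containing the simplex's vertices whose other enclosed landmarks
all lie within ε of its boundary. For witness `w` the optimal ball radius
is `m(w) = max_v d(w, v)`, giving the closed-form entry value
`min_w max(0, m(w) − min_{l∉σ} d(w, l))`; upward closure (no simplex
before its faces) then restores the filtration property, which witness
complexes lack by construction. This is the definition-level semantics;
library implementations use slightly different relaxations, and the test
suite checks ours against a brute-force scan of the witness condition.
With every point a landmark, a ring's loop forms at tiny but not exactly
zero relaxation (gap-sequence local maxima leave short arcs disconnected
at ε = 0), so tests assert "born below a few percent of the ring radius"
rather than exact zero. Landmarks are drawn uniformly without replacement
(default proportion 0.2, seed required). Complexity is
O(L³·n) in landmarks L and points n — intended for tens to low hundreds
of landmarks.

## Persistence conventions

- Total simplex order: (filtration value, dimension, lexicographic vertex
  tuple). The order is validated to be a linear extension of the face
  poset.
- Zero-persistence pairs are retained in diagrams. They count toward the
  feature total that normalises Betti curves and toward the birth
  percentiles of the *vectorisation* module, but they are excluded from
  PWDS (nothing with zero persistence is rendered, and the colour
  thresholds are computed from positive-persistence births only — the
  sliver pairs described above would otherwise dominate P90/P98 with
  births larger than the cloud itself).
- Essential (infinite-death) features are excluded from death and
  persistence percentiles and from persistence images, and are always
  alive in Betti curves.
- The death simplex of every finite feature is retained; its filtration
  value equals the death exactly. Which triangle dies a loop is unstable
  under perturbation when several empty triangles have similar
  circumradii — tests assert the death value and membership in the
  complex, never the identity of the triangle.

## PWDS

Thresholds `b_prox` and `b_dist` are the means across samples of the
per-diagram 90th and 98th birth percentiles (linear interpolation between
order statistics, the convention used everywhere percentiles appear).
They are computed per (population, filtration) across all samples of a
cohort, so colours are comparable between samples and conditions. Hue is
0 (red) below `b_prox`, 1 (blue) above `b_dist` and linear in between;
when the two thresholds coincide the gradient degenerates to a step at
the shared value. Intensity is persistence divided by the maximum finite
persistence in scope — per-diagram by default, per-dataset optionally for
cross-sample comparability — floored at 0.05 so weak features remain
visible. Only degree-1 scenes are rendered; degree-0 death simplices
(edges) are computed but not drawn.

## Vectorisations

The typical scale `s` is the mean over samples of the mean
nearest-neighbour distance of the *all-cells* cloud, and `p₀` is the
persistence of a minimal feature at that scale: `s/2` in degree 0 (the
radius at which neighbouring cells connect), `(1/√3 − 1/2)·s ≈ 0.0773·s`
in degree 1 — a loop of three cells at the corners of an equilateral
triangle of side `s` is born at `s/2` and filled at its circumradius
`s/√3`. Both are fixed from the whole point clouds even when vectorising
single-population subsets, so sparse populations stay on the common
scale.

Defaults chosen where the procedure leaves them open:

- persistence images: 20×20 grid; Gaussian sd = `p₀` for the degree
  (smoothing tied to the data scale); axis ranges `[0, max + 3·sd]` per
  (population, filtration, degree) across the cohort so rows are
  comparable. Box integrals are exact products of 1-D normal CDFs, so
  total mass equals summed weights up to truncation.
- Betti curves: 200 evenly spaced scales from 0 to the cohort-wide
  maximum finite death per (population, filtration, degree), shared
  across samples.
- Degree 1 gets all nine vectorisations; degree 0 — where birth is
  identically 0 and death equals persistence — keeps the Betti curve, the
  persistence percentiles and the flat/w₁/w₂ images.

## Clustering screen

k-means with 50 restarts (k-means++ seeding, fixed seed) per descriptor;
"correct" means exact agreement with the reference partition up to a
bijective relabelling, which implies Rand index 1. Descriptors are
clustered raw by default — each lives alone on its own scale — with
z-scoring behind a flag. The unadjusted Rand index ranks imperfect
clusterings; the adjusted version is reported alongside but not used for
ranking. Silhouette is undefined (NaN) for single clusters and for
all-singleton clusterings.

## Synthetic data

The generators produce the geometric motifs that drive the method's
behaviour on tissue:

- `make_ring`: n points at even angles on a circle, Gaussian angular and
  radial jitter, plus uniform interior noise. A tiny default angular
  jitter (sd 0.01 rad) avoids exactly co-circular, non-generic positions.
- `make_infiltration_series`: one ring with nested interior noise at
  non-decreasing levels; ring coordinates are identical across levels so
  diagram changes are attributable to infiltration alone. Study fixture:
  60-point unit ring, radial jitter sd 0.03, levels 0/10/40/160.
- `make_multi_ring`: independent rings in one cloud. The four-ring
  fixture uses collinear centres with boundary gaps ≥ 1.5 radii (radii 1
  and 2.5; 40/12 and 80/16 points), so no spurious enclosed void forms
  between rings and exactly the four ring loops are prominent.
- `make_blob_with_voids`: a dense uniform carpet perforated by circular
  voids over a sparse background — the red-pulp/white-pulp mimic.
- `make_two_condition_cohort`: labelled ring clouds per condition with
  per-cloud seeds derived from a master seed. Study conditions: 3 samples
  per condition, 150-point rings with radial jitter sd 0.08; the diseased
  condition adds 100 interior-noise cells (strong infiltration), the
  negative control uses identical parameters for both labels.

What these emulate — and what they do not: rings and perforated carpets
reproduce the loop structure, density contrasts and infiltration that the
descriptors target; they do not model cell–cell interactions, anisotropy,
boundary effects of tissue sections, segmentation error, or population
sizes in the tens of thousands. Passing tests therefore demonstrate the
machinery (exact filtration values, correct pairing, faithful
vectorisation, a screen that finds planted contrasts and stays quiet on
the negative control) — not biological conclusions about any real tissue.

## Numerical choices and degenerate inputs

- Percentiles: linear interpolation, everywhere.
- Ties in the filtration: deterministic lexicographic order (documented
  above); the choice affects which simplex is reported as death simplex
  under ties, never birth/death values.
- Missing descriptors (e.g. no finite degree-1 feature in a sparse
  cloud): NaN rows, excluded per descriptor from clustering; a descriptor
  missing for more than half the samples is dropped with a warning.
- Duplicate coordinates are kept with a warning; collinear clouds fall
  back to the 1-skeleton.
- Centroid CSV I/O uses `%.17g` writing and round-trip float parsing, so
  write-then-read reproduces coordinates bit-exactly (the determinism
  contract of `run` depends on it).

## Problem sizes

Test and acceptance fixtures use clouds of 3–260 points, cohorts of six
samples and 20-seed negative controls; these sizes exercise every code
path while keeping a full run in seconds. The implementation itself
handles clouds of a few thousand points comfortably (the reduction is the
bottleneck; the alpha complex of n points has ~6n simplices).

## Known limitations

- Planar data only; no 3-D alpha complexes and no degree-2 homology.
- The witness construction is the reference semantics, not a
  reimplementation of any library's relaxation; entry values can differ
  from other implementations near ties.
- The death simplex is intrinsically unstable under near-ties; PWDS
  locates features approximately, it does not draw cycle boundaries.
- Betti-curve grids extend to the largest finite death, which sliver
  pairs can inflate; the curves remain correct but concentrate their
  signal in the first portion of the grid.
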