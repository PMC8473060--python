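# Methods

## Problem and model

`forestseg` segments a ground-based (backpack/handheld) LiDAR point cloud of
a forest plot into individual trees and estimates each tree's stem location.
Unlike airborne data, terrestrial clouds are densest near the ground: trunks
are sampled from many directions, so in a thin horizontal slab each stem
appears as a compact ring of returns. The pipeline exploits exactly that:

1. **Outlier gate.** The scanner walks a path through the plot; long-range
   returns (stray branches, neighboring stands) lie far outside it. The
   convex hull of the trajectory's XY positions defines the survey polygon;
   a point survives iff it lies inside the polygon or within `hull_buffer`
   of its boundary.
2. **Ground separation and normalization.** A grayscale morphological
   opening (erosion then dilation, square structuring element of width
   `morph_window`) of the minimum-z raster estimates the bare-earth
   profile; points within `morph_height_tol` of the opened surface are
   ground. Ground points are interpolated by inverse distance weighting
   onto a regular grid — the DTM — and every vegetation point's z is
   replaced by its height above the bilinearly interpolated DTM. Ground
   points feed the DTM only; they are not segmented (keeping them would let
   the ground sheet density-connect neighboring trees at the cylinder
   stage) and carry label 0 in the output.
3. **Trunk detection.** Points with normalized height in
   `[slab_zmin, slab_zmax]` form the trunk layer. DBSCAN on their XY
   projection (radius `eps_trunk`, minimum `min_points` neighbors counting
   the point itself) yields one cluster per stem; the equal-weight center
   of mass of a cluster — the arithmetic mean of its XY coordinates — is
   the tree location. Stems closer together than `eps_trunk` merge into one
   cluster; this is the method's dominant failure mode and the reason the
   sweep caps `eps_trunk` at 0.5 m.
4. **Cylinder voxelization.** Each trunk's *candidate radius* is the
   distance to its nearest other trunk. Trunks are processed in ascending
   radius order; each claims every still-unclaimed point inside its
   infinite vertical cylinder and subclusters the claim with a 3D DBSCAN at
   `eps_cylinder`. The small radius deliberately oversegments so that crown
   fragments of neighboring trees captured by an oversized cylinder remain
   separable. Points claimed by no cylinder, plus per-cylinder DBSCAN
   noise, form the discarded set.
5. **Merging and noise filtering.** A subcluster is *ground-connected* if
   its z-histogram (bin `continuity_bin`) starts at most
   `continuity_ground_max` above the ground and has no run of
   `continuity_gap_bins` empty bins inside its extent; otherwise it is
   *floating* and merges into the ground-connected segment with the
   smallest minimum 3D point-to-point distance (ties to the lower id).
   Discarded points closer than `d*` (`noise_threshold`, strict) to a
   segment join it; the rest are the noise set, labeled 0.

## Validation metric

Reference trees are matched to algorithm trees iteratively. For reference
tree R with closest reference neighbor R′, the search radius d_min is the
mean distance from R's points to their nearest point of R′ (a directed mean
nearest-neighbor distance — well defined for unequal cluster sizes).
Algorithm trees with stem-to-stem XY distance to R within d_min are tried
nearest-first, with N* = |candidate|, N1 = |R|, N2 = |R′|:
N* > N1 and N* ≥ N1+N2 → false positive (consumed; the next candidate is
tried); otherwise → true positive (both consumed). A reference tree with no
surviving candidate is a false negative. Then

    DR = N_TP / N_R,   E_COM = N_FN / (N_TP + N_FN),   E_OM = N_FP / (N_TP + N_FP).

When every reference tree receives a verdict, DR + E_COM = 1 by
construction. A configuration switch (`retry_after_fp=False`) makes a
reference tree an immediate FN after an FP candidate instead of retrying;
the retry variant is the default because consumed-and-continue wastes fewer
reference trees on oversized segments.

## Parameters

| name | default | unit | why |
| --- | --- | --- | --- |
| `hull_buffer` | 1.0 | m | walking path passes within ~1 m of plot-edge stems |
| `morph_window` | 2.0 | m | wider than a trunk, narrower than a crown |
| `morph_height_tol` | 0.3 | m | ~10× ranging noise; tolerates slope within a window |
| `idw_power`, `idw_neighbors` | 2, 8 | – | conventional IDW for scattered terrain points |
| `dtm_cell` | 0.5 | m | resolves gentle relief at typical ground densities |
| `eps_trunk` | 0.1 | m | sweep optimum; smaller than typical stem spacing |
| `eps_cylinder` | 0.9 | m | sweep optimum; below typical crown gaps |
| `min_points` | 40 | – | a 0.5 m slab of a scanned stem yields hundreds of returns; 40 rejects shrub wisps |
| `min_points_cyl` | 10 | – | permissive: oversegmentation is intended here |
| `noise_threshold` (d*) | 0.87 | m | sweep optimum for the noise gate |
| `slab_zmin..zmax` | 1.0–1.5 | m | above shrubs, below crowns, near breast height |
| `continuity_bin` / `ground_max` / gap | 0.25 / 0.5 / 2 | m/m/bins | operationalizes "density discontinuity"; exposed in config |

The defaults `eps_trunk = 0.1 m`, `eps_cylinder = 0.9 m`, `d* = 0.87 m` are
the optimum reported for this method's reference deployment; the built-in
sweep (`sensitivity_sweep`) recovers an optimum in the same region on the
synthetic stands.

## Synthetic stands

The generator emulates what the pipeline needs from real backpack data: a
sloping noisy ground plane sampled everywhere; trunks as Gaussian rings
(radial distance ~ Normal(r, 0.02 m) about the stem outline, heights
uniform up to the crown base) — the ring shape mirrors how slice returns
straddle the bark; uniform ellipsoidal crowns; low shrub blobs; far-range
outliers beyond the survey polygon; a serpentine trajectory 1.5 m above the
terrain; and a mild distance-dependent dropout as an occlusion stand-in.
The default stand is 20 stems at ≥ 4 m spacing on a 30 m × 30 m plot with
~6000 returns per tree (~130 k points in total) — modest for a scanner
collecting tens of thousands of points per second. Smaller 5-tree stands
with the same per-area densities are used where many scenes are needed.

What the generator does **not** model: ray-traced occlusion shadows,
registration drift, understorey ladders connecting crowns, leaning or
forked stems, intensity. Passing on these stands therefore demonstrates
the pipeline's internal correctness and its behavior under the stated
geometry, not field-grade robustness; on real clouds the trunk-merging and
occlusion failure modes will dominate, exactly the regime the sensitivity
sweep is for.

## Numerical choices

* DBSCAN is deterministic by construction: neighbor counts include the
  point itself; clusters are the connected components of core points,
  numbered by their smallest core index; a border point joins its
  lowest-indexed core neighbor. Boundary distances use ≤ throughout
  (closed balls, closed cylinder disk, inclusive slab bounds); the noise
  gate `d*` is strict (<) so boundary points become noise.
* Cylinder iteration order is ascending candidate radius (ties by trunk
  id): small cylinders claim points before a large neighbor can swallow
  them. The candidate radius is the full nearest-neighbor distance, not
  half of it; the resulting overlap is resolved by pool removal. With a
  single detected trunk the radius falls back to the cloud's bounding
  circle.
* The morphological raster uses a sub-grid of `morph_window / 4` with
  empty cells filled from their nearest occupied cell; opening preserves
  planes exactly, so sloped terrain incurs no bias beyond intra-window
  relief.
* IDW cell centers closer than 1e-9 m to a ground point copy its
  elevation; bilinear DTM interpolation clamps to the outermost cell
  centers (nearest-cell extrapolation, logged).
* Trees are renumbered 1..N by ascending stem x then y, so labelings are
  reproducible across runs and platforms.

## Design decisions that were genuinely open

* **Ground points are excluded from segmentation** (see step 2). The
  alternative — segmenting the full normalized cloud — connects every tree
  through the ground sheet at any workable `eps_cylinder`.
* **Every ground-connected subcluster becomes a tree.** Shrub blobs thus
  surface as small spurious trees near a stem's cylinder; the validator's
  point-count rules make them harmless (they match as incomplete TPs or
  stay unmatched), which mirrors how commission behaves in the field
  metric.
* **d_min** ("average of all distances between corresponding points") is
  implemented as the directed mean nearest-neighbor distance from R to R′.
* **Vertical continuity** is a histogram-gap rule; the two-empty-bin gap
  and the 0.5 m ground reach are this package's operationalization and are
  configurable.

## Problem sizes

The default test suite and the acceptance script use the 20-tree stand
(~130 k points, one full pipeline run each) plus 5-tree stands (~18 k
points) wherever repetition is needed — ten random stands for the
conservation audit, twelve grid points for the sweep. These sizes keep a
full run on one CPU in the tens of seconds while leaving every stage's
behavior observable.

## Known limitations

* LAS support is a self-contained 1.2 codec (point formats 0–3, extra-bytes
  labels); compressed LAZ and vendor formats are not read.
* No CRS handling; coordinates are assumed planimetric meters, z up.
* The trunk slab is fixed per run; plots with strongly varying crown-base
  heights may need a different slab.
* Cylinder radii adapt per tree but not per height; interlocking crowns at
  very close spacing will still exchange points.
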