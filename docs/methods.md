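# Methods

This note documents the models, parameters and numerical choices behind
`periograft`, and what the synthetic phantom does and does not establish
about behavior on real scans.

## Coordinate and label conventions

Volumes are indexed `(i, j, k)` ↔ world axes `(x, y, z)`, 0-based and
half-open; the world frame is LPS-style (the native frame of the ITK
readers used for DICOM/NIfTI/NRRD), with the world position of voxel
`(i, j, k)` at `origin + spacing · (i, j, k)`. The `z` axis is the jaw
axis: occlusal is +z for a mandibular case and −z for a maxillary one.
Labels are 0 unlabeled, 1 teeth, 2 alveolar bone, 3 "other" (air, soft
tissue, and missing-bone cavities). Ground-truth phantoms contain labels
{1, 2, 3} only; 0 occurs only as pre-convergence segmentation state.
Meshes are in millimetres with counter-clockwise winding for outward
normals; STL export is binary little-endian.

## Synthetic jaw phantom

The phantom emulates exactly the anatomy the workflow consumes: a
rectangular alveolar-bone block; vertical teeth (root cylinder embedded
in bone, crown cylinder with a hemispherical cap above the crest); a
peri-root periodontal defect; an empty extraction socket. Defaults define
the packaged study phantom: a 128³ grid at 0.15 mm isotropic voxels (the
resolution of clinical CBCT for this application), two teeth (root radius
1.3 mm, crown radius 2.2 mm, height 10 mm), tissue intensity means
air 0 / bone 600 / tooth 1600 (CBCT-like gray values with a clear
bone–tooth contrast), 0.15 mm partial-volume Gaussian blur and additive
Gaussian noise (σ = 25, clipped to the pre-noise value range) — the
simplest degradation model sufficient to stress the region grower. A
noiseless variant (`default_phantom_spec(noiseless=True)`) zeroes blur
and noise and is the reference condition for the segmentation oracle.

The defect is an azimuthal sector of an annular cone flaring up from the
root surface: apex 4 mm below the crest, 30° flare, a 150° sector facing
buccally. A localized sector (rather than a full circumferential moat)
matches the clinical presentation of intrabony defects and gives the
cropped graft seat disk topology. The socket is a 2 mm-radius, 8 mm-deep
cylinder with a hemispherical floor. Both cavities carry the "other"
label — they are missing bone — and the generator also returns the exact
flipped-voxel masks, so cavity volumes can be voxel-counted independently
of the label map (`cavity_volume`). Closed forms used as test oracles:
sector annular cone `(θ/2)(r₀ d² tanα + d³ tan²α / 3)`; socket
`π r² (d − r) + (2/3) π r³`.

Default seeds mirror a small manual sample subset: the truth eroded by
2 voxels, restricted to 10 evenly spaced slices per reference plane
(30 slices total), at strength 1. The 2-voxel erosion guarantees a seed
dilated by one voxel never touches a label boundary.

Geometry depends only on the spec; the RNG seed drives noise only, and
reruns are bit-identical.

## Grow-from-seeds segmentation

A synchronous (Jacobi) cellular automaton in the GrowCut family. State per
voxel: (label, strength θ ∈ [0, 1]). Attack strength of neighbor q on p is
`g(|I_p − I_q|) · θ_q` with `g(d) = 1 − d / intensity_scale` clipped to
[0, 1]; `intensity_scale` defaults to the ROI's intensity range. The
strongest attacker conquers p iff its attack strictly exceeds θ_p; ties
break to the lowest label (a fixed, documented rule — required for
determinism; it can break label-permutation equivariance only on exact
floating-point ties, which do not arise on the phantom). Seeds are frozen
state, restored after every pass, so corrections always survive. The
default neighborhood is 6-connected (26 available); iteration stops at
convergence or `max_iterations` (default 500). Strength-1 fronts cannot
cross a zero-affinity step (`g = 0`), which is what pins the fronts in
the hand-derivable 8-voxel example.

The iterative-correction loop is modelled as SeedSet files merged
later-wins per voxel followed by a re-run — a reproducible artifact in
place of interactive painting.

## Meshing

Marching cubes (scikit-image) on the binary label mask at level 0.5,
scaled to world mm; closed masks yield watertight meshes re-oriented to
positive signed volume; masks touching the grid boundary yield open
meshes whose boundary edges are reported, never silently capped.
Convention values recorded by the tests: a single voxel at unit spacing
meshes to the octahedron through the six half-voxel crossings, volume
1/6 mm³; a 5 mm sphere at 0.15 mm meshes to within 0.1% of its analytic
volume, with error decreasing as spacing halves.

Cleaning removes small components by face-connectivity, smooths with
Taubin steps λ = 0.1, ν = 0.11 applied in shrink/inflate pairs (gentle on
purpose: these step sizes keep even a 12-triangle cube within 1% of its
volume, at the cost of needing more passes on dense meshes), and closes
boundary loops shorter than a length threshold. `watertight` in a mesh
report means: every edge shared by exactly two consistently wound faces
*and* positive signed volume — an inside-out mesh is not print-ready.
STL reads weld exactly equal coordinates so topology survives the
triangle-soup round trip; per-face coordinates are unchanged.

## Scaffold geometry operators

All operators are pure and deterministic. "Cutting" keeps or discards
whole faces by a centroid test against the region (box, half-space
intersection, or projected lasso polygon) rather than exact
plane-splitting: the cuts this replaces were freehand GUI lassos with no
exactness claim, and the trim tolerance absorbs the face-sized
discretization. Centroid-test crops of voxel isosurfaces can leave
boundary "pinch" vertices; a repair pass removes the incident faces so
the boundary decomposes into simple loops.

`trim_against` measures the signed height of each face centroid above the
limiter surface along a stated direction, via exact closest-point queries
accelerated by a k-d tree over face centroids (exact point-triangle
distance over the k = 24 nearest candidates; marching-cubes faces are
near-uniform in size, so small k suffices). Ray queries (thickness
probes, self-intersection probes) are brute-force Möller–Trumbore per
ray. Both kernels live in `_meshmath` and use only numpy/scipy.

`fill_holes` triangulates each qualifying boundary loop with a centroid
fan (exact for planar holes: a cube missing a face closes to volume 1
within 1e−6) and optionally fairs the patch. `bridge` spans the two
boundary edges nearest the given points with a hexagonal strip (side
midpoints inset 25% toward the strip center so the two residual loops
keep nonzero area), splitting one loop into exactly two without shared
vertices. `stitch_loops` zippers two boundary loops: for equal-length
loops (an offset copy) the cyclic alignment minimizing total rung length
recovers the exact 1:1 correspondence, which keeps the band fold-free at
sharp rim corners; otherwise the traversal synchronizes normalized arc
length.

The rigid/scale transform applies translation, then rotation about a
pivot, then uniform scaling about a stated center. The 0.98 pre-export
shrink is a uniform scale about the mesh centroid (the anchor is a
package choice, documented here); it multiplies every bounding-box edge
by exactly 0.98 and the volume by 0.98³ = 0.941192.

## Graft pipelines

**Block graft (stages A1–D2).** A1 crops the tissue surface to the graft
seat; A2 optionally cleans it; A3 inverts its normals (as part of the
tissue model they point away from the tissue; the scaffold's inner
surface must point outward from the scaffold, i.e. into the contact).
The outward offset direction is the area-weighted mean normal of the
*tissue-wound* crop — equivalently minus the mean normal of the inverted
inner surface — i.e. away from the tissue into the defect; an explicit
override is available for seats whose mean normal degenerates (a surface
containing the offset direction would slide along itself). B1 copies the
(optionally re-cropped) seat and translates it by the mean thickness
(default 1 mm) along that direction: the outer surface is literally a
moved copy, with a per-vertex normal-offset mode not needed for the
packaged fixture. B2, when `taper_deg` > 0, rotates the outer copy about
a horizontal axis (offset × jaw axis) through the bone-side boundary
centroid, tilting the occlusal side toward the inner surface so thickness
decreases away from the bone contact. B3–B6 add lateral patches when
lateral regions are supplied; B7 trims the outer surface against the
inner along the offset direction; B8 extends the rim when its occlusal
extent falls short of the inner surface's by more than half the mean
thickness (trigger measured, region supplied). C trims the inner surface
against the outer along the jaw axis. D1 concatenates inner and outer
(no weld — the vertex-index partition identifies whose boundary is
whose); D2 pairs boundary loops across the two surfaces by centroid
distance, zippers each pair, closes any remaining loops (bridging loops
longer than `fill_max_boundary_mm`, default 12 mm, then fan-filling
smallest-first), repairs winding, enforces positive volume, and applies
the export scale. A non-watertight result is a hard error listing the
remaining loops.

**Socket graft (A then B).** A1–A3 crop and re-orient the cavity lining
(a box ending 0.25 mm below the crest, so the jagged crest plane stays
out of the seat); stage B runs the same bridge-assisted closure, then
scales by 0.98 by default. On the packaged phantom the unscaled graft
fills ~97% of the voxel-counted cavity; the ~3% deficit is the ε-collar
below the crest plus the half-voxel bias of the marching-cubes surface.

**Phantom-derived parameter sets.** `phantom_block_params` seats the
plate on the bony (cone) wall of the wedge: half-space constraints clip
off the near-vertical root wall and sector side walls (their offset would
slide along itself), and the deep cut sits where the wedge first becomes
wider than the plate (`depth − thickness/tanα` below the crest), so the
offset copy never pokes through the root. These are fixture definitions,
set once from the phantom geometry.

**Validation.** `validate_scaffold` reports watertightness, signed
volume, the maximum gap from inner-surface samples to the tissue (inner
faces = faces inside the seat region whose normals oppose the offset
direction at dot < −0.5, excluding flank faces that run along the
offset), ray-probed min/max thickness, and a probe-resolution
self-intersection count (a ~300-edge segment-cast sample against
non-adjacent faces — zero means none detected at that resolution, not a
CSG-exact guarantee).

## Determinism and reproducibility

Every stage is deterministic: synchronous automaton updates, fixed
tie-breaks, order-preserving mesh operators, graph-traversal winding
repair. Two runs of the full chain on the same config produce
byte-identical STL files and manifests; the CLI records config, input and
output hashes per run. The only randomness in the package is the
phantom's additive noise, driven by an explicit seed.

## Problem sizes

Unit tests run on a down-scaled phantom (64³ at 0.3 mm — the same
anatomy in mm, coarser voxels) and small constructed fixtures; the
acceptance checks run the packaged phantom at full resolution (128³ at
0.15 mm) plus a 0.075 mm half-spacing sphere for the convergence check;
the end-to-end determinism check uses the coarse configuration, run
twice.

## What the phantom does and does not show

The phantom has piecewise-constant tissues, additive Gaussian noise,
simple convex-ish anatomy and exactly known ground truth. Passing tests
establish the correctness of the algorithms and their composition —
conquest rule, convergence, mesh extraction accuracy, the geometric
contracts of both pipelines, determinism. They do not establish clinical
segmentation accuracy on real CBCT (beam hardening, metal artifacts,
heterogeneous bone, oblique anatomy), nor that the default threshold or
seed placements transfer to scanner data: on real scans, seed ranges
come from the data and the iterative-correction loop is expected to be
used. Residual small-region segmentation errors are deliberately left to
mesh cleanup rather than fixed voxel-wise, matching the intended
workflow.

## Known limitations

* Cuts are face-granular; sub-face precision is absorbed by `trim_tol_mm`
  (default 0.3 mm ≈ two voxels) rather than exact plane splitting.
* The offset outer surface is a rigid translate; strongly curved or
  multi-lobed defects need the normal-offset mode and per-case regions.
* The self-intersection check is a sampled probe, not exact CSG.
* `bridge` takes its strip width from the boundary edges it joins; the
  `strip_width_mm` parameter is accepted for config compatibility.
* No pore/lattice infill, slicing, or FEA — the output is the watertight
  outer geometry for printing.
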