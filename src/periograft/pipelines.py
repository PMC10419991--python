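"""End-to-end graft design workflows.

Two pipelines operate on a cleaned hard-tissue surface (teeth + alveolar
bone around the defect):

* the periodontal-defect customized **block graft** — an inner surface
  conforming to the tooth root and bone wall, an outer surface restoring
  the missing bony contour at a chosen mean thickness (optionally tapering
  thinner away from the bone-contact side), joined into a watertight,
  print-ready solid;
* the extraction-socket preservation **graft** — the geometric complement
  of an empty socket cavity, closed by bridge-assisted hole filling and
  shrunk by a pre-export factor (default 0.98) so it seats in the jaw.

Each stage is recorded in a :class:`StageTrace` with a mesh report before
and after, so a run is a reproducible artifact rather than a GUI session.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import scaffold_geom as sg
from .meshing import (
    MeshReport,
    drop_boundary_pinches,
    MeshError,
    SurfaceMesh,
    boundary_loops,
    clean_mesh,
    face_areas,
    face_centroids,
    face_normals,
    loop_length,
    merge_meshes,
    remove_degenerate_faces,
    report,
    signed_volume,
)
from .scaffold_geom import RegionSpec


class PipelineError(RuntimeError):
    """A stage produced an invalid intermediate; the message names the stage."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage {stage}: {message}")


@dataclass(frozen=True)
class ScaffoldParams:
    """Parameters of a graft design run.

    jaw : "mandibular" or "maxillary"; fixes the bone-contact side (bottom
        vs top) and hence the occlusal direction.
    mean_thickness_mm : offset between inner and outer surface before any
        taper rotation (default 1.0 mm).
    taper_deg : variable-thickness rotation of the outer surface about a
        horizontal axis through its bone-side edge; 0 disables the taper.
    inner_region : region of the tissue surface that becomes the scaffold's
        inner (contact) surface.
    outer_region : region for the first outer-surface approximation
        (defaults to inner_region).
    lateral_regions : optional regions for missing lateral outer patches.
    rim_region : optional region used to extend a too-short outer rim.
    export_scale : uniform pre-export scale about the centroid (1.0 for
        block grafts; 0.98 recommended for socket grafts).
    fill_max_boundary_mm : loops up to this length are fan-filled during
        closure; longer loops are first split by bridges.
    offset_direction : override for the outward defect direction; default
        is the area-weighted mean normal of the tissue-side inner crop.
    """

    jaw: str
    inner_region: RegionSpec
    mean_thickness_mm: float = 1.0
    taper_deg: float = 0.0
    outer_region: RegionSpec | None = None
    lateral_regions: tuple[RegionSpec, ...] = ()
    rim_region: RegionSpec | None = None
    trim_tol_mm: float = 0.3
    export_scale: float = 1.0
    fill_max_boundary_mm: float = 12.0
    fairing_passes: int = 0
    offset_direction: tuple[float, float, float] | None = None
    clean_min_component_faces: int = 0
    clean_smoothing_passes: int = 0

    def __post_init__(self):
        if self.jaw not in ("mandibular", "maxillary"):
            raise ValueError(f"jaw must be 'mandibular' or 'maxillary', got {self.jaw!r}")
        if not self.mean_thickness_mm > 0:
            raise ValueError("mean_thickness_mm must be > 0")
        if not 0 < self.export_scale <= 1:
            raise ValueError("export_scale must lie in (0, 1]")
        if not 0 <= self.taper_deg <= 45:
            raise ValueError("taper_deg must lie in [0, 45]")
        object.__setattr__(self, "lateral_regions", tuple(self.lateral_regions))

    @property
    def jaw_up(self) -> np.ndarray:
        """Occlusal direction: away from the bone-contact side."""
        return np.array([0.0, 0.0, 1.0 if self.jaw == "mandibular" else -1.0])

    def to_dict(self) -> dict:
        d = {
            "jaw": self.jaw,
            "mean_thickness_mm": self.mean_thickness_mm,
            "taper_deg": self.taper_deg,
            "inner_region": self.inner_region.to_dict(),
            "trim_tol_mm": self.trim_tol_mm,
            "export_scale": self.export_scale,
            "fill_max_boundary_mm": self.fill_max_boundary_mm,
            "fairing_passes": self.fairing_passes,
            "clean_min_component_faces": self.clean_min_component_faces,
            "clean_smoothing_passes": self.clean_smoothing_passes,
        }
        if self.outer_region is not None:
            d["outer_region"] = self.outer_region.to_dict()
        if self.lateral_regions:
            d["lateral_regions"] = [r.to_dict() for r in self.lateral_regions]
        if self.rim_region is not None:
            d["rim_region"] = self.rim_region.to_dict()
        if self.offset_direction is not None:
            d["offset_direction"] = list(self.offset_direction)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScaffoldParams":
        kw = dict(d)
        kw["inner_region"] = RegionSpec.from_dict(kw["inner_region"])
        if "outer_region" in kw:
            kw["outer_region"] = RegionSpec.from_dict(kw["outer_region"])
        if "lateral_regions" in kw:
            kw["lateral_regions"] = tuple(RegionSpec.from_dict(r) for r in kw["lateral_regions"])
        if "rim_region" in kw:
            kw["rim_region"] = RegionSpec.from_dict(kw["rim_region"])
        if "offset_direction" in kw and kw["offset_direction"] is not None:
            kw["offset_direction"] = tuple(kw["offset_direction"])
        return cls(**kw)


@dataclass
class StageRecord:
    stage: str
    report_before: MeshReport | None
    report_after: MeshReport
    params: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "stage": self.stage,
            "report_before": self.report_before.to_dict() if self.report_before else None,
            "report_after": self.report_after.to_dict(),
            "params": self.params,
        }


@dataclass
class StageTrace:
    """Ordered record of pipeline stages actually executed."""

    records: list[StageRecord] = field(default_factory=list)

    def add(self, stage: str, before: SurfaceMesh | None, after: SurfaceMesh, **params) -> None:
        self.records.append(
            StageRecord(stage, report(before) if before is not None else None,
                        report(after), params)
        )

    @property
    def stages(self) -> list[str]:
        return [r.stage for r in self.records]

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps([r.to_dict() for r in self.records], indent=1))


# ---------------------------------------------------------------------------
# Shared geometry helpers
# ---------------------------------------------------------------------------

def mean_surface_normal(m: SurfaceMesh) -> np.ndarray:
    """Area-weighted mean unit normal of a surface patch."""
    n = (face_normals(m) * face_areas(m)[:, None]).sum(axis=0)
    norm = np.linalg.norm(n)
    if norm < 1e-12:
        raise MeshError("surface has no well-defined mean normal")
    return n / norm


def _bone_side_pivot(m: SurfaceMesh, jaw_up: np.ndarray) -> np.ndarray:
    """Centroid of the boundary vertices on the bone-contact side (the band
    nearest the bone along the occlusal axis)."""
    be = np.unique(np.concatenate([lp for lp in boundary_loops(m)]))
    if len(be) == 0:
        be = np.arange(len(m.vertices))
    verts = m.vertices[be]
    h = verts @ jaw_up
    band = h <= h.min() + 0.25 * max(h.max() - h.min(), 1e-9)
    return verts[band].mean(axis=0)


def _taper_rotation(m: SurfaceMesh, n_hat: np.ndarray, jaw_up: np.ndarray,
                    taper_deg: float) -> sg.RigidScale:
    """Rotation realizing the variable thickness: about a horizontal axis
    through the bone-side pivot, tilting the far (occlusal) side toward the
    inner surface so thickness decreases away from the bone contact."""
    axis = np.cross(n_hat, jaw_up)
    norm = np.linalg.norm(axis)
    if norm < 1e-8:
        raise MeshError("offset direction parallel to jaw axis: taper undefined")
    axis = axis / norm
    pivot = _bone_side_pivot(m, jaw_up)
    return sg.RigidScale(rotation_axis=tuple(axis), angle_deg=taper_deg,
                         pivot_mm=tuple(pivot))


def _largest_loop_bridge_points(m: SurfaceMesh, loop: np.ndarray):
    """Deterministic bridge endpoints: the (subsampled) vertex pair of the
    loop at maximal distance."""
    idx = loop if len(loop) <= 80 else loop[:: max(1, len(loop) // 80)]
    pts = m.vertices[idx]
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2)
    i, j = np.unravel_index(int(d2.argmax()), d2.shape)
    return pts[i], pts[j]


def close_surface(m: SurfaceMesh, fill_max_boundary_mm: float,
                  fairing_passes: int = 0, max_rounds: int = 200) -> SurfaceMesh:
    """Close all boundary loops: loops up to the fill limit are fan-filled
    smallest-first; a longer loop is first divided by a bridge (repeatedly),
    mirroring bridge-assisted hole filling."""
    out = m
    for _ in range(max_rounds):
        loops = boundary_loops(out)
        if not loops:
            return out
        lens = [loop_length(out, lp) for lp in loops]
        if min(lens) <= fill_max_boundary_mm:
            out = sg.fill_holes(out, fill_max_boundary_mm, fairing_passes)
            continue
        big = loops[int(np.argmax(lens))]
        pa, pb = _largest_loop_bridge_points(out, big)
        out = sg.bridge(out, pa, pb)
    raise MeshError("failed to close surface within the round limit")


def probe_thickness(inner: SurfaceMesh, outer: SurfaceMesh, direction,
                    max_samples: int = 200):
    """Ray-probe thickness: from inner-surface face centroids along the
    offset direction to the first outer-surface hit.

    Returns (sample_points, thickness) for the rays that hit; rays that
    miss the outer surface (patch edges) are dropped.
    """
    from ._meshmath import first_hit_distances

    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    cent = face_centroids(inner)
    step = max(1, len(cent) // max_samples)
    cent = cent[::step]
    origins = cent + 1e-6 * d
    dirs = np.tile(d, (len(origins), 1))
    dist = first_hit_distances(outer.vertices, outer.faces, origins, dirs)
    hit = np.isfinite(dist)
    return cent[hit], dist[hit]


def _pair_and_stitch(merged: SurfaceMesh, n_inner_vertices: int) -> SurfaceMesh:
    """Pair boundary loops of the inner part with loops of the outer part by
    centroid distance and zipper each pair."""
    out = merged
    while True:
        loops = boundary_loops(out)
        inner_loops = [lp for lp in loops if (lp < n_inner_vertices).all()]
        outer_loops = [lp for lp in loops if (lp >= n_inner_vertices).all()]
        if not inner_loops or not outer_loops:
            return out
        cents_i = [out.vertices[lp].mean(axis=0) for lp in inner_loops]
        cents_o = [out.vertices[lp].mean(axis=0) for lp in outer_loops]
        d = np.array([[np.linalg.norm(ci - co) for co in cents_o] for ci in cents_i])
        i, j = np.unravel_index(int(d.argmin()), d.shape)
        out = sg.stitch_loops(out, inner_loops[i], outer_loops[j])


# ---------------------------------------------------------------------------
# Block graft (stages A1..D2)
# ---------------------------------------------------------------------------

def design_block_graft(tissue: SurfaceMesh, p: ScaffoldParams):
    """Design a periodontal-defect customized block graft.

    Returns ``(scaffold, trace)``; the scaffold is watertight with positive
    volume, its inner surface congruent with the tissue inside
    ``p.inner_region``, offset by ``mean_thickness_mm`` (tapered when
    ``taper_deg > 0``), and scaled by ``export_scale`` about its centroid
    before return.
    """
    trace = StageTrace()

    def run(stage, fn, before, **params):
        try:
            after = fn()
        except (MeshError, ValueError) as exc:
            raise PipelineError(stage, str(exc)) from exc
        if after.n_faces == 0:
            raise PipelineError(stage, "empty intermediate mesh")
        trace.add(stage, before, after, **params)
        return after

    jaw_up = p.jaw_up

    a1 = run("A1", lambda: drop_boundary_pinches(
        sg.crop_by_region(tissue, p.inner_region)), tissue)
    a2 = a1
    if p.clean_min_component_faces > 0 or p.clean_smoothing_passes > 0:
        a2 = run("A2", lambda: clean_mesh(
            a1, p.clean_min_component_faces,
            ("taubin", p.clean_smoothing_passes) if p.clean_smoothing_passes else None,
        ), a1)
    inner = run("A3", lambda: sg.invert_normals(a2), a2)

    # outward defect direction: away from the tissue, i.e. the mean normal
    # of the tissue-wound crop (minus the mean normal of the inverted A3)
    if p.offset_direction is not None:
        n_hat = np.asarray(p.offset_direction, dtype=float)
        n_hat = n_hat / np.linalg.norm(n_hat)
    else:
        n_hat = -mean_surface_normal(inner)

    outer_src = sg.crop_by_region(a2, p.outer_region) if p.outer_region else a2
    outer = run(
        "B1",
        lambda: sg.translate(outer_src, p.mean_thickness_mm * n_hat),
        a2,
        thickness_mm=p.mean_thickness_mm,
        direction=[float(x) for x in n_hat],
    )
    if p.taper_deg > 0:
        rot = _taper_rotation(outer, n_hat, jaw_up, p.taper_deg)
        outer = run("B2", lambda: sg.transform(outer, rot), outer,
                    taper_deg=p.taper_deg, pivot=list(rot.pivot_mm))

    if p.lateral_regions:
        laterals = []
        for k, region in enumerate(p.lateral_regions):
            lat = run(f"B3.{k}", lambda region=region: sg.translate(
                sg.crop_by_region(a2, region), p.mean_thickness_mm * n_hat), a2)
            if p.taper_deg > 0:
                rot = _taper_rotation(lat, n_hat, jaw_up, p.taper_deg)
                lat = run(f"B4.{k}", lambda lat=lat, rot=rot: sg.transform(lat, rot), lat)
            laterals.append(lat)
        for lat in laterals:
            outer = run("B5", lambda lat=lat: merge_meshes(outer, lat, weld_tol_mm=1e-6), outer)
        outer = run("B6", lambda: sg.fill_holes(
            outer, 2.0 * p.mean_thickness_mm, p.fairing_passes), outer)

    outer = run("B7", lambda: drop_boundary_pinches(sg.trim_against(
        outer, inner, "above", n_hat, p.trim_tol_mm)), outer)

    if p.rim_region is not None:
        deficit = float((inner.vertices @ jaw_up).max() - (outer.vertices @ jaw_up).max())
        if deficit > 0.5 * p.mean_thickness_mm:
            outer = run("B8", lambda: sg.extend_patch(
                outer, p.rim_region, jaw_up * deficit), outer, deficit_mm=deficit)

    inner = run("C", lambda: drop_boundary_pinches(sg.trim_against(
        inner, outer, "below", jaw_up, p.trim_tol_mm)), inner)

    # plain concatenation (no weld) so the inner/outer loop partition by
    # vertex index survives into D2
    n_inner_vertices = len(inner.vertices)
    merged = run("D1", lambda: SurfaceMesh(
        np.vstack([inner.vertices, outer.vertices]),
        np.vstack([inner.faces, outer.faces + n_inner_vertices]),
        name="block_graft"), inner)

    def d2():
        closed = _pair_and_stitch(merged, n_inner_vertices)
        closed = close_surface(closed, p.fill_max_boundary_mm, p.fairing_passes)
        closed = sg.fix_orientation(remove_degenerate_faces(closed))
        if p.export_scale != 1.0:
            closed = sg.scale_about_centroid(closed, p.export_scale)
        return closed

    scaffold = run("D2", d2, merged, export_scale=p.export_scale)

    rep = report(scaffold)
    if not rep.watertight:
        loops = boundary_loops(scaffold)
        raise PipelineError(
            "D2",
            f"final mesh not watertight: {len(loops)} boundary loops of lengths "
            f"{[round(loop_length(scaffold, lp), 2) for lp in loops]}",
        )
    return scaffold, trace


# ---------------------------------------------------------------------------
# Socket graft (stages A1..B)
# ---------------------------------------------------------------------------

def default_socket_params(inner_region: RegionSpec, jaw: str = "mandibular",
                          **overrides) -> ScaffoldParams:
    """Socket-graft parameter set: export scale defaults to the recommended
    pre-export shrink of 0.98."""
    overrides.setdefault("export_scale", 0.98)
    return ScaffoldParams(jaw=jaw, inner_region=inner_region, **overrides)


def design_socket_graft(tissue: SurfaceMesh, p: ScaffoldParams):
    """Design an extraction-socket preservation graft: the complement of the
    socket cavity, closed by bridge-assisted hole filling.

    Returns ``(scaffold, trace)``. The tissue must expose the open cavity
    lining inside ``p.inner_region``.
    """
    trace = StageTrace()

    def run(stage, fn, before, **params):
        try:
            after = fn()
        except (MeshError, ValueError) as exc:
            raise PipelineError(stage, str(exc)) from exc
        if after.n_faces == 0:
            raise PipelineError(stage, "empty intermediate mesh")
        trace.add(stage, before, after, **params)
        return after

    a1 = run("A1", lambda: drop_boundary_pinches(
        sg.crop_by_region(tissue, p.inner_region)), tissue)
    a2 = a1
    if p.clean_min_component_faces > 0 or p.clean_smoothing_passes > 0:
        a2 = run("A2", lambda: clean_mesh(
            a1, p.clean_min_component_faces,
            ("taubin", p.clean_smoothing_passes) if p.clean_smoothing_passes else None,
        ), a1)
    inner = run("A3", lambda: sg.invert_normals(a2), a2)

    def stage_b():
        closed = close_surface(inner, p.fill_max_boundary_mm, p.fairing_passes)
        closed = sg.fix_orientation(remove_degenerate_faces(closed))
        if p.export_scale != 1.0:
            closed = sg.scale_about_centroid(closed, p.export_scale)
        return closed

    scaffold = run("B", stage_b, inner, export_scale=p.export_scale,
                   fill_max_boundary_mm=p.fill_max_boundary_mm)

    rep = report(scaffold)
    if not rep.watertight:
        loops = boundary_loops(scaffold)
        raise PipelineError(
            "B",
            f"final mesh not watertight: {len(loops)} boundary loops of lengths "
            f"{[round(loop_length(scaffold, lp), 2) for lp in loops]}",
        )
    return scaffold, trace


# ---------------------------------------------------------------------------
# Phantom-derived parameter sets
# ---------------------------------------------------------------------------

def phantom_block_params(spec, **overrides) -> ScaffoldParams:
    """Block-graft parameters for a phantom's wedge defect: the inner region
    is a box around the defect wedge, clear of the bone crest plane."""
    from .phantom import PhantomSpec  # noqa: F401  (type of `spec`)

    if spec.defect is None:
        raise ValueError("phantom spec has no defect; cannot derive block-graft regions")
    t = spec.teeth[spec.defect.tooth]
    cx, cy = t.center_xy_mm
    z_top = spec.bone_top_mm
    d = spec.defect
    r_outer = t.root_radius_mm + d.depth_mm * np.tan(np.radians(d.angle_deg))
    margin = 0.5
    # The graft plate seats on the bony (cone) wall of the wedge. The extra
    # buccal half-space clips off the near-vertical root wall and the sector
    # side walls, leaving a terrain-like patch with a well-defined offset
    # direction (its area-weighted mean normal).
    x0, x1 = cx - r_outer - margin, cx + r_outer + margin
    y0 = cy - r_outer - margin
    y1 = cy - t.root_radius_mm - spec.spacing_mm
    # seat the plate only where the wedge is wider than the plate: below
    # this depth the offset copy would poke through the root wall
    thickness = overrides.get("mean_thickness_mm", 1.0)
    flare = np.tan(np.radians(d.angle_deg))
    z0 = z_top - d.depth_mm + thickness / flare + 2 * spec.spacing_mm
    z1 = z_top - 0.2
    inner = RegionSpec("half_spaces", half_spaces=(
        ((x0, 0.0, 0.0), (-1.0, 0.0, 0.0)),
        ((x1, 0.0, 0.0), (1.0, 0.0, 0.0)),
        ((0.0, y0, 0.0), (0.0, -1.0, 0.0)),
        ((0.0, y1, 0.0), (0.0, 1.0, 0.0)),
        ((0.0, 0.0, z0), (0.0, 0.0, -1.0)),
        ((0.0, 0.0, z1), (0.0, 0.0, 1.0)),
    ))
    overrides.setdefault("jaw", "mandibular")
    return ScaffoldParams(inner_region=inner, **overrides)


def phantom_socket_params(spec, **overrides) -> ScaffoldParams:
    """Socket-graft parameters for a phantom's extraction socket: the inner
    region is a box around the cavity lining below the bone crest."""
    if spec.socket is None:
        raise ValueError("phantom spec has no socket; cannot derive socket-graft region")
    s = spec.socket
    cx, cy = s.center_xy_mm
    z_top = spec.bone_top_mm
    margin = 0.4
    inner = RegionSpec("box", box=(
        (cx - s.radius_mm - margin, cy - s.radius_mm - margin,
         z_top - s.depth_mm - margin),
        (cx + s.radius_mm + margin, cy + s.radius_mm + margin, z_top - 0.25),
    ))
    overrides.setdefault("jaw", "mandibular")
    overrides.setdefault("export_scale", 0.98)
    return ScaffoldParams(inner_region=inner, **overrides)


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

@dataclass
class ValidationReport:
    """Fit report for a designed scaffold against the tissue it must seat on
    (the graft must fill the defect without gaps)."""

    watertight: bool
    signed_volume_mm3: float
    max_gap_mm: float
    min_thickness_mm: float
    max_thickness_mm: float
    self_intersections: int
    boundary_loops: int

    def to_dict(self) -> dict:
        return {
            "watertight": self.watertight,
            "signed_volume_mm3": self.signed_volume_mm3,
            "max_gap_mm": self.max_gap_mm,
            "min_thickness_mm": self.min_thickness_mm,
            "max_thickness_mm": self.max_thickness_mm,
            "self_intersections": self.self_intersections,
            "boundary_loops": self.boundary_loops,
        }

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))


def count_self_intersections(m: SurfaceMesh, max_probes: int = 300) -> int:
    """Probe-resolution self-intersection count: casts a sample of face
    edges as segments against the mesh and counts interior hits on
    non-adjacent faces. Zero means none detected at this resolution, not a
    CSG-exact guarantee."""
    from ._meshmath import ray_hits

    edges = np.concatenate([m.faces[:, [0, 1]], m.faces[:, [1, 2]], m.faces[:, [2, 0]]])
    step = max(1, len(edges) // max_probes)
    edges = edges[::step]
    a = m.vertices[edges[:, 0]]
    b = m.vertices[edges[:, 1]]
    vec = b - a
    lens = np.linalg.norm(vec, axis=1)
    ok = lens > 1e-12
    a, vec, lens, edges = a[ok], vec[ok], lens[ok], edges[ok]
    dirs = vec / lens[:, None]
    eps = 1e-6
    ray_idx, tri_idx, ts = ray_hits(m.vertices, m.faces, a + eps * dirs, dirs)
    if len(ray_idx) == 0:
        return 0
    # faces touching either edge endpoint are adjacent, not intersections
    vert_faces: dict[int, set] = {}
    for fi, f in enumerate(m.faces):
        for v in f:
            vert_faces.setdefault(int(v), set()).add(fi)
    count = 0
    for ri, ti, t in zip(ray_idx, tri_idx, ts):
        if not (10 * eps < t < lens[ri] - 10 * eps):
            continue
        adjacent = vert_faces.get(int(edges[ri, 0]), set()) | vert_faces.get(int(edges[ri, 1]), set())
        if int(ti) not in adjacent:
            count += 1
    return count


def validate_scaffold(scaffold: SurfaceMesh, tissue: SurfaceMesh,
                      p: ScaffoldParams) -> ValidationReport:
    """Report how well a scaffold seats on the tissue.

    The inner (contact) surface is identified as the scaffold faces inside
    ``p.inner_region`` whose normals oppose the outward offset direction;
    the max gap is the largest distance from those face centroids to the
    tissue surface.
    """
    from ._meshmath import MeshDistanceQuery

    rep = report(scaffold)
    # outward direction from the tissue crop (as the pipelines define it)
    crop = sg.crop_by_region(tissue, p.inner_region)
    n_hat = (p.offset_direction / np.linalg.norm(p.offset_direction)
             if p.offset_direction is not None else mean_surface_normal(crop))
    n_hat = np.asarray(n_hat, dtype=float)

    cent = face_centroids(scaffold)
    normals = face_normals(scaffold)
    # contact faces oppose the offset direction; the -0.5 threshold keeps
    # flank (mantle) faces, which run along the offset, out of the gap stat
    inner_mask = p.inner_region.contains(cent) & (normals @ n_hat < -0.5)
    if inner_mask.any():
        samples = cent[inner_mask]
        _, dist, _ = MeshDistanceQuery(tissue.vertices, tissue.faces).closest(samples)
        max_gap = float(dist.max())
        inner_part = remove_unref_faces(scaffold, inner_mask)
        _, thick = probe_thickness(inner_part, scaffold, n_hat)
        thick = thick[thick > 1e-6]
        tmin = float(thick.min()) if len(thick) else float("nan")
        tmax = float(thick.max()) if len(thick) else float("nan")
    else:
        max_gap, tmin, tmax = float("nan"), float("nan"), float("nan")

    if rep.boundary_edge_count:
        try:
            n_loops = len(boundary_loops(scaffold))
        except MeshError:
            n_loops = -1  # non-manifold boundary
    else:
        n_loops = 0
    return ValidationReport(
        watertight=rep.watertight,
        signed_volume_mm3=rep.signed_volume_mm3,
        max_gap_mm=max_gap,
        min_thickness_mm=tmin,
        max_thickness_mm=tmax,
        self_intersections=count_self_intersections(scaffold),
        boundary_loops=n_loops,
    )


def remove_unref_faces(m: SurfaceMesh, face_mask: np.ndarray) -> SurfaceMesh:
    from dataclasses import replace as _replace

    from .meshing import remove_unreferenced

    return remove_unreferenced(_replace(m, faces=m.faces[face_mask]))
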