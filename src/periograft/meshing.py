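"""Label maps to surface meshes: marching-cubes extraction, cleaning,
merging, reporting, and STL I/O.

A :class:`SurfaceMesh` is a plain triangle mesh in millimetres with
counter-clockwise winding for outward normals. Meshes are open during
construction (crops, offsets) and watertight at export. STL is binary
little-endian by default, the 3D-printing toolchain convention.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import trimesh
from skimage import measure

from .volume_io import LabelVolume


class MeshError(ValueError):
    pass


# gentle Taubin step sizes: volume-safe (<1% drift) even on very coarse
# meshes where the umbrella operator is aggressive
TAUBIN_LAMB = 0.1
TAUBIN_NU = 0.11


@dataclass(frozen=True)
class SurfaceMesh:
    """Oriented triangle mesh: vertices (N, 3) mm, faces (M, 3) CCW-outward."""

    vertices: np.ndarray
    faces: np.ndarray
    name: str = ""

    def __post_init__(self):
        v = np.asarray(self.vertices, dtype=np.float64).reshape(-1, 3)
        f = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if len(f) and (f.min() < 0 or f.max() >= len(v)):
            raise MeshError("face indices out of range")
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "faces", f)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    @property
    def bounds(self) -> np.ndarray:
        """(2, 3) array of [min; max] vertex coordinates."""
        if len(self.vertices) == 0:
            return np.zeros((2, 3))
        return np.vstack([self.vertices.min(axis=0), self.vertices.max(axis=0)])

    def to_trimesh(self) -> trimesh.Trimesh:
        # process=False: keep vertex order and winding bit-exact
        return trimesh.Trimesh(self.vertices.copy(), self.faces.copy(), process=False)

    @classmethod
    def from_trimesh(cls, tm: trimesh.Trimesh, name: str = "") -> "SurfaceMesh":
        return cls(np.asarray(tm.vertices), np.asarray(tm.faces), name)


@dataclass(frozen=True)
class MeshReport:
    """Printable summary of a mesh (triangle count, closure, size)."""

    triangle_count: int
    boundary_edge_count: int
    connected_components: int
    watertight: bool
    signed_volume_mm3: float
    surface_area_mm2: float
    bbox_dims_mm: tuple[float, float, float]

    def to_dict(self) -> dict:
        return {
            "triangle_count": self.triangle_count,
            "boundary_edge_count": self.boundary_edge_count,
            "connected_components": self.connected_components,
            "watertight": self.watertight,
            "signed_volume_mm3": self.signed_volume_mm3,
            "surface_area_mm2": self.surface_area_mm2,
            "bbox_dims_mm": list(self.bbox_dims_mm),
        }


# ---------------------------------------------------------------------------
# Low-level mesh queries (shared with scaffold_geom)
# ---------------------------------------------------------------------------

def signed_volume(m: SurfaceMesh) -> float:
    """Signed enclosed volume via the divergence theorem; positive for
    consistently outward-wound closed meshes."""
    if m.n_faces == 0:
        return 0.0
    v0 = m.vertices[m.faces[:, 0]]
    v1 = m.vertices[m.faces[:, 1]]
    v2 = m.vertices[m.faces[:, 2]]
    return float(np.einsum("ij,ij->", v0, np.cross(v1, v2)) / 6.0)


def surface_area(m: SurfaceMesh) -> float:
    if m.n_faces == 0:
        return 0.0
    v0 = m.vertices[m.faces[:, 0]]
    v1 = m.vertices[m.faces[:, 1]]
    v2 = m.vertices[m.faces[:, 2]]
    return float(np.linalg.norm(np.cross(v1 - v0, v2 - v0), axis=1).sum() / 2.0)


def face_normals(m: SurfaceMesh) -> np.ndarray:
    v0 = m.vertices[m.faces[:, 0]]
    n = np.cross(m.vertices[m.faces[:, 1]] - v0, m.vertices[m.faces[:, 2]] - v0)
    lens = np.linalg.norm(n, axis=1)
    lens[lens == 0] = 1.0
    return n / lens[:, None]


def face_areas(m: SurfaceMesh) -> np.ndarray:
    v0 = m.vertices[m.faces[:, 0]]
    n = np.cross(m.vertices[m.faces[:, 1]] - v0, m.vertices[m.faces[:, 2]] - v0)
    return np.linalg.norm(n, axis=1) / 2.0


def face_centroids(m: SurfaceMesh) -> np.ndarray:
    return m.vertices[m.faces].mean(axis=1)


def directed_edges(m: SurfaceMesh) -> np.ndarray:
    """(3M, 2) directed edges in winding order."""
    f = m.faces
    return np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])


def boundary_edges(m: SurfaceMesh) -> np.ndarray:
    """Directed edges whose undirected pairing appears exactly once."""
    de = directed_edges(m)
    und = np.sort(de, axis=1)
    _, inv, counts = np.unique(und, axis=0, return_inverse=True, return_counts=True)
    return de[counts[inv] == 1]


def is_winding_consistent(m: SurfaceMesh) -> bool:
    """True iff every interior undirected edge is traversed exactly twice,
    once in each direction (2-manifold, consistent orientation)."""
    de = directed_edges(m)
    if len(de) == 0:
        return True
    und = np.sort(de, axis=1)
    uniq, inv, counts = np.unique(und, axis=0, return_inverse=True, return_counts=True)
    if counts.max(initial=0) > 2:
        return False
    # for doubly-used edges the two traversals must be opposite
    forward = (de == und).all(axis=1)  # directed edge equals its sorted form
    fw_count = np.bincount(inv, weights=forward, minlength=len(uniq))
    double = counts == 2
    return bool(np.all(fw_count[double] == 1))


def boundary_loops(m: SurfaceMesh) -> list[np.ndarray]:
    """Boundary loops as ordered vertex-index arrays (winding order).

    Raises :class:`MeshError` for a non-manifold boundary (a vertex with
    more than one outgoing boundary edge), listing the offending edges.
    """
    be = boundary_edges(m)
    if len(be) == 0:
        return []
    nxt: dict[int, int] = {}
    bad = []
    for u, v in be:
        if int(u) in nxt:
            bad.append((int(u), int(v)))
        nxt[int(u)] = int(v)
    if bad:
        raise MeshError(f"non-manifold boundary at edges {bad}")
    loops = []
    seen: set[int] = set()
    for start in sorted(nxt):
        if start in seen:
            continue
        loop = [start]
        seen.add(start)
        cur = nxt[start]
        while cur != start:
            if cur in seen or cur not in nxt:
                raise MeshError("boundary does not close into loops")
            loop.append(cur)
            seen.add(cur)
            cur = nxt[cur]
        loops.append(np.asarray(loop, dtype=np.int64))
    return loops


def drop_boundary_pinches(m: SurfaceMesh, max_rounds: int = 100) -> SurfaceMesh:
    """Remove faces incident to boundary 'pinch' vertices (vertices with
    more than one incoming or outgoing boundary edge), so the boundary
    decomposes into simple loops. Centroid-test crops of voxel surfaces
    routinely produce a few such pinches."""
    out = m
    for _ in range(max_rounds):
        be = boundary_edges(out)
        if len(be) == 0:
            return out
        u_out, c_out = np.unique(be[:, 0], return_counts=True)
        u_in, c_in = np.unique(be[:, 1], return_counts=True)
        bad = np.union1d(u_out[c_out > 1], u_in[c_in > 1])
        if len(bad) == 0:
            return out
        keep = ~np.isin(out.faces, bad).any(axis=1)
        if not keep.any():
            raise MeshError("boundary pinch repair removed every face")
        out = remove_unreferenced(replace(out, faces=out.faces[keep]))
    raise MeshError("could not repair boundary pinches")


def loop_length(m: SurfaceMesh, loop: np.ndarray) -> float:
    pts = m.vertices[loop]
    return float(np.linalg.norm(np.roll(pts, -1, axis=0) - pts, axis=1).sum())


def remove_unreferenced(m: SurfaceMesh) -> SurfaceMesh:
    used, inverse = np.unique(m.faces.ravel(), return_inverse=True)
    return replace(m, vertices=m.vertices[used], faces=inverse.reshape(-1, 3))


def remove_degenerate_faces(m: SurfaceMesh) -> SurfaceMesh:
    """Drop zero-area faces (repeated vertices or collinear)."""
    f = m.faces
    distinct = (f[:, 0] != f[:, 1]) & (f[:, 1] != f[:, 2]) & (f[:, 0] != f[:, 2])
    keep = distinct & (face_areas(m) > 0)
    return replace(m, faces=f[keep])


def connected_component_count(m: SurfaceMesh) -> int:
    if m.n_faces == 0:
        return 0
    tm = m.to_trimesh()
    labels = trimesh.graph.connected_component_labels(
        tm.face_adjacency, node_count=m.n_faces
    )
    return int(labels.max()) + 1


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def extract_surface(
    labels: LabelVolume,
    target_label: int | list[int],
    iso_smoothing_passes: int = 0,
) -> SurfaceMesh:
    """Marching-cubes isosurface of a label mask, in world millimetres.

    ``target_label`` may be a list to extract the union of several labels
    (e.g. teeth + bone as one hard-tissue solid). The mesh is closed and
    outward-oriented whenever the mask does not touch the grid boundary; a
    mask on the boundary yields open boundary edges, reported not hidden.
    """
    targets = np.atleast_1d(target_label)
    mask = np.isin(labels.labels, targets)
    if not mask.any():
        raise MeshError(f"label(s) {targets.tolist()} absent from label volume")
    verts, faces, _, _ = measure.marching_cubes(
        mask.astype(np.float32), level=0.5, spacing=labels.spacing_mm
    )
    mesh = SurfaceMesh(verts + np.asarray(labels.origin_mm), faces,
                       name=f"label_{'_'.join(map(str, targets.tolist()))}")
    mesh = remove_degenerate_faces(mesh)
    # enforce outward orientation on closed meshes
    if len(boundary_edges(mesh)) == 0 and signed_volume(mesh) < 0:
        mesh = replace(mesh, faces=mesh.faces[:, ::-1])
    if iso_smoothing_passes > 0:
        tm = mesh.to_trimesh()
        # one pass = a paired shrink/inflate step (odd step counts drift)
        trimesh.smoothing.filter_taubin(tm, lamb=TAUBIN_LAMB, nu=TAUBIN_NU,
                                        iterations=2 * iso_smoothing_passes)
        mesh = replace(mesh, vertices=np.asarray(tm.vertices))
    return mesh


def clean_mesh(
    m: SurfaceMesh,
    min_component_faces: int = 0,
    smoothing: tuple[str, int] | None = None,
    fill_max_boundary_mm: float = 0.0,
) -> SurfaceMesh:
    """Denoise a mesh: drop small components, smooth, close small holes.

    smoothing : ("taubin" | "laplacian", passes); taubin is volume-preserving
        and the default choice everywhere in the package.
    fill_max_boundary_mm : boundary loops shorter than this are triangulated
        closed (0 disables hole filling).
    """
    out = remove_degenerate_faces(m)
    if out.n_faces == 0:
        raise MeshError("mesh has no non-degenerate faces")
    if min_component_faces > 0:
        tm = out.to_trimesh()
        comp = trimesh.graph.connected_component_labels(
            tm.face_adjacency, node_count=out.n_faces
        )
        sizes = np.bincount(comp)
        keep = sizes[comp] >= min_component_faces
        if not keep.any():
            raise MeshError(
                f"all components smaller than min_component_faces={min_component_faces}"
            )
        out = remove_unreferenced(replace(out, faces=out.faces[keep]))
    if smoothing is not None:
        kind, passes = smoothing
        if passes > 0:
            tm = out.to_trimesh()
            if kind == "taubin":
                trimesh.smoothing.filter_taubin(tm, lamb=TAUBIN_LAMB, nu=TAUBIN_NU,
                                                iterations=2 * passes)
            elif kind == "laplacian":
                trimesh.smoothing.filter_laplacian(tm, iterations=passes)
            else:
                raise MeshError(f"unknown smoothing kind {kind!r}")
            out = replace(out, vertices=np.asarray(tm.vertices))
    if fill_max_boundary_mm > 0:
        from .scaffold_geom import fill_holes  # late import avoids cycle at module load

        out = fill_holes(out, fill_max_boundary_mm, fairing_passes=0)
    return out


def merge_meshes(a: SurfaceMesh, b: SurfaceMesh, weld_tol_mm: float = 0.0) -> SurfaceMesh:
    """Concatenate two meshes, welding duplicate vertices within tolerance.

    ``weld_tol_mm = 0`` welds exactly equal coordinates only. Face windings
    are preserved; degenerate faces created by welding are dropped.
    """
    if a.n_faces == 0:
        return b
    if b.n_faces == 0:
        return a
    verts = np.concatenate([a.vertices, b.vertices])
    faces = np.concatenate([a.faces, b.faces + len(a.vertices)])
    if weld_tol_mm > 0:
        key = np.round(verts / weld_tol_mm).astype(np.int64)
    else:
        key = verts
    _, first, inverse = np.unique(key, axis=0, return_index=True, return_inverse=True)
    merged = SurfaceMesh(verts[first], inverse[faces], name=a.name or b.name)
    return remove_unreferenced(remove_degenerate_faces(merged))


def report(m: SurfaceMesh) -> MeshReport:
    """Pure summary; never mutates the mesh. ``watertight`` requires every
    edge shared by exactly two consistently wound faces and positive signed
    volume (an inside-out mesh is not print-ready)."""
    n_boundary = len(boundary_edges(m))
    vol = signed_volume(m)
    wt = n_boundary == 0 and is_winding_consistent(m) and vol > 0 and m.n_faces > 0
    dims = (m.bounds[1] - m.bounds[0]) if m.n_faces else np.zeros(3)
    return MeshReport(
        triangle_count=m.n_faces,
        boundary_edge_count=n_boundary,
        connected_components=connected_component_count(m),
        watertight=bool(wt),
        signed_volume_mm3=vol,
        surface_area_mm2=surface_area(m),
        bbox_dims_mm=tuple(float(d) for d in dims),
    )


def write_report(m: SurfaceMesh, path) -> MeshReport:
    rep = report(m)
    Path(path).write_text(json.dumps(rep.to_dict(), indent=1))
    return rep


def write_stl(m: SurfaceMesh, path, binary: bool = True) -> None:
    tm = m.to_trimesh()
    file_type = "stl" if binary else "stl_ascii"
    data = trimesh.exchange.stl.export_stl(tm) if binary else \
        trimesh.exchange.stl.export_stl_ascii(tm).encode()
    Path(path).write_bytes(data)


def read_stl(path) -> SurfaceMesh:
    """Read binary or ASCII STL as a raw triangle soup (no vertex merging,
    so a write/read round trip preserves per-face coordinates exactly)."""
    p = Path(path)
    if not p.exists():
        raise MeshError(f"no such STL file: {p}")
    try:
        with open(p, "rb") as fh:
            data = trimesh.exchange.stl.load_stl(fh)
    except Exception as exc:
        raise MeshError(f"failed to parse STL {p}: {exc}") from exc
    if "vertices" not in data or "faces" not in data or len(data["vertices"]) == 0:
        raise MeshError(f"not a valid STL file: {p}")
    # weld exactly equal coordinates so the topology (watertightness,
    # boundary loops) survives the STL triangle-soup round trip; per-face
    # vertex coordinates are unchanged
    verts = np.asarray(data["vertices"], dtype=np.float64)
    uniq, first, inverse = np.unique(verts, axis=0, return_index=True, return_inverse=True)
    return SurfaceMesh(uniq, inverse[np.asarray(data["faces"])], name=p.stem)
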