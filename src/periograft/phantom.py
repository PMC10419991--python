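"""Synthetic jaw phantom: a CBCT-like volume with ground truth.

The phantom emulates the anatomy the graft-design workflow assumes: a block
of alveolar bone with embedded high-intensity teeth, an optional wedge-shaped
peri-root periodontal defect, and an optional empty extraction socket. Each
tissue class renders at a distinct mean intensity; partial-volume blur and
additive Gaussian noise are applied on top. Ground-truth labels and the
exact cavity masks are exported so every downstream stage (seeding, region
growing, meshing, scaffold design) is testable without patient data.

Geometry conventions: the grid is indexed (x, y, z) with z the jaw axis
(occlusal direction is +z for a mandibular phantom). Teeth are vertical:
a root cylinder embedded in bone topped by a wider crown above the bone
crest. The periodontal defect is an azimuthal sector of an annular cone
flaring upward around one tooth's root (missing bone); the extraction
socket is a cylindrical cavity with a hemispherical floor (a tooth-shaped
void). Cavity voxels carry the "other" label, matching the clinical picture
of missing bone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml
from scipy import ndimage

from .volume_io import LabelVolume, SeedSet, VoxelVolume

LABEL_TEETH = 1
LABEL_BONE = 2
LABEL_OTHER = 3

# fraction of a tooth's height that is root (embedded in bone)
ROOT_FRACTION = 0.65


class PhantomSpecError(ValueError):
    """Invalid phantom specification; the message names the offending field."""


@dataclass(frozen=True)
class ToothSpec:
    """A tooth: root cylinder below the bone crest, crown cylinder with a
    hemispherical cap above it."""

    center_xy_mm: tuple[float, float]
    root_radius_mm: float
    crown_radius_mm: float
    height_mm: float


@dataclass(frozen=True)
class DefectSpec:
    """Peri-root wedge defect: an azimuthal sector of an annular cone.

    The apex sits ``depth_mm`` below the bone crest on the root surface of
    tooth ``tooth``; the wedge flares at ``angle_deg`` from the root surface
    so its outer radius at the crest is ``root_radius + depth * tan(angle)``.
    ``azimuth_deg``/``azimuth_width_deg`` restrict it to one side of the
    tooth (periodontal defects are typically localized, not circumferential).
    """

    tooth: int = 0
    depth_mm: float = 4.0
    angle_deg: float = 30.0
    azimuth_deg: float = -90.0
    azimuth_width_deg: float = 150.0


@dataclass(frozen=True)
class SocketSpec:
    """Empty extraction socket: vertical cylinder from the bone crest with a
    hemispherical floor, total depth ``depth_mm``."""

    center_xy_mm: tuple[float, float]
    radius_mm: float = 2.0
    depth_mm: float = 8.0


@dataclass(frozen=True)
class PhantomSpec:
    """Full phantom description; defaults give the packaged study phantom.

    ``spacing_mm`` defaults to 0.15 (a 150 um CBCT voxel). ``bone_box`` is
    ``((x0, y0, z0), (x1, y1, z1))`` in mm. Intensity means must be strictly
    ordered air < bone < tooth.
    """

    grid_shape: tuple[int, int, int] = (128, 128, 128)
    spacing_mm: float = 0.15
    bone_box: tuple[tuple[float, float, float], tuple[float, float, float]] = (
        (1.0, 4.0, 1.0),
        (18.2, 15.0, 11.0),
    )
    teeth: tuple[ToothSpec, ...] = (
        ToothSpec((6.0, 9.6), 1.3, 2.2, 10.0),
        ToothSpec((10.8, 9.6), 1.3, 2.2, 10.0),
    )
    defect: DefectSpec | None = DefectSpec(tooth=0)
    socket: SocketSpec | None = SocketSpec(center_xy_mm=(15.2, 9.6))
    intensities: dict = field(
        default_factory=lambda: {"air": 0.0, "bone": 600.0, "tooth": 1600.0}
    )
    noise_sd: float = 25.0
    blur_sigma_mm: float = 0.15

    def __post_init__(self):
        gs = tuple(int(n) for n in self.grid_shape)
        if len(gs) != 3 or any(n < 8 for n in gs):
            raise PhantomSpecError(f"grid_shape: all axes must be >= 8, got {gs}")
        object.__setattr__(self, "grid_shape", gs)
        if not self.spacing_mm > 0:
            raise PhantomSpecError(f"spacing_mm must be > 0, got {self.spacing_mm}")
        (x0, y0, z0), (x1, y1, z1) = self.bone_box
        if not (x0 < x1 and y0 < y1 and z0 < z1):
            raise PhantomSpecError(f"bone_box: lower corner must be below upper, got {self.bone_box}")
        ints = self.intensities
        for key in ("air", "bone", "tooth"):
            if key not in ints:
                raise PhantomSpecError(f"intensities: missing key {key!r}")
        if not ints["air"] < ints["bone"] < ints["tooth"]:
            raise PhantomSpecError(
                "intensities: means must be strictly ordered air < bone < tooth, "
                f"got {ints}"
            )
        if self.noise_sd < 0:
            raise PhantomSpecError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.blur_sigma_mm < 0:
            raise PhantomSpecError(f"blur_sigma_mm must be >= 0, got {self.blur_sigma_mm}")
        teeth = tuple(
            t if isinstance(t, ToothSpec) else ToothSpec(*t) for t in self.teeth
        )
        object.__setattr__(self, "teeth", teeth)
        for n, t in enumerate(teeth):
            if not 0 < t.root_radius_mm <= t.crown_radius_mm:
                raise PhantomSpecError(
                    f"teeth[{n}]: require 0 < root_radius <= crown_radius"
                )
            if t.height_mm <= 0:
                raise PhantomSpecError(f"teeth[{n}]: height_mm must be > 0")
        if self.defect is not None:
            d = self.defect
            if not 0 <= d.tooth < len(teeth):
                raise PhantomSpecError(f"defect.tooth: no tooth with index {d.tooth}")
            if d.depth_mm <= 0 or d.depth_mm >= z1 - z0:
                raise PhantomSpecError("defect.depth_mm must lie within the bone height")
            if not 0 < d.angle_deg < 80:
                raise PhantomSpecError(f"defect.angle_deg out of range: {d.angle_deg}")
            if not 0 < d.azimuth_width_deg <= 360:
                raise PhantomSpecError("defect.azimuth_width_deg must be in (0, 360]")
        if self.socket is not None:
            s = self.socket
            if s.radius_mm <= 0 or s.depth_mm <= s.radius_mm:
                raise PhantomSpecError("socket: require radius_mm > 0 and depth_mm > radius_mm")

    @property
    def bone_top_mm(self) -> float:
        return self.bone_box[1][2]

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        d = dict(d)
        if d.get("teeth") is not None:
            d["teeth"] = tuple(
                ToothSpec(tuple(t["center_xy_mm"]), t["root_radius_mm"],
                          t["crown_radius_mm"], t["height_mm"])
                if isinstance(t, dict) else ToothSpec(*t)
                for t in d["teeth"]
            )
        if d.get("defect") is not None and isinstance(d["defect"], dict):
            d["defect"] = DefectSpec(**d["defect"])
        if d.get("socket") is not None and isinstance(d["socket"], dict):
            s = dict(d["socket"])
            s["center_xy_mm"] = tuple(s["center_xy_mm"])
            d["socket"] = SocketSpec(**s)
        if "bone_box" in d:
            d["bone_box"] = (tuple(d["bone_box"][0]), tuple(d["bone_box"][1]))
        if "grid_shape" in d:
            d["grid_shape"] = tuple(d["grid_shape"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PhantomSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def default_phantom_spec(noiseless: bool = False, **overrides) -> PhantomSpec:
    """The packaged study phantom; ``noiseless=True`` zeroes noise and blur."""
    if noiseless:
        overrides.setdefault("noise_sd", 0.0)
        overrides.setdefault("blur_sigma_mm", 0.0)
    return PhantomSpec(**overrides)


@dataclass(frozen=True)
class PhantomOutput:
    """Rendered phantom: image, ground truth, cavity masks, default seeds."""

    volume: VoxelVolume
    truth: LabelVolume
    default_seeds: SeedSet
    defect_mask: np.ndarray | None
    socket_mask: np.ndarray | None
    spec: PhantomSpec


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def _coordinate_grids(spec: PhantomSpec):
    """World-coordinate (mm) grids of voxel centers, one per axis."""
    nx, ny, nz = spec.grid_shape
    s = spec.spacing_mm
    x = (np.arange(nx) * s)[:, None, None]
    y = (np.arange(ny) * s)[None, :, None]
    z = (np.arange(nz) * s)[None, None, :]
    return x, y, z


def _truth_labels(spec: PhantomSpec):
    x, y, z = _coordinate_grids(spec)
    labels = np.full(spec.grid_shape, LABEL_OTHER, dtype=np.int8)

    (x0, y0, z0), (x1, y1, z1) = spec.bone_box
    bone = (x >= x0) & (x < x1) & (y >= y0) & (y < y1) & (z >= z0) & (z < z1)
    labels[np.broadcast_to(bone, spec.grid_shape)] = LABEL_BONE

    z_top = spec.bone_top_mm
    for t in spec.teeth:
        cx, cy = t.center_xy_mm
        r2 = (x - cx) ** 2 + (y - cy) ** 2
        root_len = ROOT_FRACTION * t.height_mm
        crown_len = t.height_mm - root_len
        root = (r2 <= t.root_radius_mm**2) & (z >= z_top - root_len) & (z < z_top)
        # crown: cylinder with hemispherical cap
        cap_base = z_top + max(crown_len - t.crown_radius_mm, 0.0)
        crown_cyl = (r2 <= t.crown_radius_mm**2) & (z >= z_top) & (z < cap_base)
        cap = (r2 + (z - cap_base) ** 2 <= t.crown_radius_mm**2) & (z >= cap_base)
        labels[root | crown_cyl | cap] = LABEL_TEETH

    defect_mask = None
    if spec.defect is not None:
        d = spec.defect
        t = spec.teeth[d.tooth]
        cx, cy = t.center_xy_mm
        r = np.sqrt((x - cx) ** 2 + (y - cy) ** 2)
        z_apex = z_top - d.depth_mm
        flare = np.tan(math.radians(d.angle_deg))
        outer = t.root_radius_mm + np.clip(z - z_apex, 0, None) * flare
        az = np.degrees(np.arctan2(y - cy, x - cx))
        daz = (az - d.azimuth_deg + 180.0) % 360.0 - 180.0
        wedge = (
            (r > t.root_radius_mm)
            & (r <= outer)
            & (z > z_apex)
            & (np.abs(np.broadcast_to(daz, spec.grid_shape)) <= d.azimuth_width_deg / 2)
        )
        defect_mask = wedge & (labels == LABEL_BONE)
        labels[defect_mask] = LABEL_OTHER

    socket_mask = None
    if spec.socket is not None:
        s = spec.socket
        cx, cy = s.center_xy_mm
        r2 = (x - cx) ** 2 + (y - cy) ** 2
        floor = z_top - s.depth_mm + s.radius_mm  # hemisphere center height
        cyl = (r2 <= s.radius_mm**2) & (z >= floor) & (z < z_top)
        hemi = (r2 + (z - floor) ** 2 <= s.radius_mm**2) & (z < floor)
        cavity = np.broadcast_to(cyl | hemi, spec.grid_shape)
        socket_mask = cavity & (labels == LABEL_BONE)
        labels[socket_mask] = LABEL_OTHER

    return labels, defect_mask, socket_mask


def _render_volume(spec: PhantomSpec, labels: np.ndarray, rng_seed: int) -> VoxelVolume:
    lut = np.zeros(4, dtype=np.float32)
    lut[LABEL_OTHER] = spec.intensities["air"]
    lut[LABEL_BONE] = spec.intensities["bone"]
    lut[LABEL_TEETH] = spec.intensities["tooth"]
    values = lut[labels]
    if spec.blur_sigma_mm > 0:
        values = ndimage.gaussian_filter(values, spec.blur_sigma_mm / spec.spacing_mm)
    lo, hi = float(values.min()), float(values.max())
    if spec.noise_sd > 0:
        rng = np.random.default_rng(rng_seed)
        values = values + rng.normal(0.0, spec.noise_sd, size=values.shape).astype(np.float32)
        values = np.clip(values, lo, hi)
    return VoxelVolume(values.astype(np.float32), (spec.spacing_mm,) * 3)


def _default_seeds(labels: np.ndarray, per_plane: int = 10, erosion: int = 2) -> SeedSet:
    """Seeds by 2-voxel erosion of the truth restricted to ~10 slices per
    reference plane (mirrors the small manual sample subset of the original
    workflow while remaining reproducible)."""
    from .volume_io import sample_slice_mask

    sel = sample_slice_mask(labels.shape, per_plane)
    idx_list, lab_list = [], []
    for lab in (LABEL_TEETH, LABEL_BONE, LABEL_OTHER):
        mask = labels == lab
        eroded = ndimage.binary_erosion(mask, iterations=erosion, border_value=1)
        ijk = np.argwhere(eroded & sel)
        idx_list.append(ijk)
        lab_list.append(np.full(len(ijk), lab, dtype=np.int64))
    idx = np.concatenate(idx_list)
    lab = np.concatenate(lab_list)
    return SeedSet(idx, lab, np.ones(len(lab)))


def generate_phantom(spec: PhantomSpec, rng_seed: int = 0) -> PhantomOutput:
    """Render the phantom deterministically for a fixed (spec, rng_seed).

    The ground-truth geometry depends only on ``spec``; the seed only drives
    the additive noise. Defect and socket voxels carry the "other" label
    (they are missing bone), and the exact flipped-voxel masks are returned
    so cavity volumes can be measured independently of the label map.
    """
    labels, defect_mask, socket_mask = _truth_labels(spec)
    volume = _render_volume(spec, labels, rng_seed)
    truth = LabelVolume(labels, volume.spacing_mm, volume.origin_mm)
    seeds = _default_seeds(labels)
    return PhantomOutput(volume, truth, seeds, defect_mask, socket_mask, spec)


def cavity_volume(phantom: PhantomOutput, which: str) -> float:
    """Voxel-counted volume (mm^3) of the requested cavity.

    ``which`` is ``"defect"`` or ``"socket"``. This is the oracle against
    which scaffold volumes are judged: count of cavity voxels times the
    voxel volume.
    """
    if which not in ("defect", "socket"):
        raise ValueError(f"which must be 'defect' or 'socket', got {which!r}")
    mask = phantom.defect_mask if which == "defect" else phantom.socket_mask
    if mask is None:
        raise ValueError(f"phantom has no such cavity: {which}")
    return float(mask.sum()) * phantom.truth.voxel_volume_mm3
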