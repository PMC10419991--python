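"""Volume containers and I/O: reading scans, cropping to a region of
interest, and deriving threshold-based seed candidates.

Conventions
-----------
* Voxel indexing is 0-based and half-open; arrays are indexed ``(i, j, k)``
  corresponding to the world axes ``(x, y, z)``.
* The world frame is LPS-style (the native frame of ITK readers); the world
  coordinate of voxel ``(i, j, k)`` center is ``origin + spacing * (i, j, k)``.
* Label semantics throughout the package: 0 unlabeled, 1 teeth,
  2 alveolar bone, 3 other (air, soft tissue, and missing-bone cavities).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import SimpleITK as sitk

VALID_LABELS = (0, 1, 2, 3)
SEED_LABELS = (1, 2, 3)


class VolumeError(ValueError):
    """Raised for invalid volume geometry, metadata, or file content."""


@dataclass(frozen=True)
class VoxelVolume:
    """A 3D scalar grid with physical geometry (a CBCT-like image).

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        Scalar intensities.
    spacing_mm : tuple of 3 floats
        Per-axis voxel size in millimetres, strictly positive.
    origin_mm : tuple of 3 floats
        World position of the center of voxel (0, 0, 0).
    axis_orientation : str
        Named world-frame convention; only "LPS" is produced by this package.
    """

    values: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis_orientation: str = "LPS"

    def __post_init__(self):
        v = np.asarray(self.values)
        if v.ndim != 3:
            raise VolumeError(f"values must be 3D, got shape {v.shape}")
        if any(s < 1 for s in v.shape):
            raise VolumeError(f"each axis must have >= 1 voxel, got {v.shape}")
        sp = tuple(float(s) for s in self.spacing_mm)
        if len(sp) != 3 or any(s <= 0 for s in sp):
            raise VolumeError(f"spacing_mm must be 3 positive floats, got {self.spacing_mm}")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "spacing_mm", sp)
        object.__setattr__(self, "origin_mm", tuple(float(o) for o in self.origin_mm))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))

    def voxel_to_world(self, ijk) -> np.ndarray:
        """World coordinates (mm) of voxel center(s) ``ijk`` (..., 3)."""
        ijk = np.asarray(ijk, dtype=float)
        return np.asarray(self.origin_mm) + ijk * np.asarray(self.spacing_mm)

    def world_to_voxel(self, xyz) -> np.ndarray:
        """Continuous voxel coordinates of world point(s) ``xyz``; inverse of
        :meth:`voxel_to_world`."""
        xyz = np.asarray(xyz, dtype=float)
        return (xyz - np.asarray(self.origin_mm)) / np.asarray(self.spacing_mm)


@dataclass(frozen=True)
class LabelVolume:
    """Integer label grid sharing geometry with its source VoxelVolume."""

    labels: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis_orientation: str = "LPS"

    def __post_init__(self):
        lab = np.asarray(self.labels)
        if lab.ndim != 3:
            raise VolumeError(f"labels must be 3D, got shape {lab.shape}")
        if not np.issubdtype(lab.dtype, np.integer):
            lab = lab.astype(np.int8)
        present = set(np.unique(lab).tolist())
        if not present.issubset(set(VALID_LABELS)):
            raise VolumeError(f"labels must be within {VALID_LABELS}, found {sorted(present)}")
        object.__setattr__(self, "labels", lab)
        object.__setattr__(self, "spacing_mm", tuple(float(s) for s in self.spacing_mm))
        object.__setattr__(self, "origin_mm", tuple(float(o) for o in self.origin_mm))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))

    def same_geometry_as(self, other) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing_mm, other.spacing_mm)
            and np.allclose(self.origin_mm, other.origin_mm)
        )


@dataclass(frozen=True)
class SeedSet:
    """Sparse labeled seed cells with per-cell strength in (0, 1].

    Represents both thresholding output and "manual" seed painting; manual
    editing is modelled as SeedSet files merged later-wins (see :meth:`merge`).
    """

    indices: np.ndarray  # (N, 3) int
    labels: np.ndarray  # (N,) int, in SEED_LABELS
    strengths: np.ndarray  # (N,) float in (0, 1]

    def __post_init__(self):
        idx = np.atleast_2d(np.asarray(self.indices, dtype=np.int64))
        if idx.size == 0:
            idx = idx.reshape(0, 3)
        lab = np.asarray(self.labels, dtype=np.int64).ravel()
        st = np.asarray(self.strengths, dtype=np.float64).ravel()
        if idx.shape != (len(lab), 3) or len(lab) != len(st):
            raise VolumeError("indices/labels/strengths lengths disagree")
        if len(lab) and not np.isin(lab, SEED_LABELS).all():
            raise VolumeError(f"seed labels must be in {SEED_LABELS}")
        if len(st) and not ((st > 0) & (st <= 1)).all():
            raise VolumeError("seed strengths must lie in (0, 1]")
        object.__setattr__(self, "indices", idx)
        object.__setattr__(self, "labels", lab)
        object.__setattr__(self, "strengths", st)

    def __len__(self) -> int:
        return len(self.labels)

    @classmethod
    def empty(cls) -> "SeedSet":
        return cls(np.zeros((0, 3), dtype=np.int64), np.zeros(0, dtype=np.int64), np.zeros(0))

    def validate_in_grid(self, shape) -> None:
        if len(self) == 0:
            return
        if (self.indices < 0).any() or (self.indices >= np.asarray(shape)).any():
            raise VolumeError(f"seed indices fall outside grid shape {tuple(shape)}")

    def merge(self, corrections: "SeedSet") -> "SeedSet":
        """Merge with ``corrections`` applied later-wins per voxel."""
        idx = np.concatenate([self.indices, corrections.indices])
        lab = np.concatenate([self.labels, corrections.labels])
        st = np.concatenate([self.strengths, corrections.strengths])
        # keep the LAST occurrence of every (i,j,k)
        keep = {}
        for n, cell in enumerate(map(tuple, idx)):
            keep[cell] = n
        order = sorted(keep.values())
        return SeedSet(idx[order], lab[order], st[order])

    def to_json(self, path) -> None:
        cells = [
            [int(i), int(j), int(k), int(l), float(s)]
            for (i, j, k), l, s in zip(self.indices, self.labels, self.strengths)
        ]
        Path(path).write_text(json.dumps({"cells": cells}, indent=1))

    @classmethod
    def from_json(cls, path) -> "SeedSet":
        data = json.loads(Path(path).read_text())
        cells = np.asarray(data["cells"], dtype=float)
        if cells.size == 0:
            return cls.empty()
        return cls(cells[:, :3].astype(np.int64), cells[:, 3].astype(np.int64), cells[:, 4])


@dataclass(frozen=True)
class RoiBox:
    """Axis-aligned crop region in 0-based half-open voxel indices."""

    lower: tuple[int, int, int]
    upper: tuple[int, int, int]

    def __post_init__(self):
        lo = tuple(int(x) for x in self.lower)
        up = tuple(int(x) for x in self.upper)
        if len(lo) != 3 or len(up) != 3:
            raise VolumeError("RoiBox lower/upper must have 3 entries")
        if any(l < 0 for l in lo) or any(l >= u for l, u in zip(lo, up)):
            raise VolumeError(f"RoiBox requires 0 <= lower < upper, got {lo} .. {up}")
        object.__setattr__(self, "lower", lo)
        object.__setattr__(self, "upper", up)

    def validate_for(self, shape) -> None:
        if any(u > s for u, s in zip(self.upper, shape)):
            raise VolumeError(f"RoiBox upper {self.upper} exceeds volume shape {tuple(shape)}")


# ---------------------------------------------------------------------------
# File I/O (SimpleITK behind everything; ITK images are natively LPS)
# ---------------------------------------------------------------------------

def _from_sitk(img: sitk.Image) -> VoxelVolume:
    arr = sitk.GetArrayFromImage(img)  # (z, y, x)
    values = np.ascontiguousarray(arr.transpose(2, 1, 0))
    return VoxelVolume(values, tuple(img.GetSpacing()), tuple(img.GetOrigin()))


def _to_sitk(v: VoxelVolume) -> sitk.Image:
    img = sitk.GetImageFromArray(np.ascontiguousarray(v.values.transpose(2, 1, 0)))
    img.SetSpacing(v.spacing_mm)
    img.SetOrigin(v.origin_mm)
    return img


def read_volume(path, format: str | None = None) -> VoxelVolume:
    """Read a scan from a DICOM series directory, NIfTI, or NRRD file.

    ``format`` may be one of ``{"dicom_dir", "nifti", "nrrd"}``; when omitted
    it is inferred (directory -> DICOM series, else by file suffix). A DICOM
    directory containing more than one series is rejected, naming the UIDs.
    """
    p = Path(path)
    if not p.exists():
        raise VolumeError(f"no such path: {p}")
    if format is None:
        if p.is_dir():
            format = "dicom_dir"
        elif p.suffix in (".nii", ".gz") or str(p).endswith(".nii.gz"):
            format = "nifti"
        elif p.suffix in (".nrrd", ".nhdr"):
            format = "nrrd"
        else:
            raise VolumeError(f"cannot infer volume format from {p.name}")
    if format == "dicom_dir":
        reader = sitk.ImageSeriesReader()
        series = reader.GetGDCMSeriesIDs(str(p))
        if not series:
            raise VolumeError(f"no DICOM series found under {p}")
        if len(series) > 1:
            raise VolumeError(
                "directory contains multiple DICOM series: " + ", ".join(series)
            )
        reader.SetFileNames(reader.GetGDCMSeriesFileNames(str(p), series[0]))
        img = reader.Execute()
        if img.GetNumberOfComponentsPerPixel() != 1:
            img = sitk.VectorIndexSelectionCast(img, 0)
        return _from_sitk(img)
    if format in ("nifti", "nrrd"):
        try:
            return _from_sitk(sitk.ReadImage(str(p)))
        except RuntimeError as exc:  # ITK raises RuntimeError for bad files
            raise VolumeError(f"failed to read {p}: {exc}") from exc
    raise VolumeError(f"unknown format {format!r}")


def write_volume(v: VoxelVolume | LabelVolume, path) -> None:
    """Write a volume as NIfTI (.nii/.nii.gz) or NRRD, by file suffix."""
    if isinstance(v, LabelVolume):
        v = VoxelVolume(v.labels.astype(np.uint8), v.spacing_mm, v.origin_mm)
    sitk.WriteImage(_to_sitk(v), str(Path(path)))


# ---------------------------------------------------------------------------
# ROI cropping and threshold seeding
# ---------------------------------------------------------------------------

def crop_volume(v: VoxelVolume, roi: RoiBox) -> VoxelVolume:
    """Crop to ``roi``; values are copied unchanged, origin shifts by
    ``lower * spacing``."""
    roi.validate_for(v.shape)
    lo, up = roi.lower, roi.upper
    sub = v.values[lo[0]:up[0], lo[1]:up[1], lo[2]:up[2]].copy()
    origin = tuple(o + l * s for o, l, s in zip(v.origin_mm, lo, v.spacing_mm))
    return replace(v, values=sub, origin_mm=origin)


def crop_labels(lv: LabelVolume, roi: RoiBox) -> LabelVolume:
    """Crop a label volume with the same geometry rule as :func:`crop_volume`."""
    roi.validate_for(lv.shape)
    lo, up = roi.lower, roi.upper
    sub = lv.labels[lo[0]:up[0], lo[1]:up[1], lo[2]:up[2]].copy()
    origin = tuple(o + l * s for o, l, s in zip(lv.origin_mm, lo, lv.spacing_mm))
    return LabelVolume(sub, lv.spacing_mm, origin)


def sample_slice_mask(shape, per_plane: int | None) -> np.ndarray:
    """Boolean mask selecting ``per_plane`` evenly spaced slices along each of
    the three reference planes (axial/coronal/sagittal); ``None`` selects all
    voxels."""
    if per_plane is None:
        return np.ones(shape, dtype=bool)
    mask = np.zeros(shape, dtype=bool)
    for axis, n in enumerate(shape):
        picks = np.unique(np.linspace(0, n - 1, min(per_plane, n)).round().astype(int))
        sl = [slice(None)] * 3
        sl[axis] = picks
        mask[tuple(sl)] = True
    return mask


def threshold_seeds(
    v: VoxelVolume,
    ranges: dict[int, tuple[float, float]],
    sample_slices: int | None = 10,
) -> SeedSet:
    """Seed candidates by intensity thresholding on a small slice subset.

    On the selected slices only, a voxel with value in ``(lo, hi]`` receives
    that label at strength 1. Ranges must not overlap. ``sample_slices`` is
    the number of evenly spaced slices taken per reference plane (the manual
    workflow this replaces used ~10 per plane); ``None`` means every voxel.
    """
    items = sorted(ranges.items())
    for lab, (lo, hi) in items:
        if lab not in SEED_LABELS:
            raise VolumeError(f"threshold label {lab} not in {SEED_LABELS}")
        if not lo < hi:
            raise VolumeError(f"empty threshold range for label {lab}: ({lo}, {hi}]")
    by_lo = sorted(items, key=lambda kv: kv[1][0])
    for (la, ra), (lb, rb) in zip(by_lo, by_lo[1:]):
        if ra[1] > rb[0]:
            raise VolumeError(f"threshold ranges for labels {la} and {lb} overlap")
    sel = sample_slice_mask(v.shape, sample_slices)
    idx_list, lab_list = [], []
    for lab, (lo, hi) in items:
        hit = sel & (v.values > lo) & (v.values <= hi)
        ijk = np.argwhere(hit)
        idx_list.append(ijk)
        lab_list.append(np.full(len(ijk), lab, dtype=np.int64))
    if not idx_list or sum(len(a) for a in idx_list) == 0:
        return SeedSet.empty()
    idx = np.concatenate(idx_list)
    lab = np.concatenate(lab_list)
    return SeedSet(idx, lab, np.ones(len(lab)))
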