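"""Seeded multi-label competitive region growing ("grow from seeds").

The segmentation is a synchronous cellular automaton in the GrowCut family.
Every voxel carries a state ``(label, strength theta)`` with ``theta in
[0, 1]``; seed cells start at their seeded strength (1 for user seeds) and
unlabeled cells at ``theta = 0``. In one pass, each voxel p is attacked by
every neighbor q with strength

    a(q -> p) = g(|I_p - I_q|) * theta_q,   g(d) = 1 - d / intensity_scale

where ``g`` is clipped to [0, 1] and ``intensity_scale`` defaults to the
intensity range of the ROI. The strongest attacker conquers p iff its attack
strictly exceeds ``theta_p``; p then takes the attacker's label and the
attack strength. Updates are synchronous (Jacobi-style) so reruns are
bit-identical; on exactly equal attack strength the lowest label wins.
Iteration stops at convergence (no cell changed in a full pass) or at
``max_iterations``.

Seed cells are frozen at their seeded state: an attack strength can never
strictly exceed a strength-1 seed, and lower-strength seeds are restored
after every pass so that corrections always survive in the output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volume_io import LabelVolume, SeedSet, VoxelVolume, VolumeError

_OFFSETS_6 = [
    (1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1),
]
_OFFSETS_26 = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
]


@dataclass(frozen=True)
class GrowParams:
    """Automaton parameters.

    neighborhood : 6 or 26 (6 is the default and cheapest contract)
    max_iterations : hard cap on full passes, >= 1
    intensity_scale : normalization for g(); default (None) is the max
        absolute intensity difference in the ROI
    """

    neighborhood: int = 6
    max_iterations: int = 500
    intensity_scale: float | None = None

    def __post_init__(self):
        if self.neighborhood not in (6, 26):
            raise ValueError(f"neighborhood must be 6 or 26, got {self.neighborhood}")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


def _shifted(arr: np.ndarray, off, fill) -> np.ndarray:
    """out[p] = arr[p + off], padded with ``fill`` outside the grid."""
    out = np.full_like(arr, fill)
    src, dst = [], []
    for n, o in zip(arr.shape, off):
        if o >= 0:
            src.append(slice(o, n))
            dst.append(slice(0, n - o))
        else:
            src.append(slice(0, n + o))
            dst.append(slice(-o, n))
    out[tuple(dst)] = arr[tuple(src)]
    return out


def grow_from_seeds(v: VoxelVolume, seeds: SeedSet, p: GrowParams | None = None) -> LabelVolume:
    """Run the automaton to convergence and return the label volume.

    Every voxel reachable from a seed through neighbors of nonzero affinity
    ends up labeled; seed cells keep their initial labels.
    """
    p = p or GrowParams()
    if len(seeds) == 0:
        raise VolumeError("empty SeedSet: at least one seed is required")
    seeds.validate_in_grid(v.shape)
    I = np.asarray(v.values, dtype=np.float64)
    if not np.isfinite(I).all():
        raise VolumeError("volume contains non-finite intensities")

    scale = p.intensity_scale
    if scale is None:
        scale = float(I.max() - I.min())
    if scale <= 0:
        scale = 1.0

    labels = np.zeros(v.shape, dtype=np.int8)
    theta = np.zeros(v.shape, dtype=np.float64)
    si = tuple(seeds.indices.T)
    labels[si] = seeds.labels
    theta[si] = seeds.strengths
    seed_labels = seeds.labels.astype(np.int8)
    seed_theta = seeds.strengths

    offsets = _OFFSETS_6 if p.neighborhood == 6 else _OFFSETS_26
    for _ in range(p.max_iterations):
        best_a = np.full(v.shape, -1.0)
        best_l = np.zeros(v.shape, dtype=np.int8)
        for off in offsets:
            iq = _shifted(I, off, np.inf)
            tq = _shifted(theta, off, 0.0)
            lq = _shifted(labels, off, 0)
            g = 1.0 - np.abs(I - iq) / scale
            np.clip(g, 0.0, 1.0, out=g)
            a = g * tq
            upd = (a > best_a) | ((a == best_a) & (lq < best_l))
            best_a[upd] = a[upd]
            best_l[upd] = lq[upd]
        conquered = best_a > theta
        if not conquered.any():
            break
        labels[conquered] = best_l[conquered]
        theta[conquered] = best_a[conquered]
        # seeds are immutable state
        labels[si] = seed_labels
        theta[si] = seed_theta
    return LabelVolume(labels, v.spacing_mm, v.origin_mm)


def update_segmentation(
    v: VoxelVolume,
    previous_seeds: SeedSet,
    corrections: SeedSet,
    p: GrowParams | None = None,
) -> LabelVolume:
    """Iterative correction step: merge corrections later-wins and re-grow.

    Equivalent to ``grow_from_seeds(v, previous_seeds.merge(corrections), p)``;
    corrected cells carry their corrected label in the output.
    """
    return grow_from_seeds(v, previous_seeds.merge(corrections), p)


def dice(a: LabelVolume | np.ndarray, b: LabelVolume | np.ndarray, label: int) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|) of one label between two label maps."""
    la = a.labels if isinstance(a, LabelVolume) else np.asarray(a)
    lb = b.labels if isinstance(b, LabelVolume) else np.asarray(b)
    ma, mb = la == label, lb == label
    denom = int(ma.sum()) + int(mb.sum())
    if denom == 0:
        return float("nan")
    return 2.0 * int((ma & mb).sum()) / denom
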