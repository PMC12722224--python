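"""Object-level morphometry: 3-D object counting, box-counting fractal
dimension, and 2-D Sholl analysis of cell masks."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .containers import BinaryMask


@dataclass
class ObjectSet:
    """Labeled 3-D connected components after a minimum-size filter.

    ``labels`` is an integer volume with labels contiguous from 1;
    ``voxel_counts[i]`` and ``centroids[i]`` describe label ``i + 1``.
    Density is the object count per calibrated volume (objects / µm³).
    """

    labels: np.ndarray
    voxel_counts: np.ndarray
    centroids: np.ndarray  # (n, 3) voxel coordinates (z, y, x)
    min_voxels: int
    voxel_size: tuple[float, float, float]

    @property
    def n_objects(self) -> int:
        return len(self.voxel_counts)

    @property
    def density_per_um3(self) -> float:
        dz, dy, dx = self.voxel_size
        vol = self.labels.size * dz * dy * dx
        return self.n_objects / vol

    @property
    def volumes_um3(self) -> np.ndarray:
        dz, dy, dx = self.voxel_size
        return self.voxel_counts * (dz * dy * dx)


#: 26-connectivity structuring element for 3-D labeling.
_STRUCT_26 = np.ones((3, 3, 3), dtype=int)


def count_objects_3d(mask: BinaryMask, min_voxels: int = 10) -> ObjectSet:
    """26-connected 3-D components with components below ``min_voxels`` discarded."""
    if min_voxels < 1:
        raise ValueError("min_voxels must be >= 1")
    labels, n = ndimage.label(mask.voxels, structure=_STRUCT_26)
    if n == 0:
        return ObjectSet(labels, np.empty(0, int), np.empty((0, 3)), min_voxels, mask.voxel_size)
    counts = ndimage.sum_labels(mask.voxels, labels, index=np.arange(1, n + 1)).astype(int)
    keep = counts >= min_voxels
    # relabel survivors contiguously from 1
    remap = np.zeros(n + 1, dtype=int)
    remap[1:][keep] = np.arange(1, keep.sum() + 1)
    labels = remap[labels]
    counts = counts[keep]
    if counts.size:
        centroids = np.asarray(
            ndimage.center_of_mass(labels > 0, labels, index=np.arange(1, counts.size + 1))
        )
    else:
        centroids = np.empty((0, 3))
    return ObjectSet(labels, counts, centroids, min_voxels, mask.voxel_size)


def fractal_dimension(mask: BinaryMask, box_sizes: tuple[int, ...] = (2, 4, 8, 16, 32, 64)) -> float:
    """2-D box-counting dimension of the maximum-intensity projection.

    For each box size s the projection is tiled by an origin-anchored grid
    and the number of boxes containing foreground is counted; the dimension
    is the slope of log(count) on log(1/s).  Lies in [0, 2] for any planar
    set spanning the tested scales.
    """
    proj = mask.projection()
    if not proj.any():
        raise ValueError("empty mask has no fractal dimension")
    counts = []
    for s in box_sizes:
        ny = int(np.ceil(proj.shape[0] / s))
        nx = int(np.ceil(proj.shape[1] / s))
        padded = np.zeros((ny * s, nx * s), dtype=bool)
        padded[: proj.shape[0], : proj.shape[1]] = proj
        blocks = padded.reshape(ny, s, nx, s).any(axis=(1, 3))
        counts.append(blocks.sum())
    slope = np.polyfit(np.log(1.0 / np.asarray(box_sizes, float)), np.log(counts), 1)[0]
    return float(slope)


@dataclass
class ShollProfile:
    """Intersection counts on concentric circles around a soma center."""

    radii_um: np.ndarray
    intersections: np.ndarray
    soma_center_um: tuple[float, float]

    def peak(self) -> float:
        return float(self.intersections.max()) if len(self.intersections) else 0.0

    def total(self) -> float:
        """Summed intersections: the scalar morphological-complexity index."""
        return float(self.intersections.sum())


def _count_arcs(ring: np.ndarray, bridge: int = 1) -> int:
    """Number of maximal foreground arcs on a circular boolean sample.

    Gaps of at most ``bridge`` background samples are closed first, so
    single-pixel binarization dropouts do not split an arc; arcs separated
    by >= bridge + 1 background samples count as distinct crossings.
    """
    if ring.all():
        return 1
    if not ring.any():
        return 0
    closed = ndimage.binary_closing(
        np.concatenate([ring, ring, ring]), structure=np.ones(2 * bridge + 1, bool)
    )[len(ring) : 2 * len(ring)]
    # count circular runs: rotate so position 0 is background
    start = int(np.flatnonzero(~closed)[0])
    rolled = np.roll(closed, -start)
    return int(np.sum(np.diff(rolled.astype(int)) == 1) + (1 if rolled[0] else 0))


def sholl_2d(
    cell_mask: BinaryMask,
    soma_center_um: tuple[float, float],
    r0_um: float = 7.5,
    dr_um: float = 2.5,
    n_angles: int = 360,
) -> ShollProfile:
    """Sholl analysis on the 2-D projection of a single-cell mask.

    Concentric circles start at ``r0_um`` and grow by ``dr_um``; each circle
    is discretized at 1° steps with nearest-pixel sampling and the
    intersection count is the number of maximal connected foreground arcs.
    ``soma_center_um`` is (y, x) in µm within the projected field.
    """
    proj = cell_mask.projection()
    _, dy, dx = cell_mask.voxel_size
    cy, cx = soma_center_um[0] / dy, soma_center_um[1] / dx
    if not (0 <= cy < proj.shape[0] and 0 <= cx < proj.shape[1]):
        raise ValueError("soma center lies outside the image")
    max_r = max(proj.shape[0] * dy, proj.shape[1] * dx)
    radii = np.arange(r0_um, max_r, dr_um)
    theta = np.linspace(0.0, 2 * np.pi, n_angles, endpoint=False)
    counts = []
    for r in radii:
        yy = np.round(cy + (r / dy) * np.sin(theta)).astype(int)
        xx = np.round(cx + (r / dx) * np.cos(theta)).astype(int)
        inside = (yy >= 0) & (yy < proj.shape[0]) & (xx >= 0) & (xx < proj.shape[1])
        ring = np.zeros(n_angles, dtype=bool)
        ring[inside] = proj[yy[inside], xx[inside]]
        counts.append(_count_arcs(ring))
    return ShollProfile(radii, np.asarray(counts, dtype=int), tuple(soma_center_um))
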