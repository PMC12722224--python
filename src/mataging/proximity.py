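"""Spatial-association scores between ECM, synaptic puncta, and cell
surfaces, with the 90°-rotation chance null.

The central construct is the shell ROI: the thresholded reference channel is
dilated in-plane by a fixed pixel radius (4 px = 0.5 µm at default
calibration) and the original signal subtracted, leaving a band that indexes
molecules within that distance of the reference surface.  Densities in the
shell are compared against the same score recomputed after rotating one
channel by 90° about the field center, which preserves each channel's
internal spatial statistics while destroying cross-channel alignment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import ndimage

from .containers import BinaryMask
from .morphometry import ObjectSet, _STRUCT_26


@dataclass
class ShellROI:
    """Peri-surface band: in-plane dilation of a mask minus the mask itself."""

    voxels: np.ndarray
    dilation_px: int
    thickness_um: float
    voxel_size: tuple[float, float, float]


@dataclass
class ProximityScore:
    n_puncta_in_shell: int
    n_puncta_total: int
    normalizer: float  # reference surface-area estimate, µm²
    density: float  # puncta per µm² of reference surface

    @property
    def proportion_in_shell(self) -> float:
        return self.n_puncta_in_shell / self.n_puncta_total if self.n_puncta_total else 0.0


def _disk(radius: int) -> np.ndarray:
    yy, xx = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    return yy * yy + xx * xx <= radius * radius


def shell_roi(mask: BinaryMask, dilation_px: int = 4) -> ShellROI:
    """Per-slice Euclidean-disk dilation of a mask minus the original signal."""
    if dilation_px < 1:
        raise ValueError("dilation must be >= 1")
    disk = _disk(dilation_px)
    shell = np.zeros_like(mask.voxels)
    for z in range(mask.voxels.shape[0]):
        shell[z] = ndimage.binary_dilation(mask.voxels[z], structure=disk) & ~mask.voxels[z]
    _, dy, _ = mask.voxel_size
    return ShellROI(shell, dilation_px, dilation_px * dy, mask.voxel_size)


def surface_area_um2(mask: BinaryMask) -> float:
    """Exposed-face surface-area estimate of a voxel mask.

    Counts faces of foreground voxels not shared with another foreground
    voxel, weighting each face by its physical area.  Deterministic and
    monotone under mask growth of separated objects.
    """
    v = mask.voxels
    dz, dy, dx = mask.voxel_size
    area = 0.0
    for axis, face in ((0, dy * dx), (1, dz * dx), (2, dz * dy)):
        pad = np.pad(v, [(1, 1) if a == axis else (0, 0) for a in range(3)])
        sl_lo = [slice(None)] * 3
        sl_hi = [slice(None)] * 3
        sl_lo[axis] = slice(0, -2)
        sl_hi[axis] = slice(2, None)
        area += (v & ~pad[tuple(sl_lo)]).sum() * face
        area += (v & ~pad[tuple(sl_hi)]).sum() * face
    return float(area)


def puncta_centroids(puncta_mask: BinaryMask) -> np.ndarray:
    """Centroids of 26-connected puncta objects, (n, 3) voxel coordinates."""
    labels, n = ndimage.label(puncta_mask.voxels, structure=_STRUCT_26)
    if n == 0:
        return np.empty((0, 3))
    return np.asarray(ndimage.center_of_mass(puncta_mask.voxels, labels, index=np.arange(1, n + 1)))


def puncta_shell_density(
    puncta_mask: BinaryMask, shell: ShellROI, reference_mask: BinaryMask
) -> ProximityScore:
    """Density of puncta whose centroid falls in the shell, per unit
    reference surface area.

    Membership is centroid-in-shell (nearest voxel), which counts each
    punctum at most once regardless of its size.
    """
    if puncta_mask.shape != shell.voxels.shape or puncta_mask.shape != reference_mask.shape:
        raise ValueError("masks must share dimensions")
    if not reference_mask.voxels.any():
        raise ValueError("empty reference mask: normalizer is zero")
    cents = puncta_centroids(puncta_mask)
    n_in = 0
    for c in np.round(cents).astype(int):
        c = np.clip(c, 0, np.asarray(shell.voxels.shape) - 1)
        if shell.voxels[tuple(c)]:
            n_in += 1
    area = surface_area_um2(reference_mask)
    return ProximityScore(n_in, len(cents), area, n_in / area)


def coloc_puncta(mask_a: BinaryMask, mask_b: BinaryMask) -> int:
    """Number of a-objects whose voxels overlap at least one b-voxel."""
    if mask_a.shape != mask_b.shape:
        raise ValueError("masks must share dimensions")
    labels, n = ndimage.label(mask_a.voxels, structure=_STRUCT_26)
    if n == 0:
        return 0
    overlap = ndimage.sum_labels(mask_b.voxels, labels, index=np.arange(1, n + 1))
    return int(np.count_nonzero(overlap))


def rotate90(mask: BinaryMask, crop: bool = False) -> BinaryMask:
    """Rotate a mask 90° counter-clockwise in-plane about the field center.

    Requires a square in-plane field; with ``crop=True`` a non-square field
    is first center-cropped to a square.
    """
    v = mask.voxels
    if v.shape[1] != v.shape[2]:
        if not crop:
            raise ValueError("non-square field: pass crop=True to center-crop")
        s = min(v.shape[1], v.shape[2])
        y0 = (v.shape[1] - s) // 2
        x0 = (v.shape[2] - s) // 2
        v = v[:, y0 : y0 + s, x0 : x0 + s]
    return BinaryMask(np.rot90(v, k=1, axes=(1, 2)).copy(), mask.voxel_size,
                      mask.provenance + ["rotate90(ccw, in-plane)"])


def rotation_null(
    metric: Callable[[BinaryMask, BinaryMask], float],
    mask_a: BinaryMask,
    mask_b: BinaryMask,
    crop: bool = False,
) -> tuple[float, float]:
    """Observed association score and its 90°-rotation chance value.

    The null recomputes ``metric`` after rotating ``mask_b`` in-plane by
    90°; the pair (observed, null) supports a paired comparison across
    fields of view.
    """
    if mask_a.shape[1] != mask_a.shape[2] and not crop:
        raise ValueError("non-square field: pass crop=True to center-crop")
    if crop and mask_a.shape[1] != mask_a.shape[2]:
        s = min(mask_a.shape[1], mask_a.shape[2])
        y0 = (mask_a.shape[1] - s) // 2
        x0 = (mask_a.shape[2] - s) // 2
        mask_a = BinaryMask(mask_a.voxels[:, y0 : y0 + s, x0 : x0 + s],
                            mask_a.voxel_size, mask_a.provenance)
        mask_b = BinaryMask(mask_b.voxels[:, y0 : y0 + s, x0 : x0 + s],
                            mask_b.voxel_size, mask_b.provenance)
    observed = metric(mask_a, mask_b)
    null = metric(mask_a, rotate90(mask_b))
    return float(observed), float(null)


def microglia_ecm_contacts(ecm_objects: ObjectSet, cell_mask: BinaryMask) -> float:
    """ECM objects touching the cell mask, per µm³ of cell-mask volume."""
    if ecm_objects.labels.shape != cell_mask.shape:
        raise ValueError("object volume and cell mask must share dimensions")
    if not cell_mask.voxels.any():
        raise ValueError("empty cell mask: normalizer is zero")
    n = ecm_objects.n_objects
    if n == 0:
        contacts = 0
    else:
        overlap = ndimage.sum_labels(
            cell_mask.voxels, ecm_objects.labels, index=np.arange(1, n + 1)
        )
        contacts = int(np.count_nonzero(overlap))
    dz, dy, dx = cell_mask.voxel_size
    cell_volume = cell_mask.voxels.sum() * dz * dy * dx
    return contacts / cell_volume
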