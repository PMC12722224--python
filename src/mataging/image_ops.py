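"""Channel preprocessing, max-entropy binarization, and coverage metrics.

The quantification chain mirrors a standard confocal ECM workflow: per-slice
rolling-ball background subtraction and 3x3 median de-speckling (optionally a
gamma correction for dim linker-protein labels), a single Kapur maximum-entropy
threshold computed over the whole stack's 8-bit histogram, then field-of-view
coverage and a planar size partition that separates small interstitial-matrix
puncta from larger perineuronal/perivascular accumulations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .containers import BinaryMask, ImageStack


def _ball_profile(radius: int) -> tuple[np.ndarray, np.ndarray]:
    """Height profile and support of a ball structuring element."""
    yy, xx = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    d2 = yy * yy + xx * xx
    support = d2 <= radius * radius
    height = np.where(support, np.sqrt(np.maximum(radius * radius - d2, 0.0)), 0.0)
    return height, support


@dataclass(frozen=True)
class CoverageResult:
    """Fraction of a field of view occupied by foreground signal."""

    fraction: float
    n_foreground_px: int
    total_px: int


def subtract_background(channel: np.ndarray, radius_px: int = 15) -> np.ndarray:
    """Per-slice rolling-ball background subtraction.

    The background under each slice is the grayscale opening with a
    ball-shaped (non-flat) structuring element of the given radius — the
    surface traced by rolling a ball of that radius beneath the intensity
    landscape.  The opening is anti-extensive, so after clipping the
    background at zero the result is non-negative and elementwise no larger
    than the input.
    """
    if radius_px < 1:
        raise ValueError("rolling-ball radius must be >= 1")
    channel = np.asarray(channel, dtype=float)
    vol = channel[None] if channel.ndim == 2 else channel
    if radius_px > min(vol.shape[1], vol.shape[2]):
        raise ValueError("rolling-ball radius exceeds slice dimensions")
    height, support = _ball_profile(radius_px)
    out = np.empty_like(vol)
    for z in range(vol.shape[0]):
        background = ndimage.grey_opening(
            vol[z], structure=height, footprint=support, mode="nearest"
        )
        out[z] = np.clip(vol[z] - np.clip(background, 0.0, None), 0.0, None)
    return out[0] if channel.ndim == 2 else out


def despeckle(channel: np.ndarray) -> np.ndarray:
    """Per-slice 3x3 median filter (removes isolated hot pixels)."""
    channel = np.asarray(channel, dtype=float)
    vol = channel[None] if channel.ndim == 2 else channel
    out = np.empty_like(vol)
    for z in range(vol.shape[0]):
        out[z] = ndimage.median_filter(vol[z], size=3, mode="reflect")
    return out[0] if channel.ndim == 2 else out


def gamma_correct(channel: np.ndarray, gamma: float) -> np.ndarray:
    """Power-law intensity remap preserving the original dynamic range.

    Intensities are rescaled to [0, 1], raised to ``gamma``, and rescaled
    back to the original maximum.  Monotone for any positive gamma; an
    all-zero image is returned unchanged.
    """
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    channel = np.asarray(channel, dtype=float)
    vmax = channel.max()
    if vmax == 0:
        return channel.copy()
    return (channel / vmax) ** gamma * vmax


def kapur_threshold(hist: np.ndarray) -> int:
    """Kapur maximum-entropy threshold over a 256-bin histogram.

    Returns the bin index ``t`` maximizing the sum of Shannon entropies of
    the normalized sub-histograms ``[0, t]`` and ``(t, 255]``; foreground is
    strictly above ``t``.
    """
    p = hist.astype(float) / hist.sum()
    best_t, best_h = 0, -np.inf
    for t in range(255):
        p0 = p[: t + 1].sum()
        p1 = 1.0 - p0
        if p0 <= 0 or p1 <= 0:
            continue
        q0 = p[: t + 1] / p0
        q1 = p[t + 1 :] / p1
        h = -np.sum(q0[q0 > 0] * np.log(q0[q0 > 0])) - np.sum(q1[q1 > 0] * np.log(q1[q1 > 0]))
        if h > best_h:
            best_h, best_t = h, t
    return best_t


def rescale_to_8bit(channel: np.ndarray) -> np.ndarray:
    """Linear min-max rescale to integer levels 0..255."""
    channel = np.asarray(channel, dtype=float)
    lo, hi = channel.min(), channel.max()
    if hi == lo:
        raise ValueError("constant channel: degenerate histogram")
    return np.round((channel - lo) / (hi - lo) * 255.0).astype(np.uint8)


def threshold_max_entropy(
    channel: np.ndarray,
    voxel_size: tuple[float, float, float] | None = None,
    provenance: list[str] | None = None,
) -> BinaryMask:
    """Binarize a channel with the Kapur maximum-entropy criterion.

    The channel is linearly rescaled to 8-bit, one 256-bin histogram is
    accumulated over the full stack, and the entropy-maximizing threshold is
    applied with strict inequality (tie voxels at the threshold are
    background), yielding one mask per field of view.
    """
    scaled = rescale_to_8bit(channel)
    hist = np.bincount(scaled.ravel(), minlength=256)
    t = kapur_threshold(hist)
    from .containers import DEFAULT_VOXEL_SIZE

    mask = BinaryMask(
        scaled > t,
        voxel_size=voxel_size or DEFAULT_VOXEL_SIZE,
        provenance=list(provenance or []),
    )
    return mask.with_step(f"threshold_max_entropy(t={t})")


def coverage(mask: BinaryMask) -> CoverageResult:
    """Proportion of the field of view covered by foreground voxels."""
    n_fg = int(mask.voxels.sum())
    total = int(mask.voxels.size)
    return CoverageResult(fraction=n_fg / total, n_foreground_px=n_fg, total_px=total)


def size_partition(mask: BinaryMask, cutoff_px: int = 150) -> tuple[BinaryMask, BinaryMask]:
    """Split projected foreground into small (< cutoff) and large components.

    Connected components are computed on the 2-D maximum-intensity
    projection with 8-connectivity; the two returned planar masks partition
    the projected foreground, separating putative interstitial puncta from
    larger perineuronal/perivascular accumulations.
    """
    if cutoff_px < 1:
        raise ValueError("cutoff must be >= 1")
    proj = mask.projection()
    labels, n = ndimage.label(proj, structure=np.ones((3, 3), dtype=int))
    small = np.zeros_like(proj)
    large = np.zeros_like(proj)
    if n:
        sizes = ndimage.sum_labels(proj, labels, index=np.arange(1, n + 1))
        small_ids = np.flatnonzero(sizes < cutoff_px) + 1
        small = np.isin(labels, small_ids) & proj
        large = proj & ~small
    prov = mask.provenance + [f"size_partition(cutoff={cutoff_px})"]
    return (
        BinaryMask(small, mask.voxel_size, prov + ["keep=small"]),
        BinaryMask(large, mask.voxel_size, prov + ["keep=large"]),
    )


def binarize_channel(
    stack: ImageStack,
    channel: str,
    rolling_ball_radius: int | None = 15,
    gamma: float | None = None,
    median_despeckle: bool = True,
) -> BinaryMask:
    """Full preprocessing + binarization chain for one channel.

    Order follows the histology workflow: optional gamma correction, then
    rolling-ball background subtraction, de-speckling, and the max-entropy
    threshold.  Every step is recorded in the mask provenance.
    """
    img = stack[channel]
    prov: list[str] = [f"channel={channel}"]
    if gamma is not None and gamma != 1.0:
        img = gamma_correct(img, gamma)
        prov.append(f"gamma_correct(gamma={gamma})")
    if rolling_ball_radius:
        img = subtract_background(img, rolling_ball_radius)
        prov.append(f"subtract_background(radius={rolling_ball_radius})")
    if median_despeckle:
        img = despeckle(img)
        prov.append("despeckle(3x3 median)")
    return threshold_max_entropy(img, voxel_size=stack.voxel_size, provenance=prov)
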