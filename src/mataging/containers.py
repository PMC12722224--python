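"""Core calibrated-image containers shared across the imaging modules.

An :class:`ImageStack` holds a multi-channel confocal volume with physical
voxel calibration; a :class:`BinaryMask` is a thresholded channel that
carries the provenance of every processing step that produced it, so that a
quantification can always be traced back to its exact preprocessing chain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Default calibration, µm per voxel as (z, y, x): 0.3 µm optical sections
#: at 0.125 µm in-plane pixel pitch, so 4 px = 0.5 µm in-plane.
DEFAULT_VOXEL_SIZE = (0.3, 0.125, 0.125)


@dataclass
class ImageStack:
    """Multi-channel 3-D fluorescence volume.

    Parameters
    ----------
    channels
        Mapping of channel name to a non-negative ``(z, y, x)`` intensity
        array.  All channels must share shape.
    voxel_size
        Physical voxel size in µm, ordered ``(z, y, x)``.
    """

    channels: dict[str, np.ndarray]
    voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_SIZE

    def __post_init__(self) -> None:
        shapes = {c: a.shape for c, a in self.channels.items()}
        if len(set(shapes.values())) > 1:
            raise ValueError(f"channels disagree on shape: {shapes}")
        for name, arr in self.channels.items():
            if arr.ndim != 3:
                raise ValueError(f"channel {name!r} is not 3-D")
            if not np.all(np.isfinite(arr)) or np.any(arr < 0):
                raise ValueError(f"channel {name!r} has negative or non-finite voxels")

    @property
    def shape(self) -> tuple[int, int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def channel_names(self) -> list[str]:
        return list(self.channels)

    @property
    def voxel_volume_um3(self) -> float:
        dz, dy, dx = self.voxel_size
        return dz * dy * dx

    def __getitem__(self, channel: str) -> np.ndarray:
        return self.channels[channel]


@dataclass
class BinaryMask:
    """Boolean voxel mask with calibration and processing provenance."""

    voxels: np.ndarray
    voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_SIZE
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=bool)
        if self.voxels.ndim == 2:  # accept planar masks as single-slice volumes
            self.voxels = self.voxels[None]
        if self.voxels.ndim != 3:
            raise ValueError("mask must be 2-D or 3-D")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_volume_um3(self) -> float:
        dz, dy, dx = self.voxel_size
        return dz * dy * dx

    def with_step(self, step: str) -> "BinaryMask":
        """Return self after appending one provenance entry (in place)."""
        self.provenance.append(step)
        return self

    def projection(self) -> np.ndarray:
        """2-D maximum-intensity projection (logical OR over z)."""
        return self.voxels.any(axis=0)
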