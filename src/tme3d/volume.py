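"""The unit imaging object: one channel's 3D intensity grid with physical spacing.

Axis convention is (z, y, x) throughout, matching the plane-major layout of a
light-sheet z-stack.  All physical quantities are in micrometers.  The center
of voxel ``(0, 0, 0)`` sits at ``origin_um``; by default that is half a voxel
in from the physical corner of the field, so ``physical = origin + index * Δ``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class ImageVolume:
    """A single-channel 3D image with physical voxel spacing.

    Parameters
    ----------
    intensities
        ``(nz, ny, nx)`` array, unsigned integer (or float for intermediate,
        noise-free renders).
    voxel_size_um
        ``(dz, dy, dx)`` in μm, all strictly positive.
    channel
        Marker label of the channel (e.g. ``"CD3"``).
    origin_um
        Physical position of the center of voxel ``(0, 0, 0)``, in μm,
        as ``(z, y, x)``.
    """

    intensities: np.ndarray
    voxel_size_um: tuple[float, float, float]
    channel: str = ""
    origin_um: tuple[float, float, float] = (0.0, 0.0, 0.0)
    flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities)
        if self.intensities.ndim != 3:
            raise ValueError(
                f"expected a 3D (z, y, x) array, got ndim={self.intensities.ndim}"
            )
        self.voxel_size_um = tuple(float(v) for v in self.voxel_size_um)
        if len(self.voxel_size_um) != 3 or any(v <= 0 for v in self.voxel_size_um):
            raise ValueError(f"voxel sizes must be three positive lengths, got {self.voxel_size_um}")
        self.origin_um = tuple(float(v) for v in self.origin_um)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape

    @property
    def extent_um(self) -> tuple[float, float, float]:
        """Physical size of the field along (z, y, x)."""
        return tuple(n * d for n, d in zip(self.shape, self.voxel_size_um))

    def index_to_physical(self, idx: np.ndarray) -> np.ndarray:
        """Map (possibly fractional) voxel indices (z, y, x) to physical μm."""
        idx = np.atleast_2d(np.asarray(idx, dtype=float))
        return idx * np.array(self.voxel_size_um) + np.array(self.origin_um)

    def physical_to_index(self, pos_um: np.ndarray) -> np.ndarray:
        """Map physical μm positions (z, y, x) to fractional voxel indices."""
        pos_um = np.atleast_2d(np.asarray(pos_um, dtype=float))
        return (pos_um - np.array(self.origin_um)) / np.array(self.voxel_size_um)


def default_origin(voxel_size_um: tuple[float, float, float]) -> tuple[float, float, float]:
    """Origin placing voxel (0,0,0)'s center half a voxel inside the corner."""
    return tuple(0.5 * v for v in voxel_size_um)
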