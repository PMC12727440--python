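"""Minimal in-memory image container shared by every pipeline stage.

A :class:`Volume` pairs a 3-D numpy array with a NIfTI-style 4x4 affine.
Label maps and binary masks are Volumes whose data is integer / boolean;
the helpers here keep grid compatibility checks in one place.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Volume", "ras_affine", "check_same_grid", "voxel_volume_mm3"]


def ras_affine(shape: tuple[int, int, int], voxel_size_mm: float = 1.0) -> np.ndarray:
    """RAS+ affine with isotropic spacing and the world origin at the grid centre."""
    aff = np.eye(4)
    aff[0, 0] = aff[1, 1] = aff[2, 2] = voxel_size_mm
    centre = (np.asarray(shape, dtype=float) - 1.0) / 2.0
    aff[:3, 3] = -centre * voxel_size_mm
    return aff


@dataclass
class Volume:
    """3-D image: scalar intensities, integer labels, or a boolean mask."""

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"Volume data must be 3-D, got shape {self.data.shape}")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_sizes(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def copy(self) -> "Volume":
        return Volume(self.data.copy(), self.affine.copy())

    def with_data(self, data: np.ndarray) -> "Volume":
        return Volume(np.asarray(data), self.affine.copy())


def voxel_volume_mm3(vol: Volume) -> float:
    return vol.voxel_volume_mm3


def check_same_grid(a: Volume, b: Volume, what: str = "volumes") -> None:
    """Refuse to combine images on different grids (shape or affine mismatch)."""
    if a.shape != b.shape:
        raise ValueError(f"grid mismatch between {what}: shapes {a.shape} vs {b.shape}")
    if not np.allclose(a.affine, b.affine, atol=1e-6):
        raise ValueError(f"grid mismatch between {what}: affines differ")
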