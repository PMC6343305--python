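"""Core volume containers shared by every pipeline stage.

Index order is (z, y, x) with z the scanner slice axis.  All physical
sizes are millimetres; voxels are isotropic.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = ["GrayVolume", "BinaryVolume", "mm_to_voxels"]

_MODALITIES = {"micro_ct", "cbct", "synthetic"}


def mm_to_voxels(extent_mm: float, voxel_mm: float) -> int:
    """Convert a physical extent to a voxel count, rounding half away from zero.

    A relative epsilon absorbs binary-representation error (0.15/0.1 is
    fractionally below 1.5 in floats but still rounds to 2).
    """
    q = extent_mm / voxel_mm
    eps = 1e-9 * (abs(q) + 1.0)
    if q >= 0:
        return int(math.floor(q + 0.5 + eps))
    return int(math.ceil(q - 0.5 - eps))


@dataclass
class GrayVolume:
    """A 3D scalar image with isotropic voxel size.

    Parameters
    ----------
    data:
        3D array indexed (z, y, x).  Finite, non-negative grayscale.
    voxel_mm:
        Isotropic voxel edge length in millimetres.
    modality:
        One of ``micro_ct``, ``cbct``, ``synthetic``.
    """

    data: np.ndarray
    voxel_mm: float
    modality: str = "synthetic"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3D, got ndim={self.data.ndim}")
        if min(self.data.shape) < 1:
            raise ValueError(f"all dims must be >= 1, got {self.data.shape}")
        if not self.voxel_mm > 0:
            raise ValueError(f"voxel_mm must be > 0, got {self.voxel_mm}")
        if self.modality not in _MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("grayscale values must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def with_data(self, data: np.ndarray) -> "GrayVolume":
        """Same geometry/modality, new voxel data."""
        return GrayVolume(data=data, voxel_mm=self.voxel_mm, modality=self.modality)


@dataclass
class BinaryVolume:
    """A bone/background mask; ``True`` marks bone."""

    mask: np.ndarray
    voxel_mm: float
    provenance: str = ""  # e.g. G0..G4, "truth"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask)
        if self.mask.ndim != 3:
            raise ValueError(f"mask must be 3D, got ndim={self.mask.ndim}")
        if self.mask.dtype != bool:
            self.mask = self.mask.astype(bool)
        if not self.voxel_mm > 0:
            raise ValueError(f"voxel_mm must be > 0, got {self.voxel_mm}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.mask.shape
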