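"""Voxel-grid geometry."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import DomainError

__all__ = ["VoxelGrid"]


@dataclass(frozen=True)
class VoxelGrid:
    """A regular 3-D voxel lattice.

    Parameters
    ----------
    dims
        Number of voxels along each axis.
    voxel_size
        Voxel edge lengths in mm per axis.
    """

    dims: tuple[int, int, int]
    voxel_size: tuple[float, float, float]

    def __post_init__(self):
        dims = tuple(int(d) for d in self.dims)
        size = tuple(float(s) for s in self.voxel_size)
        if len(dims) != 3 or len(size) != 3:
            raise DomainError("dims and voxel_size must have three entries")
        if any(d <= 0 for d in dims) or any(s <= 0 for s in size):
            raise DomainError("dims and voxel_size must be positive")
        object.__setattr__(self, "dims", dims)
        object.__setattr__(self, "voxel_size", size)

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in mL (mm^3 / 1000)."""
        return float(np.prod(self.voxel_size)) / 1000.0

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        """Physical size of the grid along each axis, mm."""
        return tuple(d * s for d, s in zip(self.dims, self.voxel_size))

    def contains_voxel(self, idx) -> bool:
        return all(0 <= int(i) < d for i, d in zip(idx, self.dims))

    def coordinate_arrays(self):
        """Voxel-centre physical coordinates (mm) as three broadcastable arrays."""
        axes = [
            (np.arange(d) + 0.5) * s
            for d, s in zip(self.dims, self.voxel_size)
        ]
        return np.meshgrid(*axes, indexing="ij", sparse=True)

    def to_dict(self) -> dict:
        return {"dims": list(self.dims), "voxel_size_mm": list(self.voxel_size)}

    @classmethod
    def from_dict(cls, d: dict) -> "VoxelGrid":
        return cls(tuple(d["dims"]), tuple(d["voxel_size_mm"]))
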