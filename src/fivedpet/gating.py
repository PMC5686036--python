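"""Cardiac-gate bookkeeping and the blood-volume validity check.

A gated dynamic acquisition is reconstructed as one time-static image per
(frame, gate) pair; analysing kinetics per cardiac phase requires resorting
those volumes into one dynamic series per gate.  Gated rebinning can also
drop counts when a cardiac cycle straddles a frame boundary, which depresses
early-frame activity and the fitted blood-volume fraction; the validity check
flags gates whose central cavity blood volume falls below a cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import CompletenessError, DomainError, ShapeError
from .grids import VoxelGrid
from .schedule import FrameSchedule

__all__ = [
    "GatedDynamicSeries",
    "ValidityReport",
    "resort_frames_to_gates",
    "flatten_gates_to_frames",
    "blood_volume_validity",
]

DEFAULT_N_GATES = 8
DEFAULT_VB_CUTOFF = 0.9


@dataclass(frozen=True)
class GatedDynamicSeries:
    """Per-gate dynamic series sharing one schedule and voxel grid.

    ``data`` has shape (n_gates, nx, ny, nz, n_frames).
    """

    data: np.ndarray
    schedule: FrameSchedule
    grid: VoxelGrid

    def __post_init__(self):
        expected = (self.n_gates,) + tuple(self.grid.dims) + (self.schedule.n_frames,)
        if self.data.shape != expected:
            raise ShapeError(f"gated data shape {self.data.shape}, expected {expected}")

    @property
    def n_gates(self) -> int:
        return int(self.data.shape[0])

    @property
    def n_frames(self) -> int:
        return self.schedule.n_frames

    def gate(self, g: int) -> np.ndarray:
        """The 4-D dynamic series (x, y, z, frame) of gate ``g``."""
        return self.data[g]


@dataclass(frozen=True)
class ValidityReport:
    """Per-gate centre blood-volume fractions against a cutoff."""

    centre_fraction: np.ndarray  # one value per gate
    cutoff: float
    valid: np.ndarray  # boolean per gate; fraction >= cutoff

    @property
    def n_valid(self) -> int:
        return int(np.count_nonzero(self.valid))

    def to_dict(self) -> dict:
        return {
            "centre_blood_volume_fraction": self.centre_fraction.tolist(),
            "cutoff": self.cutoff,
            "valid": self.valid.tolist(),
        }


def resort_frames_to_gates(per_frame_gated_volumes, schedule: FrameSchedule, n_gates: int,
                           grid: VoxelGrid | None = None) -> GatedDynamicSeries:
    """Reorganise per-(frame, gate) reconstructions into per-gate dynamic series.

    Parameters
    ----------
    per_frame_gated_volumes
        Iterable of ``(frame_index, gate_index, volume)`` with every pair of
        ``n_gates * n_frames`` combinations appearing exactly once.

    The operation only reorganises data; voxel values are copied verbatim.
    """
    items = list(per_frame_gated_volumes)
    n_frames = schedule.n_frames
    expected = {(f, g) for f in range(n_frames) for g in range(n_gates)}
    seen = {}
    for f, g, vol in items:
        key = (int(f), int(g))
        if key not in expected:
            raise CompletenessError(f"(frame, gate) pair {key} outside the declared layout")
        if key in seen:
            raise CompletenessError(f"duplicate (frame, gate) pair {key}")
        seen[key] = np.asarray(vol)
    missing = expected - seen.keys()
    if missing:
        raise CompletenessError(f"missing (frame, gate) pairs: {sorted(missing)[:5]}...")

    shape = seen[(0, 0)].shape
    if grid is None:
        grid = VoxelGrid(shape, (1.0, 1.0, 1.0))
    data = np.empty((n_gates,) + shape + (n_frames,), dtype=float)
    for (f, g), vol in seen.items():
        if vol.shape != shape:
            raise ShapeError("all volumes must share one shape")
        data[g, ..., f] = vol
    return GatedDynamicSeries(data=data, schedule=schedule, grid=grid)


def flatten_gates_to_frames(series: GatedDynamicSeries):
    """Inverse of :func:`resort_frames_to_gates`: list of (frame, gate, volume)."""
    out = []
    for f in range(series.n_frames):
        for g in range(series.n_gates):
            out.append((f, g, series.data[g, ..., f].copy()))
    return out


def _neighbourhood_mean(volume: np.ndarray, centre, radius: int) -> float:
    """Mean over voxels within Euclidean distance ``radius`` of ``centre``."""
    cx, cy, cz = (int(c) for c in centre)
    r = int(radius)
    lo = [max(0, c - r) for c in (cx, cy, cz)]
    hi = [min(d, c + r + 1) for c, d in zip((cx, cy, cz), volume.shape)]
    sub = volume[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    ix, iy, iz = np.meshgrid(
        np.arange(lo[0], hi[0]) - cx,
        np.arange(lo[1], hi[1]) - cy,
        np.arange(lo[2], hi[2]) - cz,
        indexing="ij",
    )
    ball = ix**2 + iy**2 + iz**2 <= r**2
    return float(sub[ball].mean())


def blood_volume_validity(vb_maps, cavity_centre, cutoff: float = DEFAULT_VB_CUTOFF,
                          neighbourhood_radius: int = 1) -> ValidityReport:
    """Check per-gate blood-volume maps at the cavity centre against a cutoff.

    In a pure-blood cavity voxel V_B should be close to 1; count loss from
    gated rebinning pulls it down.  The centre fraction is the mean V_B over a
    small Euclidean neighbourhood (radius 1 voxel -> 7 voxels) to damp
    single-voxel noise.  A gate is valid iff its fraction >= ``cutoff``
    (boundary counts as valid).

    ``vb_maps`` may be one 3-D map or a sequence of per-gate maps.
    """
    if not 0 < cutoff <= 1:
        raise DomainError("cutoff must lie in (0, 1]")
    maps = [np.asarray(vb_maps)] if np.asarray(vb_maps).ndim == 3 else [
        np.asarray(m) for m in vb_maps
    ]
    centre = tuple(int(c) for c in cavity_centre)
    for m in maps:
        if m.ndim != 3:
            raise ShapeError("each blood-volume map must be 3-D")
        if not all(0 <= c < d for c, d in zip(centre, m.shape)):
            raise DomainError(f"cavity centre {centre} outside image of shape {m.shape}")
    frac = np.array([_neighbourhood_mean(m, centre, neighbourhood_radius) for m in maps])
    return ValidityReport(centre_fraction=frac, cutoff=float(cutoff), valid=frac >= cutoff)
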