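"""Derived-image synthesis: blood-volume, transmural-flow and first-pass images.

Blood-volume images V_B = V_A + V_RV show the ventricular blood pools with
near-unity values inside the cavities; transmural flow MBFt = MBF * PTF is the
flow per mL of voxel and visualises the myocardial wall; first-pass images sum
the early bolus-transit frames and show the blood pool directly without any
kinetic modelling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ShapeError, WindowError
from .grids import VoxelGrid
from .kinetics import ParametricMaps
from .schedule import FrameSchedule

__all__ = [
    "DerivedImage",
    "blood_volume_map",
    "transmural_flow_map",
    "first_pass_image",
    "first_pass_frame_indices",
    "DEFAULT_FP_WINDOW",
    "LOW_OUTPUT_FP_WINDOW",
]

#: Default first-pass summation window, seconds after injection.
DEFAULT_FP_WINDOW = (10.0, 50.0)
#: Later window used for low-cardiac-output subjects.
LOW_OUTPUT_FP_WINDOW = (20.0, 70.0)


@dataclass(frozen=True)
class DerivedImage:
    """A 3-D scalar image derived from a fit or a dynamic series."""

    kind: str  # one of {"VB", "MBFt", "FP"}
    data: np.ndarray
    grid: VoxelGrid
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in {"VB", "MBFt", "FP"}:
            raise ValueError(f"unknown derived-image kind {self.kind!r}")
        if self.data.shape != tuple(self.grid.dims):
            raise ShapeError("data shape must equal grid dims")


def blood_volume_map(maps: ParametricMaps, provenance: dict | None = None) -> DerivedImage:
    """Voxelwise blood-volume image V_B = V_A + V_RV."""
    return DerivedImage(
        kind="VB",
        data=maps.v_a + maps.v_rv,
        grid=maps.grid,
        provenance=provenance or {},
    )


def transmural_flow_map(maps: ParametricMaps, provenance: dict | None = None) -> DerivedImage:
    """Voxelwise transmural-flow image MBFt = MBF * PTF (mL mL^-1 min^-1)."""
    return DerivedImage(
        kind="MBFt",
        data=maps.mbf * maps.ptf,
        grid=maps.grid,
        provenance=provenance or {},
    )


def first_pass_frame_indices(
    schedule: FrameSchedule, window_start: float, window_end: float
) -> np.ndarray:
    """Indices of frames whose midpoint lies in [window_start, window_end)."""
    if window_end <= window_start:
        raise WindowError("window_end must exceed window_start")
    mid = schedule.frame_mid
    idx = np.nonzero((mid >= window_start) & (mid < window_end))[0]
    if idx.size == 0:
        raise WindowError(
            f"no frame midpoint falls inside [{window_start}, {window_end}) s"
        )
    return idx


def first_pass_image(
    series: np.ndarray,
    schedule: FrameSchedule,
    grid: VoxelGrid,
    window_start: float = DEFAULT_FP_WINDOW[0],
    window_end: float = DEFAULT_FP_WINDOW[1],
    duration_weighted: bool = True,
) -> DerivedImage:
    """Sum the frames of the bolus first pass into one blood-pool image.

    Frames are selected by midpoint; by default each frame contributes its
    activity-time product (value x duration) so unequal frame lengths weigh in
    proportionally.  Set ``duration_weighted=False`` for a plain frame sum.
    """
    series = np.asarray(series, dtype=float)
    if series.shape != tuple(grid.dims) + (schedule.n_frames,):
        raise ShapeError("series shape must be grid dims + (n_frames,)")
    if window_start < schedule.frame_start[0] - 1e-9 or window_end > schedule.total_span + 1e-9:
        raise WindowError("window must lie within the schedule span")
    idx = first_pass_frame_indices(schedule, window_start, window_end)
    if duration_weighted:
        w = schedule.frame_duration[idx]
        data = np.tensordot(series[..., idx], w, axes=([-1], [0]))
    else:
        data = series[..., idx].sum(axis=-1)
    return DerivedImage(
        kind="FP",
        data=data,
        grid=grid,
        provenance={
            "window_s": [float(window_start), float(window_end)],
            "frames": idx.tolist(),
            "duration_weighted": duration_weighted,
        },
    )
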