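"""On-disk formats: NIfTI-1 volumes with JSON sidecars, CSV input functions.

A dynamic series is stored as a 4-D NIfTI whose affine encodes the voxel size,
with a JSON sidecar holding the frame schedule
(``{"frame_start_s": [...], "frame_duration_s": [...]}``).  A gated series is
one NIfTI per gate sharing a single sidecar.  Input functions are 3-column CSV
(time_s, Ca_kBq_per_mL, Crv_kBq_per_mL); reports are JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .exceptions import FormatError
from .gating import GatedDynamicSeries
from .grids import VoxelGrid
from .schedule import FrameSchedule

__all__ = [
    "write_dynamic_series",
    "read_dynamic_series",
    "write_gated_series",
    "read_gated_series",
    "write_image",
    "read_image",
    "write_json",
    "read_json",
]


def _affine(grid: VoxelGrid) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = grid.voxel_size
    return aff


def _grid_from_img(img) -> VoxelGrid:
    dims = tuple(int(d) for d in img.shape[:3])
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return VoxelGrid(dims, zooms)


def write_image(path, data: np.ndarray, grid: VoxelGrid) -> None:
    """Write a 3-D or 4-D volume as NIfTI-1."""
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float64), _affine(grid)), str(path))


def read_image(path) -> tuple[np.ndarray, VoxelGrid]:
    img = nib.load(str(path))
    return np.asarray(img.get_fdata()), _grid_from_img(img)


def write_dynamic_series(
    path, data: np.ndarray, grid: VoxelGrid, schedule: FrameSchedule, sidecar_path=None
) -> None:
    """Write a 4-D dynamic series plus its frame-schedule sidecar."""
    path = Path(path)
    if data.shape != tuple(grid.dims) + (schedule.n_frames,):
        raise FormatError("series shape must be grid dims + (n_frames,)")
    write_image(path, data, grid)
    sidecar = Path(sidecar_path) if sidecar_path else path.with_suffix("").with_suffix(".json")
    sidecar.write_text(json.dumps(schedule.to_dict(), indent=2))


def read_dynamic_series(path, sidecar_path=None) -> tuple[np.ndarray, FrameSchedule, VoxelGrid]:
    """Read a 4-D dynamic series; validates schedule against frame count."""
    path = Path(path)
    sidecar = Path(sidecar_path) if sidecar_path else path.with_suffix("").with_suffix(".json")
    data, grid = read_image(path)
    if data.ndim != 4:
        raise FormatError(f"expected a 4-D series, got {data.ndim}-D")
    schedule = FrameSchedule.from_dict(json.loads(sidecar.read_text()))
    if schedule.n_frames != data.shape[3]:
        raise FormatError(
            f"sidecar declares {schedule.n_frames} frames but the image has {data.shape[3]}"
        )
    return data, schedule, grid


def write_gated_series(directory, series: GatedDynamicSeries, prefix: str = "gate") -> None:
    """Write one NIfTI per gate plus one shared schedule sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for g in range(series.n_gates):
        write_image(directory / f"{prefix}{g:02d}.nii", series.gate(g), series.grid)
    (directory / "schedule.json").write_text(json.dumps(series.schedule.to_dict(), indent=2))


def read_gated_series(directory, prefix: str = "gate") -> GatedDynamicSeries:
    directory = Path(directory)
    schedule = FrameSchedule.from_dict(json.loads((directory / "schedule.json").read_text()))
    paths = sorted(directory.glob(f"{prefix}*.nii"))
    if not paths:
        raise FormatError(f"no {prefix}*.nii volumes found in {directory}")
    volumes, grid = [], None
    for p in paths:
        data, g = read_image(p)
        if data.ndim != 4 or data.shape[3] != schedule.n_frames:
            raise FormatError(f"{p.name}: expected 4-D with {schedule.n_frames} frames")
        grid = grid or g
        volumes.append(data)
    return GatedDynamicSeries(data=np.stack(volumes), schedule=schedule, grid=grid)


def write_json(path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_json_default))


def read_json(path):
    return json.loads(Path(path).read_text())


def _json_default(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.integer, np.floating, np.bool_)):
        return o.item()
    raise TypeError(f"not JSON-serialisable: {type(o)}")
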