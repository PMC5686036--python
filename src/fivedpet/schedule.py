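"""Dynamic-frame timing bookkeeping.

A dynamic PET acquisition is divided into contiguous frames of varying
duration.  ``FrameSchedule`` holds the per-frame start times and durations in
seconds and validates the invariants every downstream step relies on:
positive durations, contiguity, and strictly increasing starts.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .exceptions import CoverageError, DomainError

__all__ = ["FrameSchedule", "water_protocol_schedule", "frame_average"]


class FrameSchedule:
    """Per-frame start times and durations of a dynamic sequence (seconds)."""

    def __init__(self, frame_start, frame_duration):
        start = np.asarray(frame_start, dtype=float)
        dur = np.asarray(frame_duration, dtype=float)
        if start.ndim != 1 or start.shape != dur.shape:
            raise DomainError("frame_start and frame_duration must be 1-D and equal length")
        if start.size == 0:
            raise DomainError("schedule must contain at least one frame")
        if np.any(dur <= 0):
            raise DomainError("all frame durations must be positive")
        if start.size > 1 and np.any(np.diff(start) <= 0):
            raise DomainError("frame starts must be strictly increasing")
        if not np.allclose(start[1:], start[:-1] + dur[:-1]):
            raise DomainError("frames must be contiguous and non-overlapping")
        self.frame_start = start
        self.frame_duration = dur
        self.frame_start.flags.writeable = False
        self.frame_duration.flags.writeable = False

    @classmethod
    def from_durations(cls, durations, t0: float = 0.0) -> "FrameSchedule":
        dur = np.asarray(durations, dtype=float)
        start = t0 + np.concatenate(([0.0], np.cumsum(dur[:-1])))
        return cls(start, dur)

    @property
    def n_frames(self) -> int:
        return int(self.frame_start.size)

    @property
    def frame_end(self) -> np.ndarray:
        return self.frame_start + self.frame_duration

    @property
    def frame_mid(self) -> np.ndarray:
        return self.frame_start + 0.5 * self.frame_duration

    @property
    def total_span(self) -> float:
        """End of the last frame, seconds."""
        return float(self.frame_end[-1])

    def __len__(self) -> int:
        return self.n_frames

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, FrameSchedule)
            and np.array_equal(self.frame_start, other.frame_start)
            and np.array_equal(self.frame_duration, other.frame_duration)
        )

    def __repr__(self) -> str:
        return f"FrameSchedule(n_frames={self.n_frames}, span={self.total_span:g} s)"

    def to_dict(self) -> dict:
        return {
            "frame_start_s": self.frame_start.tolist(),
            "frame_duration_s": self.frame_duration.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FrameSchedule":
        return cls(d["frame_start_s"], d["frame_duration_s"])


def water_protocol_schedule() -> FrameSchedule:
    """The 20-frame O-15-water protocol: 1x10, 8x5, 4x10, 2x15, 3x20, 2x30 s."""
    durations = [10.0] + [5.0] * 8 + [10.0] * 4 + [15.0] * 2 + [20.0] * 3 + [30.0] * 2
    return FrameSchedule.from_durations(durations)


def frame_average(time_grid: np.ndarray, curve: np.ndarray, schedule: FrameSchedule) -> np.ndarray:
    """Average ``curve(t)`` over each frame interval of ``schedule``.

    The curve is treated as piecewise linear on ``time_grid``; the frame mean is
    the trapezoidal integral over [start, end) divided by the frame duration.

    Raises
    ------
    CoverageError
        If the grid does not span every frame.
    """
    t = np.asarray(time_grid, dtype=float)
    y = np.asarray(curve, dtype=float)
    if t.ndim != 1 or t.shape != y.shape:
        raise DomainError("time_grid and curve must be 1-D arrays of equal length")
    if t[0] > schedule.frame_start[0] + 1e-9 or t[-1] < schedule.total_span - 1e-9:
        raise CoverageError(
            f"time grid [{t[0]}, {t[-1]}] s does not cover the schedule span "
            f"[{schedule.frame_start[0]}, {schedule.total_span}] s"
        )
    cum = np.concatenate(([0.0], cumulative_trapezoid(y, t)))
    start_int = np.interp(schedule.frame_start, t, cum)
    end_int = np.interp(schedule.frame_end, t, cum)
    return (end_int - start_int) / schedule.frame_duration
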