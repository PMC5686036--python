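"""Arterial and right-ventricular input functions on a fine time grid.

The kinetic model needs the tracer concentration in arterial (left-ventricular)
blood, C_A(t), and in right-ventricular blood, C_RV(t).  In clinical practice
these come from cluster analysis of the non-gated dynamic scan; here they are
supplied by the user or by the phantom's ground-truth bolus simulator.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .exceptions import DomainError
from .schedule import FrameSchedule, frame_average

__all__ = ["InputFunctionSet"]

_MAX_STEP_S = 0.5


class InputFunctionSet:
    """C_A(t) and C_RV(t) sampled on a shared uniform fine time grid.

    Parameters
    ----------
    time_grid
        Uniformly spaced sample times, seconds; step must be <= 0.5 s.
    ca, crv
        Arterial and right-ventricular activity concentrations (kBq/mL),
        non-negative, one value per grid point.
    """

    def __init__(self, time_grid, ca, crv):
        t = np.asarray(time_grid, dtype=float)
        ca = np.asarray(ca, dtype=float)
        crv = np.asarray(crv, dtype=float)
        if not (t.shape == ca.shape == crv.shape) or t.ndim != 1 or t.size < 2:
            raise DomainError("time_grid, ca and crv must be equal-length 1-D arrays")
        steps = np.diff(t)
        if np.any(steps <= 0):
            raise DomainError("time grid must be strictly increasing")
        if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
            raise DomainError("time grid must be uniform")
        if steps[0] > _MAX_STEP_S + 1e-12:
            raise DomainError(f"time grid step must be <= {_MAX_STEP_S} s, got {steps[0]:g}")
        if np.any(ca < 0) or np.any(crv < 0):
            raise DomainError("input functions must be non-negative")
        self.time_grid = t
        self.ca = ca
        self.crv = crv

    @property
    def dt(self) -> float:
        return float(self.time_grid[1] - self.time_grid[0])

    def frame_averages(self, schedule: FrameSchedule) -> tuple[np.ndarray, np.ndarray]:
        """Frame-averaged (C_A, C_RV) over the schedule's intervals."""
        return (
            frame_average(self.time_grid, self.ca, schedule),
            frame_average(self.time_grid, self.crv, schedule),
        )

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {
                "time_s": self.time_grid,
                "Ca_kBq_per_mL": self.ca,
                "Crv_kBq_per_mL": self.crv,
            }
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "InputFunctionSet":
        df = pd.read_csv(path)
        return cls(
            df["time_s"].to_numpy(),
            df["Ca_kBq_per_mL"].to_numpy(),
            df["Crv_kBq_per_mL"].to_numpy(),
        )
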