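"""Single-tissue-compartment kinetics with blood spill-over terms.

The tissue activity concentration of a freely diffusible tracer is modelled as

    C_T(t) = PTF * MBF * C_A(t) (x) exp(-(MBF/V_T) * t) + V_A * C_A(t) + V_RV * C_RV(t)

where (x) denotes convolution, MBF is myocardial blood flow (mL g^-1 min^-1),
PTF the perfusable tissue fraction (g mL^-1), V_T the blood/tissue partition
coefficient of water (fixed at 0.91 mL g^-1), and V_A / V_RV the arterial and
right-ventricular blood-volume (spill-over) fractions.  Time grids are in
seconds, so the exponential rate is MBF / (60 * V_T) per second.

Fitting uses the basis-function trick: for each flow value MBF_i on a
logarithmically spaced grid, the convolution kernel

    B_i(t) = MBF_i * C_A(t) (x) exp(-(MBF_i/V_T) * t)

is precomputed and frame-averaged; the model is then linear in
(PTF, V_A, V_RV) and a 3-coefficient weighted linear least-squares problem is
solved per grid value, keeping the grid value with the smallest residual sum
of squares.

The image-level interface follows the Model/Results idiom:
``SingleTissueModel(series, inputs, schedule, grid).fit()`` returns a
``ParametricFitResults`` carrying the parametric maps, per-voxel residuals and
diagnostics, with derived blood-volume and transmural-flow images as methods.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter

from .exceptions import DomainError, ShapeError
from .grids import VoxelGrid
from .input_functions import InputFunctionSet
from .schedule import FrameSchedule, frame_average

__all__ = [
    "DEFAULT_V_T",
    "BasisSet",
    "VoxelKineticFit",
    "ParametricMaps",
    "exp_conv",
    "make_basis_set",
    "model_tac",
    "fit_voxel",
    "fit_parametric",
    "SingleTissueModel",
    "ParametricFitResults",
]

#: Partition coefficient of water between tissue and blood, mL g^-1.
DEFAULT_V_T = 0.91

#: Default flow grid: 50 log-spaced values spanning 0.1-2.2 mL g^-1 min^-1.
DEFAULT_N_BASIS = 50
DEFAULT_MBF_MIN = 0.1
DEFAULT_MBF_MAX = 2.2


def exp_conv(curve: np.ndarray, dt: float, k: float) -> np.ndarray:
    """Convolve a sampled curve with exp(-k*t): y(t) = int_0^t c(s) e^{-k(t-s)} ds.

    Exact for a piecewise-linear input, evaluated by the one-pole recursion

        y[n] = E * y[n-1] + I0 * c[n-1] + I1 * c[n],   E = exp(-k*dt),

    with I0, I1 the analytic integrals of the two linear hat weights against
    the exponential kernel over one step.  O(n), no quadrature error beyond
    the piecewise-linear representation of the input.
    """
    c = np.asarray(curve, dtype=float)
    if dt <= 0:
        raise DomainError("dt must be positive")
    if k < 0:
        raise DomainError("decay rate k must be non-negative")
    if k == 0.0:
        i0 = i1 = dt / 2.0
        e = 1.0
    else:
        e = np.exp(-k * dt)
        j0 = (1.0 - e) / k
        j1 = (1.0 - e * (1.0 + k * dt)) / k**2
        i0 = j1 / dt
        i1 = j0 - j1 / dt
    y = lfilter([i1, i0], [1.0, -e], c)
    # lfilter assumes y[0] = i1*c[0]; the true initial condition is y(0) = 0,
    # and the discrepancy decays geometrically through the recursion.
    y -= i1 * c[0] * e ** np.arange(c.size)
    return y


def _flow_kernel_frames(
    mbf: float, inputs: InputFunctionSet, schedule: FrameSchedule, v_t: float
) -> np.ndarray:
    """Frame-averaged MBF * C_A (x) exp(-(MBF/V_T) t) for one flow value."""
    k = mbf / (60.0 * v_t)  # per second
    fine = (mbf / 60.0) * exp_conv(inputs.ca, inputs.dt, k)
    return frame_average(inputs.time_grid, fine, schedule)


@dataclass(frozen=True)
class BasisSet:
    """Precomputed frame-averaged basis curves for the flow grid.

    ``basis_frame_avg[i, f]`` is the Eq.-style kernel
    MBF_i * C_A (x) exp(-(MBF_i/V_T) t) averaged over frame ``f``; the linear
    coefficient on row ``i`` is therefore PTF directly.
    """

    mbf_grid: np.ndarray
    v_t: float
    basis_frame_avg: np.ndarray
    ca_frame_avg: np.ndarray
    crv_frame_avg: np.ndarray
    schedule: FrameSchedule

    @property
    def n_basis(self) -> int:
        return int(self.mbf_grid.size)

    @property
    def n_frames(self) -> int:
        return int(self.ca_frame_avg.size)


def make_basis_set(
    inputs: InputFunctionSet,
    schedule: FrameSchedule,
    n_basis: int = DEFAULT_N_BASIS,
    mbf_min: float = DEFAULT_MBF_MIN,
    mbf_max: float = DEFAULT_MBF_MAX,
    v_t: float = DEFAULT_V_T,
) -> BasisSet:
    """Precompute the frame-averaged basis curves on a log-spaced flow grid.

    The grid endpoints equal ``mbf_min`` and ``mbf_max`` exactly.
    """
    if mbf_min <= 0 or mbf_max <= mbf_min:
        raise DomainError("flow bounds must satisfy 0 < mbf_min < mbf_max")
    if n_basis < 2:
        raise DomainError("n_basis must be at least 2")
    if v_t <= 0:
        raise DomainError("partition coefficient V_T must be positive")
    grid = np.geomspace(mbf_min, mbf_max, n_basis)
    grid[0], grid[-1] = mbf_min, mbf_max
    basis = np.stack([_flow_kernel_frames(m, inputs, schedule, v_t) for m in grid])
    ca_f, crv_f = inputs.frame_averages(schedule)
    return BasisSet(
        mbf_grid=grid,
        v_t=v_t,
        basis_frame_avg=basis,
        ca_frame_avg=ca_f,
        crv_frame_avg=crv_f,
        schedule=schedule,
    )


def model_tac(
    mbf: float,
    ptf: float,
    v_a: float,
    v_rv: float,
    inputs: InputFunctionSet,
    schedule: FrameSchedule,
    v_t: float = DEFAULT_V_T,
) -> np.ndarray:
    """Frame-averaged model tissue time-activity curve for one parameter set."""
    if v_t <= 0:
        raise DomainError("partition coefficient V_T must be positive")
    if mbf < 0:
        raise DomainError("MBF must be non-negative")
    for name, v in (("mbf", mbf), ("ptf", ptf), ("v_a", v_a), ("v_rv", v_rv)):
        if not np.isfinite(v):
            raise DomainError(f"parameter {name} must be finite")
    ca_f, crv_f = inputs.frame_averages(schedule)
    tac = v_a * ca_f + v_rv * crv_f
    if mbf > 0 and ptf != 0:
        tac = tac + ptf * _flow_kernel_frames(mbf, inputs, schedule, v_t)
    return tac


@dataclass(frozen=True)
class VoxelKineticFit:
    """Best-fitting kinetic parameters for one voxel TAC."""

    mbf: float  # mL g^-1 min^-1, one value of the basis grid (0 for empty TAC)
    ptf: float  # g mL^-1
    v_a: float  # arterial blood-volume / spill-over fraction
    v_rv: float  # right-ventricular blood-volume / spill-over fraction
    rss: float  # weighted residual sum of squares at the optimum
    clamped: bool = False  # any coefficient hit its physical bound
    failed: bool = False  # singular design matrix


def _design_matrices(basis: BasisSet, weights: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-grid-index weighted design matrices A_i (n_basis, n_frames, 3) and pinvs."""
    sw = np.sqrt(weights)
    n_b, n_f = basis.basis_frame_avg.shape
    a = np.empty((n_b, n_f, 3))
    a[:, :, 0] = basis.basis_frame_avg * sw
    a[:, :, 1] = basis.ca_frame_avg * sw
    a[:, :, 2] = basis.crv_frame_avg * sw
    pinv = np.stack([np.linalg.pinv(a[i]) for i in range(n_b)])
    return a, pinv


def _check_weights(weights, n_frames: int) -> np.ndarray:
    if weights is None:
        return np.ones(n_frames)
    w = np.asarray(weights, dtype=float)
    if w.shape != (n_frames,):
        raise ShapeError(f"weights must have length {n_frames}")
    if np.any(w < 0):
        raise DomainError("weights must be non-negative")
    return w


def _clamp(theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Clamp (PTF, V_A, V_RV) rows to physical ranges; return clamped flag."""
    clipped = np.empty_like(theta)
    clipped[:, 0] = np.clip(theta[:, 0], 0.0, None)
    clipped[:, 1] = np.clip(theta[:, 1], 0.0, 1.0)
    clipped[:, 2] = np.clip(theta[:, 2], 0.0, 1.0)
    flag = np.any(clipped != theta, axis=1)
    return clipped, flag


def fit_voxel(tac, basis: BasisSet, weights=None) -> VoxelKineticFit:
    """Fit one frame-averaged TAC by basis-function least squares.

    For each flow grid value the 3-coefficient weighted linear least-squares
    problem over (B_i, C_A, C_RV) is solved; the grid value minimising the
    weighted RSS wins, ties resolving to the smaller MBF.  V_A and V_RV are
    clamped to [0, 1] and PTF to >= 0 after the scan; an all-zero TAC returns
    an all-zero fit.
    """
    y = np.asarray(tac, dtype=float)
    if y.shape != (basis.n_frames,):
        raise ShapeError(f"tac must have length {basis.n_frames}")
    fits = fit_parametric(
        y.reshape(1, 1, 1, basis.n_frames),
        VoxelGrid((1, 1, 1), (1.0, 1.0, 1.0)),
        basis,
        weights=weights,
    )
    return VoxelKineticFit(
        mbf=float(fits.mbf[0, 0, 0]),
        ptf=float(fits.ptf[0, 0, 0]),
        v_a=float(fits.v_a[0, 0, 0]),
        v_rv=float(fits.v_rv[0, 0, 0]),
        rss=float(fits.rss[0, 0, 0]),
        clamped=bool(fits.clamped[0, 0, 0]),
        failed=bool(fits.failed[0, 0, 0]),
    )


@dataclass(frozen=True)
class ParametricMaps:
    """Voxelwise kinetic parameter volumes sharing one grid."""

    grid: VoxelGrid
    mbf: np.ndarray
    ptf: np.ndarray
    v_a: np.ndarray
    v_rv: np.ndarray
    rss: np.ndarray = None
    clamped: np.ndarray = None
    failed: np.ndarray = None

    def __post_init__(self):
        shape = tuple(self.grid.dims)
        for name in ("mbf", "ptf", "v_a", "v_rv"):
            arr = getattr(self, name)
            if arr.shape != shape:
                raise ShapeError(f"{name} map shape {arr.shape} != grid dims {shape}")


def fit_parametric(
    series: np.ndarray,
    grid: VoxelGrid,
    basis: BasisSet,
    mask: np.ndarray | None = None,
    weights=None,
) -> ParametricMaps:
    """Fit every voxel of a 4-D dynamic series (x, y, z, frame).

    Voxels outside ``mask`` (and voxels whose TAC is identically zero) are set
    to zero in every output map.  The computation is fully vectorised over
    voxels and deterministic.
    """
    series = np.asarray(series, dtype=float)
    shape = tuple(grid.dims)
    if series.shape != shape + (basis.n_frames,):
        raise ShapeError(
            f"series shape {series.shape} != grid dims + frames {shape + (basis.n_frames,)}"
        )
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    elif mask.shape != shape:
        raise ShapeError("mask shape must equal grid dims")

    w = _check_weights(weights, basis.n_frames)
    a, pinv = _design_matrices(basis, w)
    ranks = np.array([np.linalg.matrix_rank(a[i]) for i in range(basis.n_basis)])

    y = series[mask] * np.sqrt(w)  # (N, F), weighted
    n = y.shape[0]
    nonzero = np.any(series[mask] != 0, axis=1)

    best_rss = np.full(n, np.inf)
    best_idx = np.zeros(n, dtype=int)
    best_theta = np.zeros((n, 3))
    for i in range(basis.n_basis):
        theta = y @ pinv[i].T  # (N, 3)
        resid = y - theta @ a[i].T
        rss = np.einsum("nf,nf->n", resid, resid)
        better = rss < best_rss  # strict: ties keep the smaller MBF_i
        best_rss[better] = rss[better]
        best_idx[better] = i
        best_theta[better] = theta[better]

    theta_c, clamped = _clamp(best_theta)
    mbf_v = basis.mbf_grid[best_idx]
    failed_v = ranks[best_idx] < 3

    # all-zero TACs: defined as an all-zero fit, not a flow-grid value
    for arr, val in ((mbf_v, 0.0), (best_rss, 0.0)):
        arr[~nonzero] = val
    theta_c[~nonzero] = 0.0
    clamped[~nonzero] = False
    failed_v[~nonzero] = False

    def full(vec, dtype=float, fill=0):
        out = np.full(shape, fill, dtype=dtype)
        out[mask] = vec
        return out

    return ParametricMaps(
        grid=grid,
        mbf=full(mbf_v),
        ptf=full(theta_c[:, 0]),
        v_a=full(theta_c[:, 1]),
        v_rv=full(theta_c[:, 2]),
        rss=full(best_rss),
        clamped=full(clamped, dtype=bool, fill=False),
        failed=full(failed_v, dtype=bool, fill=False),
    )


class SingleTissueModel:
    """Voxelwise single-tissue-compartment model for a dynamic image series.

    Parameters
    ----------
    series
        4-D array (x, y, z, frame) of activity concentrations, kBq/mL,
        assumed decay-corrected.
    inputs
        Arterial and right-ventricular input functions.
    schedule
        Frame timing of the series.
    grid
        Voxel geometry of the series.
    v_t
        Water partition coefficient, mL g^-1.
    n_basis, mbf_min, mbf_max
        Flow grid for the basis functions (log-spaced, endpoints inclusive).

    Examples
    --------
    >>> model = SingleTissueModel(series, inputs, schedule, grid)
    >>> res = model.fit()
    >>> res.maps.mbf.shape == grid.dims
    True
    """

    def __init__(
        self,
        series: np.ndarray,
        inputs: InputFunctionSet,
        schedule: FrameSchedule,
        grid: VoxelGrid,
        v_t: float = DEFAULT_V_T,
        n_basis: int = DEFAULT_N_BASIS,
        mbf_min: float = DEFAULT_MBF_MIN,
        mbf_max: float = DEFAULT_MBF_MAX,
    ):
        self.series = np.asarray(series, dtype=float)
        self.inputs = inputs
        self.schedule = schedule
        self.grid = grid
        self.basis = make_basis_set(inputs, schedule, n_basis, mbf_min, mbf_max, v_t)
        if self.series.shape != tuple(grid.dims) + (schedule.n_frames,):
            raise ShapeError("series shape must be grid dims + (n_frames,)")

    def fit(self, mask: np.ndarray | None = None, weights: str | np.ndarray | None = None):
        """Fit all voxels; ``weights`` may be None (uniform), 'duration', or an array."""
        if isinstance(weights, str):
            if weights != "duration":
                raise DomainError("weights must be None, 'duration', or an array")
            weights = self.schedule.frame_duration / self.schedule.frame_duration.mean()
        maps = fit_parametric(self.series, self.grid, self.basis, mask=mask, weights=weights)
        return ParametricFitResults(self, maps, mask)


class ParametricFitResults:
    """Results of a voxelwise basis-function fit."""

    def __init__(self, model: SingleTissueModel, maps: ParametricMaps, mask):
        self.model = model
        self.maps = maps
        self.mask = mask

    @property
    def n_clamped(self) -> int:
        return int(np.count_nonzero(self.maps.clamped))

    @property
    def n_failed(self) -> int:
        return int(np.count_nonzero(self.maps.failed))

    def blood_volume(self):
        """Blood-volume image V_B = V_A + V_RV (DerivedImage)."""
        from .imaging import blood_volume_map

        return blood_volume_map(self.maps)

    def transmural_flow(self):
        """Transmural-flow image MBFt = MBF * PTF (DerivedImage)."""
        from .imaging import transmural_flow_map

        return transmural_flow_map(self.maps)

    def fitted_tac(self, voxel) -> np.ndarray:
        """Model-predicted frame curve at one voxel index."""
        i, j, k = voxel
        return model_tac(
            float(self.maps.mbf[i, j, k]),
            float(self.maps.ptf[i, j, k]),
            float(self.maps.v_a[i, j, k]),
            float(self.maps.v_rv[i, j, k]),
            self.model.inputs,
            self.model.schedule,
            self.model.basis.v_t,
        )

    def summary(self) -> str:
        sel = np.ones(self.maps.mbf.shape, bool) if self.mask is None else self.mask
        lines = [
            "Single-tissue-compartment basis-function fit",
            "=" * 44,
            f"voxels fitted        : {int(np.count_nonzero(sel))}",
            f"frames               : {self.model.schedule.n_frames}"
            f" (span {self.model.schedule.total_span:g} s)",
            f"flow grid            : {self.model.basis.n_basis} values,"
            f" {self.model.basis.mbf_grid[0]:g}-{self.model.basis.mbf_grid[-1]:g}"
            " mL/g/min (log-spaced)",
            f"partition coeff V_T  : {self.model.basis.v_t:g} mL/g",
            f"clamped voxels       : {self.n_clamped}",
            f"singular-fit voxels  : {self.n_failed}",
            "",
            f"{'map':>6} {'mean':>10} {'max':>10}",
        ]
        for name in ("mbf", "ptf", "v_a", "v_rv"):
            arr = getattr(self.maps, name)[sel]
            lines.append(f"{name:>6} {arr.mean():>10.4f} {arr.max():>10.4f}")
        return "\n".join(lines)

    def plot_voxel_fit(self, voxel, ax=None):
        """Plot the measured and fitted TAC at one voxel."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t = self.model.schedule.frame_mid
        ax.plot(t, self.model.series[tuple(voxel)], "o", label="measured")
        ax.plot(t, self.fitted_tac(voxel), "-", label="model")
        ax.set_xlabel("time (s)")
        ax.set_ylabel("activity (kBq/mL)")
        ax.legend()
        return ax
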