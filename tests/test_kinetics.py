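"""Kinetics: basis construction, forward model and basis-function fitting.

The independent oracles here are (i) analytic convolution of a step input
with the exponential kernel and (ii) an exhaustive per-grid-index least-squares
scan written directly in the tests.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fivedpet import (
    DomainError,
    InputFunctionSet,
    ShapeError,
    VoxelGrid,
    fit_parametric,
    fit_voxel,
    make_basis_set,
    model_tac,
    water_protocol_schedule,
)
from fivedpet.kinetics import exp_conv


def step_inputs(schedule, level=10.0, dt=0.1):
    """Constant arterial concentration from t = 0, zero RV curve."""
    t = np.arange(0.0, schedule.total_span + dt / 2, dt)
    return InputFunctionSet(t, np.full_like(t, level), np.zeros_like(t))


def step_response_frame_means(schedule, mbf, ptf, level, v_t=0.91):
    """Analytic frame means of PTF*V_T*c*(1 - exp(-MBF t / V_T)) with t in seconds."""
    k = mbf / (60.0 * v_t)
    t0, t1 = schedule.frame_start, schedule.frame_end
    integral = (t1 - t0) - (np.exp(-k * t0) - np.exp(-k * t1)) / k
    return ptf * v_t * level * integral / (t1 - t0)


class TestBasisSet:
    def test_default_grid_is_50_log_spaced_values_from_0p1_to_2p2(self, basis):
        assert basis.n_basis == 50
        assert basis.mbf_grid[0] == 0.1
        assert basis.mbf_grid[-1] == 2.2
        ratios = basis.mbf_grid[1:] / basis.mbf_grid[:-1]
        np.testing.assert_allclose(ratios, ratios[0], rtol=1e-9)
        assert np.all(np.isfinite(basis.basis_frame_avg))
        assert np.all(basis.basis_frame_avg >= 0)

    def test_two_point_grid_is_exactly_the_bounds(self, inputs, schedule):
        b = make_basis_set(inputs, schedule, n_basis=2, mbf_min=0.1, mbf_max=2.2)
        np.testing.assert_array_equal(b.mbf_grid, [0.1, 2.2])

    def test_invalid_bounds_raise(self, inputs, schedule):
        with pytest.raises(DomainError):
            make_basis_set(inputs, schedule, mbf_min=0.0)
        with pytest.raises(DomainError):
            make_basis_set(inputs, schedule, mbf_min=1.0, mbf_max=0.5)

    def test_basis_row_matches_forward_model(self, inputs, schedule, basis):
        # model with (MBF_i, PTF, 0, 0) equals PTF times basis row i
        i, ptf = 17, 0.73
        tac = model_tac(basis.mbf_grid[i], ptf, 0.0, 0.0, inputs, schedule)
        np.testing.assert_allclose(tac, ptf * basis.basis_frame_avg[i], rtol=1e-10)


class TestForwardModel:
    def test_zero_flow_leaves_only_blood_terms(self, inputs, schedule):
        ca_f, crv_f = inputs.frame_averages(schedule)
        tac = model_tac(0.0, 0.6, 0.3, 0.2, inputs, schedule)
        np.testing.assert_allclose(tac, 0.3 * ca_f + 0.2 * crv_f, rtol=1e-12)

    def test_pure_arterial_voxel_returns_frame_averaged_ca(self, inputs, schedule):
        ca_f, _ = inputs.frame_averages(schedule)
        tac = model_tac(1.0, 0.0, 1.0, 0.0, inputs, schedule)
        np.testing.assert_allclose(tac, ca_f, rtol=1e-12)

    @pytest.mark.parametrize("mbf,ptf", [(0.5, 0.6), (1.3, 0.8), (2.2, 0.3)])
    def test_step_input_matches_analytic_convolution(self, mbf, ptf):
        sch = water_protocol_schedule()
        inp = step_inputs(sch, level=10.0)
        tac = model_tac(mbf, ptf, 0.0, 0.0, inp, sch)
        expected = step_response_frame_means(sch, mbf, ptf, 10.0)
        np.testing.assert_allclose(tac, expected, rtol=1e-3)  # < 0.1 %

    def test_decay_rate_is_one_per_minute_when_mbf_equals_vt(self):
        # MBF = V_T = 0.91 -> exponent MBF/(60 V_T) = 1/60 per second = 1 per minute
        sch = water_protocol_schedule()
        inp = step_inputs(sch)
        tac = model_tac(0.91, 1.0, 0.0, 0.0, inp, sch, v_t=0.91)
        k = 1.0 / 60.0
        t0, t1 = sch.frame_start, sch.frame_end
        integral = (t1 - t0) - (np.exp(-k * t0) - np.exp(-k * t1)) / k
        expected = 0.91 * 10.0 * integral / (t1 - t0)
        np.testing.assert_allclose(tac, expected, rtol=1e-3)

    def test_negative_partition_coefficient_raises(self, inputs, schedule):
        with pytest.raises(DomainError):
            model_tac(1.0, 0.5, 0.1, 0.1, inputs, schedule, v_t=-0.5)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(scale=st.floats(0.0, 5.0))
    def test_model_is_homogeneous_in_linear_parameters(self, inputs, schedule, scale):
        base = model_tac(1.0, 0.6, 0.2, 0.1, inputs, schedule)
        scaled = model_tac(1.0, scale * 0.6, scale * 0.2, scale * 0.1, inputs, schedule)
        np.testing.assert_allclose(scaled, scale * base, rtol=1e-9, atol=1e-12)

    def test_halving_the_fine_grid_step_changes_frame_means_below_0p1_percent(self):
        sch = water_protocol_schedule()
        from fivedpet import PhantomConfig, simulate_input_functions

        coarse = simulate_input_functions(PhantomConfig(time_step_s=0.1))
        fine = simulate_input_functions(PhantomConfig(time_step_s=0.05))
        tac_c = model_tac(1.0, 0.6, 0.2, 0.1, coarse, sch)
        tac_f = model_tac(1.0, 0.6, 0.2, 0.1, fine, sch)
        assert np.max(np.abs(tac_c - tac_f) / np.abs(tac_f)) < 1e-3


def exhaustive_scan(tac, basis):
    """Independent oracle: per-grid-index 3-coefficient least squares."""
    best = None
    for i in range(basis.n_basis):
        a = np.column_stack(
            [basis.basis_frame_avg[i], basis.ca_frame_avg, basis.crv_frame_avg]
        )
        theta, *_ = np.linalg.lstsq(a, tac, rcond=None)
        rss = float(np.sum((tac - a @ theta) ** 2))
        if best is None or rss < best[1] - 1e-12 * max(1.0, best[1]):
            best = (i, rss, theta)
    return best


class TestFitVoxel:
    def test_on_grid_parameters_are_recovered_exactly(self, inputs, schedule, basis):
        mbf = basis.mbf_grid[23]
        tac = model_tac(mbf, 0.55, 0.15, 0.08, inputs, schedule)
        fit = fit_voxel(tac, basis)
        assert fit.mbf == mbf
        assert fit.ptf == pytest.approx(0.55, rel=1e-6)
        assert fit.v_a == pytest.approx(0.15, rel=1e-6)
        assert fit.v_rv == pytest.approx(0.08, rel=1e-6)
        assert not fit.failed

    def test_off_grid_flow_recovers_a_bracketing_grid_value(self, inputs, schedule, basis):
        mbf = 1.0  # strictly between two grid values
        assert mbf not in basis.mbf_grid
        tac = model_tac(mbf, 0.6, 0.1, 0.05, inputs, schedule)
        fit = fit_voxel(tac, basis)
        lo = basis.mbf_grid[basis.mbf_grid < mbf].max()
        hi = basis.mbf_grid[basis.mbf_grid > mbf].min()
        assert fit.mbf in (lo, hi)

    def test_pure_arterial_tac_yields_unit_arterial_fraction(self, inputs, schedule, basis):
        tac = inputs.frame_averages(schedule)[0]
        fit = fit_voxel(tac, basis)
        assert fit.v_a == pytest.approx(1.0, abs=1e-8)
        assert fit.ptf == pytest.approx(0.0, abs=1e-8)
        assert fit.v_rv == pytest.approx(0.0, abs=1e-8)

    def test_all_zero_tac_returns_all_zero_fit(self, basis):
        fit = fit_voxel(np.zeros(basis.n_frames), basis)
        assert (fit.mbf, fit.ptf, fit.v_a, fit.v_rv, fit.rss) == (0, 0, 0, 0, 0)
        assert not fit.failed

    def test_matches_exhaustive_scan_on_100_random_tacs(self, inputs, schedule, basis, rng):
        ca_f, _ = inputs.frame_averages(schedule)
        for _ in range(100):
            mbf = rng.uniform(0.1, 2.2)
            tac = model_tac(mbf, rng.uniform(0, 1), rng.uniform(0, 0.5),
                            rng.uniform(0, 0.5), inputs, schedule)
            tac = tac + rng.normal(0, 0.05 * ca_f.max(), tac.shape)
            fit = fit_voxel(tac, basis)
            idx_o, rss_o, _ = exhaustive_scan(tac, basis)
            assert basis.mbf_grid[idx_o] == fit.mbf
            # returned RSS is the global minimum over the grid (pre-clamping)
            assert fit.rss <= rss_o * (1 + 1e-9)

    def test_negative_coefficients_are_clamped_and_flagged(self, inputs, schedule, basis):
        # a TAC proportional to -C_A forces negative unconstrained coefficients
        tac = -inputs.frame_averages(schedule)[0]
        fit = fit_voxel(tac, basis)
        assert fit.clamped
        assert fit.ptf >= 0 and 0 <= fit.v_a <= 1 and 0 <= fit.v_rv <= 1

    def test_wrong_tac_length_raises(self, basis):
        with pytest.raises(ShapeError):
            fit_voxel(np.zeros(basis.n_frames + 1), basis)


class TestFitParametric:
    def test_uniform_zero_image_gives_all_zero_maps(self, basis):
        grid = VoxelGrid((3, 3, 2), (4.0, 4.0, 4.0))
        maps = fit_parametric(np.zeros(grid.dims + (basis.n_frames,)), grid, basis)
        for arr in (maps.mbf, maps.ptf, maps.v_a, maps.v_rv):
            assert not arr.any()

    def test_voxelwise_fit_recovers_generating_maps(self, inputs, schedule, basis, rng):
        grid = VoxelGrid((4, 3, 2), (4.0, 4.0, 4.0))
        mbf_true = rng.choice(basis.mbf_grid, size=grid.dims)
        ptf_true = rng.uniform(0.2, 0.9, grid.dims)
        va_true = rng.uniform(0.0, 0.4, grid.dims)
        vrv_true = rng.uniform(0.0, 0.4, grid.dims)
        series = np.empty(grid.dims + (basis.n_frames,))
        for idx in np.ndindex(grid.dims):
            series[idx] = model_tac(
                float(mbf_true[idx]), float(ptf_true[idx]), float(va_true[idx]),
                float(vrv_true[idx]), inputs, schedule,
            )
        maps = fit_parametric(series, grid, basis)
        np.testing.assert_array_equal(maps.mbf, mbf_true)
        np.testing.assert_allclose(maps.ptf, ptf_true, rtol=1e-6)
        np.testing.assert_allclose(maps.v_a, va_true, rtol=1e-6, atol=1e-8)
        np.testing.assert_allclose(maps.v_rv, vrv_true, rtol=1e-6, atol=1e-8)

    def test_fit_is_deterministic(self, inputs, schedule, basis, rng):
        grid = VoxelGrid((3, 2, 2), (4.0, 4.0, 4.0))
        series = rng.uniform(0, 50, grid.dims + (basis.n_frames,))
        m1 = fit_parametric(series, grid, basis)
        m2 = fit_parametric(series, grid, basis)
        for name in ("mbf", "ptf", "v_a", "v_rv", "rss"):
            np.testing.assert_array_equal(getattr(m1, name), getattr(m2, name))

    def test_mask_excludes_voxels(self, inputs, schedule, basis):
        grid = VoxelGrid((2, 2, 1), (4.0, 4.0, 4.0))
        tac = model_tac(1.0, 0.6, 0.1, 0.0, inputs, schedule)
        series = np.broadcast_to(tac, grid.dims + (basis.n_frames,)).copy()
        mask = np.zeros(grid.dims, bool)
        mask[0, 0, 0] = True
        maps = fit_parametric(series, grid, basis, mask=mask)
        assert maps.ptf[0, 0, 0] > 0
        assert not maps.ptf[~mask].any()

    def test_shape_mismatch_raises(self, basis):
        grid = VoxelGrid((3, 3, 2), (4.0, 4.0, 4.0))
        with pytest.raises(ShapeError):
            fit_parametric(np.zeros((3, 3, 3, basis.n_frames)), grid, basis)


class TestExpConv:
    def test_matches_dense_quadrature(self, rng):
        dt, k = 0.1, 0.05
        t = np.arange(0, 60, dt)
        c = np.interp(t, [0, 10, 20, 60], [0, 30, 5, 1])
        y = exp_conv(c, dt, k)
        # oracle: direct quadrature of the convolution integral on a finer grid
        tf = np.arange(0, 60, dt / 20)
        cf = np.interp(tf, t, c)
        j = np.searchsorted(tf, t[-1])
        for i in (150, 300, 599):
            ti = t[i]
            sel = tf <= ti + 1e-12
            integrand = cf[sel] * np.exp(-k * (ti - tf[sel]))
            oracle = np.trapezoid(integrand, tf[sel])
            assert y[i] == pytest.approx(oracle, rel=1e-4)
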