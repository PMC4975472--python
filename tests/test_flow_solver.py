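"""Axisymmetric solver: operators, boundary conditions, surface tracking."""

import numpy as np
import pytest

from mucusflow.constitutive import FluidModel, GiesekusMode
from mucusflow.flow_solver import (
    AxisymmetricFlowSolver,
    FlowState,
    Geometry,
    Grid,
    SolverError,
    SurfaceMarkers,
    capillary_pressure,
    curvature_from_markers,
    drive_bottom_velocity,
    fluid_volume,
    mass_flux_theta0,
    run_to_quasi_steady,
    surface_profile,
)
from mucusflow.forcing import SwirlDrive, boundary_layer_blend

GEOM = Geometry()


def make_solver(model=None, nr=32, nz=6, omega=1.57e-2, **kw):
    model = model or FluidModel(10.0, 1000.0, ())
    grid = Grid(nr, nz, GEOM.radius, GEOM.depth)
    return AxisymmetricFlowSolver(
        GEOM, grid, model, SwirlDrive(omega), 0.01, reseed_interval=1, **kw
    )


class TestTypes:
    def test_geometry_validation(self):
        with pytest.raises(ValueError):
            Geometry(depth=2e-4, height=1e-4)
        assert GEOM.aspect_ratio == pytest.approx(200.0)

    def test_grid_maps(self):
        g = Grid(16, 8, 1e-2, 5e-5)
        assert g.r_centers[0] == pytest.approx(g.dr / 2)
        assert g.z_faces[-1] == pytest.approx(5e-5)
        i, k = g.center_index(5e-3, 2.5e-5)
        assert abs(g.r_centers[i] - 5e-3) <= g.dr
        assert abs(g.z_centers[k] - 2.5e-5) <= g.dz

    def test_rest_state(self):
        st = FlowState.rest(Grid(16, 8, 1e-2, 5e-5), 3)
        assert st.tau.shape == (3, 6, 16, 8)
        assert np.all(st.divergence() == 0)


class TestCurvature:
    def test_flat_surface(self):
        mk = SurfaceMarkers.flat(1e-2, 5e-5)
        assert np.allclose(curvature_from_markers(mk), 0.0, atol=1e-6)

    def test_spherical_cap(self):
        a = 0.1
        r = np.linspace(0, 0.02, 200)
        mk = SurfaceMarkers(r, 1.0 + np.sqrt(a**2 - r**2))
        kappa = curvature_from_markers(mk, r=r[5:-5])
        assert np.allclose(kappa, 2.0 / a, rtol=1e-3)

    def test_near_axis_paraboloid(self):
        # dome h = H - c r^2: both principal curvatures 2c at the axis
        c = 50.0
        r = np.linspace(0, 5e-3, 100)
        mk = SurfaceMarkers(r, 5e-5 - c * r**2 + 1.0)
        kappa = curvature_from_markers(mk, r=np.array([0.0, 1e-4]))
        assert np.allclose(kappa, 4 * c, rtol=1e-3)

    def test_inplane_convention(self):
        a = 0.1
        r = np.linspace(0, 0.02, 200)
        mk = SurfaceMarkers(r, 1.0 + np.sqrt(a**2 - r**2))
        # trim the spline's natural-end boundary wiggle
        kappa = curvature_from_markers(mk, r=r[5:-15], convention="inplane")
        assert np.allclose(kappa, 1.0 / a, rtol=1e-3)

    def test_overturned_surface_rejected(self):
        with pytest.raises(SolverError):
            SurfaceMarkers(np.array([0.0, 2.0, 1.0, 3.0]), np.zeros(4))

    def test_capillary_pressure(self):
        assert capillary_pressure(100.0, 0.03) == pytest.approx(3.0)
        assert capillary_pressure(0.0) == 0.0
        # dome (kappa > 0) raises the interior pressure by convention
        assert capillary_pressure(10.0) > 0


class TestBoundaryConditions:
    def test_drive_vanishes_at_wall(self):
        r = np.array([0.0, 5e-3, 9.99e-3, 1e-2])
        u = drive_bottom_velocity(SwirlDrive(1.57e-2), r, 0.0, 1e-2)
        assert u[-1] == 0.0
        assert u[1] == pytest.approx(
            1.57e-2 * 5e-3 * boundary_layer_blend(1.0, 5e-3, 1e-2), rel=1e-12
        )

    def test_no_slip_enforced(self):
        s = make_solver()
        st = s.step()
        assert np.all(st.u_r[0] == 0) and np.all(st.u_r[-1] == 0)
        assert np.all(st.u_z[:, 0] == 0)

    def test_axis_symmetry_of_even_fields(self):
        s = make_solver()
        for _ in range(20):
            st = s.step()
        # one-sided difference of u_z at the axis vanishes to grid tolerance
        uzc = 0.5 * (st.u_z[:, :-1] + st.u_z[:, 1:])
        scale = np.abs(uzc).max() + 1e-30
        assert np.abs(uzc[0] - uzc[1]).max() / scale < 0.5


class TestStep:
    def test_rest_is_fixed_point(self):
        s = make_solver(omega=0.0)
        for _ in range(5):
            st = s.step()
        assert np.all(st.u_theta == 0)
        assert np.all(st.u_r == 0)
        assert np.abs(st.u_z).max() < 1e-25
        assert np.allclose(
            surface_profile(st)["h_m"], GEOM.depth, atol=1e-20
        )

    def test_divergence_free_after_projection(self):
        s = make_solver()
        for _ in range(50):
            st = s.step()
        u_ref = 1.57e-4
        assert np.abs(st.divergence()).max() <= 1e-8 * u_ref / GEOM.depth

    def test_nan_detection(self):
        s = make_solver()
        s.step()
        s.state.u_theta[3, 3] = np.nan
        with pytest.raises(SolverError):
            s.state.check_finite()

    def test_newtonian_limit_matches_fast_ucm(self):
        """Zero modes vs a UCM mode with lambda -> 0 at matched eta_0:
        identical steady swirl u_theta to < 1% relative L2."""
        newt = make_solver(FluidModel(10.0, 1000.0, ()))
        fast = make_solver(
            FluidModel(1e-3, 1000.0, (GiesekusMode(1e-3, 9999.0, 0.0),))
        )
        for _ in range(100):
            st_n = newt.step()
            st_f = fast.step()
        diff = np.linalg.norm(st_n.u_theta - st_f.u_theta)
        assert diff / np.linalg.norm(st_n.u_theta) < 0.01

    def test_grid_convergence_u_theta(self):
        """2x refinement changes the steady swirl primary flow by < 2%."""
        fields = {}
        for nr, nz in ((48, 6), (96, 12)):
            grid = Grid(nr, nz, GEOM.radius, GEOM.depth)
            s = AxisymmetricFlowSolver(
                GEOM, grid, FluidModel(10.0, 1000.0, ()),
                SwirlDrive(1.57e-2), 0.01, reseed_interval=1,
            )
            for _ in range(100):
                st = s.step()
            fields[nr] = (grid, st.u_theta)
        g_c, u_c = fields[48]
        g_f, u_f = fields[96]
        # restrict the fine solution to the coarse cells (2x2 averages land
        # exactly on the coarse cell centers)
        u_f_on_c = 0.25 * (
            u_f[0::2, 0::2] + u_f[1::2, 0::2]
            + u_f[0::2, 1::2] + u_f[1::2, 1::2]
        )
        rel = np.linalg.norm(u_f_on_c - u_c) / np.linalg.norm(u_c)
        assert rel < 0.02


class TestDiagnostics:
    def test_mass_flux_uniform_velocity(self):
        grid = Grid(32, 8, GEOM.radius, GEOM.depth)
        st = FlowState.rest(grid, 0)
        st.u_theta[:] = 2.0e-4
        flux = mass_flux_theta0(st, 1000.0)
        assert flux == pytest.approx(
            1000.0 * 2.0e-4 * GEOM.depth * GEOM.radius, rel=1e-12
        )
        st.u_theta[:] = 0.0
        assert mass_flux_theta0(st, 1000.0) == 0.0

    def test_initial_surface_profile(self):
        st = FlowState.rest(Grid(32, 8, GEOM.radius, GEOM.depth), 0)
        prof = surface_profile(st)
        assert np.allclose(prof["h_m"], GEOM.depth)

    def test_run_to_quasi_steady_newtonian(self):
        s = make_solver()
        state, diag, converged = run_to_quasi_steady(
            s, max_time=10.0, rel_tol=1e-4
        )
        assert converged
        flux = diag["mass_flux"].to_numpy()
        # monotone rise to a plateau
        assert flux[-1] > 0
        assert flux[-1] == pytest.approx(flux[len(flux) // 2], rel=1e-3)

    def test_budget_exhaustion_flagged(self):
        s = make_solver(FluidModel(1e-3, 1000.0, (GiesekusMode(50.0, 1.0, 0.5),)))
        state, diag, converged = run_to_quasi_steady(
            s, max_time=0.5, rel_tol=1e-12
        )
        assert not converged


def test_bit_identical_reruns():
    """Two runs from the same configuration produce bit-identical fields."""
    states = []
    for _ in range(2):
        s = make_solver(FluidModel(1e-3, 1000.0, (GiesekusMode(10.0, 1.0, 0.3),)))
        for _ in range(30):
            st = s.step()
        states.append((st.u_theta.copy(), st.u_r.copy(), st.p.copy()))
    assert np.array_equal(states[0][0], states[1][0])
    assert np.array_equal(states[0][1], states[1][1])
    assert np.array_equal(states[0][2], states[1][2])


class TestVolumeConservation:
    def test_volume_conserved_under_swirl(self):
        s = make_solver(FluidModel(1e-3, 1000.0, (GiesekusMode(10.0, 1.0, 0.3),)))
        v0 = fluid_volume(s.state)
        for _ in range(500):
            st = s.step()
        assert abs(fluid_volume(st) - v0) / v0 < 1e-3
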