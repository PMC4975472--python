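"""Drug advection-diffusion: Peclet numbers, layouts, absorption ledgers."""

import math

import numpy as np
import pytest
from scipy.optimize import brentq

from mucusflow.transport import (
    AbsorptionRegions,
    ConcentrationField,
    absorbed_fraction,
    init_disk,
    init_strip,
    peclet,
    stable_dt,
    step_transport,
    time_to_fraction,
    uptake_sweep,
)

R, H = 1.0e-2, 5.0e-5


class TestPeclet:
    def test_paper_endpoints(self):
        assert peclet(1e-2, 1e-9, 1e-15) == pytest.approx(1e4)
        assert peclet(1e-2, 1e-9, 1e-7) == pytest.approx(1e-4)

    def test_linear_in_velocity(self):
        assert peclet(1e-2, 2e-9, 1e-15) == pytest.approx(
            2 * peclet(1e-2, 1e-9, 1e-15)
        )

    def test_zero_diffusivity_rejected(self):
        with pytest.raises(ValueError):
            peclet(1e-2, 1e-9, 0.0)

    def test_rescaling_invariance(self):
        base = peclet(1e-2, 1e-9, 1e-15)
        assert peclet(2e-2, 1e-9, 2e-15) == pytest.approx(base)
        assert peclet(1e-3, 1e-8, 1e-15) == pytest.approx(base)


class TestInitialLayouts:
    def test_disk_area_fraction(self):
        f = ConcentrationField.zeros(50, 8, R, H, 1e-12)
        init_disk(f, 1e-3)
        top_layer_mass = 1.0 * math.pi * R**2 * (H / 8)
        assert f.initial_mass / top_layer_mass == pytest.approx(
            (1e-3 / R) ** 2, rel=1e-10
        )

    def test_strip_angular_width_constant(self):
        # deposited mass per ring is proportional to ring area: constant
        # angular width 2 pi / 100 independent of radius
        f = ConcentrationField.zeros(24, 6, R, H, 1e-12, ntheta=36)
        init_strip(f, 0.01)
        ring_mass = (f.c[:, :, -1] * f.cell_volumes()[:, None]).sum(axis=1)
        rc = f.r_centers
        expected = 0.01 * 2 * math.pi * rc * f.dr * f.dz  # arc * dr * dz
        assert np.allclose(ring_mass, expected, rtol=1e-10)

    def test_strip_requires_theta_grid(self):
        f = ConcentrationField.zeros(24, 6, R, H, 1e-12)
        with pytest.raises(ValueError):
            init_strip(f)

    def test_zero_value_gives_zero_field(self):
        f = ConcentrationField.zeros(24, 6, R, H, 1e-12)
        init_disk(f, 1e-3, value=0.0)
        assert f.total_mass() == 0.0


class TestStepTransport:
    def test_no_dynamics_field_unchanged(self):
        f = ConcentrationField.zeros(16, 6, R, H, 0.0)
        init_disk(f, 2e-3)
        before = f.c.copy()
        step_transport(f, 1.0)
        assert np.array_equal(f.c, before)

    def test_ledger_conservation(self):
        f = ConcentrationField.zeros(16, 6, R, H, 1e-10)
        init_disk(f, 2e-3)
        dt = stable_dt(f)
        for _ in range(200):
            step_transport(f, dt)
        assert f.mass_balance_error() < 1e-12
        assert absorbed_fraction(f, "total") > 0.05

    def test_rigid_rotation_leaves_axisymmetric_field(self):
        f = ConcentrationField.zeros(12, 4, R, H, 1e-12, ntheta=16)
        f.c[:] = np.linspace(1, 2, 12)[:, None, None]  # axisymmetric
        f.initial_mass = f.total_mass()
        u_theta = 0.01 * f.r_centers[:, None, None] * np.ones_like(f.c)
        before = f.c.copy()
        f.diffusivity = 0.0
        step_transport(f, 0.1, u_theta=u_theta)
        assert np.allclose(f.c, before, atol=1e-18)

    def test_concentration_nonnegative(self):
        f = ConcentrationField.zeros(20, 8, R, H, 1e-10)
        init_disk(f, 1e-3)
        dt = stable_dt(f)
        for _ in range(100):
            step_transport(f, dt)
            assert f.c.min() >= 0.0


class TestAbsorbedFraction:
    def test_unknown_region(self):
        f = ConcentrationField.zeros(12, 4, R, H, 1e-12)
        init_disk(f, 1e-3)
        with pytest.raises(ValueError):
            absorbed_fraction(f, "nope")

    def test_zero_at_start(self):
        f = ConcentrationField.zeros(12, 4, R, H, 1e-12)
        init_disk(f, 1e-3)
        for name in ("inner_disk", "outer", "total"):
            assert absorbed_fraction(f, name) == 0.0

    def test_outer_fraction_matches_separable_oracle(self):
        """Pure diffusion from a disk source: the 2-D (r, z) problem is
        exactly separable, so the outer-section uptake equals the integral
        of (vertical absorption rate) x (radial mass fraction beyond r0)
        from independent 1-D solves on the same grids."""
        nr, nz, D = 48, 8, 1e-13
        f = ConcentrationField.zeros(nr, nz, R, H, D)
        init_disk(f, 1e-3)
        dt = stable_dt(f)
        # independent 1-D radial (reflecting) and vertical (absorbing) FD
        a = f.c[:, -1].copy()  # radial profile
        b = np.zeros(nz)
        b[-1] = 1.0  # vertical profile (top layer)
        rc, rf = f.r_centers, np.arange(nr + 1) * f.dr
        outer_mask = rc > 1e-3
        vols = rc * f.dr
        oracle_outer = 0.0
        n_steps = 3000
        for _ in range(n_steps):
            # radial explicit step, zero flux both ends
            flux = np.zeros(nr + 1)
            flux[1:-1] = -D * (a[1:] - a[:-1]) / f.dr
            a = a - dt * (rf[1:] * flux[1:] - rf[:-1] * flux[:-1]) / (rc * f.dr)
            # vertical explicit step, absorbing bottom
            fz = np.zeros(nz + 1)
            fz[1:-1] = -D * (b[1:] - b[:-1]) / f.dz
            out = D * b[0] / (0.5 * f.dz)
            fz[0] = -out
            b = b - dt * (fz[1:] - fz[:-1]) / f.dz
            radial_outer = (a * vols)[outer_mask].sum() / (a * vols).sum()
            oracle_outer += out * dt / f.dz * radial_outer  # absorbed frac rate
            step_transport(f, dt)
        oracle_outer /= 1.0  # initial vertical mass is 1 per unit column
        got = absorbed_fraction(f, "outer")
        total = absorbed_fraction(f, "total")
        assert total > 0.5
        assert got == pytest.approx(oracle_outer, rel=2e-2)


class TestTimeToFraction:
    def test_target_zero(self):
        f = ConcentrationField.zeros(12, 6, R, H, 1e-10)
        init_disk(f, 1e-3)
        t, ok = time_to_fraction(f, 0.0, dt=1.0)
        assert t == 0.0 and ok

    def test_slab_diffusion_analytic(self):
        """Uniform initial slab, absorbing bottom: 95% crossing time within
        5% of the eigenfunction-series solution."""
        nz, D = 40, 1e-12
        f = ConcentrationField.zeros(4, nz, R, H, D)
        f.c[:] = 1.0
        f.initial_mass = f.total_mass()
        dt = stable_dt(f)
        t_num, ok = time_to_fraction(f, 0.95, dt)
        assert ok

        def remaining(t):
            k = np.arange(60)
            beta = (2 * k + 1) * np.pi / (2 * H)
            return np.sum(8 / ((2 * k + 1) ** 2 * np.pi**2)
                          * np.exp(-(beta**2) * D * t))

        t_ref = brentq(lambda t: remaining(t) - 0.05, 1.0, 1e9)
        assert t_num == pytest.approx(t_ref, rel=0.05)

    def test_monotone_in_diffusivity(self):
        times = []
        for D in (1e-12, 3e-12, 1e-11):
            f = ConcentrationField.zeros(8, 16, R, H, D)
            init_disk(f, 5e-3)
            t, ok = time_to_fraction(f, 0.9, stable_dt(f))
            assert ok
            times.append(t)
        assert times[0] > times[1] > times[2]


class TestUptakeSweep:
    @staticmethod
    def swirl(field):
        u_theta = 1.57e-2 * field.r_centers[:, None, None] * np.ones(
            (field.nr, field.ntheta, field.nz)
        )
        return None, u_theta, None

    def test_sector_effectiveness_bands(self):
        table = uptake_sweep(
            [1e-4, 1e2], "strip", self.swirl,
            nr=28, nz=6, ntheta=36, radius=R, depth=H,
        )
        low = table[table.peclet == 1e-4].iloc[0]
        high = table[table.peclet == 1e2].iloc[0]
        assert low.converged and high.converged
        assert low.sector_fraction < 0.005  # not effective
        assert high.sector_fraction > 0.04  # approaching the perfect 8.33%
        assert high.sector_fraction < 1 / 12 + 0.01

    def test_no_flow_equals_diffusion_oracle(self):
        kw = dict(nr=24, nz=6, ntheta=36, radius=R, depth=H)
        with_none = uptake_sweep([1.0], "strip", None, **kw)
        f = ConcentrationField.zeros(24, 6, R, H, 1e-2 * 1e-9 / 1.0, ntheta=36)
        init_strip(f, 0.01)
        dt = stable_dt(f)
        while absorbed_fraction(f, "total") < 0.99:
            step_transport(f, dt)
        assert with_none.iloc[0].sector_fraction == pytest.approx(
            absorbed_fraction(f, "sector"), rel=1e-6
        )


def test_sector_region_area_fraction():
    regions = AbsorptionRegions()
    assert regions.sector_half_angle * 2 / (2 * math.pi) == pytest.approx(
        1 / 12
    )
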