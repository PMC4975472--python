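"""Constitutive laws: SAOS moduli, steady shear, stress rates, fitting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mucusflow.constitutive import (
    FluidModel,
    GiesekusMode,
    RheoDataset,
    fit_maxwell_spectrum,
    fit_mobility,
    hbe_mucus_five_mode,
    saos_moduli,
    single_mode_reference,
    steady_shear_viscosity,
    stress_rate,
)
from mucusflow.fixtures import (
    FixtureSpec,
    generate_flowcurve_fixture,
    generate_saos_fixture,
    shear_stress_ode,
)


class TestTypes:
    def test_mode_validation(self):
        with pytest.raises(ValueError):
            GiesekusMode(-1.0, 1.0)
        with pytest.raises(ValueError):
            GiesekusMode(1.0, 0.0)
        with pytest.raises(ValueError):
            GiesekusMode(1.0, 1.0, 0.6)
        m = GiesekusMode(2.0, 3.0, 0.5)
        assert m.polymer_viscosity == 6.0

    def test_total_viscosity_sum(self):
        model = hbe_mucus_five_mode()
        expected = 1e-3 + sum(m.polymer_viscosity for m in model.modes)
        assert model.total_viscosity == pytest.approx(expected, rel=1e-15)

    def test_yaml_round_trip(self, tmp_path):
        model = hbe_mucus_five_mode()
        path = tmp_path / "model.yaml"
        model.to_yaml(path)
        back = FluidModel.from_yaml(path)
        assert back == model

    def test_rheodataset_validation(self):
        with pytest.raises(ValueError):
            RheoDataset.from_arrays(
                omega=[2.0, 1.0], g_prime=[1, 1], g_doubleprime=[1, 1]
            )
        with pytest.raises(ValueError):
            RheoDataset.from_arrays(
                omega=[1.0, 2.0], g_prime=[1, -1], g_doubleprime=[1, 1]
            )


class TestSaosModuli:
    def test_single_mode_crossover(self):
        model = FluidModel(0.0, 1000.0, (GiesekusMode(1.0, 1.0),))
        gp, gpp = saos_moduli(model, 1.0)
        assert gp == pytest.approx(0.5)
        assert gpp == pytest.approx(0.5)

    def test_low_frequency_scaling(self):
        model = hbe_mucus_five_mode()
        w = np.array([1e-5, 2e-5])
        gp, gpp = saos_moduli(model, w)
        # G' ~ w^2, G'' ~ w
        assert gp[1] / gp[0] == pytest.approx(4.0, rel=1e-3)
        assert gpp[1] / gpp[0] == pytest.approx(2.0, rel=1e-3)

    def test_five_mode_term_by_term(self):
        # independent hand-summed evaluation of the two Maxwell sums
        model = hbe_mucus_five_mode()
        w = 1.0
        gp_ref = sum(
            m.modulus * (m.relaxation_time * w) ** 2
            / (1 + (m.relaxation_time * w) ** 2)
            for m in model.modes
        )
        gpp_ref = model.solvent_viscosity * w + sum(
            m.modulus * m.relaxation_time * w
            / (1 + (m.relaxation_time * w) ** 2)
            for m in model.modes
        )
        gp, gpp = saos_moduli(model, w)
        assert gp == pytest.approx(gp_ref, rel=1e-14)
        assert gpp == pytest.approx(gpp_ref, rel=1e-14)

    def test_rejects_nonpositive_frequency(self):
        with pytest.raises(ValueError):
            saos_moduli(hbe_mucus_five_mode(), 0.0)

    @given(st.floats(min_value=-3, max_value=3))
    @settings(max_examples=25, deadline=None)
    def test_storage_modulus_monotone(self, logw):
        model = hbe_mucus_five_mode()
        w = 10.0**logw
        gp1, _ = saos_moduli(model, w)
        gp2, _ = saos_moduli(model, 1.01 * w)
        assert gp2 >= gp1 - 1e-12


class TestSteadyShear:
    def test_ucm_constant_viscosity(self):
        model = single_mode_reference(0.0)
        gdot = np.array([1e-3, 1.0, 1e3])
        eta = steady_shear_viscosity(model, gdot)
        assert np.allclose(eta, model.total_viscosity, rtol=1e-12)

    def test_zero_shear_plateau(self):
        model = hbe_mucus_five_mode()
        eta = steady_shear_viscosity(model, 1e-6)
        assert eta == pytest.approx(model.total_viscosity, rel=1e-3)

    @pytest.mark.parametrize("gdot", [1e-3, 0.1, 1.0, 10.0, 1e3])
    def test_matches_ode_to_steady_state(self, gdot):
        """Per-mode Newton solve against long-time integration of the
        constitutive ODE under constant shear (1e-6 relative)."""
        model = single_mode_reference(0.5)
        t_end = 40.0 * 10.0 / max(1.0, (10.0 * gdot) ** 0.5)
        sol = shear_stress_ode(model, lambda t: gdot, (0.0, t_end))
        eta_ode = model.solvent_viscosity + sol.y[2][-1] / gdot
        eta = steady_shear_viscosity(model, gdot)
        assert eta == pytest.approx(eta_ode, rel=1e-6)

    def test_monotone_thinning(self):
        model = hbe_mucus_five_mode()
        gdot = np.geomspace(1e-3, 1e3, 40)
        eta = steady_shear_viscosity(model, gdot)
        assert np.all(np.diff(eta) <= 1e-12)

    def test_rejects_nonpositive_rate(self):
        with pytest.raises(ValueError):
            steady_shear_viscosity(hbe_mucus_five_mode(), -1.0)


class TestStressRate:
    @staticmethod
    def shear_grad(gdot):
        # grad_u[i, j] = d u_j / d x_i for u = (gdot * y, 0, 0)
        g = np.zeros((3, 3))
        g[1, 0] = gdot
        return g

    def test_zero_stress_startup(self):
        mode = GiesekusMode(2.0, 3.0, 0.4)
        rate = stress_rate(mode, np.zeros((3, 3)), self.shear_grad(1.5))
        expected = mode.polymer_viscosity / 2.0 * 1.5
        assert rate[0, 1] == pytest.approx(expected)
        assert rate[1, 0] == pytest.approx(expected)
        assert abs(rate).sum() == pytest.approx(2 * expected)

    def test_pure_relaxation(self):
        mode = GiesekusMode(2.0, 3.0, 0.0)
        tau = np.array([[1.0, 0.5, 0.0], [0.5, -0.2, 0.1], [0.0, 0.1, 0.3]])
        rate = stress_rate(mode, tau, np.zeros((3, 3)))
        assert np.allclose(rate, -tau / 2.0)

    def test_ucm_steady_state_normal_stress(self):
        """Long-time integration gives tau_xy = eta_p*gdot, N1 = 2 eta_p
        lam gdot^2."""
        lam, G, gdot = 1.5, 2.0, 0.7
        model = FluidModel(0.0, 1000.0, (GiesekusMode(lam, G),))
        sol = shear_stress_ode(model, lambda t: gdot, (0.0, 60.0 * lam))
        eta_p = lam * G
        assert sol.y[2][-1] == pytest.approx(eta_p * gdot, rel=1e-8)
        n1 = sol.y[0][-1] - sol.y[1][-1]
        assert n1 == pytest.approx(2 * eta_p * lam * gdot**2, rel=1e-8)

    def test_symmetry_preserved(self):
        rng = np.random.default_rng(7)
        mode = GiesekusMode(1.0, 1.0, 0.3)
        tau = rng.normal(size=(3, 3))
        tau = tau + tau.T
        grad = rng.normal(size=(3, 3))
        rate = stress_rate(mode, tau, grad)
        assert np.allclose(rate, rate.T, atol=1e-14)


class TestFitting:
    def test_five_mode_recovery_noise_free(self):
        spec = FixtureSpec(kind="saos", seed=1, n_points=30, noise_sigma=0.0)
        data = generate_saos_fixture(spec)
        fit = fit_maxwell_spectrum(data, 5, solvent_viscosity=1e-3)
        ref = hbe_mucus_five_mode()
        for got, want in zip(fit.modes, ref.modes):
            assert got.relaxation_time == pytest.approx(
                want.relaxation_time, rel=1e-2
            )
            assert got.modulus == pytest.approx(want.modulus, rel=1e-2)

    def test_single_mode_exact(self):
        model = FluidModel(0.0, 1000.0, (GiesekusMode(0.5, 2.0),))
        w = np.geomspace(0.05, 50, 12)
        gp, gpp = saos_moduli(model, w)
        data = RheoDataset.from_arrays(omega=w, g_prime=gp, g_doubleprime=gpp)
        fit = fit_maxwell_spectrum(data, 1)
        assert fit.modes[0].relaxation_time == pytest.approx(0.5, rel=1e-8)
        assert fit.modes[0].modulus == pytest.approx(2.0, rel=1e-8)

    def test_noisy_fit_residual_at_noise_scale(self):
        spec = FixtureSpec(kind="saos", seed=11, n_points=30, noise_sigma=0.05)
        data = generate_saos_fixture(spec)
        fit = fit_maxwell_spectrum(data, 5, solvent_viscosity=1e-3)
        gp, gpp = saos_moduli(fit, data.saos["omega_rad_s"].to_numpy())
        resid = np.concatenate(
            [
                np.log(gp / data.saos["G_prime_Pa"]),
                np.log(gpp / data.saos["G_doubleprime_Pa"]),
            ]
        )
        assert np.sqrt(np.mean(resid**2)) <= 0.08  # ~ injected sigma

    def test_too_few_points_rejected(self):
        w = np.geomspace(0.1, 10, 6)
        model = hbe_mucus_five_mode()
        gp, gpp = saos_moduli(model, w)
        data = RheoDataset.from_arrays(omega=w, g_prime=gp, g_doubleprime=gpp)
        with pytest.raises(ValueError):
            fit_maxwell_spectrum(data, 5)

    def test_mobility_curve_recovery(self):
        spec = FixtureSpec(
            kind="flowcurve", seed=2, n_points=20, noise_sigma=0.0,
            x_min=1e-2, x_max=1e2,
        )
        data = generate_flowcurve_fixture(spec)
        fitted = fit_mobility(data, hbe_mucus_five_mode(ucm=True))
        eta = steady_shear_viscosity(
            fitted, data.flow_curve["shear_rate_per_s"].to_numpy()
        )
        assert np.allclose(
            eta, data.flow_curve["viscosity_Pa_s"].to_numpy(), rtol=1e-2
        )

    def test_ucm_curve_drives_mobility_to_zero(self):
        model = hbe_mucus_five_mode(ucm=True)
        gdot = np.geomspace(0.01, 100, 15)
        eta = np.full_like(gdot, model.total_viscosity)
        data = RheoDataset.from_arrays(shear_rate=gdot, viscosity=eta)
        fitted = fit_mobility(data, model)
        assert max(m.mobility for m in fitted.modes) < 1e-4

    def test_strong_thinning_hits_upper_bound(self):
        # curve generated with all alpha = 0.5 stays at the bound
        gen = hbe_mucus_five_mode(ucm=True).with_mobilities([0.5] * 5)
        gdot = np.geomspace(0.01, 100, 15)
        eta = steady_shear_viscosity(gen, gdot)
        data = RheoDataset.from_arrays(shear_rate=gdot, viscosity=eta)
        fitted = fit_mobility(data, hbe_mucus_five_mode(ucm=True))
        assert max(m.mobility for m in fitted.modes) <= 0.5 + 1e-12
        # the strongly thinning part of the spectrum sits at the bound
        assert any(m.mobility > 0.49 for m in fitted.modes)

    def test_bounds_outside_range_rejected(self):
        data = generate_flowcurve_fixture(
            FixtureSpec(kind="flowcurve", seed=3, n_points=10)
        )
        with pytest.raises(ValueError):
            fit_mobility(data, hbe_mucus_five_mode(ucm=True), bounds=(0.0, 0.7))

    def test_fit_reproduces_own_prediction(self):
        """Evaluating saos_moduli of a fitted model at the fitting
        frequencies reproduces the fitted curves (self-consistency)."""
        spec = FixtureSpec(kind="saos", seed=5, n_points=24, noise_sigma=0.02)
        data = generate_saos_fixture(spec)
        fit = fit_maxwell_spectrum(data, 3, solvent_viscosity=1e-3)
        w = data.saos["omega_rad_s"].to_numpy()
        gp1, gpp1 = saos_moduli(fit, w)
        gp2, gpp2 = saos_moduli(fit, w.copy())
        assert np.array_equal(gp1, gp2) and np.array_equal(gpp1, gpp2)
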