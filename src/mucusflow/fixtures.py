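"""Synthetic-fixture generators.

The rheometric curves the constitutive fits consume (frequency sweep,
flow curve) are generated from a reference model plus multiplicative
log-normal noise, standing in for cone-and-plate measurements of culture
mucus; oscillatory shear signals are produced by integrating the
single-point (0-D) multi-mode Giesekus equations under an imposed
sinusoidal shear.  All generators are deterministic given the spec
(same seed -> bit-identical output).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from pydantic import BaseModel, ConfigDict, Field
from scipy.integrate import solve_ivp

from .constitutive import (
    FluidModel,
    RheoDataset,
    hbe_mucus_five_mode,
    saos_moduli,
    steady_shear_viscosity,
)
from .laos import OscillationRecord

__all__ = [
    "FixtureSpec",
    "generate_saos_fixture",
    "generate_flowcurve_fixture",
    "laos_signal",
    "shear_stress_ode",
]


class FixtureSpec(BaseModel):
    """Declarative description of a synthetic dataset."""

    model_config = ConfigDict(extra="forbid")

    kind: str = Field(pattern="^(saos|flowcurve|laos-signal)$")
    seed: int
    n_points: int = 30
    noise_sigma: float = 0.0  # sigma of multiplicative log-normal noise
    x_min: float = 1.0e-2  # rad/s or 1/s
    x_max: float = 1.0e2
    model: dict | None = None  # FluidModel.to_dict(); default: 5-mode HBE
    # laos-signal settings
    strain_amplitude: float = 0.05
    omega0: float = 10.0 * np.pi
    n_periods: int = 8
    samples_per_period: int = 256

    def fluid_model(self) -> FluidModel:
        if self.model is None:
            return hbe_mucus_five_mode()
        return FluidModel.from_dict(self.model)


def _noisy(values: np.ndarray, sigma: float, rng: np.random.Generator
           ) -> np.ndarray:
    if sigma == 0.0:
        return values
    return values * np.exp(rng.normal(0.0, sigma, size=values.shape))


def generate_saos_fixture(spec: FixtureSpec) -> RheoDataset:
    """Frequency sweep (omega, G', G'') from the spec's model plus noise."""
    if spec.kind != "saos":
        raise ValueError("spec.kind must be 'saos'")
    rng = np.random.default_rng(spec.seed)
    omega = np.geomspace(spec.x_min, spec.x_max, spec.n_points)
    gp, gpp = saos_moduli(spec.fluid_model(), omega)
    return RheoDataset.from_arrays(
        omega=omega,
        g_prime=_noisy(gp, spec.noise_sigma, rng),
        g_doubleprime=_noisy(gpp, spec.noise_sigma, rng),
    )


def generate_flowcurve_fixture(spec: FixtureSpec) -> RheoDataset:
    """Steady flow curve (shear rate, viscosity) from the spec's model."""
    if spec.kind != "flowcurve":
        raise ValueError("spec.kind must be 'flowcurve'")
    rng = np.random.default_rng(spec.seed)
    gdot = np.geomspace(spec.x_min, spec.x_max, spec.n_points)
    eta = steady_shear_viscosity(spec.fluid_model(), gdot)
    return RheoDataset.from_arrays(
        shear_rate=gdot, viscosity=_noisy(eta, spec.noise_sigma, rng)
    )


def shear_stress_ode(model: FluidModel, rate_fn, t_span, y0=None,
                     t_eval=None, rtol=1e-9, atol=1e-12):
    """Integrate the 0-D multi-mode Giesekus equations under imposed shear.

    State per mode: (tau_xx, tau_yy, tau_xy); ``rate_fn(t)`` is the imposed
    shear rate.  Returns the solve_ivp result; the total shear stress is
    ``eta_s * rate + sum tau_xy,i``.
    """
    modes = model.modes
    nm = len(modes)
    lam = np.array([m.relaxation_time for m in modes])
    eta_p = np.array([m.polymer_viscosity for m in modes])
    alpha = np.array([m.mobility for m in modes])

    def rhs(t, y):
        g = rate_fn(t)
        txx, tyy, txy = y[:nm], y[nm:2 * nm], y[2 * nm:]
        dxx = 2.0 * g * txy - txx / lam - (alpha / eta_p) * (txx**2 + txy**2)
        dyy = -tyy / lam - (alpha / eta_p) * (tyy**2 + txy**2)
        dxy = (
            g * tyy
            + (eta_p / lam) * g
            - txy / lam
            - (alpha / eta_p) * txy * (txx + tyy)
        )
        return np.concatenate([dxx, dyy, dxy])

    if y0 is None:
        y0 = np.zeros(3 * nm)
    return solve_ivp(rhs, t_span, y0, t_eval=t_eval, rtol=rtol, atol=atol,
                     method="LSODA")


def laos_signal(
    model: FluidModel,
    strain_amplitude: float,
    omega0: float,
    n_periods: int = 8,
    samples_per_period: int = 256,
    discard_periods: int = 4,
) -> OscillationRecord:
    """Synthetic single-point LAOS record for an imposed sinusoidal strain.

    gamma = gamma_0 sin(w0 t); the multi-mode stress response is integrated
    from rest and the first ``discard_periods`` periods are discarded.
    """
    period = 2.0 * np.pi / omega0
    t = np.arange(n_periods * samples_per_period) * (period / samples_per_period)

    def rate(tt):
        return strain_amplitude * omega0 * np.cos(omega0 * tt)

    sol = shear_stress_ode(model, rate, (0.0, t[-1]), t_eval=t)
    nm = len(model.modes)
    txy = sol.y[2 * nm:].sum(axis=0)
    stress = model.solvent_viscosity * rate(t) + txy
    keep = slice(discard_periods * samples_per_period, None)
    return OscillationRecord(
        time=t[keep],
        strain=strain_amplitude * np.sin(omega0 * t[keep]),
        rate=rate(t[keep]),
        stress=stress[keep],
        omega0=omega0,
    )


def generate_fixture(spec: FixtureSpec):
    """Dispatch on the spec kind."""
    if spec.kind == "saos":
        return generate_saos_fixture(spec)
    if spec.kind == "flowcurve":
        return generate_flowcurve_fixture(spec)
    if spec.kind == "laos-signal":
        return laos_signal(
            spec.fluid_model(),
            spec.strain_amplitude,
            spec.omega0,
            spec.n_periods,
            spec.samples_per_period,
        )
    raise ValueError(f"unknown fixture kind {spec.kind!r}")
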