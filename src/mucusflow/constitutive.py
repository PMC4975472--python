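"""Multi-mode Giesekus / upper-convected Maxwell constitutive laws for mucus.

The extra stress is a sum of modes, each obeying

    tau_i + lambda_i * tau_i(1) + (alpha_i lambda_i / eta_pi) tau_i . tau_i
        = eta_pi * gamma_dot,

where ``tau(1)`` is the upper-convected derivative and
``gamma_dot = grad_u + grad_u^T`` the rate-of-strain tensor.  ``alpha = 0``
recovers the UCM model; a model with no modes is Newtonian with viscosity
``eta_s``.  The mobility is restricted to ``0 <= alpha <= 0.5`` (larger values
produce non-monotonic flow curves).

This module provides the analytic SAOS moduli, the steady simple-shear
viscosity (per-mode damped Newton solve), the local stress-rate used by the
flow solver, and fitting of (lambda_i, G_i) to a frequency sweep and of
alpha_i to a flow curve.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import least_squares, nnls

__all__ = [
    "GiesekusMode",
    "FluidModel",
    "RheoDataset",
    "hbe_mucus_five_mode",
    "single_mode_reference",
    "saos_moduli",
    "steady_shear_viscosity",
    "stress_rate",
    "fit_maxwell_spectrum",
    "fit_mobility",
]

# Reference parameters for 2.5 wt% HBE culture mucus.
_HBE_MODES = (
    (0.0089, 3.3472, 0.2),
    (0.0821, 0.7551, 0.3),
    (0.4660, 0.5350, 0.5),
    (3.1290, 0.4543, 0.5),
    (49.733, 0.8486, 0.5),
)
SOLVENT_VISCOSITY = 1.0e-3  # Pa s
MUCUS_DENSITY = 1.0e3  # kg / m^3


@dataclass(frozen=True)
class GiesekusMode:
    """One relaxation mode: (relaxation time, modulus, mobility)."""

    relaxation_time: float  # lambda_i [s]
    modulus: float  # G_i [Pa]
    mobility: float = 0.0  # alpha_i, dimensionless

    def __post_init__(self) -> None:
        if not self.relaxation_time > 0:
            raise ValueError("relaxation_time must be > 0")
        if not self.modulus > 0:
            raise ValueError("modulus must be > 0")
        if not 0.0 <= self.mobility <= 0.5:
            raise ValueError("mobility must lie in [0, 0.5]")

    @property
    def polymer_viscosity(self) -> float:
        """eta_p,i = G_i * lambda_i [Pa s]."""
        return self.modulus * self.relaxation_time


@dataclass(frozen=True)
class FluidModel:
    """Solvent plus an ordered list of Giesekus modes.

    No modes -> Newtonian; all mobilities zero -> multi-mode UCM.
    """

    solvent_viscosity: float = SOLVENT_VISCOSITY  # eta_s [Pa s]
    density: float = MUCUS_DENSITY  # rho [kg/m^3]
    modes: tuple[GiesekusMode, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.solvent_viscosity < 0:
            raise ValueError("solvent_viscosity must be >= 0")
        if not self.density > 0:
            raise ValueError("density must be > 0")
        object.__setattr__(self, "modes", tuple(self.modes))

    @property
    def total_viscosity(self) -> float:
        """Zero-shear viscosity eta_0 = eta_s + sum(eta_p,i)."""
        return self.solvent_viscosity + sum(m.polymer_viscosity for m in self.modes)

    @property
    def is_newtonian(self) -> bool:
        return len(self.modes) == 0

    @property
    def is_ucm(self) -> bool:
        return len(self.modes) > 0 and all(m.mobility == 0.0 for m in self.modes)

    def with_mobilities(self, alphas) -> "FluidModel":
        alphas = np.asarray(alphas, dtype=float)
        if alphas.shape != (len(self.modes),):
            raise ValueError("one mobility per mode required")
        new = tuple(replace(m, mobility=float(a)) for m, a in zip(self.modes, alphas))
        return replace(self, modes=new)

    # -- serialization (field names mirror the reference parameter tables) --
    def to_dict(self) -> dict:
        return {
            "solvent_viscosity_Pa_s": self.solvent_viscosity,
            "density_kg_m3": self.density,
            "modes": [
                {
                    "relaxation_time_s": m.relaxation_time,
                    "modulus_Pa": m.modulus,
                    "mobility": m.mobility,
                }
                for m in self.modes
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FluidModel":
        modes = tuple(
            GiesekusMode(m["relaxation_time_s"], m["modulus_Pa"], m.get("mobility", 0.0))
            for m in d.get("modes", [])
        )
        return cls(d["solvent_viscosity_Pa_s"], d["density_kg_m3"], modes)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "FluidModel":
        try:
            with open(source) as fh:
                d = yaml.safe_load(fh)
        except (OSError, TypeError):
            d = yaml.safe_load(source)
        return cls.from_dict(d)


def hbe_mucus_five_mode(
    solvent_viscosity: float = SOLVENT_VISCOSITY,
    density: float = MUCUS_DENSITY,
    ucm: bool = False,
) -> FluidModel:
    """Five-mode model fitted to 2.5 wt% HBE culture mucus.

    ``ucm=True`` zeroes the mobilities (the linear-spectrum variant used to
    fit the SAOS data).
    """
    modes = tuple(
        GiesekusMode(lam, g, 0.0 if ucm else a) for lam, g, a in _HBE_MODES
    )
    return FluidModel(solvent_viscosity, density, modes)


def single_mode_reference(alpha: float = 0.0) -> FluidModel:
    """Single-mode reference model: eta_p = 10 Pa s, lambda = 10 s."""
    return FluidModel(
        SOLVENT_VISCOSITY, MUCUS_DENSITY, (GiesekusMode(10.0, 1.0, alpha),)
    )


# ---------------------------------------------------------------------------
# Rheometric dataset container
# ---------------------------------------------------------------------------

SAOS_COLUMNS = ("omega_rad_s", "G_prime_Pa", "G_doubleprime_Pa")
FLOWCURVE_COLUMNS = ("shear_rate_per_s", "viscosity_Pa_s")


def _validate_monotone_positive(x: np.ndarray, name: str) -> None:
    if np.any(x <= 0):
        raise ValueError(f"{name} must be strictly positive")
    if np.any(np.diff(x) <= 0):
        raise ValueError(f"{name} must be strictly increasing")


@dataclass
class RheoDataset:
    """SAOS frequency sweep and/or steady flow curve as tidy tables."""

    saos: pd.DataFrame | None = None
    flow_curve: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.saos is not None:
            missing = set(SAOS_COLUMNS) - set(self.saos.columns)
            if missing:
                raise ValueError(f"SAOS table missing columns {sorted(missing)}")
            _validate_monotone_positive(
                self.saos["omega_rad_s"].to_numpy(), "omega_rad_s"
            )
            for c in SAOS_COLUMNS[1:]:
                if np.any(self.saos[c].to_numpy() <= 0):
                    raise ValueError(f"{c} must be positive")
        if self.flow_curve is not None:
            missing = set(FLOWCURVE_COLUMNS) - set(self.flow_curve.columns)
            if missing:
                raise ValueError(f"flow-curve table missing columns {sorted(missing)}")
            _validate_monotone_positive(
                self.flow_curve["shear_rate_per_s"].to_numpy(), "shear_rate_per_s"
            )
            if np.any(self.flow_curve["viscosity_Pa_s"].to_numpy() <= 0):
                raise ValueError("viscosity_Pa_s must be positive")

    @classmethod
    def from_arrays(cls, omega=None, g_prime=None, g_doubleprime=None,
                    shear_rate=None, viscosity=None) -> "RheoDataset":
        saos = None
        if omega is not None:
            saos = pd.DataFrame(
                {"omega_rad_s": omega, "G_prime_Pa": g_prime,
                 "G_doubleprime_Pa": g_doubleprime}
            )
        fc = None
        if shear_rate is not None:
            fc = pd.DataFrame(
                {"shear_rate_per_s": shear_rate, "viscosity_Pa_s": viscosity}
            )
        return cls(saos=saos, flow_curve=fc)

    def write_saos(self, path) -> None:
        self.saos.to_csv(path, sep="\t", index=False)

    def write_flow_curve(self, path) -> None:
        self.flow_curve.to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, saos_path=None, flow_curve_path=None) -> "RheoDataset":
        saos = pd.read_csv(saos_path, sep="\t") if saos_path is not None else None
        fc = (
            pd.read_csv(flow_curve_path, sep="\t")
            if flow_curve_path is not None
            else None
        )
        return cls(saos=saos, flow_curve=fc)


# ---------------------------------------------------------------------------
# Analytic SAOS moduli
# ---------------------------------------------------------------------------

def saos_moduli(model: FluidModel, omega):
    """Storage and loss moduli of the multi-mode Maxwell spectrum.

    G'(w)  = sum_i G_i (lam_i w)^2 / (1 + (lam_i w)^2)
    G''(w) = eta_s w + sum_i G_i lam_i w / (1 + (lam_i w)^2)

    The linear moduli do not depend on the mobilities.
    """
    omega = np.asarray(omega, dtype=float)
    if np.any(omega <= 0):
        raise ValueError("angular frequency must be > 0")
    gp = np.zeros_like(omega)
    gpp = model.solvent_viscosity * omega
    for m in model.modes:
        lw = m.relaxation_time * omega
        gp = gp + m.modulus * lw**2 / (1.0 + lw**2)
        gpp = gpp + m.modulus * lw / (1.0 + lw**2)
    if gp.ndim == 0:
        return float(gp), float(gpp)
    return gp, gpp


# ---------------------------------------------------------------------------
# Steady simple shear
# ---------------------------------------------------------------------------

def _mode_steady_residual(tau, a, lam, eta_p, gdot):
    txx, tyy, tzz, txy = tau
    f = np.empty(4)
    f[0] = txx - 2.0 * lam * gdot * txy + a * (txx**2 + txy**2)
    f[1] = tyy + a * (tyy**2 + txy**2)
    f[2] = tzz + a * tzz**2
    f[3] = txy - lam * gdot * tyy + a * txy * (txx + tyy) - eta_p * gdot
    return f


def _mode_steady_jacobian(tau, a, lam, gdot):
    txx, tyy, tzz, txy = tau
    J = np.zeros((4, 4))
    J[0, 0] = 1.0 + 2.0 * a * txx
    J[0, 3] = -2.0 * lam * gdot + 2.0 * a * txy
    J[1, 1] = 1.0 + 2.0 * a * tyy
    J[1, 3] = 2.0 * a * txy
    J[2, 2] = 1.0 + 2.0 * a * tzz
    J[3, 0] = a * txy
    J[3, 1] = -lam * gdot + a * txy
    J[3, 3] = 1.0 + a * (txx + tyy)
    return J


def _mode_steady_stress(mode: GiesekusMode, gdot: float, tau0=None,
                        tol: float = 1e-12, max_iter: int = 100) -> np.ndarray:
    """Steady (tau_xx, tau_yy, tau_zz, tau_xy) of one mode under shear rate gdot.

    Damped Newton on the four coupled steady components; the UCM solution
    seeds the iteration unless a warm start is supplied.
    """
    lam, eta_p, alpha = mode.relaxation_time, mode.polymer_viscosity, mode.mobility
    a = alpha * lam / eta_p
    if alpha == 0.0:
        return np.array(
            [2.0 * eta_p * lam * gdot**2, 0.0, 0.0, eta_p * gdot]
        )
    if tau0 is None:
        # linearized (small Wi) seed
        wi = lam * gdot
        scale = 1.0 / (1.0 + alpha * wi**2)
        tau0 = np.array(
            [2.0 * eta_p * lam * gdot**2 * scale, 0.0, 0.0, eta_p * gdot * scale]
        )
    tau = np.asarray(tau0, dtype=float).copy()
    fscale = max(eta_p * abs(gdot), mode.modulus, 1e-300)
    for _ in range(max_iter):
        f = _mode_steady_residual(tau, a, lam, eta_p, gdot)
        if np.max(np.abs(f)) < tol * fscale:
            return tau
        J = _mode_steady_jacobian(tau, a, lam, gdot)
        try:
            step = np.linalg.solve(J, -f)
        except np.linalg.LinAlgError as exc:  # pragma: no cover
            raise FloatingPointError(
                f"singular Jacobian in steady-shear solve at gdot={gdot}"
            ) from exc
        # damped line search on the residual norm
        norm0 = np.linalg.norm(f)
        t = 1.0
        for _ in range(40):
            trial = tau + t * step
            if np.linalg.norm(
                _mode_steady_residual(trial, a, lam, eta_p, gdot)
            ) < norm0:
                tau = trial
                break
            t *= 0.5
        else:
            raise FloatingPointError(
                f"steady-shear Newton stalled at gdot={gdot} "
                f"(lambda={lam}, alpha={alpha}, residual={norm0:.3e})"
            )
    raise FloatingPointError(
        f"steady-shear Newton did not converge at gdot={gdot} "
        f"(lambda={lam}, alpha={alpha})"
    )


def steady_shear_viscosity(model: FluidModel, gammadot):
    """Steady simple-shear viscosity eta(gdot) = eta_s + sum_i tau_xy,i / gdot.

    Solves the steady algebraic Giesekus system per mode with continuation in
    shear rate (ascending warm starts) for robustness at high Wi.
    """
    g = np.atleast_1d(np.asarray(gammadot, dtype=float))
    if np.any(g <= 0):
        raise ValueError("shear rate must be > 0")
    order = np.argsort(g)
    eta = np.full(g.shape, model.solvent_viscosity)
    for mode in model.modes:
        tau_prev = None
        txy_sorted = np.empty(g.size)
        for j, idx in enumerate(order):
            tau_prev = _mode_steady_stress(mode, g[idx], tau0=tau_prev)
            txy_sorted[j] = tau_prev[3]
        eta[order] += txy_sorted / g[order]
    if np.isscalar(gammadot) or np.ndim(gammadot) == 0:
        return float(eta[0])
    return eta


# ---------------------------------------------------------------------------
# Local stress rate (used by the flow solver and by ODE oracles)
# ---------------------------------------------------------------------------

def stress_rate(mode: GiesekusMode, tau: np.ndarray, grad_u: np.ndarray) -> np.ndarray:
    """Local time derivative of one mode's extra stress.

    ``grad_u`` uses the gradient convention ``grad_u[i, j] = d u_j / d x_i``
    (so the upper-convected terms read ``tau . grad_u + grad_u^T . tau``).
    The advective term ``u . grad tau`` is the caller's responsibility.
    Input and output are symmetric 3x3 arrays (trailing 3x3 axes broadcast).
    """
    tau = np.asarray(tau, dtype=float)
    grad_u = np.asarray(grad_u, dtype=float)
    if tau.shape[-2:] != (3, 3) or grad_u.shape[-2:] != (3, 3):
        raise ValueError("tau and grad_u must be (..., 3, 3)")
    lam, eta_p, alpha = mode.relaxation_time, mode.polymer_viscosity, mode.mobility
    gdot = grad_u + np.swapaxes(grad_u, -1, -2)
    uc = tau @ grad_u + np.swapaxes(grad_u, -1, -2) @ tau
    rate = uc + (eta_p / lam) * gdot - tau / lam
    if alpha != 0.0:
        rate = rate - (alpha / eta_p) * (tau @ tau)
    return rate


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _maxwell_design(omega: np.ndarray, lams: np.ndarray):
    lw = np.outer(omega, lams)
    num = lw**2 / (1.0 + lw**2)  # G' basis
    den = lw / (1.0 + lw**2)  # G'' basis
    return num, den


def fit_maxwell_spectrum(
    data: RheoDataset,
    n_modes: int = 5,
    solvent_viscosity: float = 0.0,
    density: float = MUCUS_DENSITY,
    refine: bool = True,
) -> FluidModel:
    """Fit an ``n_modes`` discrete Maxwell spectrum (alpha = 0) to SAOS data.

    Relaxation times are seeded log-spaced across the inverse-frequency window
    of the sweep, moduli by non-negative linear least squares at fixed times,
    followed by a joint bounded refinement minimizing the summed squared
    log-ratios of G' and G'' (equal weight).
    """
    if data.saos is None:
        raise ValueError("dataset has no SAOS table")
    omega = data.saos["omega_rad_s"].to_numpy(dtype=float)
    gp = data.saos["G_prime_Pa"].to_numpy(dtype=float)
    gpp = data.saos["G_doubleprime_Pa"].to_numpy(dtype=float)
    if n_modes < 1:
        raise ValueError("n_modes must be >= 1")
    if omega.size < 2 * n_modes:
        raise ValueError(
            f"need at least {2 * n_modes} SAOS points for {n_modes} modes, "
            f"got {omega.size}"
        )
    gpp_fit = gpp - solvent_viscosity * omega
    if np.any(gpp_fit <= 0):
        raise ValueError("solvent viscosity exceeds measured loss modulus")

    if n_modes == 1:
        lams = np.array([np.sqrt(1.0 / (omega.min() * omega.max()))])
    else:
        lams = np.geomspace(1.0 / omega.max(), 1.0 / omega.min(), n_modes)
    num, den = _maxwell_design(omega, lams)
    A = np.vstack([num, den])
    b = np.concatenate([gp, gpp_fit])
    g0, _ = nnls(A, b)
    g0 = np.clip(g0, 1e-8 * max(gp.max(), 1.0), None)

    if refine:
        def resid(theta):
            lam = np.exp(theta[:n_modes])
            g = np.exp(theta[n_modes:])
            n, d = _maxwell_design(omega, lam)
            mp = n @ g
            mpp = d @ g + solvent_viscosity * omega
            return np.concatenate([np.log(mp / gp), np.log(mpp / gpp)])

        theta0 = np.concatenate([np.log(lams), np.log(g0)])
        sol = least_squares(resid, theta0, method="lm", xtol=1e-14, ftol=1e-14)
        lams = np.exp(sol.x[:n_modes])
        g0 = np.exp(sol.x[n_modes:])

    order = np.argsort(lams)
    modes = tuple(GiesekusMode(float(lams[i]), float(g0[i])) for i in order)
    return FluidModel(solvent_viscosity, density, modes)


def fit_mobility(
    data: RheoDataset,
    maxwell_model: FluidModel,
    bounds: tuple[float, float] = (0.0, 0.5),
) -> FluidModel:
    """Fit the per-mode mobilities to a steady flow curve.

    The relaxation times and moduli of ``maxwell_model`` are held fixed; only
    alpha_i in ``bounds`` (within [0, 0.5]) are adjusted to minimize the
    squared log-ratio misfit of the steady shear viscosity.
    """
    if data.flow_curve is None:
        raise ValueError("dataset has no flow-curve table")
    lo, hi = bounds
    if lo < 0.0 or hi > 0.5 or lo > hi:
        raise ValueError("mobility bounds must lie within [0, 0.5]")
    gdot = data.flow_curve["shear_rate_per_s"].to_numpy(dtype=float)
    eta_data = data.flow_curve["viscosity_Pa_s"].to_numpy(dtype=float)
    n = len(maxwell_model.modes)
    if n == 0:
        raise ValueError("maxwell_model has no modes")

    def resid(alphas):
        model = maxwell_model.with_mobilities(np.clip(alphas, lo, hi))
        eta = steady_shear_viscosity(model, gdot)
        return np.log(eta / eta_data)

    x0 = np.full(n, np.clip(0.25, lo, hi))
    sol = least_squares(resid, x0, bounds=(lo, hi), xtol=1e-12, ftol=1e-12)
    return maxwell_model.with_mobilities(sol.x)
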