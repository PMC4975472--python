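"""Idealized cilia driving conditions for the culture bottom plate.

Three drives are supported: constant-rate swirl, a piecewise-sinusoidal
power/return stroke mimicking the coordinated cilia beat, and the
strain-controlled oscillation used for LAOS analysis.  All return the
azimuthal velocity imposed at z = 0; the solver blends the imposed profile to
zero at the side wall with ``boundary_layer_blend``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SwirlDrive",
    "CiliaDrive",
    "StrainDrive",
    "cilia_velocity",
    "amplitudes_from_displacement",
    "strain_controlled_velocity",
    "boundary_layer_blend",
    "observed_cilia_drive",
]

BLEND_EPSILON = 0.05  # wall boundary-layer parameter used in the simulations


@dataclass(frozen=True)
class SwirlDrive:
    """Constant angular velocity omega_0 [rad/s]; sign sets the direction."""

    omega0: float

    def angular_velocity(self, t: float) -> float:
        return self.omega0

    @property
    def period(self) -> float | None:
        return None


@dataclass(frozen=True)
class CiliaDrive:
    """Piecewise-sinusoidal power/return stroke.

    One cycle lasts pi/omega_p + pi/omega_r: a positive half-sine of amplitude
    P0 (power stroke) followed by a negative half-sine of amplitude R0
    (return stroke, the printed branch R0*sin(omega_r t) evaluated at absolute
    time, which is negative on the return window).
    """

    power_amplitude: float  # P0 [rad/s]
    return_amplitude: float  # R0 [rad/s]
    power_frequency: float  # omega_p [rad/s]
    return_frequency: float  # omega_r [rad/s]

    def __post_init__(self) -> None:
        if self.power_amplitude <= 0:
            raise ValueError("P0 must be > 0")
        if self.return_amplitude < 0:
            raise ValueError("R0 must be >= 0")
        if self.power_frequency <= 0 or self.return_frequency <= 0:
            raise ValueError("stroke frequencies must be > 0")

    @property
    def period(self) -> float:
        return math.pi / self.power_frequency + math.pi / self.return_frequency

    def angular_velocity(self, t):
        return cilia_velocity(self, t)

    def net_angular_displacement(self) -> float:
        """Net angle advanced per cycle (rad): 2 P0/omega_p - 2 R0/omega_r."""
        return (
            2.0 * self.power_amplitude / self.power_frequency
            - 2.0 * self.return_amplitude / self.return_frequency
        )


@dataclass(frozen=True)
class StrainDrive:
    """Strain-controlled oscillation: u_theta = g0 w0 r cos(w0 t) ln(r/R)."""

    strain_amplitude: float  # gamma_0
    omega0: float  # rad/s
    radius: float  # culture (or hurricane) radius R [m]

    def __post_init__(self) -> None:
        if self.strain_amplitude <= 0:
            raise ValueError("strain amplitude must be > 0")
        if self.omega0 <= 0 or self.radius <= 0:
            raise ValueError("omega0 and radius must be > 0")

    @property
    def period(self) -> float:
        return 2.0 * math.pi / self.omega0


def cilia_velocity(drive: CiliaDrive, t):
    """Angular velocity f(t) of the piecewise-sinusoidal cilia drive.

    f(t) = P0 sin(w_p t) on the power half-cycle, R0 sin(w_r t) continued at
    absolute time on the return half-cycle (a negative half-sine), extended
    periodically; continuous and zero at the phase boundaries.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be >= 0")
    t_pow = math.pi / drive.power_frequency
    phase = np.mod(t, drive.period)
    power = drive.power_amplitude * np.sin(drive.power_frequency * phase)
    ret = drive.return_amplitude * np.sin(drive.return_frequency * phase)
    out = np.where(phase < t_pow, power, ret)
    return float(out) if out.ndim == 0 else out


def amplitudes_from_displacement(
    delta_forward: float,
    delta_back: float,
    t_forward: float,
    t_back: float,
    r: float,
) -> CiliaDrive:
    """Construct a CiliaDrive from observed stroke arc displacements.

    Half-cycle durations set the stroke frequencies (w = pi/T); amplitudes
    solve the half-sine displacement integrals exactly:
    integral P0 r sin(w_p t) dt over a half cycle = 2 P0 r / w_p = delta.
    """
    if r <= 0:
        raise ValueError("observation radius must be > 0")
    if delta_forward <= 0 or t_forward <= 0 or t_back <= 0:
        raise ValueError("forward displacement and durations must be > 0")
    if delta_back < 0:
        raise ValueError("backward displacement must be >= 0")
    omega_p = math.pi / t_forward
    omega_r = math.pi / t_back
    p0 = delta_forward * omega_p / (2.0 * r)
    r0 = delta_back * omega_r / (2.0 * r)
    return CiliaDrive(p0, r0, omega_p, omega_r)


def observed_cilia_drive(radius: float = 1.0e-2) -> CiliaDrive:
    """The observed stroke displacements (10 um forward / 5 um back in 0.1 s
    half-cycles) converted to a drive at the given culture-edge radius."""
    return amplitudes_from_displacement(1.0e-5, 5.0e-6, 0.1, 0.1, radius)


def strain_controlled_velocity(drive: StrainDrive, r, t):
    """u_theta(r, t) = gamma_0 omega_0 r cos(omega_0 t) ln(r / R).

    Yields a spatially uniform shear rate
    gdot_rtheta = r d/dr(u_theta/r) = gamma_0 omega_0 cos(omega_0 t)
    and pins u_theta to zero at r = R.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("radius must be > 0")
    out = (
        drive.strain_amplitude
        * drive.omega0
        * r
        * np.cos(drive.omega0 * np.asarray(t, dtype=float))
        * np.log(r / drive.radius)
    )
    return float(out) if np.ndim(out) == 0 else out


def strain_amplitude_matching(
    p0: float, omega0: float, r_match_fraction: float = 0.99
) -> float:
    """Strain amplitude gamma_0 of the logarithmic strain-controlled drive whose |u_theta|/r equals
    the power-stroke amplitude P0 at r = r_match_fraction * R."""
    if not 0 < r_match_fraction < 1:
        raise ValueError("matching radius must lie strictly inside the culture")
    return p0 / (omega0 * abs(math.log(r_match_fraction)))


def boundary_layer_blend(u_imposed, r, radius: float, epsilon: float = BLEND_EPSILON):
    """Wall boundary layer u(r) * (1 - exp[-(R^2 - r^2)/(eps R^2)]).

    Reconciles a non-zero imposed plate velocity with the no-slip side wall:
    exactly zero at r = R, within e^(-1/eps) of the imposed value at the axis.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    r = np.asarray(r, dtype=float)
    if np.any(r < 0) or np.any(r > radius * (1 + 1e-12)):
        raise ValueError("radius must lie in [0, R]")
    factor = 1.0 - np.exp(-(radius**2 - r**2) / (epsilon * radius**2))
    out = np.asarray(u_imposed) * factor
    return float(out) if np.ndim(out) == 0 else out
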