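"""Axisymmetric incompressible flow solver for the culture geometry.

Solves conservation of mass and momentum,

    div u = 0,
    rho (du/dt + u . grad u) = -grad p + eta_s Lap u + div tau + rho g,

in (r, z) with swirl (u_theta) on a staggered (MAC) grid, with the
multi-mode Giesekus extra stress of :mod:`mucusflow.constitutive`, the
bottom-plate driving conditions of :mod:`mucusflow.forcing`, no-slip solid
walls, axis regularity, and a free air-mucus interface carried by marker
particles whose spline curvature sets the capillary pressure sigma*kappa in
the normal-stress balance.

Numerical scheme
----------------
* Staggered grid: p, u_theta, stress and concentration at cell centers,
  u_r / u_z on faces.
* Semi-implicit time stepping: advection and stress divergence explicit,
  solvent diffusion implicit, plus an implicit/explicit stabilization
  viscosity eta_add = sum_i G_i lambda_i dt/(lambda_i+dt) added to the
  implicit operator and subtracted explicitly (cancels identically at
  stationarity) so the explicit polymer-stress coupling is stable at time
  steps far beyond the elastic CFL limit.
* Per-mode stress update with the relaxation term implicit (integrating
  factor), upper-convected and quadratic mobility terms explicit, and
  first-order upwind advection.
* Incremental pressure projection; direct sparse factorizations are built
  once and reused (the grid and dt are fixed for a run).
* The free surface is handled in small-deformation form on a fixed domain of
  depth H: markers are advected with the bilinearly interpolated velocity
  and periodically reseeded, the fitted height h(r) feeds the surface
  pressure p_s = sigma*kappa + rho g (h - H) + tau_zz and the wetted-volume
  diagnostics.  Gravity is absorbed hydrostatically (well-balanced), so a
  resting fluid is an exact discrete equilibrium.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline, PchipInterpolator
from scipy.sparse import csc_matrix
from scipy.sparse.linalg import splu

from .constitutive import FluidModel
from .forcing import (
    BLEND_EPSILON,
    CiliaDrive,
    StrainDrive,
    SwirlDrive,
    boundary_layer_blend,
    strain_controlled_velocity,
)

__all__ = [
    "Geometry",
    "Grid",
    "SurfaceMarkers",
    "FlowState",
    "AxisymmetricFlowSolver",
    "SolverError",
    "curvature_from_markers",
    "capillary_pressure",
    "mass_flux_theta0",
    "surface_profile",
    "fluid_volume",
    "run_to_quasi_steady",
]

GRAVITY = 9.81  # m/s^2
SURFACE_TENSION = 0.03  # N/m, air-mucus


class SolverError(RuntimeError):
    """Raised when the solver loses validity (NaN, divergence, positivity)."""


@dataclass(frozen=True)
class Geometry:
    """Culture geometry: radius R, domain height Z, initial mucus depth H."""

    radius: float = 1.0e-2
    height: float = 1.0e-4
    depth: float = 5.0e-5

    def __post_init__(self) -> None:
        if not 0 < self.depth <= self.height:
            raise ValueError("require 0 < H <= Z")
        if self.radius <= 0:
            raise ValueError("radius must be > 0")

    @property
    def aspect_ratio(self) -> float:
        return self.radius / self.depth


@dataclass(frozen=True)
class Grid:
    """Uniform staggered grid over [0, R] x [0, H] (the mucus layer)."""

    nr: int
    nz: int
    radius: float
    depth: float

    def __post_init__(self) -> None:
        if self.nr < 4 or self.nz < 4:
            raise ValueError("need at least 4 cells in each direction")

    @property
    def dr(self) -> float:
        return self.radius / self.nr

    @property
    def dz(self) -> float:
        return self.depth / self.nz

    @property
    def r_centers(self) -> np.ndarray:
        return (np.arange(self.nr) + 0.5) * self.dr

    @property
    def r_faces(self) -> np.ndarray:
        return np.arange(self.nr + 1) * self.dr

    @property
    def z_centers(self) -> np.ndarray:
        return (np.arange(self.nz) + 0.5) * self.dz

    @property
    def z_faces(self) -> np.ndarray:
        return np.arange(self.nz + 1) * self.dz

    def center_index(self, r: float, z: float) -> tuple[int, int]:
        i = int(np.clip(r / self.dr - 0.5 + 0.5, 0, self.nr - 1))
        k = int(np.clip(z / self.dz - 0.5 + 0.5, 0, self.nz - 1))
        return i, k


# ---------------------------------------------------------------------------
# Free surface markers
# ---------------------------------------------------------------------------

@dataclass
class SurfaceMarkers:
    """Ordered marker particles (r, z) spanning the interface r in [0, R]."""

    r: np.ndarray
    z: np.ndarray

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        if self.r.size != self.z.size or self.r.size < 4:
            raise ValueError("need at least 4 markers")
        if np.any(np.diff(self.r) <= 0):
            raise SolverError(
                "overturned surface: marker radii are not strictly increasing"
            )

    @classmethod
    def flat(cls, radius: float, depth: float, n: int = 129) -> "SurfaceMarkers":
        r = np.linspace(0.0, radius, n)
        return cls(r, np.full(n, depth))

    def height_spline(self) -> CubicSpline:
        # axis symmetry pins dh/dr = 0 at r = 0; natural end at the wall
        return CubicSpline(self.r, self.z, bc_type=((1, 0.0), (2, 0.0)))

    def height(self, r) -> np.ndarray:
        return self.height_spline()(np.asarray(r, dtype=float))

    def reseed(self, radius: float, n: int | None = None) -> "SurfaceMarkers":
        """Resample to uniform radial spacing (monotone interpolant)."""
        n = n or self.r.size
        rs = np.linspace(0.0, radius, n)
        interp = PchipInterpolator(self.r, self.z)
        return SurfaceMarkers(rs, interp(np.clip(rs, self.r[0], self.r[-1])))


def curvature_from_markers(
    markers: SurfaceMarkers, r=None, convention: str = "full"
):
    """Interface curvature kappa(r) from the cubic-spline height fit.

    Sign convention: kappa > 0 where the interface bulges toward the air
    (a dome), so a spherical cap of radius a gives kappa = 2/a under the
    default ``full`` (sum of both principal curvatures) convention and a
    near-axis dome h = H - c r^2 gives kappa(0) = +4c.  ``convention``
    may be "full" or "inplane" (spline curvature of the generating curve
    only).
    """
    spline = markers.height_spline()
    if r is None:
        r = markers.r
    r = np.asarray(r, dtype=float)
    hp = spline(r, 1)
    hpp = spline(r, 2)
    k_plane = -hpp / (1.0 + hp**2) ** 1.5
    if convention == "inplane":
        return k_plane
    if convention != "full":
        raise ValueError("convention must be 'full' or 'inplane'")
    with np.errstate(divide="ignore", invalid="ignore"):
        k_azim = np.where(
            r > 0, -hp / (r * np.sqrt(1.0 + hp**2)), k_plane
        )  # L'Hopital: h'/r -> h'' at the axis
    return k_plane + k_azim


def capillary_pressure(kappa, surface_tension: float = SURFACE_TENSION):
    """Capillary pressure P_cap = sigma * kappa (normal-stress boundary value).

    Positive kappa (dome toward the air) raises the interior pressure; the
    tangential traction at the interface is zero.
    """
    return surface_tension * np.asarray(kappa, dtype=float)


# ---------------------------------------------------------------------------
# Flow state
# ---------------------------------------------------------------------------

STRESS_COMPONENTS = ("rr", "rt", "rz", "tt", "tz", "zz")
_RR, _RT, _RZ, _TT, _TZ, _ZZ = range(6)


@dataclass
class FlowState:
    """Staggered axisymmetric fields plus per-mode stresses and markers."""

    grid: Grid
    u_r: np.ndarray  # (nr+1, nz) radial faces
    u_theta: np.ndarray  # (nr, nz) centers
    u_z: np.ndarray  # (nr, nz+1) vertical faces
    p: np.ndarray  # (nr, nz) centers
    tau: np.ndarray  # (n_modes, 6, nr, nz) centers
    markers: SurfaceMarkers
    t: float = 0.0

    @classmethod
    def rest(cls, grid: Grid, n_modes: int, n_markers: int | None = None
             ) -> "FlowState":
        nr, nz = grid.nr, grid.nz
        n_markers = n_markers or 2 * nr + 1
        return cls(
            grid=grid,
            u_r=np.zeros((nr + 1, nz)),
            u_theta=np.zeros((nr, nz)),
            u_z=np.zeros((nr, nz + 1)),
            p=np.zeros((nr, nz)),
            tau=np.zeros((max(n_modes, 0), 6, nr, nz)),
            markers=SurfaceMarkers.flat(grid.radius, grid.depth, n_markers),
        )

    @property
    def total_stress(self) -> np.ndarray:
        """Sum of the mode stresses, shape (6, nr, nz)."""
        if self.tau.shape[0] == 0:
            return np.zeros((6, self.grid.nr, self.grid.nz))
        return self.tau.sum(axis=0)

    def divergence(self) -> np.ndarray:
        g = self.grid
        rf = g.r_faces[:, None]
        rc = g.r_centers[:, None]
        dradial = (rf[1:] * self.u_r[1:] - rf[:-1] * self.u_r[:-1]) / (rc * g.dr)
        dvert = (self.u_z[:, 1:] - self.u_z[:, :-1]) / g.dz
        return dradial + dvert

    def check_finite(self) -> None:
        for name in ("u_r", "u_theta", "u_z", "p", "tau"):
            arr = getattr(self, name)
            if not np.all(np.isfinite(arr)):
                raise SolverError(f"non-finite values detected in field '{name}'")


def surface_profile(state: FlowState, r=None) -> pd.DataFrame:
    """Sampled interface height h(r) (cell centers by default)."""
    r = state.grid.r_centers if r is None else np.asarray(r, dtype=float)
    return pd.DataFrame({"r_m": r, "h_m": state.markers.height(r)})


def mass_flux_theta0(state: FlowState, density: float) -> float:
    """Mass transport rate across the theta = 0 half-plane [kg/s]:
    integral of rho * u_theta over the wetted (r, z) region below h(r)."""
    g = state.grid
    h = state.markers.height(g.r_centers)
    zf = g.z_faces
    wet = np.clip((h[:, None] - zf[None, :-1]) / g.dz, 0.0, 1.0)
    return float(density * np.sum(state.u_theta * wet) * g.dr * g.dz)


def fluid_volume(state: FlowState) -> float:
    """Axisymmetric volume under the marker surface, 2 pi int h r dr."""
    g = state.grid
    h = state.markers.height(g.r_centers)
    return float(2.0 * math.pi * np.sum(h * g.r_centers) * g.dr)


# ---------------------------------------------------------------------------
# Drive dispatch
# ---------------------------------------------------------------------------

def drive_bottom_velocity(drive, r, t: float, radius: float,
                          epsilon: float = BLEND_EPSILON) -> np.ndarray:
    """Blended azimuthal velocity imposed at the bottom plate.

    Swirl and cilia drives impose u_theta = omega(t) r; the strain drive the
    logarithmic profile of the equivalent imposed sinusoidal strain.  The
    profile is multiplied by the wall boundary-layer blend; a drive with an
    effective radius smaller than the culture radius is blended to zero at
    its own radius and vanishes outside it.
    """
    r = np.asarray(r, dtype=float)
    r_eff = radius
    if isinstance(drive, StrainDrive):
        r_eff = min(drive.radius, radius)
        u = np.where(
            (r > 0) & (r < r_eff),
            strain_controlled_velocity(
                StrainDrive(drive.strain_amplitude, drive.omega0, r_eff),
                np.clip(r, 1e-30, r_eff * (1 - 1e-12)),
                t,
            ),
            0.0,
        )
    elif isinstance(drive, (SwirlDrive, CiliaDrive)):
        u = drive.angular_velocity(t) * r
    else:
        raise TypeError(f"unsupported drive {type(drive).__name__}")
    inside = r < r_eff
    blend = np.where(
        inside,
        1.0 - np.exp(-(r_eff**2 - np.minimum(r, r_eff) ** 2) / (epsilon * r_eff**2)),
        0.0,
    )
    return u * blend


def apply_boundary_conditions(state: FlowState, drive, geometry: Geometry,
                              t: float | None = None,
                              epsilon: float = BLEND_EPSILON) -> np.ndarray:
    """Enforce the wall/axis conditions on the state and return the blended
    bottom-plate u_theta profile at cell centers.

    No-slip: u_r = u_z = 0 on the plate and side wall, u_theta = 0 at r = R
    (via the blend and the wall ghost), axis regularity at r = 0; tau = 0 on
    solid walls is applied inside the stress-divergence stencils.
    """
    state.u_r[0, :] = 0.0
    state.u_r[-1, :] = 0.0
    state.u_z[:, 0] = 0.0
    tt = state.t if t is None else t
    return drive_bottom_velocity(drive, state.grid.r_centers, tt,
                                 geometry.radius, epsilon)


# ---------------------------------------------------------------------------
# Sparse operator assembly
# ---------------------------------------------------------------------------

def _assemble(n: int, entries) -> csc_matrix:
    rows, cols, vals = zip(*entries)
    return csc_matrix((vals, (rows, cols)), shape=(n, n))


def _build_utheta_operator(grid: Grid):
    """Matrix of L_theta = (1/r) d_r(r d_r .) - ./r^2 + d_zz with
    axis antisymmetric ghost, wall Dirichlet-0 ghost, bottom Dirichlet
    (inhomogeneous part returned as a mask), top Neumann."""
    nr, nz, dr, dz = grid.nr, grid.nz, grid.dr, grid.dz
    rc, rf = grid.r_centers, grid.r_faces
    idx = lambda i, k: i * nz + k
    entries = []
    for i in range(nr):
        for k in range(nz):
            m = idx(i, k)
            diag = -1.0 / rc[i] ** 2
            # radial fluxes
            if i + 1 < nr:
                c = rf[i + 1] / (rc[i] * dr * dr)
                entries += [(m, idx(i + 1, k), c)]
                diag -= c
            else:  # wall ghost u = -u_last
                c = rf[i + 1] / (rc[i] * dr * dr)
                diag -= 2.0 * c
            if i > 0:
                c = rf[i] / (rc[i] * dr * dr)
                entries += [(m, idx(i - 1, k), c)]
                diag -= c
            # (axis: rf[0] = 0, no inner flux)
            # vertical
            if k + 1 < nz:
                entries += [(m, idx(i, k + 1), 1.0 / dz**2)]
                diag -= 1.0 / dz**2
            # top: Neumann ghost = u -> no contribution
            if k > 0:
                entries += [(m, idx(i, k - 1), 1.0 / dz**2)]
                diag -= 1.0 / dz**2
            else:  # bottom Dirichlet ghost = 2 u_b - u
                diag -= 2.0 / dz**2
            entries.append((m, m, diag))
    return _assemble(nr * nz, entries)


def _apply_utheta_operator(grid: Grid, u: np.ndarray, u_b: np.ndarray
                           ) -> np.ndarray:
    """Explicit application of L_theta including the inhomogeneous bottom
    Dirichlet value (used for the subtracted stabilization term)."""
    nr, nz, dr, dz = grid.nr, grid.nz, grid.dr, grid.dz
    rc, rf = grid.r_centers[:, None], grid.r_faces[:, None]
    ur = np.vstack([u[1:], -u[-1:]])  # i+1 with wall ghost
    ul = np.vstack([-u[:1], u[:-1]])  # i-1 with antisymmetric axis ghost
    radial = (rf[1:] * (ur - u) - rf[:-1] * (u - ul)) / (rc * dr * dr)
    radial[0] = (rf[1, 0] * (u[1] - u[0])) / (rc[0] * dr * dr)  # no inner flux
    up = np.hstack([u[:, 1:], u[:, -1:]])  # top Neumann ghost
    dn = np.hstack([2.0 * u_b[:, None] - u[:, :1], u[:, :-1]])
    vert = (up - 2.0 * u + dn) / dz**2
    return radial + vert - u / rc**2


def _build_ur_operator(grid: Grid):
    """L_r on interior radial faces i = 1..nr-1: (1/r) d_r(r d_r .) - ./r^2
    + d_zz; bottom ghost -u (no-slip), top ghost +u (free tangential)."""
    nr, nz, dr, dz = grid.nr, grid.nz, grid.dr, grid.dz
    rc, rf = grid.r_centers, grid.r_faces
    ni = nr - 1
    idx = lambda i, k: (i - 1) * nz + k
    entries = []
    for i in range(1, nr):
        for k in range(nz):
            m = idx(i, k)
            diag = -1.0 / rf[i] ** 2
            cp = rc[i] / (rf[i] * dr * dr)
            cm = rc[i - 1] / (rf[i] * dr * dr)
            if i + 1 < nr:
                entries += [(m, idx(i + 1, k), cp)]
            diag -= cp  # u[nr] = 0 Dirichlet contributes nothing
            if i - 1 >= 1:
                entries += [(m, idx(i - 1, k), cm)]
            diag -= cm  # u[0] = 0
            if k + 1 < nz:
                entries += [(m, idx(i, k + 1), 1.0 / dz**2)]
                diag -= 1.0 / dz**2
            # top ghost = +u -> cancels
            if k > 0:
                entries += [(m, idx(i, k - 1), 1.0 / dz**2)]
                diag -= 1.0 / dz**2
            else:  # bottom ghost = -u
                diag -= 2.0 / dz**2
            entries.append((m, m, diag))
    return _assemble(ni * nz, entries)


def _apply_ur_operator(grid: Grid, u_r: np.ndarray) -> np.ndarray:
    """Explicit L_r on the full (nr+1, nz) face array (ends are zero)."""
    nr, nz, dr, dz = grid.nr, grid.nz, grid.dr, grid.dz
    rc, rf = grid.r_centers[:, None], grid.r_faces[:, None]
    u = u_r
    dcent = (u[1:] - u[:-1]) / dr  # at centers
    radial = np.zeros_like(u)
    radial[1:-1] = (rc[1:] * dcent[1:] - rc[:-1] * dcent[:-1]) / (rf[1:-1] * dr)
    up = np.hstack([u[:, 1:], u[:, -1:]])
    dn = np.hstack([-u[:, :1], u[:, :-1]])
    vert = (up - 2.0 * u + dn) / dz**2
    out = radial + vert
    out[1:-1] -= u[1:-1] / rf[1:-1] ** 2
    out[0] = 0.0
    out[-1] = 0.0
    return out


def _build_uz_operator(grid: Grid):
    """L_z on interior vertical faces k = 1..nz-1: (1/r) d_r(r d_r .) + d_zz;
    wall Dirichlet-0 ghost, axis mirror, bottom u_z(0)=0, top Neumann ghost."""
    nr, nz, dr, dz = grid.nr, grid.nz, grid.dr, grid.dz
    rc, rf = grid.r_centers, grid.r_faces
    nk = nz - 1
    idx = lambda i, k: i * nk + (k - 1)
    entries = []
    for i in range(nr):
        for k in range(1, nz):
            m = idx(i, k)
            diag = 0.0
            if i + 1 < nr:
                c = rf[i + 1] / (rc[i] * dr * dr)
                entries += [(m, idx(i + 1, k), c)]
                diag -= c
            else:  # wall ghost = -u
                c = rf[i + 1] / (rc[i] * dr * dr)
                diag -= 2.0 * c
            if i > 0:
                c = rf[i] / (rc[i] * dr * dr)
                entries += [(m, idx(i - 1, k), c)]
                diag -= c
            if k + 1 < nz:
                entries += [(m, idx(i, k + 1), 1.0 / dz**2)]
                diag -= 1.0 / dz**2
            # k+1 == nz: top face handled explicitly; Neumann ghost -> cancel
            if k - 1 >= 1:
                entries += [(m, idx(i, k - 1), 1.0 / dz**2)]
                diag -= 1.0 / dz**2
            else:  # u_z(:,0) = 0 Dirichlet
                diag -= 1.0 / dz**2
            entries.append((m, m, diag))
    return _assemble(nr * nk, entries)


def _apply_uz_operator(grid: Grid, u_z: np.ndarray) -> np.ndarray:
    nr, nz, dr, dz = grid.nr, grid.nz, grid.dr, grid.dz
    rc, rf = grid.r_centers[:, None], grid.r_faces[:, None]
    u = u_z[:, 1:-1]
    ur_ = np.vstack([u[1:], -u[-1:]])
    ul_ = np.vstack([u[:1], u[:-1]])  # axis mirror
    radial = (rf[1:] * (ur_ - u) - rf[:-1] * (u - ul_)) / (rc * dr * dr)
    radial[0] = (rf[1, 0] * (u[1] - u[0])) / (rc[0] * dr * dr)
    full = np.hstack([u_z[:, :1] * 0.0, u, u[:, -1:]])  # bottom 0, top Neumann
    vert = (full[:, 2:] - 2.0 * u + full[:, :-2]) / dz**2
    out = np.zeros_like(u_z)
    out[:, 1:-1] = radial + vert
    return out


def _build_poisson_operator(grid: Grid, top_scale: float = 1.0):
    """Pressure Poisson operator: Neumann at axis/wall/bottom; at the free
    surface a Robin row: the Dirichlet ghost coefficient is scaled by
    ``top_scale`` = 1/(1 + beta c dt), the implicit surface-stiffness factor
    (c = rho g + 4 sigma / dr^2), so capillary-gravity response is treated
    implicitly and the over-damped surface relaxes quasi-statically."""
    nr, nz, dr, dz = grid.nr, grid.nz, grid.dr, grid.dz
    rc, rf = grid.r_centers, grid.r_faces
    idx = lambda i, k: i * nz + k
    entries = []
    for i in range(nr):
        for k in range(nz):
            m = idx(i, k)
            diag = 0.0
            if i + 1 < nr:
                c = rf[i + 1] / (rc[i] * dr * dr)
                entries += [(m, idx(i + 1, k), c)]
                diag -= c
            if i > 0:
                c = rf[i] / (rc[i] * dr * dr)
                entries += [(m, idx(i - 1, k), c)]
                diag -= c
            if k + 1 < nz:
                entries += [(m, idx(i, k + 1), 1.0 / dz**2)]
                diag -= 1.0 / dz**2
            else:  # top Robin row (implicitly stiffened Dirichlet ghost)
                diag -= 2.0 * top_scale / dz**2
            if k > 0:
                entries += [(m, idx(i, k - 1), 1.0 / dz**2)]
                diag -= 1.0 / dz**2
            entries.append((m, m, diag))
    return _assemble(nr * nz, entries)


# ---------------------------------------------------------------------------
# The solver
# ---------------------------------------------------------------------------

class AxisymmetricFlowSolver:
    """Time integrator for one run configuration.

    Parameters
    ----------
    geometry, grid, model, drive
        Culture geometry, staggered grid (the solver integrates the mucus
        layer [0, R] x [0, H]), fluid model, and bottom-plate drive.
    dt
        Fixed time step [s].
    surface_tension, gravity
        sigma [N/m] and g [m/s^2]; ``gravity=0`` disables the hydrostatic
        restoring term of the deformed surface.
    free_surface
        If False the interface is held flat (markers not advected); the
        tangential stress-free top condition still applies.
    stabilization
        Multiplier on the added/subtracted polymer stabilization viscosity.
    """

    def __init__(
        self,
        geometry: Geometry,
        grid: Grid,
        model: FluidModel,
        drive,
        dt: float,
        *,
        surface_tension: float = SURFACE_TENSION,
        gravity: float = GRAVITY,
        free_surface: bool = True,
        stabilization: float = 1.0,
        stabilization_bias: float = 0.25,
        grid_damping: float = 0.02,
        epsilon_blend: float = BLEND_EPSILON,
        reseed_interval: int = 50,
        n_markers: int | None = None,
        conformation_check_interval: int = 200,
        divergence_tol: float = 1.0e-8,
        ramp_time: float = 0.0,
    ) -> None:
        if abs(grid.radius - geometry.radius) > 1e-12 * geometry.radius:
            raise ValueError("grid radius must match the geometry")
        if abs(grid.depth - geometry.depth) > 1e-12 * geometry.depth:
            raise ValueError("grid depth must match the initial mucus depth")
        if dt <= 0:
            raise ValueError("dt must be > 0")
        self.geometry = geometry
        self.grid = grid
        self.model = model
        self.drive = drive
        self.dt = float(dt)
        self.sigma = surface_tension
        self.gravity = gravity
        self.free_surface = free_surface
        self.epsilon_blend = epsilon_blend
        self.reseed_interval = reseed_interval
        self.conformation_check_interval = conformation_check_interval
        self.divergence_tol = divergence_tol
        # smooth start: an impulsively started oscillatory drive would shear
        # the bottom cell at O(u_b/dz) for one step and break the stress
        # update; the ramp spreads the start over ramp_time seconds
        self.ramp_time = float(ramp_time)
        self.rho = model.density
        self.eta_s = model.solvent_viscosity
        self.modes = model.modes
        self.eta_add = stabilization * sum(
            m.modulus * m.relaxation_time * dt / (m.relaxation_time + dt)
            for m in self.modes
        )
        # A small fraction of the polymer viscosity is added implicitly and
        # never subtracted: the centered strain / averaged stress-divergence
        # stencils are blind to grid-scale stress modes, whose ~1% leakage
        # back into the momentum balance would otherwise pump them; the
        # residual damping must therefore scale with the polymer viscosity.
        # At resolved scales this biases the azimuthal balance by O(2%) of
        # the polymer stress response.
        self.eta_grid = grid_damping * sum(m.polymer_viscosity for m in self.modes)
        self.eta_imp = self.eta_s + self.eta_add + self.eta_grid
        self.eta_sub = (1.0 - stabilization_bias) * self.eta_add
        # The meridional (u_r, u_z) momentum is damped implicitly with the
        # full polymer viscosity (not subtracted): at quasi-steady state the
        # polymer stress responds to the slow secondary flow as a viscosity
        # ~ sum eta_p,i, so the steady balance is preserved while the weakly
        # damped elastic meridional oscillations (which would otherwise ring
        # at the hoop-stress forcing) are suppressed.
        self.eta_polymer = sum(m.polymer_viscosity for m in self.modes)
        self.eta_imp_mer = self.eta_s + self.eta_polymer
        self._step_count = 0

        g = grid
        ident = lambda n: csc_matrix(
            (np.full(n, self.rho / dt), (np.arange(n), np.arange(n))),
            shape=(n, n),
        )
        self._lu_theta = splu(
            (ident(g.nr * g.nz) - self.eta_imp * _build_utheta_operator(g)).tocsc()
        )
        self._lu_r = splu(
            (
                ident((g.nr - 1) * g.nz)
                - self.eta_imp_mer * _build_ur_operator(g)
            ).tocsc()
        )
        self._lu_z = splu(
            (
                ident(g.nr * (g.nz - 1))
                - self.eta_imp_mer * _build_uz_operator(g)
            ).tocsc()
        )
        # implicit surface stiffness (hydrostatic + worst-case grid-scale
        # capillary response of the discrete curvature, with margin)
        self._beta = 2.0 * dt / (self.rho * g.dz)
        c_stiff = self.rho * abs(gravity) + 8.0 * surface_tension / g.dr**2
        self._top_scale = 1.0 / (1.0 + self._beta * c_stiff * dt)
        self._lu_p = splu(_build_poisson_operator(g, self._top_scale).tocsc())
        # balance pressure: grad^2 p = div F with Dirichlet p_s at the surface
        self._lu_pbal = splu(_build_poisson_operator(g, 1.0).tocsc())

        self.state = FlowState.rest(grid, len(self.modes), n_markers)
        self._p_surf = self._surface_pressure(self.state)

    # -- helpers ----------------------------------------------------------

    def suggested_dt(self) -> float:
        """Advective CFL and fastest-relaxation bounds (diffusion implicit)."""
        g = self.grid
        u_ref = max(self._u_ref(), 1e-30)
        bounds = [0.25 * g.dr / u_ref]
        if self.modes:
            bounds.append(min(m.relaxation_time for m in self.modes) / 10.0)
        period = getattr(self.drive, "period", None)
        if period:
            bounds.append(period / 128.0)
        return min(bounds)

    def _u_ref(self) -> float:
        period = getattr(self.drive, "period", None)
        times = np.linspace(0.0, period, 16, endpoint=False) if period else [0.0]
        u_max = max(
            float(
                np.max(
                    np.abs(
                        drive_bottom_velocity(
                            self.drive, self.grid.r_centers, t,
                            self.geometry.radius, self.epsilon_blend,
                        )
                    )
                )
            )
            for t in times
        )
        return u_max + 1e-30

    def _ramp(self, t: float) -> float:
        if self.ramp_time <= 0.0 or t >= self.ramp_time:
            return 1.0
        return 0.5 * (1.0 - math.cos(math.pi * t / self.ramp_time))

    def _bottom_velocity(self, t: float) -> np.ndarray:
        return self._ramp(t) * drive_bottom_velocity(
            self.drive, self.grid.r_centers, t, self.geometry.radius,
            self.epsilon_blend,
        )

    # -- kinematics -------------------------------------------------------

    def _gradients(self, state: FlowState, u_b: np.ndarray):
        """Velocity-gradient entries A_ij = d_i u_j at cell centers."""
        g = self.grid
        dr, dz = g.dr, g.dz
        rc = g.r_centers[:, None]
        u, ur, uz = state.u_theta, state.u_r, state.u_z
        urc = 0.5 * (ur[:-1] + ur[1:])
        uzc = 0.5 * (uz[:, :-1] + uz[:, 1:])

        A_rr = (ur[1:] - ur[:-1]) / dr
        A_zz = (uz[:, 1:] - uz[:, :-1]) / dz
        A_tt = urc / rc
        A_tr = -u / rc

        uR = np.vstack([u[1:], -u[-1:]])
        uL = np.vstack([-u[:1], u[:-1]])
        A_rt = (uR - uL) / (2.0 * dr)

        uzR = np.vstack([uzc[1:], -uzc[-1:]])
        uzL = np.vstack([uzc[:1], uzc[:-1]])
        A_rz = (uzR - uzL) / (2.0 * dr)

        urcU = np.hstack([urc[:, 1:], urc[:, -1:]])
        urcD = np.hstack([-urc[:, :1], urc[:, :-1]])
        A_zr = (urcU - urcD) / (2.0 * dz)

        uU = np.hstack([u[:, 1:], u[:, -1:]])
        uD = np.hstack([2.0 * u_b[:, None] - u[:, :1], u[:, :-1]])
        A_zt = (uU - uD) / (2.0 * dz)

        return {
            "rr": A_rr, "rt": A_rt, "rz": A_rz, "tr": A_tr, "tt": A_tt,
            "zr": A_zr, "zt": A_zt, "zz": A_zz,
            "urc": urc, "uzc": uzc,
        }

    @staticmethod
    def strain_rate(A) -> dict:
        return {
            "rr": 2.0 * A["rr"],
            "rt": A["rt"] + A["tr"],
            "rz": A["rz"] + A["zr"],
            "tt": 2.0 * A["tt"],
            "tz": A["zt"],
            "zz": 2.0 * A["zz"],
        }

    # -- stress update ----------------------------------------------------

    def _upwind_advect(self, f: np.ndarray, urc, uzc, parity_r: int) -> np.ndarray:
        """First-order upwind u.grad f at centers; axis ghost by parity,
        wall/bottom ghosts tau=0, top zero-gradient."""
        g = self.grid
        fL = np.vstack([parity_r * f[:1], f[:-1]])
        fR = np.vstack([f[1:], -f[-1:]])
        dfdr = np.where(urc > 0, (f - fL) / g.dr, (fR - f) / g.dr)
        fD = np.hstack([-f[:, :1], f[:, :-1]])
        fU = np.hstack([f[:, 1:], f[:, -1:]])
        dfdz = np.where(uzc > 0, (f - fD) / g.dz, (fU - f) / g.dz)
        return urc * dfdr + uzc * dfdz

    def _advance_stress(self, state: FlowState, A, gd) -> None:
        if not self.modes:
            return
        g = self.grid
        rc = g.r_centers[:, None]
        u_over_r = state.u_theta / rc
        urc, uzc = A["urc"], A["uzc"]
        parity = {"rr": 1, "rt": 1, "rz": -1, "tt": 1, "tz": -1, "zz": 1}
        for m_idx, mode in enumerate(self.modes):
            lam = mode.relaxation_time
            eta_p = mode.polymer_viscosity
            alpha = mode.mobility
            t = state.tau[m_idx]
            trr, trt, trz, ttt, ttz, tzz = t

            M_rr = trr * A["rr"] + trt * A["tr"] + trz * A["zr"]
            M_rt = trr * A["rt"] + trt * A["tt"] + trz * A["zt"]
            M_rz = trr * A["rz"] + trz * A["zz"]
            M_tr = trt * A["rr"] + ttt * A["tr"] + ttz * A["zr"]
            M_tt = trt * A["rt"] + ttt * A["tt"] + ttz * A["zt"]
            M_tz = trt * A["rz"] + ttz * A["zz"]
            M_zr = trz * A["rr"] + ttz * A["tr"] + tzz * A["zr"]
            M_zt = trz * A["rt"] + ttz * A["tt"] + tzz * A["zt"]
            M_zz = trz * A["rz"] + tzz * A["zz"]

            uc = np.empty_like(t)
            uc[_RR] = 2.0 * M_rr
            uc[_RT] = M_rt + M_tr
            uc[_RZ] = M_rz + M_zr
            uc[_TT] = 2.0 * M_tt
            uc[_TZ] = M_tz + M_zt
            uc[_ZZ] = 2.0 * M_zz

            # theta-advection basis-rotation terms of u . grad tau
            rot = np.zeros_like(t)
            rot[_RR] = -2.0 * u_over_r * trt
            rot[_RT] = u_over_r * (trr - ttt)
            rot[_TT] = 2.0 * u_over_r * trt
            rot[_RZ] = -u_over_r * ttz
            rot[_TZ] = u_over_r * trz

            rhs = uc - rot
            for c_idx, name in enumerate(STRESS_COMPONENTS):
                rhs[c_idx] -= self._upwind_advect(
                    t[c_idx], urc, uzc, parity[name]
                )
            rhs[_RR] += (eta_p / lam) * gd["rr"]
            rhs[_RT] += (eta_p / lam) * gd["rt"]
            rhs[_RZ] += (eta_p / lam) * gd["rz"]
            rhs[_TT] += (eta_p / lam) * gd["tt"]
            rhs[_TZ] += (eta_p / lam) * gd["tz"]
            rhs[_ZZ] += (eta_p / lam) * gd["zz"]
            if alpha != 0.0:
                coeff = alpha / eta_p
                rhs[_RR] -= coeff * (trr**2 + trt**2 + trz**2)
                rhs[_RT] -= coeff * (trr * trt + trt * ttt + trz * ttz)
                rhs[_RZ] -= coeff * (trr * trz + trt * ttz + trz * tzz)
                rhs[_TT] -= coeff * (trt**2 + ttt**2 + ttz**2)
                rhs[_TZ] -= coeff * (trt * trz + ttt * ttz + ttz * tzz)
                rhs[_ZZ] -= coeff * (trz**2 + ttz**2 + tzz**2)

            state.tau[m_idx] = (t + self.dt * rhs) / (1.0 + self.dt / lam)

    def conformation_positive(self, state: FlowState) -> bool:
        """Positive-definiteness of c = I + (lambda/eta_p) tau per mode."""
        for m_idx, mode in enumerate(self.modes):
            s = mode.relaxation_time / mode.polymer_viscosity
            trr = 1.0 + s * state.tau[m_idx, _RR]
            ttt = 1.0 + s * state.tau[m_idx, _TT]
            tzz = 1.0 + s * state.tau[m_idx, _ZZ]
            trt = s * state.tau[m_idx, _RT]
            trz = s * state.tau[m_idx, _RZ]
            ttz = s * state.tau[m_idx, _TZ]
            m1 = trr
            m2 = trr * ttt - trt**2
            det = (
                trr * (ttt * tzz - ttz**2)
                - trt * (trt * tzz - ttz * trz)
                + trz * (trt * ttz - ttt * trz)
            )
            if np.any(m1 <= 0) or np.any(m2 <= 0) or np.any(det <= 0):
                return False
        return True

    # -- stress divergence -------------------------------------------------

    def _stress_divergence(self, tau_sum: np.ndarray):
        g = self.grid
        nr, nz, dr, dz = g.nr, g.nz, g.dr, g.dz
        rc, rf = g.r_centers, g.r_faces
        trr, trt, trz, ttt, ttz, tzz = tau_sum

        # theta component at centers
        face_rt = np.zeros((nr + 1, nz))
        face_rt[1:-1] = 0.5 * (trt[:-1] + trt[1:])
        # wall face tau = 0; axis face weighted by r^2 = 0
        div_t = (
            rf[1:, None] ** 2 * face_rt[1:] - rf[:-1, None] ** 2 * face_rt[:-1]
        ) / (rc[:, None] ** 2 * dr)
        face_tz = np.zeros((nr, nz + 1))
        face_tz[:, 1:-1] = 0.5 * (ttz[:, :-1] + ttz[:, 1:])
        # bottom & top faces tau = 0 (literal solid-wall condition / free surface)
        div_t += (face_tz[:, 1:] - face_tz[:, :-1]) / dz

        # corner (r-face, z-face) values of tau_rz, zero on all boundaries
        corner = np.zeros((nr + 1, nz + 1))
        corner[1:-1, 1:-1] = 0.25 * (
            trz[:-1, :-1] + trz[1:, :-1] + trz[:-1, 1:] + trz[1:, 1:]
        )

        # r component at interior radial faces (nr-1, nz)
        div_r = (
            (rc[1:, None] * trr[1:] - rc[:-1, None] * trr[:-1])
            / (rf[1:-1, None] * dr)
            - 0.5 * (ttt[:-1] + ttt[1:]) / rf[1:-1, None]
            + (corner[1:-1, 1:] - corner[1:-1, :-1]) / dz
        )

        # z component at interior vertical faces (nr, nz-1)
        div_z = (
            rf[1:, None] * corner[1:, 1:-1] - rf[:-1, None] * corner[:-1, 1:-1]
        ) / (rc[:, None] * dr)
        div_z += (tzz[:, 1:] - tzz[:, :-1]) / dz
        return div_r, div_t, div_z

    # -- surface ----------------------------------------------------------

    def _surface_pressure(self, state: FlowState) -> np.ndarray:
        """p at the interface: sigma*kappa + rho g (h - H) + tau_zz(top).

        kappa is evaluated at grid scale (second differences of the height
        resampled at cell centers) so the curvature feedback respects the
        implicit stiffness bound; the spline curvature of the raw markers is
        available via :func:`curvature_from_markers`.
        """
        g = self.grid
        rc = g.r_centers
        if not self.free_surface:
            return state.total_stress[_ZZ][:, -1] * 0.0 + (
                state.total_stress[_ZZ][:, -1]
            )
        h = state.markers.height(rc)
        dh = h - g.depth
        # grid-scale curvature: -(h'' + h'/r) linearized
        dh_ext = np.concatenate([[dh[0]], dh, [dh[-1]]])  # mirror / natural
        hpp = (dh_ext[2:] - 2.0 * dh + dh_ext[:-2]) / g.dr**2
        hp = (dh_ext[2:] - dh_ext[:-2]) / (2.0 * g.dr)
        kappa = -(hpp + hp / rc)
        tzz_top = state.total_stress[_ZZ][:, -1]
        return (
            capillary_pressure(kappa, self.sigma)
            + self.rho * self.gravity * dh
            + tzz_top
        )

    def _interp_face_velocity(self, state: FlowState, r: np.ndarray,
                              z: np.ndarray):
        """Bilinear interpolation of (u_r, u_z) at points, z clamped to the
        layer."""
        g = self.grid
        zc = np.clip(z, 0.0, g.depth)
        # u_r: nodes at (r_f[i], z_c[k]); pad z ends with bc-consistent rows
        fr = np.clip(r / g.dr, 0.0, g.nr - 1e-9)
        i0 = fr.astype(int)
        wr = fr - i0
        fz = np.clip(zc / g.dz - 0.5, 0.0, g.nz - 1 - 1e-9)
        k0 = fz.astype(int)
        wz = fz - k0
        ur = state.u_r
        u_r_val = (
            ur[i0, k0] * (1 - wr) * (1 - wz)
            + ur[i0 + 1, k0] * wr * (1 - wz)
            + ur[i0, k0 + 1] * (1 - wr) * wz
            + ur[i0 + 1, k0 + 1] * wr * wz
        )
        # u_z: nodes at (r_c[i], z_f[k])
        fr2 = np.clip(r / g.dr - 0.5, 0.0, g.nr - 1 - 1e-9)
        i0b = fr2.astype(int)
        wrb = fr2 - i0b
        fz2 = np.clip(zc / g.dz, 0.0, g.nz - 1e-9)
        k0b = fz2.astype(int)
        wzb = fz2 - k0b
        uz = state.u_z
        u_z_val = (
            uz[i0b, k0b] * (1 - wrb) * (1 - wzb)
            + uz[i0b + 1, k0b] * wrb * (1 - wzb)
            + uz[i0b, k0b + 1] * (1 - wrb) * wzb
            + uz[i0b + 1, k0b + 1] * wrb * wzb
        )
        return u_r_val, u_z_val

    def _advect_markers(self, state: FlowState) -> None:
        mk = state.markers
        u_r_val, u_z_val = self._interp_face_velocity(state, mk.r, mk.z)
        r_new = mk.r + self.dt * u_r_val
        z_new = mk.z + self.dt * u_z_val
        r_new[0] = 0.0
        r_new[-1] = self.grid.radius  # pinned contact line at the wall film
        z_new[-1] = mk.z[-1]
        if np.any(np.diff(r_new) <= 0):
            raise SolverError("overturned surface: markers crossed in r")
        state.markers = SurfaceMarkers(r_new, z_new)
        if self._step_count % self.reseed_interval == 0:
            state.markers = state.markers.reseed(self.grid.radius)

    # -- one time step -----------------------------------------------------

    def step(self) -> FlowState:
        state = self.state
        g = self.grid
        dt, rho = self.dt, self.rho
        nr, nz = g.nr, g.nz
        rc = g.r_centers[:, None]
        rf = g.r_faces[:, None]

        apply_boundary_conditions(
            state, self.drive, self.geometry, state.t, self.epsilon_blend
        )
        u_b_old = self._bottom_velocity(state.t)
        u_b_new = self._bottom_velocity(state.t + dt)

        A = self._gradients(state, u_b_old)
        gd = self.strain_rate(A)
        self._advance_stress(state, A, gd)
        div_r, div_t, div_z = self._stress_divergence(state.total_stress)

        urc, uzc = A["urc"], A["uzc"]

        # --- meridional force field (without pressure) ---
        ut_face = np.zeros((nr + 1, nz))
        ut_face[1:-1] = 0.5 * (state.u_theta[:-1] + state.u_theta[1:])
        centrifugal = rho * ut_face[1:-1] ** 2 / rf[1:-1]
        adv_r = urc * A["rr"]
        adv_r_face = 0.5 * (adv_r[:-1] + adv_r[1:])
        uz_face_r = 0.5 * (uzc[:-1] + uzc[1:])
        dur_dz = np.gradient(state.u_r[1:-1], g.dz, axis=1)
        adv_r_face = adv_r_face + uz_face_r * dur_dz
        F_r = centrifugal - rho * adv_r_face + div_r  # (nr-1, nz)

        adv_z = uzc * A["zz"]
        adv_z_face = 0.5 * (adv_z[:, :-1] + adv_z[:, 1:])
        duz_dr = np.gradient(state.u_z[:, 1:-1], g.dr, axis=0)
        ur_face_z = 0.5 * (urc[:, :-1] + urc[:, 1:])
        adv_z_face = adv_z_face + ur_face_z * duz_dr
        F_z = div_z - rho * adv_z_face  # (nr, nz-1)

        # --- balance pressure: grad^2 p = div F, p = p_s at the surface ---
        p_surf_old = self._p_surf
        F_r_full = np.zeros((nr + 1, nz))
        F_r_full[1:-1] = F_r
        F_z_full = np.zeros((nr, nz + 1))
        F_z_full[:, 1:-1] = F_z
        rhs_bal = (
            (rf[1:] * F_r_full[1:] - rf[:-1] * F_r_full[:-1]) / (rc * g.dr)
            + (F_z_full[:, 1:] - F_z_full[:, :-1]) / g.dz
        )
        rhs_bal[:, -1] -= 2.0 * p_surf_old / g.dz**2
        p_bal = self._lu_pbal.solve(rhs_bal.ravel()).reshape(nr, nz)

        # --- theta momentum ---
        adv_t = urc * A["rt"] + uzc * A["zt"] + urc * state.u_theta / rc
        rhs_t = (
            rho / dt * state.u_theta
            - rho * adv_t
            + div_t
            - self.eta_sub * _apply_utheta_operator(g, state.u_theta, u_b_old)
        )
        rhs_t[:, 0] += self.eta_imp * 2.0 * u_b_new / g.dz**2
        u_t_new = self._lu_theta.solve(rhs_t.ravel()).reshape(nr, nz)

        # --- r momentum (interior faces) ---
        dpdr = (p_bal[1:] - p_bal[:-1]) / g.dr
        rhs_r = rho / dt * state.u_r[1:-1] + F_r - dpdr
        u_r_new = np.zeros_like(state.u_r)
        u_r_new[1:-1] = self._lu_r.solve(rhs_r.ravel()).reshape(nr - 1, nz)

        # --- z momentum (interior faces) ---
        dpdz = (p_bal[:, 1:] - p_bal[:, :-1]) / g.dz
        rhs_z = rho / dt * state.u_z[:, 1:-1] + F_z - dpdz
        u_z_new = np.zeros_like(state.u_z)
        u_z_new[:, 1:-1] = self._lu_z.solve(rhs_z.ravel()).reshape(nr, nz - 1)

        # top face: implicitly stiffened surface response
        # u_top^{n+1} = [u_top^n - beta (p_s - p_top)] / (1 + beta c dt)
        #             + top_scale * beta * phi_top
        u_z_new[:, -1] = self._top_scale * (
            state.u_z[:, -1] - self._beta * (p_surf_old - p_bal[:, -1])
        )

        # --- projection (incremental) ---
        div_star = (
            (rf[1:] * u_r_new[1:] - rf[:-1] * u_r_new[:-1]) / (rc * g.dr)
            + (u_z_new[:, 1:] - u_z_new[:, :-1]) / g.dz
        )
        rhs_p = rho / dt * div_star
        phi = self._lu_p.solve(rhs_p.ravel()).reshape(nr, nz)
        u_r_new[1:-1] -= dt / rho * (phi[1:] - phi[:-1]) / g.dr
        u_z_new[:, 1:-1] -= dt / rho * (phi[:, 1:] - phi[:, :-1]) / g.dz
        u_z_new[:, -1] += self._top_scale * self._beta * phi[:, -1]
        state.p = p_bal + phi

        state.u_theta = u_t_new
        state.u_r = u_r_new
        state.u_z = u_z_new
        state.t += dt
        self._step_count += 1

        if self.free_surface:
            self._advect_markers(state)
        self._p_surf = self._surface_pressure(state)

        # validity checks
        div = state.divergence()
        u_ref = self._u_ref()
        if np.max(np.abs(div)) > self.divergence_tol * u_ref / g.depth:
            raise SolverError(
                f"divergence residual {np.max(np.abs(div)):.3e} exceeds "
                f"tolerance after projection at t={state.t:.4g}"
            )
        if self._step_count % 50 == 0:
            state.check_finite()
        if (
            self.conformation_check_interval
            and self._step_count % self.conformation_check_interval == 0
            and not self.conformation_positive(state)
        ):
            raise SolverError(
                f"conformation tensor lost positive definiteness at "
                f"t={state.t:.4g}"
            )
        return state

    # -- drivers -----------------------------------------------------------

    def run(
        self,
        t_end: float,
        probes: list[tuple[float, float]] | None = None,
        record_interval: int = 1,
        diagnostics_interval: int | None = None,
    ):
        """Advance to t_end, recording probe signals and diagnostics.

        Probe records hold u_theta, the rtheta / thetaz shear rates and the
        corresponding total shear stresses (polymer + solvent) at the nearest
        cell center.  Returns (probe DataFrame or None, diagnostics DataFrame).
        """
        g = self.grid
        n_steps = int(round((t_end - self.state.t) / self.dt))
        probe_idx = [g.center_index(r, z) for (r, z) in (probes or [])]
        rows = []
        diag = []
        if diagnostics_interval is None:
            diagnostics_interval = max(1, n_steps // 400)
        for n in range(n_steps):
            state = self.step()
            if probe_idx and (n % record_interval == 0):
                u_b = self._bottom_velocity(state.t)
                A = self._gradients(state, u_b)
                gd = self.strain_rate(A)
                tau = state.total_stress
                for (pi, (i, k)) in enumerate(probe_idx):
                    rows.append(
                        {
                            "t": state.t,
                            "probe": pi,
                            "r": g.r_centers[i],
                            "z": g.z_centers[k],
                            "u_theta": state.u_theta[i, k],
                            "rate_rt": gd["rt"][i, k],
                            "rate_tz": gd["tz"][i, k],
                            "stress_rt": tau[_RT][i, k]
                            + self.eta_s * gd["rt"][i, k],
                            "stress_tz": tau[_TZ][i, k]
                            + self.eta_s * gd["tz"][i, k],
                        }
                    )
            if n % diagnostics_interval == 0 or n == n_steps - 1:
                h = state.markers.height(g.r_centers)
                diag.append(
                    {
                        "t": state.t,
                        "mass_flux": mass_flux_theta0(state, self.rho),
                        "h_center": h[0],
                        "h_wall": state.markers.height(0.95 * g.radius),
                        "volume": fluid_volume(state),
                        "max_div": float(np.max(np.abs(state.divergence()))),
                    }
                )
        probe_df = pd.DataFrame(rows) if rows else None
        return probe_df, pd.DataFrame(diag)


def run_to_quasi_steady(
    solver: AxisymmetricFlowSolver,
    max_time: float,
    check_window: float | None = None,
    rel_tol: float = 1.0e-5,
    diagnostics_interval: int | None = None,
):
    """Integrate until the mass flux and surface shape are quasi-steady.

    Steadiness: relative change of the theta=0 mass flux and of h(r) over one
    check window (one drive period, or 1 s for constant swirl) below
    ``rel_tol``.  Returns (state, diagnostics DataFrame, converged flag); if
    the time budget is exhausted first the partial result is flagged
    non-converged.
    """
    period = getattr(solver.drive, "period", None)
    if check_window is None:
        check_window = period if period else 1.0
    g = solver.grid
    steps_per_check = max(1, int(round(check_window / solver.dt)))
    if diagnostics_interval is None:
        diagnostics_interval = max(1, steps_per_check // 8)
    diag = []
    last_flux = None
    last_h = None
    converged = False
    n = 0
    state = solver.state
    while state.t < max_time - 0.5 * solver.dt:
        state = solver.step()
        n += 1
        if n % diagnostics_interval == 0:
            diag.append(
                {
                    "t": state.t,
                    "mass_flux": mass_flux_theta0(state, solver.rho),
                    "h_center": state.markers.height(0.0),
                    "h_wall": state.markers.height(0.95 * g.radius),
                    "volume": fluid_volume(state),
                }
            )
        if n % steps_per_check == 0:
            flux = mass_flux_theta0(state, solver.rho)
            h = state.markers.height(g.r_centers)
            if last_flux is not None:
                scale = max(abs(flux), abs(last_flux), 1e-300)
                dflux = abs(flux - last_flux) / scale
                dh = np.max(np.abs(h - last_h)) / g.depth
                if dflux < rel_tol and dh < rel_tol:
                    converged = True
                    break
            last_flux, last_h = flux, h
    return state, pd.DataFrame(diag), converged
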