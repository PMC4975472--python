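"""Advection-diffusion of a passive drug concentration in the mucus layer.

The concentration obeys

    dC/dt = D Lap C - div(u C),

solved in conservative finite-volume form on either the axisymmetric (r, z)
grid or the theta-resolved (r, theta, z) grid.  The bottom plate (the
PCL-mucus interface) absorbs any concentration that reaches it (C = 0
Dirichlet); the absorbed outflux is accumulated cell-exactly into named
bottom-plate region ledgers (inner disk, outer section, angular sector).
The side wall and the free surface (treated as flat for transport; the
interface deformations are micron-scale) are zero-flux.  Advection uses a
monotone first-order upwind flux, diffusion an explicit centered stencil.

The drug is passive: it does not alter the mucus properties or the flow,
so the velocity field is frozen (solver snapshots, a cycle-averaged field,
or a prescribed analytic swirl).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ConcentrationField",
    "AbsorptionRegions",
    "peclet",
    "init_disk",
    "init_strip",
    "step_transport",
    "stable_dt",
    "absorbed_fraction",
    "time_to_fraction",
    "uptake_sweep",
]


def peclet(length: float, velocity: float, diffusivity: float) -> float:
    """Peclet number Pe = L * V / D (advective over diffusive transport)."""
    if length <= 0 or velocity <= 0:
        raise ValueError("length and velocity must be > 0")
    if diffusivity <= 0:
        raise ValueError("diffusivity must be > 0 (D = 0 is purely advective)")
    return length * velocity / diffusivity


@dataclass(frozen=True)
class AbsorptionRegions:
    """Named bottom-plate regions used for the uptake ledgers.

    inner_disk: r <= r0;  outer: r > r0;  sector: -pi/12 < theta < pi/12
    (1/12, i.e. 8.33%, of the plate area, opposite the initial strip).
    """

    disk_radius: float = 1.0e-3
    sector_half_angle: float = math.pi / 12.0

    def names(self, axisymmetric: bool) -> tuple[str, ...]:
        base = ("inner_disk", "outer", "total")
        return base if axisymmetric else base + ("sector",)


@dataclass
class ConcentrationField:
    """Concentration on an (r, z) or (r, theta, z) cell-centered grid.

    ``c`` has shape (nr, nz) in axisymmetric mode or (nr, ntheta, nz);
    theta cells are uniform over [-pi, pi).  The ledger tracks absorbed
    mass per region as absolute mass (volume-integrated concentration).
    """

    radius: float
    depth: float
    c: np.ndarray
    diffusivity: float
    regions: AbsorptionRegions = field(default_factory=AbsorptionRegions)
    absorbed: dict = field(default_factory=dict)
    initial_mass: float = 0.0
    t: float = 0.0

    @classmethod
    def zeros(
        cls,
        nr: int,
        nz: int,
        radius: float,
        depth: float,
        diffusivity: float,
        ntheta: int | None = None,
        regions: AbsorptionRegions | None = None,
    ) -> "ConcentrationField":
        shape = (nr, nz) if ntheta is None else (nr, ntheta, nz)
        regions = regions or AbsorptionRegions()
        f = cls(radius, depth, np.zeros(shape), diffusivity, regions)
        for name in regions.names(f.axisymmetric):
            f.absorbed[name] = 0.0
        return f

    @property
    def axisymmetric(self) -> bool:
        return self.c.ndim == 2

    @property
    def nr(self) -> int:
        return self.c.shape[0]

    @property
    def ntheta(self) -> int:
        return 1 if self.axisymmetric else self.c.shape[1]

    @property
    def nz(self) -> int:
        return self.c.shape[-1]

    @property
    def dr(self) -> float:
        return self.radius / self.nr

    @property
    def dz(self) -> float:
        return self.depth / self.nz

    @property
    def dtheta(self) -> float:
        return 2.0 * math.pi / self.ntheta

    @property
    def r_centers(self) -> np.ndarray:
        return (np.arange(self.nr) + 0.5) * self.dr

    @property
    def theta_centers(self) -> np.ndarray:
        return -math.pi + (np.arange(self.ntheta) + 0.5) * self.dtheta

    def cell_volumes(self) -> np.ndarray:
        """(nr,) volumes of one cell ring (axisym) or one cell (3D)."""
        v_ring = self.r_centers * self.dr * self.dz * 2.0 * math.pi
        if self.axisymmetric:
            return v_ring
        return v_ring / self.ntheta

    def total_mass(self) -> float:
        vols = self.cell_volumes()
        if self.axisymmetric:
            return float(np.sum(self.c * vols[:, None]))
        return float(np.sum(self.c * vols[:, None, None]))

    def mass_balance_error(self) -> float:
        """|remaining + absorbed - initial| / initial."""
        if self.initial_mass == 0:
            return 0.0
        tot = self.total_mass() + self.absorbed["total"]
        return abs(tot - self.initial_mass) / self.initial_mass


def init_disk(field_: ConcentrationField, r0: float, value: float = 1.0,
              layers: int = 1) -> ConcentrationField:
    """Deposit a disk of concentration (radius r0) on the top mucus layer."""
    if r0 > field_.radius:
        raise ValueError("disk radius exceeds the culture radius")
    rf = np.arange(field_.nr + 1) * field_.dr
    # area-overlap weight of each annular cell with the disk r <= r0
    overlap = (np.clip(r0, rf[:-1], rf[1:]) ** 2 - rf[:-1] ** 2) / (
        rf[1:] ** 2 - rf[:-1] ** 2
    )
    if field_.axisymmetric:
        field_.c[:, -layers:] = value * overlap[:, None]
    else:
        field_.c[:, :, -layers:] = value * overlap[:, None, None]
    field_.initial_mass = field_.total_mass()
    return field_


def init_strip(field_: ConcentrationField, fraction: float = 0.01,
               value: float = 1.0, layers: int = 1) -> ConcentrationField:
    """Deposit a radial strip whose arc width grows as 2 pi r * fraction.

    The arc width 2 pi r / 100 (default) corresponds to a constant angular
    width 2 pi / 100 independent of radius; requires a theta-resolved grid.
    The strip is centered at theta = pi, diametrically opposite the
    absorption sector at |theta| < pi/12.
    """
    if field_.axisymmetric:
        raise ValueError("strip layout requires a theta-resolved grid")
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    half = math.pi * fraction
    # angular distance of each cell's [lo, hi) edges from theta = pi
    lo = field_.theta_centers - 0.5 * field_.dtheta
    hi = field_.theta_centers + 0.5 * field_.dtheta
    dist_lo = math.pi - np.abs(lo)
    dist_hi = math.pi - np.abs(hi)
    # overlap of each cell with the band (pi - half, pi]
    overlap = (
        np.clip(half - np.minimum(dist_lo, dist_hi), 0.0, field_.dtheta)
        / field_.dtheta
    )
    field_.c[:, :, -layers:] = value * overlap[None, :, None]
    field_.initial_mass = field_.total_mass()
    return field_


def _region_masks(field_: ConcentrationField) -> dict:
    r = field_.r_centers
    masks = {
        "inner_disk": r <= field_.regions.disk_radius,
        "outer": r > field_.regions.disk_radius,
        "total": np.ones_like(r, dtype=bool),
    }
    return masks


def stable_dt(field_: ConcentrationField, u_r=None, u_theta=None, u_z=None,
              safety: float = 0.45) -> float:
    """Explicit stability bound: diffusive and advective CFL limits."""
    D = field_.diffusivity
    bounds = []
    if D > 0:
        inv = 2.0 * D * (1.0 / field_.dr**2 + 1.0 / field_.dz**2)
        if not field_.axisymmetric:
            inv += 2.0 * D / (field_.r_centers.min() * field_.dtheta) ** 2
        bounds.append(1.0 / inv)
    for u, h in ((u_r, field_.dr), (u_z, field_.dz)):
        if u is not None and np.max(np.abs(u)) > 0:
            bounds.append(h / np.max(np.abs(u)))
    if u_theta is not None and np.max(np.abs(u_theta)) > 0:
        # per-cell bound: arc length r dtheta against the local speed
        r_loc = field_.r_centers[:, None, None]
        with np.errstate(divide="ignore"):
            cell = np.where(
                np.abs(u_theta) > 0,
                r_loc * field_.dtheta / np.abs(u_theta),
                np.inf,
            )
        bounds.append(float(cell.min()))
    if not bounds:
        raise ValueError("no dynamics: provide D > 0 or a velocity field")
    return safety * min(bounds)


def _upwind_flux(u_face: np.ndarray, c_minus: np.ndarray, c_plus: np.ndarray
                 ) -> np.ndarray:
    return np.where(u_face > 0, u_face * c_minus, u_face * c_plus)


def step_transport(
    field_: ConcentrationField,
    dt: float,
    u_r: np.ndarray | None = None,
    u_theta: np.ndarray | None = None,
    u_z: np.ndarray | None = None,
) -> ConcentrationField:
    """Advance the concentration one step (explicit, conservative).

    Velocities are face-located: ``u_r`` on radial faces (nr+1, [ntheta,] nz),
    ``u_z`` on vertical faces (nr, [ntheta,] nz+1), ``u_theta`` on theta faces
    (nr, ntheta, nz) (face j between cells j-1 and j, periodic).  Absorbing
    C = 0 at z = 0 with the diffusive outflux credited to the regional
    ledgers; all other boundaries zero-flux.
    """
    D = field_.diffusivity
    c = field_.c
    axi = field_.axisymmetric
    dr, dz = field_.dr, field_.dz
    nr, nz = field_.nr, field_.nz
    rc = field_.r_centers
    rf = np.arange(nr + 1) * dr

    if axi:
        c3 = c[:, None, :]
    else:
        c3 = c
    nth = c3.shape[1]

    # ---- radial fluxes (area ~ r_f) ----
    flux_r = np.zeros((nr + 1, nth, nz))
    dcdr = (c3[1:] - c3[:-1]) / dr
    flux_r[1:-1] = -D * dcdr
    if u_r is not None:
        u_r3 = u_r[:, None, :] if u_r.ndim == 2 else u_r
        flux_r[1:-1] += _upwind_flux(u_r3[1:-1], c3[:-1], c3[1:])
    # axis (r=0): zero area; wall: zero flux

    # ---- vertical fluxes ----
    flux_z = np.zeros((nr, nth, nz + 1))
    dcdz = (c3[:, :, 1:] - c3[:, :, :-1]) / dz
    flux_z[:, :, 1:-1] = -D * dcdz
    if u_z is not None:
        u_z3 = u_z[:, None, :] if u_z.ndim == 2 else u_z
        flux_z[:, :, 1:-1] += _upwind_flux(
            u_z3[:, :, 1:-1], c3[:, :, :-1], c3[:, :, 1:]
        )
    # absorbing bottom: C = 0 Dirichlet half-cell diffusive flux (outward,
    # i.e. negative z direction)
    bottom_out = D * c3[:, :, 0] / (0.5 * dz)  # mass per area per time, > 0
    flux_z[:, :, 0] = -bottom_out
    # free surface: zero flux

    # ---- azimuthal fluxes (theta-resolved only) ----
    div_theta = 0.0
    if not axi:
        dth = field_.dtheta
        c_m = np.roll(c3, 1, axis=1)  # cell j-1 at face j
        flux_t = -D * (c3 - c_m) / (rc[:, None, None] * dth)
        if u_theta is not None:
            flux_t = flux_t + _upwind_flux(u_theta, c_m, c3)
        div_theta = (np.roll(flux_t, -1, axis=1) - flux_t) / (
            rc[:, None, None] * dth
        )

    div_r = (rf[1:, None, None] * flux_r[1:] - rf[:-1, None, None] * flux_r[:-1]) / (
        rc[:, None, None] * dr
    )
    div_z = (flux_z[:, :, 1:] - flux_z[:, :, :-1]) / dz

    c_new3 = c3 - dt * (div_r + div_z + div_theta)

    # ledger: mass absorbed through the bottom per region
    area = rc * dr * 2.0 * math.pi / nth  # per theta cell
    absorbed_cells = bottom_out * dt * area[:, None]  # (nr, nth)
    masks = _region_masks(field_)
    for name, mask in masks.items():
        field_.absorbed[name] += float(np.sum(absorbed_cells[mask]))
    if not axi and "sector" in field_.absorbed:
        smask = np.abs(field_.theta_centers) < field_.regions.sector_half_angle
        field_.absorbed["sector"] += float(np.sum(absorbed_cells[:, smask]))

    c_new = c_new3[:, 0, :] if axi else c_new3
    neg = c_new < 0
    if np.any(neg):
        worst = float(-c_new[neg].min())
        if worst > 1e-9 * max(float(np.max(c_new)), 1e-300):
            raise FloatingPointError(
                f"transport scheme produced negative concentration {-worst:.3e}"
            )
        c_new = np.clip(c_new, 0.0, None)
    field_.c = c_new
    field_.t += dt
    return field_


def absorbed_fraction(field_: ConcentrationField, region: str) -> float:
    """Absorbed mass in a named region divided by the initial mass."""
    if region not in field_.absorbed:
        raise ValueError(
            f"unknown region '{region}'; known: {sorted(field_.absorbed)}"
        )
    if field_.initial_mass == 0:
        return 0.0
    return field_.absorbed[region] / field_.initial_mass


def time_to_fraction(
    field_: ConcentrationField,
    target: float,
    dt: float,
    region: str = "total",
    max_time: float = np.inf,
    max_steps: int = 10_000_000,
    u_r=None,
    u_theta=None,
    u_z=None,
):
    """Integrate until the cumulative absorbed fraction in ``region`` first
    reaches ``target``; the crossing time is linearly interpolated.

    Returns (time, converged); a budget overrun returns the last time with
    ``converged=False``.
    """
    if not 0 <= target < 1:
        raise ValueError("target fraction must lie in [0, 1)")
    if target == 0:
        return 0.0, True
    prev_t, prev_f = field_.t, absorbed_fraction(field_, region)
    if prev_f >= target:
        return field_.t, True
    for _ in range(max_steps):
        step_transport(field_, dt, u_r=u_r, u_theta=u_theta, u_z=u_z)
        f = absorbed_fraction(field_, region)
        if f >= target:
            frac = (target - prev_f) / max(f - prev_f, 1e-300)
            return prev_t + frac * (field_.t - prev_t), True
        prev_t, prev_f = field_.t, f
        if field_.t >= max_time:
            break
    return field_.t, False


def uptake_sweep(
    peclet_values,
    layout: str,
    flow,
    *,
    nr: int = 48,
    nz: int = 8,
    ntheta: int = 64,
    radius: float = 1.0e-2,
    depth: float = 5.0e-5,
    length_scale: float = 1.0e-2,
    velocity_scale: float = 1.0e-9,
    end_fraction: float = 0.99,
    max_steps: int = 2_000_000,
) -> pd.DataFrame:
    """Absorption metrics versus Peclet number for a frozen flow field.

    ``flow`` maps a field to face velocities: a callable returning
    ``(u_r, u_theta, u_z)`` given the field, or None for pure diffusion.
    Pe sets D = L*V/Pe at fixed characteristic length and velocity.  Each
    run integrates until ``end_fraction`` of the mass is absorbed (or the
    step budget is exhausted; such cells are flagged, not dropped).

    Effectiveness bands: Pe < 0.1 not effective, Pe > 1 effective,
    Pe > 100 extremely effective (sector fraction near the perfect 8.33%).
    """
    rows = []
    for pe in np.atleast_1d(peclet_values):
        D = length_scale * velocity_scale / pe
        f = ConcentrationField.zeros(
            nr, nz, radius, depth, D,
            ntheta=None if layout == "disk" else ntheta,
        )
        if layout == "disk":
            init_disk(f, f.regions.disk_radius)
        elif layout == "strip":
            init_strip(f, 0.01)
        else:
            raise ValueError("layout must be 'disk' or 'strip'")
        u_r = u_theta = u_z = None
        if flow is not None:
            u_r, u_theta, u_z = flow(f)
        dt = stable_dt(f, u_r=u_r, u_theta=u_theta, u_z=u_z)
        converged = False
        for _ in range(max_steps):
            step_transport(f, dt, u_r=u_r, u_theta=u_theta, u_z=u_z)
            if absorbed_fraction(f, "total") >= end_fraction:
                converged = True
                break
        row = {
            "peclet": float(pe),
            "diffusivity_m2_s": D,
            "outer_fraction": absorbed_fraction(f, "outer"),
            "total_fraction": absorbed_fraction(f, "total"),
            "t_end_s": f.t,
            "converged": converged,
        }
        if not f.axisymmetric:
            row["sector_fraction"] = absorbed_fraction(f, "sector")
        rows.append(row)
    return pd.DataFrame(rows)
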