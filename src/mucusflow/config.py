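"""Structured run configuration (validated, unit-suffixed, YAML-backed).

Every physical quantity carries its SI unit in the field name; unknown keys
are rejected; the random seed is mandatory so any stochastic fixture is
reproducible.  Defaults mirror the reference parameter tables: the five-mode
mucus model and the culture geometry (R = 10 mm, Z = 100 um, H = 50 um,
sigma = 30 mN/m, rho = 1000 kg/m^3, omega_0 = 1.57e-2 rad/s).
"""

from __future__ import annotations

import hashlib
import json
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import constitutive
from .constitutive import FluidModel, GiesekusMode
from .flow_solver import AxisymmetricFlowSolver, Geometry, Grid
from .forcing import CiliaDrive, StrainDrive, SwirlDrive, observed_cilia_drive

__all__ = ["RunConfig", "load_config", "default_run_config", "config_hash"]

SCHEMA_VERSION = 1


class _StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GeometryConfig(_StrictModel):
    radius_m: float = 1.0e-2
    height_m: float = 1.0e-4
    depth_m: float = 5.0e-5

    def build(self) -> Geometry:
        return Geometry(self.radius_m, self.height_m, self.depth_m)


class GridConfig(_StrictModel):
    nr: int = 128
    nz: int = 32

    def build(self, geometry: Geometry) -> Grid:
        return Grid(self.nr, self.nz, geometry.radius, geometry.depth)


class ModeConfig(_StrictModel):
    relaxation_time_s: float
    modulus_Pa: float
    mobility: float = 0.0


class FluidConfig(_StrictModel):
    solvent_viscosity_Pa_s: float = constitutive.SOLVENT_VISCOSITY
    density_kg_m3: float = constitutive.MUCUS_DENSITY
    modes: list[ModeConfig] = Field(
        default_factory=lambda: [
            ModeConfig(relaxation_time_s=lam, modulus_Pa=g, mobility=a)
            for lam, g, a in constitutive._HBE_MODES
        ]
    )

    def build(self) -> FluidModel:
        return FluidModel(
            self.solvent_viscosity_Pa_s,
            self.density_kg_m3,
            tuple(
                GiesekusMode(m.relaxation_time_s, m.modulus_Pa, m.mobility)
                for m in self.modes
            ),
        )


class DriveConfig(_StrictModel):
    kind: Literal["swirl", "cilia", "strain"] = "swirl"
    # swirl
    omega0_rad_s: float = 1.57e-2
    # cilia (defaults: observed 10 um / 5 um strokes at the culture edge)
    power_amplitude_rad_s: Optional[float] = None
    return_amplitude_rad_s: Optional[float] = None
    power_frequency_rad_s: Optional[float] = None
    return_frequency_rad_s: Optional[float] = None
    # strain-controlled
    strain_amplitude: float = 0.05
    strain_omega0_rad_s: float = 31.41592653589793
    drive_radius_m: Optional[float] = None

    def build(self, geometry: Geometry):
        if self.kind == "swirl":
            return SwirlDrive(self.omega0_rad_s)
        if self.kind == "cilia":
            if self.power_amplitude_rad_s is None:
                return observed_cilia_drive(geometry.radius)
            return CiliaDrive(
                self.power_amplitude_rad_s,
                self.return_amplitude_rad_s or 0.0,
                self.power_frequency_rad_s,
                self.return_frequency_rad_s,
            )
        return StrainDrive(
            self.strain_amplitude,
            self.strain_omega0_rad_s,
            self.drive_radius_m or geometry.radius,
        )


class SolverConfig(_StrictModel):
    dt_s: float = 2.0e-3
    t_end_s: float = 10.0
    surface_tension_N_m: float = 3.0e-2
    gravity_m_s2: float = 9.81
    free_surface: bool = True
    stabilization: float = 1.0
    blend_epsilon: float = 0.05
    reseed_interval: int = 50
    steadiness_rel_tol: float = 1.0e-5
    divergence_tol: float = 1.0e-8
    # startup ramp [s]; None -> one drive period for oscillatory drives
    ramp_time_s: Optional[float] = None


class TransportConfig(_StrictModel):
    layout: Literal["disk", "strip"] = "disk"
    diffusivity_m2_s: Optional[float] = None
    peclet: Optional[list[float]] = None
    nr: int = 48
    nz: int = 8
    ntheta: int = 64
    disk_radius_m: float = 1.0e-3
    strip_fraction: float = 0.01
    length_scale_m: float = 1.0e-2
    velocity_scale_m_s: float = 1.0e-9


class RunConfig(_StrictModel):
    schema_version: int = SCHEMA_VERSION
    seed: int
    geometry: GeometryConfig = Field(default_factory=GeometryConfig)
    grid: GridConfig = Field(default_factory=GridConfig)
    fluid: FluidConfig = Field(default_factory=FluidConfig)
    drive: DriveConfig = Field(default_factory=DriveConfig)
    solver: SolverConfig = Field(default_factory=SolverConfig)
    transport: TransportConfig = Field(default_factory=TransportConfig)

    @model_validator(mode="after")
    def _check_schema(self):
        if self.schema_version != SCHEMA_VERSION:
            raise ValueError(
                f"unsupported schema_version {self.schema_version}"
            )
        return self

    def build_solver(self) -> AxisymmetricFlowSolver:
        geometry = self.geometry.build()
        drive = self.drive.build(geometry)
        ramp = self.solver.ramp_time_s
        if ramp is None:
            ramp = getattr(drive, "period", None) or 0.0
        return AxisymmetricFlowSolver(
            geometry,
            self.grid.build(geometry),
            self.fluid.build(),
            drive,
            self.solver.dt_s,
            ramp_time=ramp,
            surface_tension=self.solver.surface_tension_N_m,
            gravity=self.solver.gravity_m_s2,
            free_surface=self.solver.free_surface,
            stabilization=self.solver.stabilization,
            epsilon_blend=self.solver.blend_epsilon,
            reseed_interval=self.solver.reseed_interval,
            divergence_tol=self.solver.divergence_tol,
        )

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.model_dump(), sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def load_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return RunConfig.model_validate(data)


def default_run_config(seed: int = 0) -> RunConfig:
    return RunConfig(seed=seed)


def config_hash(cfg: RunConfig) -> str:
    payload = json.dumps(cfg.model_dump(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]
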