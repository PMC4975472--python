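"""Shared fixtures: the expensive solver runs are session-scoped so the
flow-solver property tests and the acceptance tests reuse them.

Two simulation regimes are used (documented in docs/methods.md):

* the culture regime — the physical parameters of the HBE culture
  (R = 10 mm, H = 50 um, five-mode mucus); inertia is dynamically
  negligible there, so interface shape, mass flux, and LAOS diagnostics
  are meaningful, while inertial spin-up transients are not observable;
* a scaled laboratory swirl regime (R = 5 cm, H = 1 cm, order-one
  Reynolds and Weissenberg numbers) in which the inertial secondary-flow
  structure (vortex orientation, flux transients) is resolved.
"""

from __future__ import annotations

import numpy as np
import pytest

from mucusflow.constitutive import (
    FluidModel,
    GiesekusMode,
    hbe_mucus_five_mode,
    single_mode_reference,
)
from mucusflow.flow_solver import (
    AxisymmetricFlowSolver,
    Geometry,
    Grid,
    mass_flux_theta0,
)
from mucusflow.forcing import SwirlDrive, observed_cilia_drive
from mucusflow.regimes import gap_envelope, strain_controlled_run

OMEGA0 = 10.0 * np.pi

CULTURE_MODELS = {
    "newtonian": FluidModel(10.0, 1000.0, ()),
    "ucm": single_mode_reference(0.0),
    "giesekus": single_mode_reference(0.3),
    "five_mode": hbe_mucus_five_mode(),
}

LAB_MODELS = {
    "newtonian": FluidModel(1.0, 1000.0, ()),
    "ucm": FluidModel(0.1, 1000.0, (GiesekusMode(5.0, 0.18, 0.0),)),
    "giesekus": FluidModel(0.1, 1000.0, (GiesekusMode(5.0, 0.18, 0.3),)),
    "multi_mode": FluidModel(
        0.1, 1000.0,
        (GiesekusMode(5.0, 0.09, 0.3), GiesekusMode(1.0, 0.45, 0.2)),
    ),
}


@pytest.fixture(scope="session")
def culture_swirl_runs():
    """Swirl runs at the culture parameters (reference swirl drive), t = 0..150 s."""
    geom = Geometry()
    out = {}
    for name, model in CULTURE_MODELS.items():
        grid = Grid(128, 8, geom.radius, geom.depth)
        solver = AxisymmetricFlowSolver(
            geom, grid, model, SwirlDrive(1.57e-2), 0.01, reseed_interval=1
        )
        _, diag = solver.run(150.0, diagnostics_interval=200)
        out[name] = {"solver": solver, "state": solver.state, "diag": diag}
    return out


@pytest.fixture(scope="session")
def lab_swirl_runs():
    """Scaled laboratory swirl runs (R = 5 cm, H = 1 cm, Re ~ 10)."""
    geom = Geometry(radius=0.05, height=0.02, depth=0.01)
    out = {}
    for name, model in LAB_MODELS.items():
        grid = Grid(48, 16, geom.radius, geom.depth)
        solver = AxisymmetricFlowSolver(
            geom, grid, model, SwirlDrive(0.1), 0.005, reseed_interval=1
        )
        _, diag = solver.run(40.0, diagnostics_interval=20)
        out[name] = {"solver": solver, "state": solver.state, "diag": diag}
    return out


@pytest.fixture(scope="session")
def laos_ar200():
    """Strain-controlled five-mode run, full-radius culture (R/H = 200)."""
    probe_df, solver = strain_controlled_run(
        hbe_mucus_five_mode(), 0.05, OMEGA0, 1.0e-2, 5.0e-5,
        nr=96, nz=10, samples_per_period=128, n_periods=9,
    )
    env = gap_envelope(solver, r_fractions=(0.5,))
    return {"probe_df": probe_df, "solver": solver, "envelope": env}


@pytest.fixture(scope="session")
def laos_ar100():
    """Localized hurricane (R = 5 mm, H = 50 um, matched edge displacement
    -> gamma_0 ~ 0.1)."""
    probe_df, solver = strain_controlled_run(
        hbe_mucus_five_mode(), 0.1, OMEGA0, 5.0e-3, 5.0e-5,
        nr=96, nz=10, samples_per_period=128, n_periods=9,
        probe_fractions=((0.4, 0.4), (0.5, 0.5)),
    )
    env = gap_envelope(solver, r_fractions=(0.5,))
    return {"probe_df": probe_df, "solver": solver, "envelope": env}


@pytest.fixture(scope="session")
def cilia_frozen_flow():
    """Cycle-averaged velocity field of the cilia-driven five-mode culture."""
    geom = Geometry()
    grid = Grid(96, 10, geom.radius, geom.depth)
    drive = observed_cilia_drive()
    solver = AxisymmetricFlowSolver(
        geom, grid, hbe_mucus_five_mode(), drive, drive.period / 128,
        ramp_time=drive.period, reseed_interval=1,
    )
    n_cycle = 128
    n_steps = 12 * n_cycle
    acc_ur = np.zeros_like(solver.state.u_r)
    acc_uz = np.zeros_like(solver.state.u_z)
    for i in range(n_steps):
        st = solver.step()
        if i >= n_steps - n_cycle:
            acc_ur += st.u_r
            acc_uz += st.u_z
    return {
        "solver": solver,
        "u_r": acc_ur / n_cycle,
        "u_z": acc_uz / n_cycle,
        "grid": grid,
    }
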