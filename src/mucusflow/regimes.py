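"""Linear/nonlinear regime characterization of driven culture flows.

Runs the axisymmetric solver under the strain-controlled drive and reduces
probe time series to harmonic ratios and third-harmonic Chebyshev
coefficients, sweeping hurricane aspect ratio (R/H) and drive amplitude.
The full-radius culture (aspect ratio 200) with the matched strain amplitude
gamma_0 = 0.05 sits in the gap-loading, linear regime; halving the hurricane
radius at matched edge displacement roughly doubles the local strain and can
drive the mucus into measurable strain softening (e3 < 0).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .constitutive import FluidModel, hbe_mucus_five_mode
from .flow_solver import AxisymmetricFlowSolver, Geometry, Grid
from .forcing import StrainDrive
from .laos import chebyshev_coefficients, record_from_series

__all__ = ["strain_controlled_run", "analyze_probes", "regime_sweep"]


def strain_controlled_run(
    model: FluidModel,
    strain_amplitude: float,
    omega0: float,
    radius: float,
    depth: float,
    *,
    nr: int = 48,
    nz: int = 12,
    samples_per_period: int = 128,
    n_periods: int = 9,
    probe_fractions=((0.25, 0.25), (0.5, 0.5), (0.75, 0.5), (0.9, 0.75),
                     (0.5, 0.25), (0.4, 0.4)),
    free_surface: bool = False,
):
    """Run the solver under the logarithmic strain drive and record probe series.

    The interface stays flat by default for these oscillatory runs (its
    deformation over a few drive periods is negligible); probes record the
    r-theta and theta-z shear rates and total shear stresses.
    Returns (probe DataFrame, solver).
    """
    geometry = Geometry(radius=radius, height=2 * depth, depth=depth)
    grid = Grid(nr, nz, radius, depth)
    drive = StrainDrive(strain_amplitude, omega0, radius)
    dt = drive.period / samples_per_period
    solver = AxisymmetricFlowSolver(
        geometry, grid, model, drive, dt, free_surface=free_surface,
        ramp_time=drive.period,
    )
    probes = [(fr * radius, fz * depth) for fr, fz in probe_fractions]
    probe_df, _ = solver.run(n_periods * drive.period, probes=probes)
    return probe_df, solver


def analyze_probes(
    probe_df: pd.DataFrame,
    omega0: float,
    discard_periods: int = 5,
    n_max: int = 7,
    shear_plane: str = "rt",
) -> pd.DataFrame:
    """Per-probe harmonic ratios and Chebyshev coefficients.

    ``shear_plane`` selects the analyzed shear pair: "rt" (the in-plane
    shear imposed by the strain drive, the dominant one) or "tz" (across
    the gap).
    """
    rows = []
    for pi, sub in probe_df.groupby("probe"):
        rec = record_from_series(
            sub["t"].to_numpy(),
            sub[f"rate_{shear_plane}"].to_numpy(),
            sub[f"stress_{shear_plane}"].to_numpy(),
            omega0,
            discard_periods=discard_periods,
            location=(sub["r"].iloc[0], sub["z"].iloc[0]),
        )
        res = chebyshev_coefficients(rec, n_max=n_max)
        rows.append(
            {
                "probe": pi,
                "r": sub["r"].iloc[0],
                "z": sub["z"].iloc[0],
                "strain_amplitude": res.strain_amplitude,
                "G_prime": res.G_prime,
                "G_doubleprime": res.G_doubleprime,
                "e1": res.e_n[0],
                "e3": res.e3,
                "v1": res.v_n[0],
                "v3": res.v3,
                "ratio_stress": res.harmonics_stress.ratio_to_fundamental(),
                "ratio_rate": res.harmonics_rate.ratio_to_fundamental(),
            }
        )
    return pd.DataFrame(rows)


def gap_envelope(solver, r_fractions=(0.5,), n_periods: int = 1) -> dict:
    """Continue a (strain-driven) run for ``n_periods`` and record the
    amplitude envelope of u_theta across the gap at the given radii.

    Returns {r_fraction: envelope array over z}; the gap-loading limit shows
    an envelope uniform across the gap to a fraction of a percent, while
    departures from gap loading appear as z-structure of the envelope.
    """
    g = solver.grid
    idx = {fr: min(int(fr * g.nr), g.nr - 1) for fr in r_fractions}
    period = solver.drive.period
    n_steps = int(round(n_periods * period / solver.dt))
    env = {fr: np.zeros(g.nz) for fr in r_fractions}
    for _ in range(n_steps):
        st = solver.step()
        for fr, i in idx.items():
            env[fr] = np.maximum(env[fr], np.abs(st.u_theta[i, :]))
    return env


def regime_sweep(
    aspect_ratios,
    strain_amplitudes,
    *,
    model: FluidModel | None = None,
    depth: float = 5.0e-5,
    omega0: float = 10.0 * np.pi,
    nr: int = 40,
    nz: int = 10,
    n_periods: int = 8,
    base_config=None,
) -> pd.DataFrame:
    """e3 / v3 surfaces over (aspect ratio, drive amplitude).

    Each cell runs the solver on a coarse grid with hurricane radius
    R = aspect * H and extracts the record at r = 0.5 R, z = 0.5 H.
    Non-converged (failed) cells are flagged in the ``converged`` column,
    never dropped.
    """
    if model is None:
        model = base_config.fluid.build() if base_config else hbe_mucus_five_mode()
    rows = []
    for ar in np.atleast_1d(aspect_ratios):
        for g0 in np.atleast_1d(strain_amplitudes):
            radius = float(ar) * depth
            try:
                probe_df, _ = strain_controlled_run(
                    model, float(g0), omega0, radius, depth,
                    nr=nr, nz=nz, n_periods=n_periods,
                    probe_fractions=((0.5, 0.5),),
                )
                res = analyze_probes(probe_df, omega0, discard_periods=5).iloc[0]
                rows.append(
                    {
                        "aspect_ratio": float(ar),
                        "strain_amplitude": float(g0),
                        "e3": res["e3"],
                        "v3": res["v3"],
                        "e1": res["e1"],
                        "v1": res["v1"],
                        "harmonic_ratio": max(
                            res["ratio_stress"], res["ratio_rate"]
                        ),
                        "elastically_dominated": abs(res["e3"]) > abs(res["v3"])
                        * omega0,
                        "converged": True,
                    }
                )
            except Exception as exc:  # flagged, not silently dropped
                rows.append(
                    {
                        "aspect_ratio": float(ar),
                        "strain_amplitude": float(g0),
                        "e3": np.nan, "v3": np.nan, "e1": np.nan, "v1": np.nan,
                        "harmonic_ratio": np.nan,
                        "elastically_dominated": False,
                        "converged": False,
                        "error": str(exc),
                    }
                )
    return pd.DataFrame(rows)
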