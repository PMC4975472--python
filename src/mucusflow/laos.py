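"""Large-amplitude oscillatory shear (LAOS) diagnostics.

Turns shear-strain / shear-rate / shear-stress time series (from the flow
solver or synthetic generators) into Fourier harmonics, Chebyshev
coefficients e_n (elastic) and v_n (viscous), Lissajous traces with an
ellipse-distance metric, first-harmonic moduli, and a linear/nonlinear
regime classification.

Conventions follow the Ewoldt orthogonal decomposition: for an imposed
strain gamma = gamma_0 sin(w0 t) the stress is expanded as

    sigma(t) = sum_n odd gamma_0 [ G'_n sin(n w0 t) + G''_n cos(n w0 t) ]

and the Chebyshev coefficients obey e_n = G'_n (-1)^((n-1)/2) and
v_n = G''_n / w0, so e_3 = -G'_3 and v_3 = G''_3 / w0.  e_3 < 0 flags
strain softening, v_3 > 0 shear thickening.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "OscillationRecord",
    "LAOSResult",
    "LissajousTrace",
    "fourier_harmonics",
    "harmonic_ratio",
    "chebyshev_coefficients",
    "classify_nonlinearity",
    "local_moduli",
    "lissajous",
    "analyze_record",
    "record_from_series",
]

DEFAULT_NOISE_THRESHOLD = 1e-3  # relative harmonic content below which a
#                                 signal is treated as linear


@dataclass
class OscillationRecord:
    """Uniformly sampled oscillation covering an integer number of periods."""

    time: np.ndarray
    strain: np.ndarray
    rate: np.ndarray
    stress: np.ndarray
    omega0: float
    location: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.strain = np.asarray(self.strain, dtype=float)
        self.rate = np.asarray(self.rate, dtype=float)
        self.stress = np.asarray(self.stress, dtype=float)
        n = self.time.size
        if not (self.strain.size == self.rate.size == self.stress.size == n):
            raise ValueError("all series must share the time grid")
        dt = np.diff(self.time)
        if n < 8 or not np.allclose(dt, dt[0], rtol=1e-8):
            raise ValueError("time grid must be uniform")
        self.dt = float(dt[0])
        # the window is [t0, t0 + N dt); an integer number of periods means
        # N dt is a multiple of 2 pi / omega0
        periods = n * self.dt * self.omega0 / (2.0 * np.pi)
        if abs(periods - round(periods)) > 1e-6 * max(1.0, periods):
            raise ValueError(
                f"window covers {periods:.6f} periods; an integer number is "
                "required to avoid spectral leakage"
            )
        self.n_periods = int(round(periods))
        if self.n_periods < 1:
            raise ValueError("window must cover at least one period")

    @property
    def samples_per_period(self) -> int:
        return self.time.size // self.n_periods


@dataclass
class HarmonicSpectrum:
    """One-sided harmonic decomposition relative to the fundamental omega0."""

    amplitudes: np.ndarray  # index n-1 -> harmonic n of omega0
    phases: np.ndarray  # phase of A_n cos(n w0 t' + phi_n)? see sine/cos parts
    sin_parts: np.ndarray  # coefficient of sin(n w0 t')
    cos_parts: np.ndarray  # coefficient of cos(n w0 t')
    mean: float

    def ratio_to_fundamental(self) -> float:
        if self.amplitudes[0] == 0:
            return 0.0
        return float(np.max(self.amplitudes[1:]) / self.amplitudes[0])


def _project_harmonics(t, signal, omega0, n_max, t_ref=0.0):
    """Least-squares-exact Fourier projection on an integer-period window.

    Returns sin/cos coefficients of sin(n w0 (t - t_ref)), cos(...) for
    n = 1..n_max plus the mean.
    """
    n = t.size
    theta = omega0 * (t - t_ref)
    sin_parts = np.empty(n_max)
    cos_parts = np.empty(n_max)
    for k in range(1, n_max + 1):
        sin_parts[k - 1] = 2.0 / n * np.dot(signal, np.sin(k * theta))
        cos_parts[k - 1] = 2.0 / n * np.dot(signal, np.cos(k * theta))
    return sin_parts, cos_parts, float(np.mean(signal))


def fourier_harmonics(
    record: OscillationRecord, n_max: int = 9, signal: str = "stress"
) -> HarmonicSpectrum:
    """Harmonic amplitudes and phases of one of the record's signals.

    Projection on an integer-period window (validated by the record), so the
    discrete projection is exact for band-limited inputs.  ``n_max`` must be
    resolvable: n_max < samples_per_period / 2.
    """
    y = getattr(record, signal)
    spp = record.samples_per_period
    if n_max >= spp // 2:
        raise ValueError(
            f"n_max={n_max} is at or above the Nyquist limit for "
            f"{spp} samples per period"
        )
    s, c, mean = _project_harmonics(record.time, y, record.omega0, n_max,
                                    t_ref=record.time[0])
    amps = np.hypot(s, c)
    phases = np.arctan2(c, s)
    return HarmonicSpectrum(amps, phases, s, c, mean)


def harmonic_ratio(record: OscillationRecord, n_max: int = 9,
                   signals=("stress", "rate")) -> float:
    """max_{n>1} A_n / A_1 over the requested signals (the 3% linearity metric)."""
    return max(
        fourier_harmonics(record, n_max, s).ratio_to_fundamental()
        for s in signals
    )


def _strain_phase(record: OscillationRecord) -> float:
    """Time t_ref at which the fundamental of the strain is gamma_0 sin(w0 (t - t_ref))."""
    s, c, _ = _project_harmonics(record.time, record.strain, record.omega0, 1,
                                 t_ref=record.time[0])
    # strain fundamental = A sin(w0 (t - t0) + phi), phi = atan2(c, s)
    phi = np.arctan2(c[0], s[0])
    return record.time[0] - phi / record.omega0


@dataclass
class LAOSResult:
    """Harmonics and Chebyshev coefficients of one oscillation record."""

    omega0: float
    strain_amplitude: float
    rate_amplitude: float
    harmonics_stress: HarmonicSpectrum
    harmonics_rate: HarmonicSpectrum
    g_prime_n: np.ndarray  # G'_n, n = 1..n_max (odd entries meaningful)
    g_doubleprime_n: np.ndarray
    e_n: np.ndarray  # elastic Chebyshev coefficients, index n-1
    v_n: np.ndarray  # viscous Chebyshev coefficients
    location: tuple[float, float] | None = None
    warnings: list = field(default_factory=list)

    @property
    def G_prime(self) -> float:
        return float(self.g_prime_n[0])

    @property
    def G_doubleprime(self) -> float:
        return float(self.g_doubleprime_n[0])

    @property
    def e3(self) -> float:
        return float(self.e_n[2])

    @property
    def v3(self) -> float:
        return float(self.v_n[2])

    @property
    def harmonic_ratio(self) -> float:
        return max(
            self.harmonics_stress.ratio_to_fundamental(),
            self.harmonics_rate.ratio_to_fundamental(),
        )


def chebyshev_coefficients(record: OscillationRecord, n_max: int = 9) -> LAOSResult:
    """Chebyshev decomposition of the stress into elastic and viscous parts.

    The stress is first decomposed into Fourier harmonics relative to the
    strain phase; sine (in-phase with strain) components give G'_n, cosine
    (in phase with the rate) give G''_n.  The Chebyshev coefficients follow
    from e_n = G'_n (-1)^((n-1)/2), v_n = G''_n / omega_0 for odd n.
    """
    gamma0 = _fundamental_amplitude(record, "strain")
    if gamma0 <= 0:
        raise ValueError("zero strain amplitude")
    rate0 = _fundamental_amplitude(record, "rate")
    t_ref = _strain_phase(record)
    s, c, _ = _project_harmonics(record.time, record.stress, record.omega0,
                                 n_max, t_ref=t_ref)
    gp_n = s / gamma0
    gpp_n = c / gamma0
    n = np.arange(1, n_max + 1)
    sign = np.where(n % 2 == 1, (-1.0) ** ((n - 1) // 2), 0.0)
    e_n = gp_n * sign
    v_n = np.where(n % 2 == 1, gpp_n / record.omega0, 0.0)
    spec_stress = fourier_harmonics(record, n_max, "stress")
    spec_rate = fourier_harmonics(record, n_max, "rate")
    return LAOSResult(
        omega0=record.omega0,
        strain_amplitude=gamma0,
        rate_amplitude=rate0,
        harmonics_stress=spec_stress,
        harmonics_rate=spec_rate,
        g_prime_n=gp_n,
        g_doubleprime_n=gpp_n,
        e_n=e_n,
        v_n=v_n,
        location=record.location,
    )


analyze_record = chebyshev_coefficients


def _fundamental_amplitude(record: OscillationRecord, signal: str) -> float:
    s, c, _ = _project_harmonics(record.time, getattr(record, signal),
                                 record.omega0, 1, t_ref=record.time[0])
    return float(np.hypot(s[0], c[0]))


def classify_nonlinearity(
    e_n, v_n, threshold: float = DEFAULT_NOISE_THRESHOLD
) -> tuple[str, str]:
    """Label the elastic and viscous nonlinearity from the signs of e3, v3.

    Returns (elastic, viscous) in {strain-softening, strain-stiffening,
    linear} x {shear-thinning, shear-thickening, linear}; coefficients whose
    third-to-first harmonic ratio falls below ``threshold`` are classified as
    linear.
    """
    e_n = np.asarray(e_n, dtype=float)
    v_n = np.asarray(v_n, dtype=float)
    e1, e3 = e_n[0], e_n[2]
    v1, v3 = v_n[0], v_n[2]
    if e1 == 0 or abs(e3) / abs(e1) < threshold:
        elastic = "linear"
    else:
        elastic = "strain-stiffening" if e3 > 0 else "strain-softening"
    if v1 == 0 or abs(v3) / abs(v1) < threshold:
        viscous = "linear"
    else:
        viscous = "shear-thickening" if v3 > 0 else "shear-thinning"
    return elastic, viscous


def local_moduli(
    record: OscillationRecord, threshold: float = 0.03
) -> tuple[float, float]:
    """First-harmonic storage and loss moduli G', G'' at the probe.

    Valid in the linear regime; a record whose harmonic ratio exceeds
    ``threshold`` triggers a warning (the moduli returned are then the
    first-harmonic "large-amplitude" moduli).
    """
    res = chebyshev_coefficients(record, n_max=5)
    if res.harmonic_ratio > threshold:
        warnings.warn(
            f"record at {record.location} has harmonic ratio "
            f"{res.harmonic_ratio:.3g} > {threshold}; first-harmonic moduli "
            "reported for a nonlinear record",
            stacklevel=2,
        )
    return res.G_prime, res.G_doubleprime


@dataclass
class LissajousTrace:
    """One-period normalized Lissajous traces and ellipse-distance metrics."""

    strain: np.ndarray  # gamma / gamma_0
    rate: np.ndarray  # gdot / gdot_0
    stress: np.ndarray  # sigma / max|sigma|
    ellipse_residual_elastic: float  # RMS distance from best-fit ellipse, sigma-gamma
    ellipse_residual_viscous: float  # sigma-gdot


def _ellipse_residual(x: np.ndarray, y: np.ndarray) -> float:
    """RMS residual of the best-fit conic (algebraic ellipse fit), normalized.

    Fits a x^2 + b xy + c y^2 + d x + e y = 1 by linear least squares and
    returns the RMS of the algebraic residual.  Degenerate traces (lines)
    are handled by falling back to the line-fit residual.
    """
    A = np.column_stack([x**2, x * y, y**2, x, y])
    coef, res, rank, _ = np.linalg.lstsq(A, np.ones_like(x), rcond=None)
    pred = A @ coef
    rms = float(np.sqrt(np.mean((pred - 1.0) ** 2)))
    if rank < 5:  # degenerate (collinear) trace: a line is a perfect "ellipse"
        return 0.0
    return rms


def lissajous(record: OscillationRecord) -> LissajousTrace:
    """Normalized one-period Lissajous curves (transient must be discarded
    upstream).  The residuals measure departure from a perfect ellipse, the
    linear-regime signature."""
    spp = record.samples_per_period
    sl = slice(record.time.size - spp, record.time.size)
    g = record.strain[sl]
    r = record.rate[sl]
    s = record.stress[sl]
    g0 = np.max(np.abs(g)) or 1.0
    r0 = np.max(np.abs(r)) or 1.0
    s0 = np.max(np.abs(s)) or 1.0
    gn, rn, sn = g / g0, r / r0, s / s0
    return LissajousTrace(
        strain=gn,
        rate=rn,
        stress=sn,
        ellipse_residual_elastic=_ellipse_residual(gn, sn),
        ellipse_residual_viscous=_ellipse_residual(rn, sn),
    )


def record_from_series(
    t,
    rate,
    stress,
    omega0: float,
    discard_periods: int = 5,
    location=None,
    strain=None,
) -> OscillationRecord:
    """Build an analysis record from raw probe series.

    The local shear strain is accumulated by trapezoidal integration of the
    shear rate (Eulerian strain measure at a fixed grid point) unless given.
    The first ``discard_periods`` drive periods are dropped and the window is
    truncated to an integer number of periods.
    """
    t = np.asarray(t, dtype=float)
    rate = np.asarray(rate, dtype=float)
    stress = np.asarray(stress, dtype=float)
    if strain is None:
        strain = np.concatenate(
            [[0.0], np.cumsum(0.5 * (rate[1:] + rate[:-1]) * np.diff(t))]
        )
    else:
        strain = np.asarray(strain, dtype=float)
    dt = t[1] - t[0]
    period = 2.0 * np.pi / omega0
    spp = int(round(period / dt))
    if not np.isclose(spp * dt, period, rtol=1e-6):
        raise ValueError("sample spacing must divide the drive period")
    start = discard_periods * spp
    n_keep = ((t.size - start) // spp) * spp
    if n_keep < spp:
        raise ValueError("series too short after transient discard")
    sl = slice(start, start + n_keep)
    # remove the residual mean drift of the strain over the window so the
    # oscillatory component is analyzed
    strain_w = strain[sl] - np.mean(strain[sl])
    return OscillationRecord(
        time=t[sl],
        strain=strain_w,
        rate=rate[sl],
        stress=stress[sl],
        omega0=omega0,
        location=location,
    )


from .regimes import regime_sweep  # noqa: E402,F401  (solver-backed sweep)
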