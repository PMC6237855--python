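"""Cumulant nonlinear spectroscopy: lineshape, echo intensity, and S3PE.

Within the second-order cumulant (Gaussian fluctuation) approximation all
third-order observables follow from the lineshape function

    g(t) = int_0^t dt' int_0^t' dt'' C(t''),

with C the frequency-fluctuation autocorrelation in rad^2/fs^2.  The three
rephasing pathways of a two-level (0-1 coherence) Condon chromophore share
the envelope

    R(t1, t2, t3) = exp[-g(t1) + g(t2) - g(t3)
                        - g(t1+t2) - g(t2+t3) + g(t1+t2+t3)],

so the integrated echo intensity is

    I(t1, t2) = int_0^t3_max dt3 | 3 R(t1, t2, t3) |^2,

and the slope of the three-pulse echo (S3PE) is its short-time t1 slope,

    S(t2) = dI/dt1 |_{t1=0},    C(t2) = S(t2) / S(0).

The classical treatment keeps g real (no solvation-Stokes-shift imaginary
part), as appropriate for frequency statistics harvested from classical
trajectories; 1->2 anharmonic pathways and vibrational lifetime decay are
neglected, which leaves the S3PE shape governed purely by spectral
diffusion.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.integrate import cumulative_trapezoid, trapezoid

from ._units import C_CM_PER_FS
from .correlations import TCF, BiExpFit, fit_biexp

#: (2 pi c)^2 with c in cm/fs: converts cm^-2 to rad^2/fs^2.
CM2_TO_RAD2_PER_FS2 = (2.0 * np.pi * C_CM_PER_FS) ** 2


@dataclasses.dataclass
class LineshapeFn:
    """Cumulant lineshape g(t) on a uniform time grid (dimensionless phase).

    Off-grid evaluation uses a cubic spline: the echo's short-time t1 slope
    is a ~1e-4 relative variation of I, far below the ~h^2 error of linear
    interpolation on a typical 5 fs grid, so interpolation order matters.
    """

    t_grid: np.ndarray  # fs
    g: np.ndarray  # real under the classical treatment
    source_kind: str = "FTCF"

    def __post_init__(self):
        from scipy.interpolate import CubicSpline

        self._spline = (
            CubicSpline(self.t_grid, self.g) if len(self.t_grid) > 3 else None
        )

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        if self._spline is not None:
            return self._spline(t)
        return np.interp(t, self.t_grid, self.g)


@dataclasses.dataclass
class EchoSurface:
    """Integrated echo intensity I(t1, t2) >= 0 with truncation diagnostics."""

    t1_grid: np.ndarray  # fs
    t2_grid: np.ndarray  # fs
    I: np.ndarray  # shape (n_t1, n_t2)
    t3_max: float  # fs
    tail_ratio: float = 0.0  # max integrand tail / peak; > 1e-3 -> warning
    truncation_warning: bool = False

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("t1_fs\tt2_fs\tintensity\n")
            for i, t1 in enumerate(self.t1_grid):
                for j, t2 in enumerate(self.t2_grid):
                    fh.write(f"{t1:.6g}\t{t2:.6g}\t{self.I[i, j]:.10g}\n")


@dataclasses.dataclass
class S3PECurve:
    """Short-time echo slope S(t2) and its normalization C(t2) = S/S(0)."""

    t2_grid: np.ndarray  # fs
    S: np.ndarray
    C: np.ndarray
    fit: BiExpFit | None = None

    def write(self, path) -> None:
        import pandas as pd

        pd.DataFrame({"t2_fs": self.t2_grid, "S": self.S, "C": self.C}).to_csv(
            path, sep="\t", index=False
        )


def lineshape(ftcf: TCF, input_units: str = "cm-2") -> LineshapeFn:
    """Double time-integral of an unnormalized frequency TCF.

    ``input_units`` is "cm-2" for a TCF of wavenumber fluctuations (converted
    to angular units) or "rad2fs-2" if already converted.
    """
    if ftcf.normalized:
        raise ValueError("lineshape needs the unnormalized TCF (variance at lag 0)")
    lags = np.asarray(ftcf.lags, dtype=float)
    d = np.diff(lags)
    if len(d) == 0 or not np.allclose(d, d[0], rtol=1e-8, atol=1e-9):
        raise ValueError("lineshape requires a uniform lag grid")
    values = np.asarray(ftcf.values, dtype=float)
    if input_units == "cm-2":
        c = values * CM2_TO_RAD2_PER_FS2
    elif input_units == "rad2fs-2":
        c = values
    else:
        raise ValueError(f"unknown input_units {input_units!r}")
    inner = cumulative_trapezoid(c, lags, initial=0.0)
    g = cumulative_trapezoid(inner, lags, initial=0.0)
    return LineshapeFn(t_grid=lags, g=g, source_kind=ftcf.kind)


def echo_intensity(
    g: LineshapeFn,
    t1_grid,
    t2_grid,
    t3_max: float,
    dt3: float | None = None,
) -> EchoSurface:
    """Integrated echo intensity I(t1, t2) = int_0^t3_max |3 R|^2 dt3.

    Requires g defined on [0, max(t1) + max(t2) + t3_max].  The relative
    magnitude of the integrand at t3_max (worst case over the surface) is
    recorded; above 1e-3 a truncation warning is flagged on the surface.
    """
    t1_grid = np.asarray(t1_grid, dtype=float)
    t2_grid = np.asarray(t2_grid, dtype=float)
    if dt3 is None:
        dt3 = g.t_grid[1] - g.t_grid[0] if len(g.t_grid) > 1 else 2.0
    needed = t1_grid.max() + t2_grid.max() + t3_max
    if needed > g.t_grid[-1] + 1e-9:
        raise ValueError(
            f"lineshape covers only [0, {g.t_grid[-1]} fs] but the echo "
            f"needs g up to {needed} fs"
        )
    t3 = np.arange(0.0, t3_max + dt3 / 2, dt3)
    g1 = g(t1_grid)
    g3 = g(t3)
    I = np.empty((len(t1_grid), len(t2_grid)))
    tail_ratio = 0.0
    for j, t2 in enumerate(t2_grid):
        g2 = g(t2)
        g12 = g(t1_grid + t2)
        g23 = g(t2 + t3)
        g123 = g((t1_grid[:, None] + t2) + t3[None, :])
        expo = (
            -g1[:, None]
            + g2
            - g3[None, :]
            - g12[:, None]
            - g23[None, :]
            + g123
        )
        integrand = 9.0 * np.exp(2.0 * expo)  # |sum of 3 identical pathways|^2
        I[:, j] = trapezoid(integrand, dx=dt3, axis=1)
        peak = integrand.max()
        if peak > 0:
            tail_ratio = max(tail_ratio, float(integrand[:, -1].max() / peak))
    return EchoSurface(
        t1_grid=t1_grid,
        t2_grid=t2_grid,
        I=I,
        t3_max=t3_max,
        tail_ratio=tail_ratio,
        truncation_warning=tail_ratio > 1e-3,
    )


def s3pe(surface: EchoSurface, fit: bool = False, fit_t_max: float | None = None) -> S3PECurve:
    """Short-time t1 slope of the echo intensity and its normalization.

    Uses a one-sided second-order finite difference on the first three t1
    grid points (0, dt1, 2 dt1).
    """
    t1 = surface.t1_grid
    if len(t1) < 3:
        raise ValueError("need t1 grid points (0, dt1, 2 dt1) for the slope stencil")
    if abs(t1[0]) > 1e-12 or not np.isclose(t1[2] - t1[1], t1[1] - t1[0]):
        raise ValueError("t1 grid must start at 0 with uniform spacing")
    dt1 = t1[1] - t1[0]
    S = (-3.0 * surface.I[0] + 4.0 * surface.I[1] - surface.I[2]) / (2.0 * dt1)
    if S[0] == 0:
        raise ValueError("cannot normalize S3PE: S(0) = 0")
    C = S / S[0]
    curve = S3PECurve(t2_grid=surface.t2_grid, S=S, C=C)
    if fit:
        tcf_like = TCF(lags=surface.t2_grid, values=C, normalized=True, kind="S3PE")
        curve.fit = fit_biexp(tcf_like, t_max=fit_t_max)
    return curve


def s3pe_pipeline(
    ftcf: TCF,
    dt1: float = 2.0,
    t2_max: float = 4000.0,
    n_t2: int = 81,
    t3_max: float = 2000.0,
    dt3: float = 2.0,
    input_units: str = "cm-2",
    fit: bool = True,
    fit_t_max: float | None = None,
) -> S3PECurve:
    """Full cumulant pipeline: unnormalized TCF -> g(t) -> I(t1,t2) -> S3PE.

    The t2 grid spans [0, t2_max] with n_t2 points; the t1 stencil is
    (0, dt1, 2*dt1).  The input TCF must extend to 2*dt1 + t2_max + t3_max.
    """
    g = lineshape(ftcf, input_units=input_units)
    t1_grid = np.array([0.0, dt1, 2 * dt1])
    t2_grid = np.linspace(0.0, t2_max, n_t2)
    surface = echo_intensity(g, t1_grid, t2_grid, t3_max, dt3=dt3)
    return s3pe(surface, fit=fit, fit_t_max=fit_t_max)


def rescale_series_to_frequency(series: list, slope: float) -> list:
    """Convert observable fluctuation series to frequency units via a linear map.

    Divides each (mean-free) series by the fitted map slope (units of y per
    cm^-1) so that HB-strength or charge-transfer fluctuations can drive the
    same cumulant pipeline as frequency fluctuations.  NaNs are preserved.
    """
    if slope == 0:
        raise ValueError("map slope is zero; cannot rescale to frequency units")
    out = []
    for x in series:
        x = np.asarray(x, dtype=float)
        out.append(x / slope)
    return out
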