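"""Linear frequency maps between OH stretch frequency and HB observables.

Ordinary least-squares maps y = intercept + slope * omega for y in
{dE (kJ/mol), dCT (a.u.), LSRI (kJ/mol)}, their root-mean-square errors, and
2-D probability densities of (omega, y) scatter.

The module also ships reference coefficient sets for liquid water at ambient
conditions.  As printed in the source literature the map equations are
dimensionally ambiguous; the convention adopted here takes the
small-magnitude coefficient as the slope (per cm^-1) and the large one as
the intercept, signed so that the HB strength |dE|, the charge transfer dCT
and the LSRI all decrease toward zero with increasing frequency (a higher
OH stretch frequency means a weaker hydrogen bond).  The library primarily
*fits* maps from data; these constants are a documented interpretation, not
a recovered ground truth.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np
from scipy import stats


@dataclasses.dataclass
class LinearMap:
    """y = intercept + slope * omega with residual RMSE."""

    slope: float  # units of y per cm^-1
    intercept: float  # units of y
    rmse: float  # units of y
    n_samples: int
    y_kind: str  # one of {"dE", "dCT", "LSRI"} or free-form

    def __post_init__(self):
        if self.rmse < 0:
            raise ValueError("rmse must be non-negative")
        if self.n_samples < 2:
            raise ValueError("need at least 2 samples")

    def to_json(self, path=None) -> str:
        payload = dataclasses.asdict(self)
        payload["units"] = _UNITS.get(self.y_kind, "arbitrary")
        s = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s + "\n")
        return s

    @classmethod
    def from_json(cls, path) -> "LinearMap":
        with open(path) as fh:
            d = json.load(fh)
        d.pop("units", None)
        return cls(**d)


_UNITS = {"dE": "kJ/mol", "dCT": "a.u.", "LSRI": "kJ/mol"}

#: Reference maps (coefficient interpretation documented in the module docstring).
DE_MAP_REFERENCE = LinearMap(slope=0.0392, intercept=-150.6, rmse=7.27,
                             n_samples=2, y_kind="dE")
DCT_MAP_REFERENCE = LinearMap(slope=-0.0000221, intercept=0.086, rmse=0.004,
                              n_samples=2, y_kind="dCT")
LSRI_MAP_REFERENCE = LinearMap(slope=-0.01755, intercept=72.34, rmse=0.0,
                               n_samples=2, y_kind="LSRI")


@dataclasses.dataclass
class Density2D:
    """Normalized 2-D probability density on a rectangular grid.

    Samples outside the edges are clipped into the boundary bins (open
    boundary convention) and their count reported in ``n_clipped``.
    """

    x_edges: np.ndarray  # cm^-1
    y_edges: np.ndarray
    P: np.ndarray  # probability density per cell
    n_clipped: int = 0

    def integral(self) -> float:
        dx = np.diff(self.x_edges)
        dy = np.diff(self.y_edges)
        return float(np.sum(self.P * np.outer(dx, dy)))


def fit_linear(omega, y, y_kind: str = "dE") -> LinearMap:
    """Ordinary least-squares fit of y on omega with RMSE of the residuals."""
    omega = np.asarray(omega, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(omega) & np.isfinite(y)
    omega, y = omega[ok], y[ok]
    if len(omega) < 2:
        raise ValueError("need at least 2 finite samples")
    if np.ptp(omega) == 0:
        raise ValueError("degenerate fit: all omega values are equal")
    res = stats.linregress(omega, y)
    resid = y - (res.intercept + res.slope * omega)
    rmse = float(np.sqrt(np.mean(resid**2)))
    return LinearMap(
        slope=float(res.slope),
        intercept=float(res.intercept),
        rmse=rmse,
        n_samples=len(omega),
        y_kind=y_kind,
    )


def predict(linmap: LinearMap, omega):
    """Evaluate y = intercept + slope * omega."""
    return linmap.intercept + linmap.slope * np.asarray(omega, dtype=float)


def density2d(omega, y, x_edges, y_edges) -> Density2D:
    """Normalized 2-D histogram density of (omega, y) samples."""
    omega = np.asarray(omega, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(omega) & np.isfinite(y)
    omega, y = omega[ok], y[ok]
    if len(omega) == 0:
        raise ValueError("no samples")
    x_edges = np.asarray(x_edges, dtype=float)
    y_edges = np.asarray(y_edges, dtype=float)
    out_x = (omega < x_edges[0]) | (omega > x_edges[-1])
    out_y = (y < y_edges[0]) | (y > y_edges[-1])
    n_clipped = int(np.sum(out_x | out_y))
    xc = np.clip(omega, x_edges[0], x_edges[-1])
    yc = np.clip(y, y_edges[0], y_edges[-1])
    H, _, _ = np.histogram2d(xc, yc, bins=[x_edges, y_edges])
    area = np.outer(np.diff(x_edges), np.diff(y_edges))
    P = H / (H.sum() * area)
    return Density2D(x_edges=x_edges, y_edges=y_edges, P=P, n_clipped=n_clipped)


def default_frequency_edges(window_cm=(2800.0, 4000.0), step_cm: float = 5.0):
    """Default frequency bin edges: 5 cm^-1 over the configured window."""
    lo, hi = window_cm
    return np.arange(lo, hi + step_cm / 2, step_cm)
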