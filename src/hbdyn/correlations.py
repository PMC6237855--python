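"""Time-correlation engine and bi-exponential relaxation fitting.

Computes lag-resolved autocorrelation functions pooled over entities (OH
modes, HB pairs or molecules) and time origins:

    C(t) = < x(0) x(t) >,

with per-entity mean removal by default so the functions measure
fluctuations and decay to zero.  Entities with gaps (a pair that breaks its
hydrogen bond) contribute only contiguous bonded segments; absent frames are
never zero-filled.  Specialized estimators cover the continuous hydrogen-bond
survival probability S_HB(t), the HB-number correlation

    C_N(t) = < dn(0) dn(t) > / < dn^2 >,    dn = n - <n>,

the bi-exponential relaxation model

    f(t) = a0 exp(-t/tau0) + (1 - a0) exp(-t/tau1),

and block-averaged standard errors from contiguous sub-trajectories.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import fft as sfft
from scipy.optimize import least_squares


@dataclasses.dataclass
class TCF:
    """A lag-indexed correlation curve.

    lags start at zero with uniform spacing (fs); ``stderr`` holds per-lag
    block-average standard errors when computed.
    """

    lags: np.ndarray  # fs
    values: np.ndarray
    stderr: np.ndarray | None = None
    normalized: bool = False
    kind: str = "TCF"

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"lag_fs": self.lags, "value": self.values})
        if self.stderr is not None:
            df["stderr"] = self.stderr
        return df

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclasses.dataclass
class BiExpFit:
    """Bi-exponential fit result; time constants in ps, tau0 <= tau1."""

    a0: float
    tau0: float  # ps
    tau1: float  # ps
    covariance: np.ndarray | None = None  # 3x3 over (a0, tau0, tau1)
    tau1_stderr: float | None = None  # ps, block-derived

    def __call__(self, t_fs):
        t = np.asarray(t_fs, dtype=float) / 1000.0
        return self.a0 * np.exp(-t / self.tau0) + (1 - self.a0) * np.exp(-t / self.tau1)


def biexp(t_fs, a0: float, tau0_ps: float, tau1_ps: float):
    """Evaluate the bi-exponential relaxation model on a time grid in fs."""
    t = np.asarray(t_fs, dtype=float)
    return a0 * np.exp(-t / (tau0_ps * 1000.0)) + (1 - a0) * np.exp(
        -t / (tau1_ps * 1000.0)
    )


def _contiguous_runs(mask: np.ndarray):
    """Yield (start, stop) of maximal True runs in a boolean mask."""
    idx = np.flatnonzero(np.diff(np.concatenate(([False], mask, [False])).astype(int)))
    for s, e in zip(idx[::2], idx[1::2]):
        yield int(s), int(e)


def _autocorr_sums(x: np.ndarray, k_max: int):
    """Linear autocorrelation sums c[k] = sum_j x_j x_{j+k} via FFT."""
    n = len(x)
    k = min(k_max, n - 1)
    nfft = sfft.next_fast_len(n + k)
    fx = sfft.rfft(x, nfft)
    c = sfft.irfft(fx * np.conj(fx), nfft)[: k + 1]
    counts = n - np.arange(k + 1)
    return c, counts


def tcf(
    series: list,
    dt: float,
    max_lag: float,
    normalize: bool = True,
    center: bool = True,
    kind: str = "TCF",
) -> TCF:
    """Pooled autocorrelation over entities and time origins.

    ``series`` is a list of equally-sampled 1-D arrays (NaN marks absent
    frames; only contiguous finite segments contribute).  ``center`` selects
    the fluctuation reference: True removes each entity's own mean over its
    present frames (appropriate when entities have genuinely different
    baselines, e.g. HB pairs of different strength); ``"global"`` removes the
    pooled mean over all entities (appropriate for identically distributed
    entities such as OH-mode frequencies, where per-entity means estimated
    from a record only ~20 correlation times long would bias the tail of the
    correlation downward); False removes nothing.  All (entity, origin)
    products at a lag are pooled before averaging.
    """
    k_max = int(round(max_lag / dt))
    n_frames = max(len(np.asarray(x)) for x in series)
    if k_max >= n_frames:
        raise ValueError(
            f"max_lag ({max_lag} fs = {k_max} frames) must be shorter than "
            f"the series length ({n_frames} frames)"
        )
    num = np.zeros(k_max + 1)
    cnt = np.zeros(k_max + 1)
    if center == "global":
        pooled = np.concatenate([np.asarray(x, dtype=float) for x in series])
        global_mean = np.nanmean(pooled)
    for x in series:
        x = np.asarray(x, dtype=float)
        mask = np.isfinite(x)
        if not mask.any():
            continue
        if center == "global":
            mean = global_mean
        elif center:
            mean = x[mask].mean()
        else:
            mean = 0.0
        for s, e in _contiguous_runs(mask):
            y = x[s:e] - mean
            c, counts = _autocorr_sums(y, k_max)
            num[: len(c)] += c
            cnt[: len(c)] += counts
    if cnt[0] == 0:
        raise ValueError("no finite data in any series")
    values = np.full(k_max + 1, np.nan)
    nz = cnt > 0
    values[nz] = num[nz] / cnt[nz]
    if normalize:
        if values[0] == 0:
            raise ValueError("cannot normalize: zero variance at lag 0")
        values = values / values[0]
    return TCF(
        lags=np.arange(k_max + 1) * dt,
        values=values,
        normalized=normalize,
        kind=kind,
    )


def _bond_presence(records_per_frame: list) -> dict:
    """Boolean presence series per (donor_mol, donor_H, acceptor_mol)."""
    n = len(records_per_frame)
    presence: dict = {}
    for f, frame in enumerate(records_per_frame):
        for r in frame:
            key = (r.donor_mol, r.donor_H, r.acceptor_mol)
            if key not in presence:
                presence[key] = np.zeros(n, dtype=bool)
            presence[key][f] = True
    return presence


def s_hb(
    records_per_frame: list,
    dt: float,
    max_lag: float,
    allowance: int = 0,
) -> TCF:
    """Continuous hydrogen-bond survival probability S_HB(t).

    S_HB(t) is the probability that a bond present at a time origin remains
    intact at every frame through t, averaged over origins and pairs.  Only
    origins whose observation window fits inside the trajectory are counted
    at each lag (standard censoring), so a permanently intact bond gives
    S_HB = 1 at every lag.  ``allowance`` (frames) lets transient breaks of
    at most that length count as intact; the default 0 is the strictly
    continuous definition.
    """
    k_max = int(round(max_lag / dt))
    n_frames = len(records_per_frame)
    if k_max >= n_frames:
        raise ValueError("max_lag must be shorter than the trajectory")
    presence = _bond_presence(records_per_frame)
    if not presence:
        raise ValueError("no HBs present in any frame")
    num = np.zeros(k_max + 1)
    den = np.zeros(k_max + 1)
    ks = np.arange(k_max + 1)
    for mask in presence.values():
        if allowance > 0:
            mask = mask.copy()
            for s, e in _contiguous_runs(~mask):
                if e - s <= allowance and s > 0 and e < n_frames:
                    mask[s:e] = True
        bonded_idx = np.flatnonzero(mask)
        # eligible origins at lag k: bonded frames with index < n_frames - k
        den += np.searchsorted(bonded_idx, n_frames - ks)
        for s, e in _contiguous_runs(mask):
            run = e - s
            k = min(run - 1, k_max)
            num[: k + 1] += run - np.arange(k + 1)
    values = np.where(den > 0, num / np.maximum(den, 1), np.nan)
    return TCF(
        lags=np.arange(k_max + 1) * dt,
        values=values,
        normalized=True,
        kind="S_HB",
    )


def hb_counts(records_per_frame: list, n_molecules: int) -> np.ndarray:
    """Per-molecule HB count n(t) (donated + accepted), shape (n_mol, n_frames)."""
    n_frames = len(records_per_frame)
    n = np.zeros((n_molecules, n_frames))
    for f, frame in enumerate(records_per_frame):
        for r in frame:
            n[r.donor_mol, f] += 1
            n[r.acceptor_mol, f] += 1
    return n


def n_hb(
    records_per_frame: list,
    n_molecules: int,
    dt: float,
    max_lag: float,
) -> TCF:
    """Normalized HB-number correlation <dn(0) dn(t)> / <dn^2>.

    dn is measured against the global ensemble mean <n> over all molecules
    and frames.
    """
    counts = hb_counts(records_per_frame, n_molecules)
    dn = counts - counts.mean()
    if np.allclose(dn, 0.0):
        raise ValueError("zero variance: every molecule has a constant HB count")
    out = tcf(list(dn), dt, max_lag, normalize=True, center=False, kind="N_HB")
    return out


_BIEXP_STARTS = [
    (a0, t0, t1)
    for a0 in (0.3, 0.7)
    for t0 in (0.02, 0.05, 0.1)  # ps
    for t1 in (0.5, 1.0, 2.0)  # ps
]


def default_fit_window(max_lag_fs: float) -> float:
    """Default upper fit limit: 4 ps or 40% of the max lag, whichever is smaller."""
    return min(4000.0, 0.4 * max_lag_fs)


def fit_biexp(
    curve: TCF,
    t_min: float = 0.0,
    t_max: float | None = None,
) -> BiExpFit:
    """Least-squares bi-exponential fit of a normalized correlation curve.

    Multistart Levenberg-Marquardt (trust-region) over a grid of initial
    (a0, tau0, tau1); bounds a0 in [0, 1], tau > 0; the returned constants
    are ordered tau0 <= tau1.
    """
    if not curve.normalized:
        raise ValueError("fit_biexp expects a normalized curve (values[0] = 1)")
    if t_max is None:
        t_max = default_fit_window(curve.lags[-1])
    sel = (curve.lags >= t_min) & (curve.lags <= t_max) & np.isfinite(curve.values)
    t = curve.lags[sel]
    y = curve.values[sel]
    if len(t) < 3:
        raise ValueError(f"fit window contains only {len(t)} points (need >= 3)")

    def resid(p):
        return biexp(t, *p) - y

    best = None
    lb = [0.0, 1e-6, 1e-6]
    ub = [1.0, np.inf, np.inf]
    for start in _BIEXP_STARTS:
        try:
            res = least_squares(
                resid, start, bounds=(lb, ub),
                ftol=1e-14, xtol=1e-14, gtol=1e-14, max_nfev=2000,
            )
        except Exception:
            continue
        if res.success and (best is None or res.cost < best.cost):
            best = res
    if best is None:
        raise RuntimeError(
            "bi-exponential fit failed to converge from all "
            f"{len(_BIEXP_STARTS)} starts (window {t_min}-{t_max} fs, "
            f"{len(t)} points)"
        )
    a0, tau0, tau1 = best.x
    cov = None
    try:
        jtj = best.jac.T @ best.jac
        dof = max(len(t) - 3, 1)
        cov = np.linalg.inv(jtj) * 2 * best.cost / dof
    except np.linalg.LinAlgError:
        pass
    if tau0 > tau1:
        a0, tau0, tau1 = 1.0 - a0, tau1, tau0
        if cov is not None:
            perm = np.array([[-1, 0, 0], [0, 0, 1], [0, 1, 0]], dtype=float)
            cov = perm @ cov @ perm.T
    return BiExpFit(a0=float(a0), tau0=float(tau0), tau1=float(tau1), covariance=cov)


def fit_exponential(
    curve: TCF,
    t_min: float = 0.0,
    t_max: float | None = None,
) -> tuple:
    """Fit A exp(-t/tau) to a correlation curve; returns (tau_ps, A)."""
    if t_max is None:
        t_max = default_fit_window(curve.lags[-1])
    sel = (curve.lags >= t_min) & (curve.lags <= t_max) & np.isfinite(curve.values)
    t = curve.lags[sel]
    y = curve.values[sel]
    if len(t) < 2:
        raise ValueError("fit window contains fewer than 2 points")

    def resid(p):
        A, tau_ps = p
        return A * np.exp(-t / (tau_ps * 1000.0)) - y

    best = None
    for tau0 in (0.2, 0.5, 1.0, 2.0):
        res = least_squares(
            resid, [1.0, tau0], bounds=([0.0, 1e-6], [np.inf, np.inf]),
            ftol=1e-14, xtol=1e-14, gtol=1e-14, max_nfev=2000,
        )
        if res.success and (best is None or res.cost < best.cost):
            best = res
    if best is None:
        raise RuntimeError("exponential fit failed to converge")
    A, tau_ps = best.x
    return float(tau_ps), float(A)


def block_errors(
    data,
    n_frames: int,
    estimator,
    n_blocks: int = 3,
    slicer=None,
):
    """Block-averaged standard error of a scalar estimator.

    The time axis is split into ``n_blocks`` contiguous segments; the
    estimator is applied to each and the standard error of the block
    estimates is returned as (mean, stderr, block_values).  ``slicer(data,
    lo, hi)`` extracts one time block; the default slices every entity array
    in a list.
    """
    if n_blocks < 2:
        raise ValueError("need at least 2 blocks")
    if slicer is None:
        slicer = lambda d, lo, hi: [np.asarray(x)[lo:hi] for x in d]
    edges = np.linspace(0, n_frames, n_blocks + 1).astype(int)
    vals = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        vals.append(float(estimator(slicer(data, lo, hi))))
    vals = np.asarray(vals)
    stderr = float(vals.std(ddof=1) / np.sqrt(n_blocks))
    return float(vals.mean()), stderr, vals


def frame_slicer(records_per_frame, lo, hi):
    """Block slicer for per-frame record lists (S_HB / N_HB estimators)."""
    return records_per_frame[lo:hi]
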