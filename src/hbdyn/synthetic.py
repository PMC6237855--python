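"""Seeded synthetic generators emulating the statistics the analysis assumes.

Every statistical structure the pipeline measures can be planted exactly:

* Gaussian frequency processes with a bi-exponential autocorrelation,
  realized as the sum of two independent Ornstein-Uhlenbeck processes with
  variances a0*Delta^2 and (1-a0)*Delta^2 — the target autocorrelation is
  exact, not approximate;
* linearly coupled HB observables (dE, dCT, LSRI) with Gaussian scatter of
  configurable RMSE around the planted frequency maps;
* two-state Markov hydrogen bonds using the exact discrete skeleton of the
  continuous-time make/break chain, so indicator autocorrelations decay as
  exp(-(k_break + k_form) t) and continuous survival as
  ~exp(-k_break t);
* a single-molecule oscillator trajectory with analytic velocities whose
  instantaneous frequency follows any supplied omega(t), for closed-loop
  wavelet tests.

All generators are deterministic given (spec, seed).
"""

from __future__ import annotations

import dataclasses

import numpy as np

from ._units import wavenumber_to_angular
from .eda_interface import PairSeries
from .traj_io import HBRecord, Trajectory


@dataclasses.dataclass(frozen=True)
class KuboProcessSpec:
    """Bi-exponential Gaussian frequency process specification.

    Target autocorrelation: Delta^2 [a0 e^{-t/tau0} + (1-a0) e^{-t/tau1}],
    stationary mean ``mean_cm``.
    """

    a0: float = 0.6
    tau0_ps: float = 0.1
    tau1_ps: float = 1.02
    delta_cm: float = 100.0  # sqrt(variance), cm^-1
    mean_cm: float = 3400.0
    dt_fs: float = 5.0
    n_frames: int = 5000
    n_modes: int = 128

    def __post_init__(self):
        if not (0.0 <= self.a0 <= 1.0):
            raise ValueError("a0 must lie in [0, 1]")
        if self.tau0_ps <= 0 or self.tau1_ps <= 0:
            raise ValueError("time constants must be positive")
        if self.delta_cm <= 0:
            raise ValueError("delta_cm must be positive")

    def target_acf(self, t_fs):
        """Planted autocorrelation (cm^-2) at lags t_fs."""
        t = np.asarray(t_fs, dtype=float)
        return self.delta_cm**2 * (
            self.a0 * np.exp(-t / (self.tau0_ps * 1000.0))
            + (1 - self.a0) * np.exp(-t / (self.tau1_ps * 1000.0))
        )


@dataclasses.dataclass(frozen=True)
class CouplingSpec:
    """Linear frequency couplings and residual scatter for dE/dCT/LSRI."""

    de_slope: float = 0.0392  # kJ/mol per cm^-1
    de_intercept: float = -150.6  # kJ/mol
    de_sigma: float = 7.27  # kJ/mol
    ct_slope: float = -0.0000221  # a.u. per cm^-1
    ct_intercept: float = 0.086  # a.u.
    ct_sigma: float = 0.004  # a.u.
    lsri_slope: float = -0.01755  # kJ/mol per cm^-1
    lsri_intercept: float = 72.34  # kJ/mol
    lsri_sigma: float = 5.0  # kJ/mol

    def __post_init__(self):
        for s in (self.de_sigma, self.ct_sigma, self.lsri_sigma):
            if s < 0:
                raise ValueError("residual sigma must be non-negative")


@dataclasses.dataclass(frozen=True)
class MarkovHBSpec:
    """Independent two-state (bonded/unbonded) Markov hydrogen bonds."""

    k_break: float  # 1/ps
    k_form: float  # 1/ps
    n_pairs: int = 128
    dt_fs: float = 5.0
    n_frames: int = 5000

    def __post_init__(self):
        if self.k_break <= 0 or self.k_form <= 0:
            raise ValueError("rates must be positive")

    @property
    def bonded_fraction(self) -> float:
        return self.k_form / (self.k_form + self.k_break)

    @property
    def relaxation_ps(self) -> float:
        return 1.0 / (self.k_break + self.k_form)


def gen_frequency_process(spec: KuboProcessSpec, seed: int) -> tuple:
    """Stationary Gaussian frequency tracks with exact bi-exponential ACF.

    Returns (t_grid_fs, omega) with omega of shape (n_modes, n_frames) in
    cm^-1.
    """
    rng = np.random.default_rng(seed)
    n, m = spec.n_frames, spec.n_modes
    omega = np.full((m, n), spec.mean_cm)
    for amp, tau_ps in ((spec.a0, spec.tau0_ps), (1 - spec.a0, spec.tau1_ps)):
        var = amp * spec.delta_cm**2
        if var == 0:
            continue
        tau_fs = tau_ps * 1000.0
        rho = np.exp(-spec.dt_fs / tau_fs)
        innov_sd = np.sqrt(var * (1 - rho**2))
        x = np.empty((m, n))
        x[:, 0] = rng.normal(0.0, np.sqrt(var), m)
        noise = rng.normal(0.0, innov_sd, (m, n - 1))
        for k in range(1, n):
            x[:, k] = rho * x[:, k - 1] + noise[:, k - 1]
        omega += x
    t_grid = np.arange(n) * spec.dt_fs
    return t_grid, omega


def gen_coupled_observables(
    t_grid: np.ndarray,
    omega: np.ndarray,
    coupling: CouplingSpec,
    seed: int,
) -> tuple:
    """Linearly coupled dE/dCT pair series and LSRI samples from omega tracks.

    Each frequency track i is emitted as the donor-H1 bond of molecule i to a
    distinct phantom acceptor (n_modes + i), so the pair table is structurally
    valid without imposing a closed HB graph.  Returns (pairs, lsri) where
    ``pairs`` is a list of PairSeries and ``lsri`` an array like omega.
    """
    rng = np.random.default_rng(seed)
    omega = np.atleast_2d(omega)
    m, n = omega.shape
    dE = coupling.de_intercept + coupling.de_slope * omega
    dCT = coupling.ct_intercept + coupling.ct_slope * omega
    lsri_vals = coupling.lsri_intercept + coupling.lsri_slope * omega
    if coupling.de_sigma > 0:
        dE = dE + rng.normal(0.0, coupling.de_sigma, (m, n))
    if coupling.ct_sigma > 0:
        dCT = dCT + rng.normal(0.0, coupling.ct_sigma, (m, n))
    if coupling.lsri_sigma > 0:
        lsri_vals = lsri_vals + rng.normal(0.0, coupling.lsri_sigma, (m, n))
    pairs = [
        PairSeries(
            donor_mol=i,
            donor_H=1,
            acceptor_mol=m + i,
            t_grid=np.asarray(t_grid, dtype=float),
            dE=dE[i],
            dCT=dCT[i],
        )
        for i in range(m)
    ]
    return pairs, lsri_vals


def gen_markov_states(spec: MarkovHBSpec, seed: int) -> np.ndarray:
    """Boolean bonded-state matrix (n_pairs, n_frames), exact CT skeleton."""
    rng = np.random.default_rng(seed)
    r = spec.k_break + spec.k_form  # 1/ps
    dt_ps = spec.dt_fs / 1000.0
    decay = np.exp(-r * dt_ps)
    pi_b = spec.bonded_fraction
    p_break = (1 - pi_b) * (1 - decay)  # P(bonded -> unbonded) per step
    p_form = pi_b * (1 - decay)  # P(unbonded -> bonded) per step
    states = np.empty((spec.n_pairs, spec.n_frames), dtype=bool)
    states[:, 0] = rng.random(spec.n_pairs) < pi_b
    u = rng.random((spec.n_pairs, spec.n_frames - 1))
    for k in range(1, spec.n_frames):
        prev = states[:, k - 1]
        states[:, k] = np.where(prev, u[:, k - 1] >= p_break, u[:, k - 1] < p_form)
    return states


def gen_markov_hbonds(spec: MarkovHBSpec, seed: int) -> list:
    """Frame-resolved HBRecord lists for independent Markov bonds.

    Pair i bonds donor molecule 2i (H1) to acceptor molecule 2i+1, so each
    molecule participates in exactly one potential bond and per-molecule HB
    counts are independent two-state processes.  Geometric fields are
    nominal placeholders (2.8 Å, 10 deg).
    """
    states = gen_markov_states(spec, seed)
    records = []
    for f in range(spec.n_frames):
        bonded = np.where(states[:, f])[0]
        records.append(
            [HBRecord(f, int(2 * i), 1, int(2 * i + 1), 2.8, 10.0) for i in bonded]
        )
    return records


def gen_oscillator_trajectory(
    t_grid: np.ndarray,
    omega_cm: np.ndarray,
    r0: float = 0.96,
    amplitude: float = 0.05,
    box_edge: float = 20.0,
    phase0: float = 0.0,
) -> Trajectory:
    """One-molecule trajectory whose first OH bond oscillates at omega(t).

    r(t) = r0 + A cos(phi(t)) with phi' = 2 pi c omega(t); velocities are
    analytic, so the extracted bond momentum is exactly mu dr/dt.  The second
    OH bond is rigid (degenerate signal for the wavelet stage).
    """
    t_grid = np.asarray(t_grid, dtype=float)
    omega_rad = wavenumber_to_angular(np.asarray(omega_cm, dtype=float))
    from scipy.integrate import cumulative_trapezoid

    phi = phase0 + cumulative_trapezoid(omega_rad, t_grid, initial=0.0)
    r = r0 + amplitude * np.cos(phi)
    rdot = -amplitude * np.sin(phi) * omega_rad
    n = len(t_grid)
    pos = np.zeros((n, 3, 3))
    vel = np.zeros((n, 3, 3))
    center = box_edge / 2.0
    pos[:, 0, :] = center  # O fixed
    pos[:, 1, :] = center
    pos[:, 1, 0] += r  # H1 along x
    vel[:, 1, 0] = rdot
    pos[:, 2, :] = center
    pos[:, 2, 1] += r0  # H2 rigid along y
    dt = t_grid[1] - t_grid[0] if n > 1 else 1.0
    return Trajectory(
        symbols=["O", "H", "H"],
        positions=pos,
        velocities=vel,
        box_edge=box_edge,
        dt=dt,
    )
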