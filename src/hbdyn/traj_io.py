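"""Extended-XYZ trajectory I/O, OH-mode extraction and hydrogen-bond geometry.

Provides the geometric substrate for all downstream analysis: per-frame atomic
positions/velocities of a cubic-box water system, the bond-length/bond-momentum
series of every OH oscillator, and geometric hydrogen-bond assignments.

Conventions: coordinates in Å, time in fs, masses in amu, 0-based molecule and
atom indices, molecules stored contiguously as O,H,H.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from ._units import DEFAULT_MASSES


class TrajectoryParseError(ValueError):
    """Raised when a trajectory file is malformed."""


class CapabilityError(RuntimeError):
    """Raised when an operation needs data (e.g. velocities) the input lacks."""


def minimum_image(vec: np.ndarray, box_edge: float) -> np.ndarray:
    """Map displacement vector(s) to the minimum image in a cubic box."""
    vec = np.asarray(vec, dtype=float)
    return vec - box_edge * np.round(vec / box_edge)


@dataclasses.dataclass
class Trajectory:
    """A fixed-topology water trajectory in a cubic periodic box.

    Attributes
    ----------
    symbols : list of str
        Element label per atom; validated to repeat O,H,H per molecule.
    positions : ndarray, shape (n_frames, n_atoms, 3)
        Cartesian positions in Å.
    velocities : ndarray or None, shape (n_frames, n_atoms, 3)
        Velocities in Å/fs; optional.
    box_edge : float
        Cubic box length in Å.
    dt : float
        Frame spacing in fs.
    """

    symbols: list
    positions: np.ndarray
    velocities: np.ndarray | None
    box_edge: float
    dt: float

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise ValueError("positions must have shape (n_frames, n_atoms, 3)")
        if self.velocities is not None:
            self.velocities = np.asarray(self.velocities, dtype=float)
            if self.velocities.shape != self.positions.shape:
                raise ValueError("velocities shape must match positions")
        if self.box_edge <= 0:
            raise ValueError("box_edge must be positive")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        n_atoms = self.positions.shape[1]
        if len(self.symbols) != n_atoms:
            raise ValueError("symbols length must equal atom count")
        if n_atoms % 3 != 0:
            raise ValueError(f"atom count {n_atoms} is not a multiple of 3")
        for m in range(n_atoms // 3):
            trio = tuple(self.symbols[3 * m : 3 * m + 3])
            if trio != ("O", "H", "H"):
                raise ValueError(
                    f"molecule {m} is {trio}, expected ('O', 'H', 'H'); "
                    "molecules must be contiguous O,H,H"
                )

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.positions.shape[1]

    @property
    def n_molecules(self) -> int:
        return self.n_atoms // 3

    @property
    def has_velocities(self) -> bool:
        return self.velocities is not None


@dataclasses.dataclass
class OHModeSeries:
    """Bond length and relative-momentum series of one OH oscillator.

    ``bond_momentum`` is the reduced-mass relative momentum projected on the
    instantaneous OH unit vector: p(t) = mu * (v_H - v_O) . u_OH, in amu·Å/fs.
    """

    mode_id: tuple  # (molecule index, H index 1|2)
    bond_length: np.ndarray  # Å
    bond_momentum: np.ndarray  # amu·Å/fs
    reduced_mass: float  # amu
    dt: float  # fs


class HBRecord(NamedTuple):
    """One donor-H -> acceptor-O hydrogen bond at one frame."""

    frame: int
    donor_mol: int
    donor_H: int
    acceptor_mol: int
    r_OO: float  # Å
    angle: float  # H-O...O angle at the donor oxygen, degrees


@dataclasses.dataclass(frozen=True)
class HBCriterion:
    """Geometric hydrogen-bond criterion (standard liquid-water values)."""

    r_OO_max: float = 3.5  # Å
    angle_max: float = 30.0  # degrees


def read_trajectory(path, dt: float, box_edge: float) -> Trajectory:
    """Read an extended-XYZ trajectory (frame blocks of natoms/comment/atoms).

    Atom lines are ``El x y z`` or ``El x y z vx vy vz``; all frames must have
    the same atom count, ordering and velocity presence.  H positions are
    unwrapped to the minimum image relative to their molecule's O.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    pos_frames, vel_frames = [], []
    symbols0 = None
    has_vel = None
    i, frame_idx = 0, 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            natoms = int(lines[i].split()[0])
        except ValueError as exc:
            raise TrajectoryParseError(
                f"frame {frame_idx}: expected atom count, got {lines[i]!r}"
            ) from exc
        if i + 1 + natoms >= len(lines) + 1 and i + 2 + natoms > len(lines):
            raise TrajectoryParseError(
                f"frame {frame_idx}: file truncated ({natoms} atoms declared)"
            )
        symbols, pos, vel = [], [], []
        for j in range(natoms):
            k = i + 2 + j
            if k >= len(lines):
                raise TrajectoryParseError(
                    f"frame {frame_idx}: atom count mismatch "
                    f"(declared {natoms}, file ended after {j})"
                )
            tokens = lines[k].split()
            if len(tokens) not in (4, 7):
                raise TrajectoryParseError(
                    f"frame {frame_idx}: atom line {j} has {len(tokens)} "
                    f"fields, expected 4 or 7: {lines[k]!r}"
                )
            symbols.append(tokens[0])
            pos.append([float(t) for t in tokens[1:4]])
            if len(tokens) == 7:
                vel.append([float(t) for t in tokens[4:7]])
        frame_has_vel = len(vel) == natoms
        if len(vel) not in (0, natoms):
            raise TrajectoryParseError(
                f"frame {frame_idx}: mixed velocity presence within frame"
            )
        if symbols0 is None:
            symbols0, has_vel = symbols, frame_has_vel
        else:
            if symbols != symbols0:
                raise TrajectoryParseError(
                    f"frame {frame_idx}: atom labels/ordering differ from frame 0"
                )
            if frame_has_vel != has_vel:
                raise TrajectoryParseError(
                    f"frame {frame_idx}: velocity presence differs from frame 0"
                )
        pos_frames.append(pos)
        if frame_has_vel:
            vel_frames.append(vel)
        i += 2 + natoms
        frame_idx += 1
    if not pos_frames:
        raise TrajectoryParseError(f"{path}: no frames found")
    positions = np.array(pos_frames, dtype=float)
    velocities = np.array(vel_frames, dtype=float) if has_vel else None
    traj = Trajectory(symbols0, positions, velocities, box_edge, dt)
    # unwrap H positions relative to their O so intra-molecular vectors are
    # continuous across the periodic boundary
    for m in range(traj.n_molecules):
        o = traj.positions[:, 3 * m, :]
        for h in (1, 2):
            d = traj.positions[:, 3 * m + h, :] - o
            traj.positions[:, 3 * m + h, :] = o + minimum_image(d, box_edge)
    return traj


def write_trajectory(traj: Trajectory, path) -> None:
    """Write a Trajectory in the extended-XYZ dialect read by read_trajectory."""
    path = Path(path)
    with path.open("w") as fh:
        for f in range(traj.n_frames):
            fh.write(f"{traj.n_atoms}\n")
            fh.write(f"frame {f} box {traj.box_edge:.6f} dt {traj.dt:.6f}\n")
            for a in range(traj.n_atoms):
                x, y, z = traj.positions[f, a]
                line = f"{traj.symbols[a]} {x:.10f} {y:.10f} {z:.10f}"
                if traj.has_velocities:
                    vx, vy, vz = traj.velocities[f, a]
                    line += f" {vx:.10f} {vy:.10f} {vz:.10f}"
                fh.write(line + "\n")


def extract_oh_modes(traj: Trajectory, masses: dict | None = None) -> list:
    """Extract the 2 x n_molecules OH bond-length/momentum series.

    The momentum is the reduced-mass relative momentum mu * d(r_OH)/dt
    projected on the instantaneous minimum-image OH unit vector, so each
    series is the phase-space trajectory of a 1-D oscillator.
    """
    if not traj.has_velocities:
        raise CapabilityError(
            "traj_io: trajectory has no velocities; OH momenta unavailable"
        )
    masses = dict(DEFAULT_MASSES if masses is None else masses)
    mu = masses["O"] * masses["H"] / (masses["O"] + masses["H"])
    modes = []
    for m in range(traj.n_molecules):
        i_o = 3 * m
        for h in (1, 2):
            i_h = 3 * m + h
            d = minimum_image(
                traj.positions[:, i_h, :] - traj.positions[:, i_o, :],
                traj.box_edge,
            )
            r = np.linalg.norm(d, axis=1)
            if np.any(r <= 0):
                raise ValueError(f"degenerate OH bond in molecule {m}")
            u = d / r[:, None]
            v_rel = traj.velocities[:, i_h, :] - traj.velocities[:, i_o, :]
            p = mu * np.einsum("ij,ij->i", v_rel, u)
            modes.append(
                OHModeSeries(
                    mode_id=(m, h),
                    bond_length=r,
                    bond_momentum=p,
                    reduced_mass=mu,
                    dt=traj.dt,
                )
            )
    return modes


def assign_hbonds(
    traj: Trajectory, criterion: HBCriterion | None = None
) -> list:
    """Assign hydrogen bonds per frame with a geometric criterion.

    A donor H forms a bond to the acceptor O with the smallest O...O
    distance among those satisfying r_OO <= r_OO_max and H-O...O angle
    <= angle_max; ties break to the lower acceptor molecule index.  Returns
    one list of HBRecord per frame.
    """
    crit = criterion or HBCriterion()
    n_mol = traj.n_molecules
    o_idx = np.arange(n_mol) * 3
    records_per_frame = []
    for f in range(traj.n_frames):
        o_pos = traj.positions[f, o_idx, :]
        # pairwise minimum-image O-O displacements: d_oo[d, a] = O_a - O_d
        d_oo = minimum_image(o_pos[None, :, :] - o_pos[:, None, :], traj.box_edge)
        r_oo = np.linalg.norm(d_oo, axis=2)
        frame_records = []
        for d in range(n_mol):
            for h in (1, 2):
                hv = minimum_image(
                    traj.positions[f, 3 * d + h, :] - o_pos[d], traj.box_edge
                )
                hn = np.linalg.norm(hv)
                with np.errstate(invalid="ignore", divide="ignore"):
                    cosang = (d_oo[d] @ hv) / (r_oo[d] * hn)
                angles = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
                ok = (r_oo[d] <= crit.r_OO_max) & (angles <= crit.angle_max)
                ok[d] = False
                if not np.any(ok):
                    continue
                cand = np.where(ok)[0]
                a = cand[np.argmin(r_oo[d, cand])]  # first minimum = lowest index
                frame_records.append(
                    HBRecord(f, d, h, int(a), float(r_oo[d, a]), float(angles[a]))
                )
        records_per_frame.append(frame_records)
    return records_per_frame


def write_hbond_table(records_per_frame: Sequence, path) -> None:
    """Write per-frame HB records as TSV (frame, donor_mol, donor_H, acceptor_mol, r_OO, angle)."""
    rows = [r for frame in records_per_frame for r in frame]
    df = pd.DataFrame(rows, columns=HBRecord._fields)
    df.to_csv(path, sep="\t", index=False)


def read_hbond_table(path, n_frames: int | None = None) -> list:
    """Read a TSV HB table back into per-frame record lists."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if n_frames is None:
        n_frames = int(df["frame"].max()) + 1 if len(df) else 0
    records = [[] for _ in range(n_frames)]
    for row in df.itertuples(index=False):
        records[int(row.frame)].append(
            HBRecord(
                int(row.frame),
                int(row.donor_mol),
                int(row.donor_H),
                int(row.acceptor_mol),
                float(row.r_OO),
                float(row.angle),
            )
        )
    return records
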