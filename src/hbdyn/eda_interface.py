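"""Per-pair energy-decomposition data contract and the LSRI order parameter.

Consumes per-frame, per-hydrogen-bond donor->acceptor delocalization energies
dE (kJ/mol, negative = stabilizing) and charge transfer dCT (a.u.) as produced
by an upstream energy decomposition analysis, and computes the local solvent
reorganization index (LSRI)

    O_h = D_Acc + A_Don - D_Don - A_Acc

for each hydrogen-bonded pair: the net charge-transfer-induced energy flux
through the donated/accepted bonds of the donor (D) and acceptor (A)
molecules.  Sums run over ALL bonds of a molecule in the given role,
including the pair's own bond (``exclude_self_bond`` implements the
alternative reading); signed dE values enter directly, which fixes the sign
convention: an isolated single-bond dimer with dE = -20 kJ/mol has
O_h = 0 + 0 - (-20) - (-20) = +40 kJ/mol.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

PAIR_TABLE_COLUMNS = [
    "frame",
    "time_fs",
    "donor_mol",
    "donor_H",
    "acceptor_mol",
    "dE_kJmol",
    "dCT_au",
]


@dataclasses.dataclass
class PairSeries:
    """dE/dCT time series of one donor-H -> acceptor pair.

    Frames where the pair is not hydrogen-bonded are NaN (explicit absence,
    never zero).
    """

    donor_mol: int
    donor_H: int
    acceptor_mol: int
    t_grid: np.ndarray  # fs, uniform, shared across pairs
    dE: np.ndarray  # kJ/mol, NaN where absent
    dCT: np.ndarray  # a.u., NaN where absent

    @property
    def key(self) -> tuple:
        return (self.donor_mol, self.donor_H, self.acceptor_mol)

    @property
    def present(self) -> np.ndarray:
        return np.isfinite(self.dE)


@dataclasses.dataclass
class LSRISeries:
    """Per-pair LSRI time series with its four flux components."""

    pair: tuple  # (donor_mol, donor_H, acceptor_mol)
    t_grid: np.ndarray
    O_h: np.ndarray  # kJ/mol, NaN where pair absent
    components: np.ndarray  # shape (4, n): D_Acc, A_Don, D_Don, A_Acc


def read_pair_table(path) -> list:
    """Read a TSV pair table into PairSeries on a validated uniform time grid.

    Columns: frame, time_fs, donor_mol, donor_H, acceptor_mol, dE_kJmol,
    dCT_au.  Duplicate (frame, pair) rows and non-uniform time grids are
    errors.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(PAIR_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"pair table missing columns: {sorted(missing)}")
    dup = df.duplicated(subset=["frame", "donor_mol", "donor_H", "acceptor_mol"])
    if dup.any():
        row = df[dup].iloc[0]
        raise ValueError(
            "duplicate (frame, pair) row: frame "
            f"{int(row.frame)}, pair ({int(row.donor_mol)}, "
            f"{int(row.donor_H)}, {int(row.acceptor_mol)})"
        )
    frames = np.sort(df["frame"].unique())
    frame_time = df.groupby("frame")["time_fs"].first()
    n_frames = int(frames.max()) + 1
    times = np.full(n_frames, np.nan)
    times[frame_time.index.astype(int)] = frame_time.values
    # infer dt from consecutive observed frames and validate uniformity
    obs = np.where(np.isfinite(times))[0]
    if len(obs) < 2:
        dt = 1.0
    else:
        dts = np.diff(times[obs]) / np.diff(obs)
        dt = dts[0]
        bad = np.where(~np.isclose(dts, dt, rtol=1e-8, atol=1e-9))[0]
        if len(bad):
            raise ValueError(
                f"non-uniform time grid: first offending frame {obs[bad[0] + 1]}"
            )
    t_grid = np.arange(n_frames) * dt + (times[obs[0]] - obs[0] * dt if len(obs) else 0.0)
    out = []
    for key, grp in df.groupby(["donor_mol", "donor_H", "acceptor_mol"], sort=True):
        dE = np.full(n_frames, np.nan)
        dCT = np.full(n_frames, np.nan)
        idx = grp["frame"].to_numpy(dtype=int)
        dE[idx] = grp["dE_kJmol"].to_numpy(dtype=float)
        dCT[idx] = grp["dCT_au"].to_numpy(dtype=float)
        out.append(PairSeries(int(key[0]), int(key[1]), int(key[2]), t_grid, dE, dCT))
    return out


def write_pair_table(pairs: list, path, header_comment: str | None = None) -> None:
    """Write PairSeries to TSV, emitting only frames where the pair is present."""
    rows = []
    for p in pairs:
        idx = np.where(p.present)[0]
        for i in idx:
            rows.append(
                (i, p.t_grid[i], p.donor_mol, p.donor_H, p.acceptor_mol, p.dE[i], p.dCT[i])
            )
    df = pd.DataFrame(rows, columns=PAIR_TABLE_COLUMNS)
    df = df.sort_values(["frame", "donor_mol", "donor_H", "acceptor_mol"])
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, sep="\t", index=False)


def lsri(
    pairs: list,
    frame: int,
    exclude_self_bond: bool = False,
    min_abs_dE: float = 0.0,
) -> list:
    """LSRI O_h and components for every pair present at one frame.

    Returns a list of (pair_key, O_h, (D_Acc, A_Don, D_Don, A_Acc)).
    Pairs absent at the frame are excluded.  ``min_abs_dE`` optionally drops
    near-zero marginal contacts from the bond graph.
    """
    bonds = []  # (donor_mol, acceptor_mol, dE)
    keys = []
    for p in pairs:
        v = p.dE[frame]
        if np.isfinite(v) and abs(v) >= min_abs_dE:
            bonds.append((p.donor_mol, p.acceptor_mol, float(v)))
            keys.append(p.key)
    don_sum: dict = {}
    acc_sum: dict = {}
    for d, a, e in bonds:
        don_sum[d] = don_sum.get(d, 0.0) + e
        acc_sum[a] = acc_sum.get(a, 0.0) + e
    out = []
    for (d, a, e), key in zip(bonds, keys):
        d_acc = acc_sum.get(d, 0.0)
        a_don = don_sum.get(a, 0.0)
        d_don = don_sum.get(d, 0.0)
        a_acc = acc_sum.get(a, 0.0)
        if exclude_self_bond:
            d_don -= e
            a_acc -= e
        o_h = d_acc + a_don - d_don - a_acc
        out.append((key, o_h, (d_acc, a_don, d_don, a_acc)))
    return out


def lsri_series(
    pairs: list, exclude_self_bond: bool = False, min_abs_dE: float = 0.0
) -> list:
    """LSRI time series for every pair (NaN where the pair is absent)."""
    if not pairs:
        return []
    t_grid = pairs[0].t_grid
    n = len(t_grid)
    store = {
        p.key: (np.full(n, np.nan), np.full((4, n), np.nan)) for p in pairs
    }
    for f in range(n):
        for key, o_h, comps in lsri(pairs, f, exclude_self_bond, min_abs_dE):
            store[key][0][f] = o_h
            store[key][1][:, f] = comps
    return [
        LSRISeries(pair=key, t_grid=t_grid, O_h=vals, components=comps)
        for key, (vals, comps) in store.items()
    ]


def match_pairs_to_tracks(
    pairs: list,
    tracks: list,
    lsri_data: list | None = None,
) -> pd.DataFrame:
    """Join pair dE/dCT (and optionally LSRI) samples with frequency tracks.

    The donor OH of each pair is matched to the FrequencyTrack of the same
    (molecule, H) mode; times are matched to the nearest track sample within
    half a track time step.  Returns a DataFrame with columns time_fs,
    donor_mol, donor_H, acceptor_mol, omega_cm, dE_kJmol, dCT_au [, O_h].
    """
    track_map = {t.mode_id: t for t in tracks}
    lsri_map = {s.pair: s for s in (lsri_data or [])}
    rows = []
    for p in pairs:
        tr = track_map.get((p.donor_mol, p.donor_H))
        if tr is None or len(tr.t_grid) == 0:
            continue
        track_dt = tr.t_grid[1] - tr.t_grid[0] if len(tr.t_grid) > 1 else np.inf
        ls = lsri_map.get(p.key)
        idx_present = np.where(p.present)[0]
        for i in idx_present:
            t = p.t_grid[i]
            j = int(np.argmin(np.abs(tr.t_grid - t)))
            if abs(tr.t_grid[j] - t) > track_dt / 2 + 1e-9:
                continue
            row = {
                "time_fs": t,
                "donor_mol": p.donor_mol,
                "donor_H": p.donor_H,
                "acceptor_mol": p.acceptor_mol,
                "omega_cm": tr.omega[j],
                "dE_kJmol": p.dE[i],
                "dCT_au": p.dCT[i],
            }
            if ls is not None:
                row["O_h"] = ls.O_h[i]
            rows.append(row)
    if not rows:
        warnings.warn("no overlapping times between pairs and tracks")
        cols = [
            "time_fs", "donor_mol", "donor_H", "acceptor_mol",
            "omega_cm", "dE_kJmol", "dCT_au",
        ]
        return pd.DataFrame(columns=cols)
    return pd.DataFrame(rows)


def write_lsri_table(series: list, path) -> None:
    """Write LSRI series as TSV: frame, donor_mol, donor_H, acceptor_mol, O_h + components."""
    rows = []
    for s in series:
        for f in np.where(np.isfinite(s.O_h))[0]:
            rows.append(
                (
                    f, s.pair[0], s.pair[1], s.pair[2], s.O_h[f],
                    *s.components[:, f],
                )
            )
    df = pd.DataFrame(
        rows,
        columns=[
            "frame", "donor_mol", "donor_H", "acceptor_mol",
            "O_h", "D_Acc", "A_Don", "D_Don", "A_Acc",
        ],
    )
    df.to_csv(path, sep="\t", index=False)
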