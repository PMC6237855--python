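"""Pair-table contract, LSRI order parameter and track matching."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hbdyn.eda_interface import (
    PairSeries,
    lsri,
    lsri_series,
    match_pairs_to_tracks,
    read_pair_table,
    write_pair_table,
)
from hbdyn.linear_maps import fit_linear
from hbdyn.synthetic import CouplingSpec, KuboProcessSpec, gen_coupled_observables, gen_frequency_process
from hbdyn.wavelet_freq import FrequencyTrack


def _pair(d, h, a, dE, dCT=None, dt=5.0):
    dE = np.asarray(dE, dtype=float)
    dCT = np.asarray(dCT, dtype=float) if dCT is not None else dE * 1e-4
    return PairSeries(d, h, a, np.arange(len(dE)) * dt, dE, dCT)


def _graph_pairs(bonds, n_frames=1):
    """Static bond graph: list of (donor, acceptor, dE) held for n_frames."""
    return [
        _pair(d, 1, a, np.full(n_frames, e)) for d, a, e in bonds
    ]


class TestPairTable:
    def test_round_trip_toy(self, tmp_path):
        pairs = [_pair(0, 1, 1, [-20.0, -21.0])]
        path = tmp_path / "pairs.tsv"
        write_pair_table(pairs, path)
        back = read_pair_table(path)
        assert len(back) == 1
        assert len(back[0].dE) == 2
        np.testing.assert_allclose(back[0].dE, [-20.0, -21.0])

    def test_gap_frame_is_explicit_absence(self, tmp_path):
        dE = np.array([-20.0, np.nan, -19.0])
        pairs = [_pair(0, 1, 1, dE)]
        path = tmp_path / "pairs.tsv"
        write_pair_table(pairs, path)
        back = read_pair_table(path)[0]
        assert np.isnan(back.dE[1])
        assert back.present.tolist() == [True, False, True]

    def test_duplicate_rows_rejected(self, tmp_path):
        rows = "frame\ttime_fs\tdonor_mol\tdonor_H\tacceptor_mol\tdE_kJmol\tdCT_au\n"
        rows += "0\t0.0\t0\t1\t1\t-20.0\t0.01\n0\t0.0\t0\t1\t1\t-19.0\t0.01\n"
        p = tmp_path / "dup.tsv"
        p.write_text(rows)
        with pytest.raises(ValueError, match="duplicate"):
            read_pair_table(p)

    def test_non_uniform_grid_rejected(self, tmp_path):
        rows = "frame\ttime_fs\tdonor_mol\tdonor_H\tacceptor_mol\tdE_kJmol\tdCT_au\n"
        rows += "0\t0.0\t0\t1\t1\t-20.0\t0.01\n"
        rows += "1\t5.0\t0\t1\t1\t-20.0\t0.01\n"
        rows += "2\t12.0\t0\t1\t1\t-20.0\t0.01\n"
        p = tmp_path / "bad.tsv"
        p.write_text(rows)
        with pytest.raises(ValueError, match="non-uniform.*frame 2"):
            read_pair_table(p)

    def test_synthetic_table_shape(self, tmp_path):
        spec = KuboProcessSpec(n_modes=3, n_frames=50)
        t, om = gen_frequency_process(spec, 1)
        pairs, _ = gen_coupled_observables(t, om, CouplingSpec(), 2)
        path = tmp_path / "synth.tsv"
        write_pair_table(pairs, path)
        back = read_pair_table(path)
        assert len(back) == 3
        assert all(len(p.dE) == 50 for p in back)
        assert back[0].t_grid[1] - back[0].t_grid[0] == pytest.approx(5.0)


class TestLSRI:
    def test_isolated_dimer_hand_value(self):
        # single bond 0->1 with dE = -20: O_h = 0 + 0 - (-20) - (-20) = 40
        out = lsri(_graph_pairs([(0, 1, -20.0)]), 0)
        assert len(out) == 1
        key, o_h, comps = out[0]
        assert key == (0, 1, 1)
        assert comps == (0.0, 0.0, -20.0, -20.0)
        assert o_h == pytest.approx(40.0)

    def test_symmetric_motif_gives_zero(self):
        # doubly hydrogen-bonded dimer: donor/acceptor environments mirror
        out = lsri(_graph_pairs([(0, 1, -20.0), (1, 0, -20.0)]), 0)
        for _, o_h, _ in out:
            assert o_h == pytest.approx(0.0)

    def test_exclude_self_bond_variant(self):
        out = lsri(_graph_pairs([(0, 1, -20.0)]), 0, exclude_self_bond=True)
        _, o_h, comps = out[0]
        assert comps[2] == 0.0 and comps[3] == 0.0
        assert o_h == 0.0

    def test_absent_pair_excluded_not_zero_filled(self):
        p = _pair(0, 1, 1, [-20.0, np.nan])
        assert len(lsri([p], 0)) == 1
        assert len(lsri([p], 1)) == 0

    @given(st.lists(
        st.tuples(st.integers(0, 5), st.integers(0, 5),
                  st.floats(-40, -0.5)).filter(lambda b: b[0] != b[1]),
        min_size=1, max_size=12, unique_by=lambda b: (b[0], b[1]),
    ))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_invariance_under_global_role_exchange(self, bonds):
        # exchanging every bond's donor/acceptor roles swaps D_Acc<->A_Don and
        # D_Don<->A_Acc, leaving O_h = D_Acc + A_Don - D_Don - A_Acc unchanged
        fwd = lsri(_graph_pairs(bonds), 0)
        rev = lsri(_graph_pairs([(a, d, e) for d, a, e in bonds]), 0)
        fwd_map = {(k[0], k[2]): v for k, v, _ in fwd}
        rev_map = {(k[2], k[0]): v for k, v, _ in rev}
        for key, val in fwd_map.items():
            assert rev_map[key] == pytest.approx(val, abs=1e-10)

    @given(st.lists(
        st.tuples(st.integers(0, 5), st.integers(0, 5),
                  st.floats(-40, -0.5)).filter(lambda b: b[0] != b[1]),
        min_size=1, max_size=12, unique_by=lambda b: (b[0], b[1]),
    ))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_permutation_invariance(self, bonds):
        perm = {m: (m * 7 + 3) % 29 for m in range(6)}
        base = {(k[0], k[2]): v for k, v, _ in lsri(_graph_pairs(bonds), 0)}
        relabeled = lsri(
            _graph_pairs([(perm[d], perm[a], e) for d, a, e in bonds]), 0
        )
        for k, v, _ in relabeled:
            inv = {pv: pk for pk, pv in perm.items()}
            assert base[(inv[k[0]], inv[k[2]])] == pytest.approx(v, abs=1e-10)

    def test_molecule_flux_bookkeeping_conserved(self, rng):
        # total energy donated == total accepted == sum over bonds, exactly
        bonds = [(d, a, float(e)) for (d, a), e in zip(
            [(0, 1), (0, 2), (1, 3), (2, 3), (3, 0), (4, 1)],
            rng.uniform(-30, -1, 6),
        )]
        pairs = _graph_pairs(bonds)
        out = lsri(pairs, 0)
        don, acc = {}, {}
        for d, a, e in bonds:
            don[d] = don.get(d, 0.0) + e
            acc[a] = acc.get(a, 0.0) + e
        total = sum(e for _, _, e in bonds)
        assert sum(don.values()) == pytest.approx(total, rel=1e-12)
        assert sum(acc.values()) == pytest.approx(total, rel=1e-12)
        # components reported by lsri agree with the independent tally
        for (d, h, a), _, (d_acc, a_don, d_don, a_acc) in out:
            assert d_don == pytest.approx(don.get(d, 0.0))
            assert a_acc == pytest.approx(acc.get(a, 0.0))

    def test_series_recomputable_from_components(self):
        pairs = _graph_pairs([(0, 1, -20.0), (1, 2, -10.0), (2, 0, -5.0)], n_frames=4)
        for s in lsri_series(pairs):
            d_acc, a_don, d_don, a_acc = s.components
            np.testing.assert_allclose(s.O_h, d_acc + a_don - d_don - a_acc)


def _track(mode_id, t_grid, omega):
    n = len(t_grid)
    return FrequencyTrack(
        mode_id=mode_id, t_grid=np.asarray(t_grid, float),
        omega=np.asarray(omega, float), modulus=np.ones(n),
        boundary=np.zeros(n, bool), edge=np.zeros(n, bool),
    )


class TestMatching:
    def test_common_frames_counted(self):
        t = np.arange(10) * 5.0
        pairs = [_pair(0, 1, 1, np.full(10, -20.0))]
        tracks = [_track((0, 1), t, np.full(10, 3400.0))]
        joined = match_pairs_to_tracks(pairs, tracks)
        assert len(joined) == 10

    def test_grid_intersection_subsamples(self):
        # track on 1 fs grid, pairs on 5 fs grid -> one sample per pair frame
        t_track = np.arange(0, 50, 1.0)
        tracks = [_track((0, 1), t_track, np.full(len(t_track), 3400.0))]
        pairs = [_pair(0, 1, 1, np.full(10, -20.0), dt=5.0)]
        joined = match_pairs_to_tracks(pairs, tracks)
        assert len(joined) == 10
        np.testing.assert_allclose(np.diff(np.sort(joined["time_fs"])), 5.0)

    def test_no_overlap_warns_and_returns_empty(self):
        tracks = [_track((0, 1), np.arange(5) * 1.0, np.full(5, 3400.0))]
        pairs = [_pair(0, 1, 1, np.full(3, -20.0), dt=1.0)]
        pairs[0].t_grid = pairs[0].t_grid + 1000.0
        with pytest.warns(UserWarning, match="no overlapping"):
            joined = match_pairs_to_tracks(pairs, tracks)
        assert joined.empty

    def test_generator_coupling_sign_recovered(self):
        # dE becomes more negative at lower frequency -> positive slope
        spec = KuboProcessSpec(n_modes=8, n_frames=400)
        t, om = gen_frequency_process(spec, 11)
        pairs, _ = gen_coupled_observables(t, om, CouplingSpec(), 12)
        tracks = [_track((p.donor_mol, 1), t, om[i]) for i, p in enumerate(pairs)]
        joined = match_pairs_to_tracks(pairs, tracks)
        m = fit_linear(joined["omega_cm"], joined["dE_kJmol"], "dE")
        assert m.slope > 0
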