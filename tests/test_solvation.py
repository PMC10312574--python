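"""Superposition, contact machinery, autocorrelation, and ΔG_solv tests.

Independent oracles: an Euler-angle rotation search for the Kabsch
superposition, an all-pairs O(N²) distance loop for contact detection,
and closed-form laws (1 − τ/D decay, (1 − 1/e)·D residence time,
√2·σ jitter plateau) for the event statistics.
"""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st_
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

import sterictrap as st
from sterictrap.constants import R_KCAL


def random_rigid(rng):
    R = Rotation.random(random_state=np.random.RandomState(
        rng.integers(2**31))).as_matrix()
    t = rng.uniform(-20, 20, 3)
    return R, t


# ---------------------------------------------------------------- superpose

class TestSuperpose:
    def test_identity_and_planted_rigid_transform(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(0, 3, (12, 3))
        assert st.superposed_rmsd(pts, pts) == pytest.approx(0.0, abs=1e-10)
        Rz = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        moved = pts @ Rz.T + np.array([5.0, -3.0, 2.0])
        assert st.superposed_rmsd(pts, moved) == pytest.approx(0.0, abs=1e-8)

    def test_rmsd_invariant_under_rigid_motion_of_either_input(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 3, (10, 3))
        b = a + rng.normal(0, 0.5, (10, 3))
        base = st.superposed_rmsd(a, b)
        for _ in range(5):
            R, t = random_rigid(rng)
            assert st.superposed_rmsd(a @ R.T + t, b) == pytest.approx(
                base, abs=1e-8)
            assert st.superposed_rmsd(a, b @ R.T + t) == pytest.approx(
                base, abs=1e-8)

    def test_proper_rotation_returned(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0, 3, (8, 3))
        b = rng.normal(0, 3, (8, 3))
        R, t, _ = st.superpose(a, b)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-10)

    def test_matches_rotation_search_oracle(self):
        """Brute-force search over rotations agrees to 10⁻³ Å."""
        ref = np.array([[0, 0, 0], [3, 0, 0], [0, 3, 0], [0, 0, 3]], float)
        mov = ref.copy()
        mov[1, 1] += 1.0    # one point displaced by 1 Å

        ref_c = ref - ref.mean(0)
        mov_c = mov - mov.mean(0)

        def rmsd_of_angles(angles):
            R = Rotation.from_euler("xyz", angles).as_matrix()
            d = ref_c - mov_c @ R.T
            return math.sqrt(np.mean(np.sum(d * d, axis=1)))

        best = math.inf
        grid = np.linspace(-math.pi, math.pi, 5)
        for ax in grid:
            for ay in grid:
                for az in grid:
                    res = minimize(rmsd_of_angles, [ax, ay, az],
                                   method="Nelder-Mead",
                                   options={"xatol": 1e-6, "fatol": 1e-12})
                    best = min(best, res.fun)
        assert st.superposed_rmsd(ref, mov) == pytest.approx(best, abs=1e-3)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            st.superpose(np.zeros((2, 3)), np.zeros((2, 3)))
        line = np.outer(np.arange(5.0), [1.0, 0, 0])
        with pytest.raises(ValueError):
            st.superpose(line, line)


class TestRmsdRmsf:
    def test_rmsd_to_reference_zero_for_rigid_motion(self):
        frames, _ = st.gen_frames(3, n_frames=4)
        sel = np.flatnonzero(
            (frames.atoms["molecule_type"] == "protein").to_numpy())
        ref = frames.coords[0, sel, :]
        rng = np.random.default_rng(4)
        for f in range(frames.n_frames):
            R, t = random_rigid(rng)
            frames.coords[f] = frames.coords[f] @ R.T + t
        series = st.rmsd_to_reference(frames, sel, ref)
        np.testing.assert_allclose(series, 0.0, atol=1e-8)

    def test_rmsd_single_displaced_atom_bounded_by_direct_formula(self):
        rng = np.random.default_rng(5)
        n = 200
        ref = rng.normal(0, 5, (n, 3))
        mov = ref.copy()
        d = 2.0
        mov[0, 0] += d
        r = st.superposed_rmsd(ref, mov)
        assert r <= d / math.sqrt(n) + 1e-12
        assert r >= 0.9 * d / math.sqrt(n)   # alignment correction is small

    def test_rmsf_static_zero_and_rigid_invariance(self):
        frames, _ = st.gen_frames(6, n_frames=5)
        assert np.allclose(st.rmsf_per_residue(frames), 0.0, atol=1e-8)
        rng = np.random.default_rng(6)
        jittered = frames.coords + rng.normal(0, 0.2, frames.coords.shape)
        f1 = st.FrameSet(atoms=frames.atoms, coords=jittered, dt=frames.dt)
        base = st.rmsf_per_residue(f1)
        moved = jittered.copy()
        for f in range(moved.shape[0]):
            R, t = random_rigid(rng)
            moved[f] = moved[f] @ R.T + t
        f2 = st.FrameSet(atoms=frames.atoms, coords=moved, dt=frames.dt)
        # mean-structure alignment is iterated once, so invariance under a
        # global rigid motion of every frame is approximate, not exact
        np.testing.assert_allclose(st.rmsf_per_residue(f2).to_numpy(),
                                   base.to_numpy(), atol=1e-4)

    def test_rmsf_alternating_atom_closed_form(self):
        # one atom alternates ±d about its mean, alignment disabled
        n_frames, d = 6, 0.8
        atoms = pd.DataFrame({"atom_name": ["C1", "C2", "C3", "C4"],
                              "residue_id": [1, 1, 2, 2],
                              "molecule_id": ["M"] * 4,
                              "molecule_type": ["protein"] * 4})
        base = np.array([[0, 0, 0], [3, 0, 0], [0, 3, 0], [3, 3, 0]], float)
        coords = np.repeat(base[None], n_frames, axis=0)
        coords[:, 0, 2] = d * np.array([1, -1] * (n_frames // 2))
        frames = st.FrameSet(atoms=atoms, coords=coords, dt=1.0)
        rmsf = st.rmsf_per_residue(frames, align=False)
        assert rmsf.loc[1] == pytest.approx(d / 2)   # residue mean over 2 atoms
        assert rmsf.loc[2] == pytest.approx(0.0, abs=1e-12)


class TestRmsdTau:
    def test_frozen_conformations_give_zero(self):
        frames, _ = st.gen_frames(7, n_frames=6, jitter_sd=0.0)
        curve = st.rmsd_tau(frames, frames.molecule_ids("lipid"), 2.0)
        np.testing.assert_allclose(curve.rmsd, 0.0, atol=1e-10)
        assert curve.rmsd[0] == 0.0

    def test_iid_jitter_plateau_matches_analytic_value(self):
        sigma = 0.5
        frames, _ = st.gen_frames(8, n_frames=30, n_protein_atoms=10,
                                  n_in_shell=0, n_bulk=1,
                                  atoms_per_amphiphile=60, jitter_sd=sigma)
        curve = st.rmsd_tau(frames, ["L0"], max_lag_ns=5.0)
        expected = math.sqrt(2) * sigma * math.sqrt(59 / 60)
        assert curve.rmsd[-1] == pytest.approx(expected, rel=0.10)
        # nondecreasing within sampling error for iid noise
        assert np.all(np.diff(curve.rmsd) > -0.05 * expected)


# ---------------------------------------------------------------- contacts

def brute_force_contacts(frames, cutoff=5.0):
    """All-pairs O(N²) heavy-atom contact counts vs protein."""
    heavy = frames.heavy_mask()
    prot = np.flatnonzero(
        (frames.atoms["molecule_type"] == "protein").to_numpy() & heavy)
    out = {}
    for mol in [m for t in ("lipid", "detergent")
                for m in frames.molecule_ids(t)]:
        idx = frames.atom_indices(mol)
        qs = []
        for f in range(frames.n_frames):
            q = 0
            for i in idx:
                for j in prot:
                    if np.linalg.norm(frames.coords[f, i] -
                                      frames.coords[f, j]) <= cutoff:
                        q += 1
                        break
            qs.append(q)
        out[mol] = qs
    return out


class TestContacts:
    def _toy_frames(self, dist):
        atoms = pd.DataFrame({
            "atom_name": ["CA", "C1"],
            "residue_id": [1, 1000],
            "molecule_id": ["PROT", "L0"],
            "molecule_type": ["protein", "lipid"]})
        coords = np.array([[[0, 0, 0], [dist, 0, 0]]], float)
        return st.FrameSet(atoms=atoms, coords=coords, dt=1.0)

    @pytest.mark.parametrize("dist,q", [(4.9, 1), (5.1, 0)])
    def test_cutoff_threshold(self, dist, q):
        series = st.detect_contacts(self._toy_frames(dist))
        assert series.data["q"].tolist() == [q]

    def test_counts_all_atoms_within_cutoff(self):
        atoms = pd.DataFrame({
            "atom_name": ["CA", "C1", "C2", "C3"],
            "residue_id": [1, 1000, 1000, 1000],
            "molecule_id": ["PROT", "L0", "L0", "L0"],
            "molecule_type": ["protein", "lipid", "lipid", "lipid"]})
        coords = np.array([[[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]]],
                          float)
        frames = st.FrameSet(atoms=atoms, coords=coords, dt=1.0)
        assert st.detect_contacts(frames).data["q"].tolist() == [3]

    def test_hydrogens_excluded_by_name(self):
        atoms = pd.DataFrame({
            "atom_name": ["CA", "C1", "H11"],
            "residue_id": [1, 1000, 1000],
            "molecule_id": ["PROT", "L0", "L0"],
            "molecule_type": ["protein", "lipid", "lipid"]})
        coords = np.array([[[0, 0, 0], [1, 0, 0], [1.5, 0, 0]]], float)
        frames = st.FrameSet(atoms=atoms, coords=coords, dt=1.0)
        assert st.detect_contacts(frames).data["q"].tolist() == [1]

    def test_matches_all_pairs_oracle_on_random_frames(self):
        frames, _ = st.gen_frames(10, n_frames=8, n_protein_atoms=15,
                                  n_in_shell=2, n_bulk=2,
                                  atoms_per_amphiphile=5, jitter_sd=1.0)
        series = st.detect_contacts(frames)
        oracle = brute_force_contacts(frames)
        for (mol, _), _, q in series.tracks():
            assert q.tolist() == oracle[mol]

    def test_head_tail_partition_conservation(self):
        # DMPC-style naming: tail carbons from the shipped list, rest head
        tail_names = sorted(st.tail_atom_names("dmpc"))[:4]
        names = ["CA"] + ["P", "O2"] + tail_names
        atoms = pd.DataFrame({
            "atom_name": names,
            "residue_id": [1] + [1000] * 6,
            "molecule_id": ["PROT"] + ["L0"] * 6,
            "molecule_type": ["protein"] + ["lipid"] * 6})
        rng = np.random.default_rng(11)
        coords = rng.uniform(0, 7, (5, 7, 3))
        frames = st.FrameSet(atoms=atoms, coords=coords, dt=1.0)
        whole = st.detect_contacts(frames).data["q"].to_numpy()
        head = st.detect_contacts(
            frames, atom_names={"P", "O2"}).data["q"].to_numpy()
        tail = st.detect_contacts(
            frames, atom_names=set(tail_names)).data["q"].to_numpy()
        assert np.all(whole >= np.maximum(head, tail))
        assert np.all(whole <= head + tail)

    def test_tail_selections_are_disjoint_partitions(self):
        dmpc = st.tail_atom_names("dmpc")
        assert "C22" in dmpc and "C214" in dmpc and "C314" in dmpc
        assert len(dmpc) == 26
        ddm = st.tail_atom_names("ddm")
        assert ddm == {f"C{i}" for i in range(1, 13)}


class TestEvents:
    def _series(self, q, dt=1.0):
        df = pd.DataFrame({"time_ns": np.arange(len(q)) * dt,
                           "amphiphile_id": "A0", "partner": "protein",
                           "q": q})
        return st.ContactSeries(data=df, dt=dt)

    def test_gap_within_tolerance_merged(self):
        events = st.segment_events(self._series([1, 1, 0, 0, 1, 1]), 20.0)
        assert len(events) == 1
        assert events[0].q.tolist() == [1, 1, 0, 0, 1, 1]

    def test_gap_beyond_tolerance_splits(self):
        events = st.segment_events(self._series([1, 1, 0, 0, 1, 1]), 1.0)
        assert len(events) == 2
        assert [e.q.tolist() for e in events] == [[1, 1], [1, 1]]

    def test_all_zero_series_empty(self):
        assert st.segment_events(self._series([0, 0, 0]), 20.0) == []

    def test_events_trimmed_to_contacting_frames(self):
        events = st.segment_events(self._series([0, 0, 2, 3, 0, 0]), 1.0)
        assert len(events) == 1
        assert events[0].start_ns == 2.0
        assert events[0].end_ns == 3.0


class TestAutocorrelation:
    def _const_event(self, n, q0=5, dt=1.0):
        return st.ContactEvent("A0", "protein", 0.0, (n - 1) * dt,
                               np.full(n, q0), dt, 20.0)

    def test_constant_event_closed_form(self):
        D, dt = 10.0, 1.0
        ev = self._const_event(10, dt=dt)
        curve = st.contact_autocorrelation([ev], max_lag_ns=12.0)
        expected = np.maximum(0.0, 1.0 - curve.tau_ns / D)
        np.testing.assert_allclose(curve.c, expected, atol=1e-12)

    def test_c0_is_one_and_scale_invariance(self):
        rng = np.random.default_rng(12)
        q = rng.integers(1, 10, 30)
        ev1 = st.ContactEvent("A", "protein", 0, 29, q, 1.0, 20.0)
        ev2 = st.ContactEvent("A", "protein", 0, 29, 2 * q, 1.0, 20.0)
        c1 = st.contact_autocorrelation([ev1], 15.0)
        c2 = st.contact_autocorrelation([ev2], 15.0)
        assert c1.c[0] == 1.0
        np.testing.assert_allclose(c1.c, c2.c, atol=1e-12)

    def test_constant_q_curve_nonincreasing(self):
        evs = [self._const_event(n) for n in (5, 12, 30)]
        curve = st.contact_autocorrelation(evs, 25.0)
        assert np.all(np.diff(curve.c) <= 1e-12)


class TestResidence:
    def test_pure_exponential_crossing(self):
        tau = np.arange(0, 40.5, 0.5)
        curve = st.AutocorrCurve(tau_ns=tau, c=np.exp(-tau / 10.0), n_events=1)
        assert st.residence_time(curve).tau_R == pytest.approx(10.0, abs=1e-9)

    def test_linear_decay_crossing(self):
        D = 10.0
        tau = np.arange(0, 10.5, 0.5)
        curve = st.AutocorrCurve(tau_ns=tau, c=np.maximum(0, 1 - tau / D),
                                 n_events=1)
        assert st.residence_time(curve).tau_R == pytest.approx(
            (1 - 1 / math.e) * D, abs=1e-9)

    def test_halving_dt_stable_within_interpolation_bound(self):
        rng = np.random.default_rng(13)
        for dt in (1.0, 0.5):
            tau = np.arange(0, 30 + dt / 2, dt)
            c = 0.6 * np.exp(-tau / 4) + 0.4 * np.exp(-tau / 15)
            curve = st.AutocorrCurve(tau_ns=tau, c=c, n_events=1)
            tr = st.residence_time(curve)
            if dt == 1.0:
                coarse = tr.tau_R
        assert abs(coarse - tr.tau_R) < 0.5    # < dt/2 of the coarser grid

    def test_no_crossing_extrapolates_with_flag(self):
        tau = np.arange(0, 5.25, 0.25)
        curve = st.AutocorrCurve(tau_ns=tau, c=np.exp(-tau / 50.0), n_events=1)
        tr = st.residence_time(curve)
        assert tr.extrapolated
        assert tr.tau_R == pytest.approx(50.0, rel=0.05)

    def test_monotone_increasing_curve_rejected(self):
        tau = np.arange(0, 5.0, 1.0)
        curve = st.AutocorrCurve(tau_ns=tau, c=1 + 0.1 * tau, n_events=1)
        with pytest.raises(ValueError):
            st.residence_time(curve)


class TestTripleExp:
    def test_single_exponential_degenerate_recovery(self):
        tau = np.arange(0, 60.5, 0.5)
        curve = st.AutocorrCurve(tau_ns=tau, c=np.exp(-tau / 8.0), n_events=1)
        fit = st.fit_triple_exponential(curve)
        k = int(np.argmax(fit.amplitudes))
        assert fit.amplitudes[k] > 0.99
        assert fit.times[k] == pytest.approx(8.0, rel=0.01)
        assert fit.amplitudes.sum() == pytest.approx(1.0, abs=1e-6)

    def test_three_component_recovery(self):
        tau = np.arange(0, 300.5, 0.5)
        c = 0.5 * np.exp(-tau / 1) + 0.3 * np.exp(-tau / 10) \
            + 0.2 * np.exp(-tau / 100)
        fit = st.fit_triple_exponential(
            st.AutocorrCurve(tau_ns=tau, c=c, n_events=1))
        np.testing.assert_allclose(fit.amplitudes, [0.5, 0.3, 0.2], rtol=0.05)
        np.testing.assert_allclose(fit.times, [1, 10, 100], rtol=0.05)
        assert np.all(np.diff(fit.times) >= 0)

    def test_beats_single_exponential_on_heterogeneous_decay(self):
        from scipy.optimize import curve_fit
        tau = np.arange(0, 100.5, 0.5)
        c = 0.6 * np.exp(-tau / 2) + 0.4 * np.exp(-tau / 50)
        fit3 = st.fit_triple_exponential(
            st.AutocorrCurve(tau_ns=tau, c=c, n_events=1))
        popt, _ = curve_fit(lambda t, tc: np.exp(-t / tc), tau, c, p0=[10.0])
        ssr1 = float(np.sum((np.exp(-tau / popt[0]) - c) ** 2))
        assert fit3.ssr <= ssr1


class TestSolvationFreeEnergy:
    def test_equal_residence_times_no_preference(self):
        assert st.solvation_free_energy(30.0, 30.0).dG_solv == 0.0

    def test_lipid_and_detergent_reference_values(self):
        # lipid on protein 90 ns vs lipid-lipid 40 ns at 310 K
        lip = st.solvation_free_energy(90.0, 40.0, T=310.0)
        assert round(lip.dG_solv, 2) == -0.50
        ddm = st.solvation_free_energy(80.0, 20.0, T=310.0)
        assert round(ddm.dG_solv, 2) == -0.85

    @settings(derandomize=True, max_examples=50)
    @given(a=st_.floats(0.1, 1e3), b=st_.floats(0.1, 1e3))
    def test_antisymmetry(self, a, b):
        assert st.solvation_free_energy(a, b).dG_solv == pytest.approx(
            -st.solvation_free_energy(b, a).dG_solv, abs=1e-12)

    def test_sd_propagation_delta_method(self):
        res = st.solvation_free_energy(80.0, 20.0, T=310.0,
                                       sd_PL=8.0, sd_LL=2.0)
        expected = R_KCAL * 310 * math.hypot(8 / 80, 2 / 20)
        assert res.sd == pytest.approx(expected, rel=1e-12)

    def test_nonpositive_times_rejected(self):
        with pytest.raises(ValueError):
            st.solvation_free_energy(0.0, 10.0)


class TestCensus:
    def test_planted_membership_counted(self):
        frames, truth = st.gen_frames(14, n_frames=4, n_in_shell=3, n_bulk=2)
        table, means, members = st.first_shell_census(frames)
        assert means["lipid"] == pytest.approx(3.0)
        assert set(members[0.0]) == set(truth["in_shell"])

    def test_empty_shell(self):
        frames, _ = st.gen_frames(15, n_frames=2, n_in_shell=0, n_bulk=2)
        _, means, _ = st.first_shell_census(frames)
        assert means["lipid"] == 0.0

    def test_consistent_with_detect_contacts(self):
        frames, _ = st.gen_frames(16, n_frames=3, n_in_shell=2, n_bulk=1,
                                  jitter_sd=0.5)
        series = st.detect_contacts(frames)
        _, _, members = st.first_shell_census(frames)
        for t_ns, grp in series.data.groupby("time_ns"):
            nonzero = set(grp.loc[grp["q"] >= 1, "amphiphile_id"])
            assert nonzero == set(members[float(t_ns)])
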