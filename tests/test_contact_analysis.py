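"""Contact criterion semantics, residence times and contact probabilities."""

import numpy as np
import pytest

from gaschannel.contact_analysis import (ContactSummary, ContactTimeline,
                                         contact_matrix, contact_probability,
                                         contact_timeline,
                                         cumulative_contact_time,
                                         frequent_contact_residues,
                                         summarize_contacts)
from gaschannel.errors import AnalysisError
from gaschannel.model_io import Atom, LigandInstance, Species, Structure, Trajectory

from conftest import bf_contact_matrix, random_structure


def gas_and_residues(distances):
    """One O2 at the origin plus single-atom residues at given x distances."""
    atoms = [
        Atom(1, "O1", "O", 701, "OXY", "G", np.array([0.0, 0.0, 0.0])),
        Atom(2, "O2", "O", 701, "OXY", "G", np.array([0.0, 0.0, 1.2])),
    ]
    for i, d in enumerate(distances, start=1):
        atoms.append(Atom(2 + i, "CA", "C", i, "ALA", "A", np.array([d, 0.0, 0.0])))
    st = Structure(atoms)
    lig = LigandInstance("OXY_701", Species.O2, (1, 2))
    keys = [("A", i, "ALA") for i in range(1, len(distances) + 1)]
    return st, lig, keys


class TestContactMatrix:
    def test_coincident_atom_is_contact(self):
        st, lig, keys = gas_and_residues([0.0])
        assert contact_matrix(st, st.coords, lig, keys).tolist() == [True]

    def test_cutoff_is_strictly_less_than(self):
        # min distances 3.4 / 3.5 / 3.6 Å: only the first is a contact
        st, lig, keys = gas_and_residues([3.4, 3.5, 3.6])
        assert contact_matrix(st, st.coords, lig, keys, cutoff=3.5).tolist() == \
            [True, False, False]

    def test_empty_residue_selection_rejected(self):
        st, lig, _ = gas_and_residues([3.0])
        with pytest.raises(AnalysisError, match="empty residue"):
            contact_matrix(st, st.coords, lig, [])

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_bruteforce_on_random_frames(self, seed):
        rng = np.random.default_rng(100 + seed)
        st = random_structure(rng, 200)
        # adopt two heavy atoms as a pseudo-ligand
        heavy = [a for a in st.atoms if a.is_heavy]
        lig = LigandInstance("X_1", Species.OTHER, (heavy[0].atom_id, heavy[1].atom_id))
        keys = st.residue_keys
        cutoff = float(rng.uniform(2, 8))
        got = contact_matrix(st, st.coords, lig, keys, cutoff=cutoff)
        expected = bf_contact_matrix(st, st.coords, lig, keys, cutoff)
        assert got.tolist() == expected

    def test_monotone_in_cutoff(self):
        rng = np.random.default_rng(7)
        st = random_structure(rng, 150)
        heavy = [a for a in st.atoms if a.is_heavy]
        lig = LigandInstance("X_1", Species.OTHER, (heavy[0].atom_id, heavy[1].atom_id))
        small = contact_matrix(st, st.coords, lig, st.residue_keys, cutoff=3.5)
        large = contact_matrix(st, st.coords, lig, st.residue_keys, cutoff=6.0)
        assert np.all(large[small])  # enlarging the cutoff never removes a contact


class TestContactTimeline:
    def test_static_trajectory_constant(self):
        st, lig, keys = gas_and_residues([3.0, 5.0])
        coords = np.repeat(st.coords[None, :, :], 10, axis=0)
        traj = Trajectory(coords, frame_interval=0.1)
        tls = contact_timeline(traj, st, lig, keys)
        assert tls[0].contact.all() and not tls[1].contact.any()

    def test_linear_flyby_crossing_matches_analytic_bounds(self):
        # ligand (point-like: both atoms coincident) moves along x past a
        # residue at x=0; |x(t)| < cutoff determines the contact run exactly
        st, lig, keys = gas_and_residues([0.0])
        n, v, x0 = 100, 0.2, -8.0
        coords = np.repeat(st.coords[None, :, :], n, axis=0)
        xs = x0 + v * np.arange(n)
        coords[:, 0, 0] = xs
        coords[:, 1, 0] = xs
        coords[:, 1, 2] = 0.0  # collapse the bond so distance is exactly |x|
        traj = Trajectory(coords, frame_interval=0.1)
        tl = contact_timeline(traj, st, lig, keys, cutoff=3.5)[0]
        expected = np.abs(xs) < 3.5
        np.testing.assert_array_equal(tl.contact, expected)

    def test_matches_planted_contacts_exactly(self, showcase):
        # the generator's S1 dwell of OXY_701 spans frames 200..899
        s = showcase
        lig = next(l for l in s.ligands if l.label == "OXY_701")
        site = s.catalog["S1"]
        tls = contact_timeline(s.trajectory, s.structure, lig,
                               sorted(site.residue_keys))
        any_contact = np.any([tl.contact for tl in tls], axis=0)
        expected = np.zeros(s.trajectory.n_frames, dtype=bool)
        expected[200:900] = True
        np.testing.assert_array_equal(any_contact, expected)


class TestCumulativeTime:
    def _tl(self, contact, fi=0.1):
        return ContactTimeline("L", ("A", 1, "ALA"), np.asarray(contact, bool), fi)

    def test_all_false_is_zero(self):
        assert cumulative_contact_time(self._tl(np.zeros(50))) == 0.0

    def test_frame_count_times_interval(self):
        contact = np.zeros(100, dtype=bool)
        contact[:25] = True
        assert cumulative_contact_time(self._tl(contact)) == pytest.approx(2.5)

    def test_complement_conservation(self):
        rng = np.random.default_rng(0)
        contact = rng.random(400) < 0.3
        tl, ntl = self._tl(contact), self._tl(~contact)
        total = cumulative_contact_time(tl) + cumulative_contact_time(ntl)
        assert total == pytest.approx(400 * 0.1)


class TestFrequentContacts:
    def _summary(self, key, t):
        return ContactSummary(("A", key, "ALA"), t, 1, (t,))

    def test_threshold_boundary_inclusive(self):
        summaries = [self._summary(1, 2.5), self._summary(2, 2.4)]
        assert frequent_contact_residues(summaries, 2.5) == [("A", 1, "ALA")]

    def test_zero_threshold_keeps_everything(self):
        summaries = [self._summary(1, 0.1), self._summary(2, 7.0)]
        assert len(frequent_contact_residues(summaries, 0.0)) == 2

    def test_empty_input(self):
        assert frequent_contact_residues([], 2.5) == []

    def test_sorted_by_time_then_residue_number(self):
        summaries = [self._summary(9, 3.0), self._summary(2, 3.0),
                     self._summary(5, 8.0)]
        keys = frequent_contact_residues(summaries, 2.5)
        assert [k[1] for k in keys] == [5, 2, 9]

    def test_cross_run_counts_runs_independently(self):
        tl_a = ContactTimeline("L", ("A", 1, "ALA"),
                               np.ones(30, dtype=bool), 0.1)
        tl_b = ContactTimeline("L", ("A", 1, "ALA"),
                               np.zeros(30, dtype=bool), 0.1)
        summaries = summarize_contacts([[tl_a], [tl_b]], threshold=2.5)
        assert summaries[0].n_runs_observed == 1
        assert summaries[0].per_run == (3.0, 0.0)
        assert summaries[0].cumulative_time == pytest.approx(3.0)  # not summed


class TestContactProbability:
    def test_always_in_contact_is_one(self):
        st, lig, keys = gas_and_residues([2.0])
        coords = np.repeat(st.coords[None, :, :], 8, axis=0)
        traj = Trajectory(coords, frame_interval=0.1)
        probs = contact_probability(traj, st, range(8), lig.atom_ids, keys)
        assert probs[("A", 1, "ALA")] == 1.0

    def test_fraction_of_selected_frames(self):
        # in contact during 75 of the 100 selected frames -> 0.75
        st, lig, keys = gas_and_residues([2.0])
        coords = np.repeat(st.coords[None, :, :], 100, axis=0)
        coords[75:, 0, 0] += 50.0
        coords[75:, 1, 0] += 50.0
        traj = Trajectory(coords, frame_interval=0.1)
        probs = contact_probability(traj, st, range(100), lig.atom_ids, keys)
        assert probs[("A", 1, "ALA")] == pytest.approx(0.75)

    def test_empty_selection_rejected(self):
        st, lig, keys = gas_and_residues([2.0])
        traj = Trajectory(st.coords[None, :, :], frame_interval=0.1)
        with pytest.raises(AnalysisError, match="non-empty"):
            contact_probability(traj, st, [], lig.atom_ids, keys)

    def test_invariant_under_residue_reordering(self):
        rng = np.random.default_rng(3)
        st = random_structure(rng, 80)
        heavy = [a for a in st.atoms if a.is_heavy]
        subject = (heavy[0].atom_id, heavy[1].atom_id)
        traj = Trajectory(np.repeat(st.coords[None, :, :], 5, axis=0),
                          frame_interval=0.1)
        keys = st.residue_keys
        p1 = contact_probability(traj, st, range(5), subject, keys)
        p2 = contact_probability(traj, st, range(5), subject, keys[::-1])
        assert p1 == p2
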