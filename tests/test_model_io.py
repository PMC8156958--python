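"""Structure/trajectory I/O, selections and superposition."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from gaschannel.errors import AnalysisError, InputError
from gaschannel.model_io import (Atom, Species, Structure, Trajectory,
                                 find_ligands, load_structure, load_trajectory,
                                 region_displacement, residues_within,
                                 write_structure, write_text_trajectory)

from conftest import bf_residues_within, random_structure


def make_atom(aid, resnum=1, resname="ALA", chain="A", name="CA", element="C",
              pos=(0.0, 0.0, 0.0)):
    return Atom(aid, name, element, resnum, resname, chain, np.asarray(pos, float))


class TestStructure:
    def test_minimal_pdb_identity_parse(self, tmp_path):
        pdb = tmp_path / "one.pdb"
        pdb.write_text(
            "ATOM      1  CA  ALA A   1       1.500   2.250  -3.125  1.00  0.00           C\n"
            "END\n"
        )
        st = load_structure(pdb)
        assert st.n_atoms == 1
        assert st.atoms[0].residue_key == ("A", 1, "ALA")
        np.testing.assert_allclose(st.atoms[0].position, [1.5, 2.25, -3.125])

    def test_text_fixture_residue_grouping(self, tmp_path):
        # 4 atoms over 2 residues, written by the test itself
        path = tmp_path / "s.txt"
        path.write_text(
            "1 CA C A 1 ALA 0 0 0\n"
            "2 CB C A 1 ALA 1 0 0\n"
            "3 CA C A 2 GLY 5 0 0\n"
            "4 N N A 2 GLY 6 0 0\n"
        )
        st = load_structure(path, format="text")
        assert st.n_atoms == 4
        assert len(st.residue_keys) == 2
        assert set(st.residue_keys) == {("A", 1, "ALA"), ("A", 2, "GLY")}

    def test_duplicate_atom_id_rejected(self):
        with pytest.raises(InputError, match="duplicate"):
            Structure([make_atom(1), make_atom(1, resnum=2)])

    def test_conflicting_residue_name_rejected(self):
        with pytest.raises(InputError, match="two names"):
            Structure([make_atom(1, resname="ALA"), make_atom(2, resname="GLY")])

    def test_empty_structure_rejected(self):
        with pytest.raises(InputError, match="empty"):
            Structure([])

    def test_structure_roundtrip_text_bitexact(self, tmp_path, ):
        rng = np.random.default_rng(5)
        st = random_structure(rng, 50)
        p = tmp_path / "s.txt"
        write_structure(st, p, format="text")
        st2 = load_structure(p, format="text")
        np.testing.assert_array_equal(st.coords, st2.coords)

    def test_pdb_roundtrip(self, tmp_path):
        rng = np.random.default_rng(6)
        st = random_structure(rng, 30, n_chains=1)
        p = tmp_path / "s.pdb"
        write_structure(st, p, format="pdb")
        st2 = load_structure(p)
        assert st2.n_atoms == st.n_atoms
        assert [a.residue_key for a in st2.atoms] == [a.residue_key for a in st.atoms]
        np.testing.assert_allclose(st.coords, st2.coords, atol=1.5e-3)


class TestTrajectory:
    def test_single_frame(self):
        rng = np.random.default_rng(0)
        st = random_structure(rng, 10)
        traj = Trajectory(st.coords[None, :, :], frame_interval=0.1)
        assert traj.n_frames == 1

    def test_run_length_matches_frames_times_interval(self, tmp_path):
        # 1500 frames at 0.1 ns/frame = a 150 ns run
        rng = np.random.default_rng(1)
        st = random_structure(rng, 5)
        coords = np.repeat(st.coords[None, :, :], 1500, axis=0)
        traj = Trajectory(coords, frame_interval=0.1)
        p = tmp_path / "t.txt"
        write_text_trajectory(traj, st, p)
        traj2 = load_trajectory(p, st)
        assert traj2.n_frames == 1500
        assert traj2.run_length == pytest.approx(150.0)

    def test_text_roundtrip_bitexact(self, tmp_path):
        rng = np.random.default_rng(2)
        st = random_structure(rng, 20)
        coords = rng.normal(size=(7, 20, 3)) * 10
        traj = Trajectory(coords, frame_interval=0.25)
        p = tmp_path / "t.txt"
        write_text_trajectory(traj, st, p)
        traj2 = load_trajectory(p, st)
        np.testing.assert_array_equal(traj.coordinates, traj2.coordinates)
        assert traj2.frame_interval == 0.25

    def test_atom_count_mismatch_rejected(self, tmp_path):
        rng = np.random.default_rng(3)
        st = random_structure(rng, 10)
        smaller = random_structure(rng, 9)
        traj = Trajectory(smaller.coords[None, :, :], frame_interval=0.1)
        p = tmp_path / "t.txt"
        write_text_trajectory(traj, smaller, p)
        with pytest.raises(InputError, match="atoms"):
            load_trajectory(p, st)

    def test_bad_frame_interval_rejected(self):
        rng = np.random.default_rng(4)
        st = random_structure(rng, 4)
        with pytest.raises(InputError, match="frame_interval"):
            Trajectory(st.coords[None, :, :], frame_interval=0.0)


class TestFindLigands:
    def _gas_structure(self):
        atoms = [
            make_atom(1, resnum=100, resname="ALA"),
            Atom(2, "O1", "O", 701, "OXY", "G", np.array([0.0, 0, 0])),
            Atom(3, "O2", "O", 701, "OXY", "G", np.array([1.2, 0, 0])),
            Atom(4, "N", "N", 805, "NO", "G", np.array([5.0, 0, 0])),
            Atom(5, "O", "O", 805, "NO", "G", np.array([6.2, 0, 0])),
        ]
        return Structure(atoms)

    def test_dialect_labels_and_species(self):
        ligs = find_ligands(self._gas_structure())
        assert [(l.label, l.species) for l in ligs] == [
            ("OXY_701", Species.O2), ("NO_805", Species.NO)]

    def test_no_gas_residues_empty(self):
        st = Structure([make_atom(1)])
        assert find_ligands(st) == []

    def test_wrong_atom_count_rejected(self):
        atoms = [
            Atom(1, "O1", "O", 701, "OXY", "G", np.zeros(3)),
            Atom(2, "O2", "O", 701, "OXY", "G", np.array([1.2, 0, 0])),
            Atom(3, "O3", "O", 701, "OXY", "G", np.array([2.4, 0, 0])),
        ]
        with pytest.raises(InputError, match="expected 2"):
            find_ligands(Structure(atoms))

    def test_wrong_elements_rejected(self):
        atoms = [
            Atom(1, "N", "N", 701, "OXY", "G", np.zeros(3)),
            Atom(2, "O", "O", 701, "OXY", "G", np.array([1.2, 0, 0])),
        ]
        with pytest.raises(InputError, match="inconsistent"):
            find_ligands(Structure(atoms))


class TestResiduesWithin:
    def test_shell_boundary_inclusive(self):
        # residues at 5 / 19.9 / 20.1 Å from the center atom; 20 Å keeps two
        atoms = [make_atom(1, resnum=1, pos=(0, 0, 0))]
        for i, d in enumerate((5.0, 19.9, 20.1), start=2):
            atoms.append(make_atom(i, resnum=i, pos=(d, 0, 0)))
        st = Structure(atoms)
        keys = residues_within(st, st.coords, 1, 20.0)
        nums = {k[1] for k in keys}
        assert nums == {1, 2, 3}

    def test_tiny_radius_self_only(self):
        atoms = [make_atom(1, resnum=1, pos=(0, 0, 0)),
                 make_atom(2, resnum=2, pos=(4, 0, 0))]
        st = Structure(atoms)
        assert residues_within(st, st.coords, 1, 1e-6) == {("A", 1, "ALA")}

    def test_missing_center_atom(self):
        st = Structure([make_atom(1)])
        with pytest.raises(AnalysisError, match="atom_id"):
            residues_within(st, st.coords, 99, 5.0)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_bruteforce_on_random_structures(self, seed):
        rng = np.random.default_rng(seed)
        st = random_structure(rng, 500)
        frame = st.coords
        center = st.atoms[int(rng.integers(st.n_atoms))].atom_id
        radius = float(rng.uniform(3, 25))
        assert residues_within(st, frame, center, radius) == \
            bf_residues_within(st, frame, center, radius)

    def test_minimum_image_wraps(self):
        atoms = [make_atom(1, resnum=1, pos=(1.0, 5.0, 5.0)),
                 make_atom(2, resnum=2, pos=(19.0, 5.0, 5.0))]
        st = Structure(atoms)
        box = (20.0, 20.0, 20.0)
        # direct separation 18 Å, minimum-image separation 2 Å
        assert residues_within(st, st.coords, 1, 3.0, box=box) == \
            {("A", 1, "ALA"), ("A", 2, "ALA")}
        assert residues_within(st, st.coords, 1, 3.0) == {("A", 1, "ALA")}


class TestRegionDisplacement:
    def _system(self, seed=0):
        rng = np.random.default_rng(seed)
        st = random_structure(rng, 60)
        region = [k for k in st.residue_keys[:4]]
        reference = [k for k in st.residue_keys[4:12]]
        return st, region, reference

    def test_identical_inputs_zero(self):
        st, region, reference = self._system()
        table, rmsd = region_displacement(st, st.coords, st, st.coords,
                                          region, reference)
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        assert table["displacement"].abs().max() == pytest.approx(0.0, abs=1e-9)

    def test_rigid_region_translation_detected(self):
        st, region, reference = self._system(1)
        coords_b = st.coords.copy()
        region_idx = np.concatenate([st.residue_atom_indices(k, heavy_only=False)
                                     for k in region])
        coords_b[region_idx] += np.array([0.0, 0.0, 4.0])
        table, rmsd = region_displacement(st, st.coords, st, coords_b,
                                          region, reference)
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(table["displacement"], 4.0, atol=1e-9)

    def test_global_rotation_invariance(self):
        st, region, reference = self._system(2)
        rot = Rotation.from_euler("xyz", [31.0, -12.0, 55.0], degrees=True)
        coords_b = rot.apply(st.coords - st.coords.mean(0)) + st.coords.mean(0) + 7.0
        table, rmsd = region_displacement(st, st.coords, st, coords_b,
                                          region, reference)
        assert rmsd == pytest.approx(0.0, abs=1e-8)
        assert table["displacement"].abs().max() < 1e-8

    def test_collinear_reference_rejected(self):
        atoms = [make_atom(i, resnum=i, pos=(float(i), 0, 0)) for i in range(1, 6)]
        st = Structure(atoms)
        keys = st.residue_keys
        with pytest.raises(AnalysisError, match="collinear"):
            region_displacement(st, st.coords, st, st.coords, keys[:1], keys[1:])


class TestDistanceInvariance:
    def test_distances_invariant_under_rigid_transform(self):
        from gaschannel.geometry import pairwise_distances

        rng = np.random.default_rng(11)
        a = rng.normal(size=(12, 3)) * 5
        b = rng.normal(size=(8, 3)) * 5
        rot = Rotation.random(random_state=3)
        shift = rng.normal(size=3) * 10
        d0 = pairwise_distances(a, b)
        d1 = pairwise_distances(rot.apply(a) + shift, rot.apply(b) + shift)
        np.testing.assert_allclose(d0, d1, atol=1e-9)
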