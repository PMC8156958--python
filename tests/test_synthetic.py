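"""The synthetic generator: geometry, determinism, plant fidelity, bundles."""

import hashlib
from pathlib import Path

import numpy as np
import pytest

from gaschannel.errors import InputError
from gaschannel.model_io import Species, load_structure, load_trajectory
from gaschannel.synthetic import (LigandPlan, Plant, SystemGeometry,
                                  SyntheticSystemSpec, build_protein_model,
                                  default_system_spec, displacement_scenario_specs,
                                  dwell_sampling_spec, ratio_counts,
                                  read_fixture_bundle, simulate_gas_trajectory,
                                  write_fixture_bundle)


class TestProteinModel:
    def test_default_model_resolves_all_sites(self):
        model = build_protein_model()
        assert set(model.catalog) == {"E1", "E3", "S1", "S2", "CAT"}
        for site in model.catalog.values():
            for key in site.residue_keys:
                assert model.structure.has_residue(key)
        model.refs.validate(model.structure)

    def test_zero_pocket_radius_rejected(self):
        with pytest.raises(InputError, match="pocket_radius"):
            build_protein_model(SystemGeometry(pocket_radius=0.0))

    def test_site_centroids_well_separated(self):
        model = build_protein_model()
        names = sorted(model.site_centroids)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                sep = np.linalg.norm(model.site_centroids[a] - model.site_centroids[b])
                assert sep >= 8.0, (a, b, sep)

    def test_overlapping_sites_rejected(self):
        geo = SystemGeometry(s1_offset=(0.0, 0.0, 15.0), s2_offset=(0.0, 2.0, 15.0))
        with pytest.raises(InputError, match="overlap"):
            build_protein_model(geo)


class TestRatios:
    def test_presets(self):
        assert ratio_counts("1:1") == (5, 5)
        assert ratio_counts("1:3") == (5, 15)
        assert ratio_counts("3:1") == (15, 5)

    def test_one_to_one_is_five_of_each(self):
        s = simulate_gas_trajectory(default_system_spec(3, ratio="1:1"))
        o2 = [l for l in s.ligands if l.species is Species.O2]
        no = [l for l in s.ligands if l.species is Species.NO]
        assert (len(o2), len(no)) == (5, 5)

    def test_unknown_preset_rejected(self):
        with pytest.raises(InputError, match="preset"):
            ratio_counts("2:7")


class TestDeterminism:
    def test_same_seed_identical_trajectories(self):
        s1 = simulate_gas_trajectory(default_system_spec(9))
        s2 = simulate_gas_trajectory(default_system_spec(9))
        np.testing.assert_array_equal(s1.trajectory.coordinates,
                                      s2.trajectory.coordinates)

    def test_different_seed_differs(self):
        s1 = simulate_gas_trajectory(default_system_spec(9))
        s2 = simulate_gas_trajectory(default_system_spec(10))
        assert not np.array_equal(s1.trajectory.coordinates,
                                  s2.trajectory.coordinates)

    def test_bundle_byte_identical(self, tmp_path):
        dirs = []
        for name in ("a", "b"):
            s = simulate_gas_trajectory(default_system_spec(11))
            d = tmp_path / name
            write_fixture_bundle(s, d, dcd=True)
            dirs.append(d)
        files = sorted(p.name for p in dirs[0].iterdir())
        assert files
        for fname in files:
            h = [hashlib.md5((d / fname).read_bytes()).hexdigest() for d in dirs]
            assert h[0] == h[1], fname


class TestPlantFidelity:
    def test_infeasible_overlapping_plants_rejected(self):
        plans = (LigandPlan(Species.O2, (Plant("site", "S1", 10, 100),
                                         Plant("site", "S2", 50, 120))),)
        spec = SyntheticSystemSpec(seed=1, n_o2=1, n_no=0, plans=plans)
        with pytest.raises(InputError, match="overlapping"):
            simulate_gas_trajectory(spec)

    def test_planted_dwell_recovered_within_one_frame(self, showcase):
        from gaschannel.contact_analysis import contact_timeline
        from gaschannel.site_occupancy import site_occupancy

        s = showcase
        recovered = set()
        for lig in s.ligands:
            for name, site in s.catalog.items():
                tls = contact_timeline(s.trajectory, s.structure, lig,
                                       sorted(site.residue_keys))
                for iv in site_occupancy(tls, site, ligand_label=lig.label):
                    recovered.add((lig.label, name, iv.start_frame, iv.end_frame))
        for label, site, start, end in s.truth.dwells:
            match = [r for r in recovered
                     if r[0] == label and r[1] == site
                     and abs(r[2] - start) <= 1 and abs(r[3] - end) <= 1]
            assert match, (label, site, start, end)
        assert len(recovered) == len(s.truth.dwells)  # nothing spurious

    def test_free_ligands_never_touch_sites(self, showcase):
        from gaschannel.contact_analysis import contact_timeline

        s = showcase
        free = next(l for l in s.ligands if l.label == "NO_805")
        for site in s.catalog.values():
            tls = contact_timeline(s.trajectory, s.structure, free,
                                   sorted(site.residue_keys))
            assert not any(tl.contact.any() for tl in tls)

    def test_substrate_excursion_suppresses_competence(self):
        from gaschannel.pose_competence import competent_poses

        base = default_system_spec(21)
        spec = SyntheticSystemSpec(
            seed=21, n_o2=base.n_o2, n_no=base.n_no, plans=base.plans,
            planted_displacements=base.planted_displacements,
            substrate_excursions=((500, 699),))
        s = simulate_gas_trajectory(spec)
        poses = competent_poses(s.trajectory, s.structure, s.refs, s.ligands)
        frames = {p.frame_index for p in poses}
        assert frames.isdisjoint(range(500, 700))
        expected = {f for fr in s.truth.competent_frames.values() for f in fr}
        assert frames == expected

    def test_periodic_variant_smoke(self):
        spec = SyntheticSystemSpec(seed=5, n_o2=1, n_no=1, run_length=5.0,
                                   periodic=True)
        s = simulate_gas_trajectory(spec)
        assert s.trajectory.box is not None
        assert np.all(s.trajectory.coordinates >= 0)


class TestDwellStatistics:
    def test_mean_dwell_recovered_within_ten_percent(self):
        from gaschannel.contact_analysis import contact_timeline
        from gaschannel.site_occupancy import site_occupancy

        s = simulate_gas_trajectory(dwell_sampling_spec(seed=20260925))
        site = s.catalog["S1"]
        durations = []
        for lig in s.ligands:
            tls = contact_timeline(s.trajectory, s.structure, lig,
                                   sorted(site.residue_keys))
            durations.extend(
                iv.duration for iv in site_occupancy(tls, site,
                                                     ligand_label=lig.label))
        assert len(durations) >= 100
        assert np.mean(durations) == pytest.approx(10.0, rel=0.10)


class TestBundles:
    def test_roundtrip_reproduces_coordinates_exactly(self, tmp_path):
        s = simulate_gas_trajectory(default_system_spec(13))
        write_fixture_bundle(s, tmp_path, dcd=False)
        st, tr, cat, refs, truth = read_fixture_bundle(tmp_path)
        np.testing.assert_array_equal(tr.coordinates, s.trajectory.coordinates)
        assert st.n_atoms == s.structure.n_atoms
        assert set(cat) == set(s.catalog)
        assert truth.dwells == s.truth.dwells
        assert truth.entrances == s.truth.entrances
        assert truth.competent_frames == {k: tuple(v) for k, v in
                                          s.truth.competent_frames.items()}

    def test_truth_tsv_row_counts(self, tmp_path):
        s = simulate_gas_trajectory(default_system_spec(14))
        paths = write_fixture_bundle(s, tmp_path, dcd=False)
        n_rows = len(Path(paths["truth_dwells"]).read_text().splitlines()) - 1
        assert n_rows == len(s.truth.dwells)

    def test_dcd_reload_matches_to_float32(self, tmp_path):
        spec = SyntheticSystemSpec(seed=15, n_o2=2, n_no=2, run_length=2.0)
        s = simulate_gas_trajectory(spec)
        paths = write_fixture_bundle(s, tmp_path, dcd=True)
        st = load_structure(paths["structure_text"], format="text")
        tr = load_trajectory(paths["trajectory_dcd"], st, frame_interval=0.1)
        np.testing.assert_allclose(tr.coordinates, s.trajectory.coordinates,
                                   atol=1e-4)

    def test_displacement_scenarios_cover_requested_events(self):
        specs = displacement_scenario_specs(25, seed=2)
        total = sum(len(sp.planted_displacements) for sp in specs)
        assert total == 25
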