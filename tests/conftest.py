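"""Shared fixtures: a seeded showcase system and brute-force oracles.

The oracles are deliberately naive (pure-Python double loops over atoms and
frames) and independent of the package's vectorised implementations; they are
the reference the fast paths are checked against.
"""

import math

import pytest

from gaschannel.model_io import Atom, Structure
from gaschannel.synthetic import default_system_spec, simulate_gas_trajectory

SHOWCASE_SEED = 1234


@pytest.fixture(scope="session")
def showcase():
    """The default synthetic system (150 ns, five O2 + five NO, scripted
    routes, one displacement), shared read-only across tests."""
    return simulate_gas_trajectory(default_system_spec(SHOWCASE_SEED))


def random_structure(rng, n_atoms, box_side=30.0, n_chains=2):
    """A random multi-residue structure with 1–4 atoms per residue and ~10%
    hydrogens, for oracle-equivalence checks."""
    atoms = []
    atom_id = 1
    resnum = 1
    while len(atoms) < n_atoms:
        chain = "AB"[rng.integers(n_chains)]
        n_in_res = int(rng.integers(1, 5))
        resname = ["ALA", "LEU", "PHE", "HIS"][rng.integers(4)]
        center = rng.uniform(0, box_side, 3)
        for j in range(n_in_res):
            if len(atoms) >= n_atoms:
                break
            element = "H" if rng.random() < 0.1 and j > 0 else "C"
            atoms.append(
                Atom(atom_id, f"X{j}", element, resnum, resname, chain,
                     center + rng.normal(scale=1.0, size=3))
            )
            atom_id += 1
        resnum += 1
    return Structure(atoms, title="random fixture")


# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------

def bf_dist(p, q, box=None):
    d = [p[k] - q[k] for k in range(3)]
    if box is not None:
        d = [d[k] - box[k] * round(d[k] / box[k]) for k in range(3)]
    return math.sqrt(sum(x * x for x in d))


def bf_contact_matrix(structure, frame, ligand, residues, cutoff, box=None,
                      heavy_only=True):
    lig_idx = [structure.atom_index(a) for a in ligand.atom_ids]
    out = []
    for key in residues:
        hit = False
        for i, atom in enumerate(structure.atoms):
            if atom.residue_key != tuple(key):
                continue
            if heavy_only and not atom.is_heavy:
                continue
            for li in lig_idx:
                if bf_dist(frame[i], frame[li], box) < cutoff:
                    hit = True
        out.append(hit)
    return out


def bf_residues_within(structure, frame, center_atom_id, radius, box=None,
                       heavy_only=True):
    ci = structure.atom_index(center_atom_id)
    keys = set()
    for i, atom in enumerate(structure.atoms):
        if heavy_only and not atom.is_heavy:
            continue
        if bf_dist(frame[i], frame[ci], box) <= radius:
            keys.add(atom.residue_key)
    return keys


def bf_competent_poses(traj, structure, refs, ligands, threshold=7.5):
    from gaschannel.model_io import Species

    fe = structure.atom_index(refs.fe_atom_id)
    c13 = structure.atom_index(refs.c13_atom_id)
    c15 = structure.atom_index(refs.c15_atom_id)
    poses = []
    for f in range(traj.n_frames):
        frame = traj.coordinates[f]
        d_c13_fe = bf_dist(frame[c13], frame[fe], traj.box)
        for lig in ligands:
            if lig.species is not Species.O2:
                continue
            d = min(
                bf_dist(frame[structure.atom_index(a)], frame[c15], traj.box)
                for a in lig.atom_ids
            )
            if d < threshold and d_c13_fe < threshold:
                poses.append((f, lig.label))
    return poses
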