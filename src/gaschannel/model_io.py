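"""Structures, trajectories, selections and conformational comparison.

The in-memory model is deliberately small: a :class:`Structure` is an ordered
atom table, a :class:`Trajectory` is a ``(n_frames, n_atoms, 3)`` coordinate
array in Å with a fixed frame interval in ns.  Residues are addressed by the
key ``(chain_id, residue_number, residue_name)`` everywhere in the package,
written ``"chain:resnum:resname"`` in configuration files.

File formats
------------
* Structures: PDB (parsed with ``gemmi``) or a plain-text fixture format —
  one line per atom, ``atom_id name element chain resnum resname x y z``.
* Trajectories: DCD/XTC (read through ``MDAnalysis``) or a plain-text fixture
  format — header line ``n_atoms n_frames frame_interval_ns`` followed by
  ``n_atoms`` lines of ``atom_id x y z`` per frame.  Text coordinates are
  written with 17 significant digits so a write/read round trip is
  bit-identical for float64 data.

The frame interval is never inferred from a binary trajectory header; it is a
required input for DCD/XTC (the text format carries it explicitly).
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .errors import AnalysisError, InputError
from .geometry import pairwise_distances, superpose

__all__ = [
    "Atom",
    "Structure",
    "Trajectory",
    "Species",
    "LigandInstance",
    "ReferenceAtoms",
    "ResidueKey",
    "parse_residue_key",
    "format_residue_key",
    "load_structure",
    "write_structure",
    "load_trajectory",
    "write_text_trajectory",
    "find_ligands",
    "residues_within",
    "region_displacement",
    "DEFAULT_GAS_NAMING",
]

ResidueKey = tuple  # (chain_id: str, residue_number: int, residue_name: str)


def parse_residue_key(text: str) -> ResidueKey:
    """Parse ``"A:154:TYR"`` into ``("A", 154, "TYR")``."""
    parts = text.strip().split(":")
    if len(parts) != 3:
        raise InputError(f"bad residue key {text!r}; expected 'chain:resnum:resname'")
    chain, num, name = parts
    try:
        return (chain, int(num), name)
    except ValueError as exc:
        raise InputError(f"bad residue number in key {text!r}") from exc


def format_residue_key(key: ResidueKey) -> str:
    return f"{key[0]}:{key[1]}:{key[2]}"


@dataclass(frozen=True)
class Atom:
    """One atom of a structure; ``position`` is an (3,) array in Å."""

    atom_id: int
    name: str
    element: str
    residue_number: int
    residue_name: str
    chain_id: str
    position: np.ndarray

    @property
    def residue_key(self) -> ResidueKey:
        return (self.chain_id, self.residue_number, self.residue_name)

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() not in ("H", "D")


class Structure:
    """Ordered atom table with residue indexing.

    Invariants enforced at construction: non-empty, unique atom ids, non-empty
    element symbols, finite coordinates, and a ``(chain, residue_number)`` pair
    mapping to exactly one residue name.
    """

    def __init__(self, atoms: Sequence[Atom], title: str = ""):
        atoms = list(atoms)
        if not atoms:
            raise InputError("empty structure")
        self.title = title
        seen_ids: dict[int, int] = {}
        resname_by_num: dict[tuple, str] = {}
        coords = np.empty((len(atoms), 3), dtype=float)
        residues: dict[ResidueKey, list[int]] = {}
        for i, a in enumerate(atoms):
            if a.atom_id in seen_ids:
                raise InputError(f"duplicate atom_id {a.atom_id}")
            seen_ids[a.atom_id] = i
            if not a.element:
                raise InputError(f"atom {a.atom_id}: empty element symbol")
            pos = np.asarray(a.position, dtype=float)
            if pos.shape != (3,) or not np.all(np.isfinite(pos)):
                raise InputError(f"atom {a.atom_id}: non-finite or mis-shaped position")
            coords[i] = pos
            num_key = (a.chain_id, a.residue_number)
            prev = resname_by_num.setdefault(num_key, a.residue_name)
            if prev != a.residue_name:
                raise InputError(
                    f"residue {num_key} has two names: {prev!r} and {a.residue_name!r}"
                )
            residues.setdefault(a.residue_key, []).append(i)
        self.atoms = atoms
        self._coords = coords
        self._id_index = seen_ids
        self._residues = {k: np.asarray(v, dtype=int) for k, v in residues.items()}
        self._heavy = np.array([a.is_heavy for a in atoms], dtype=bool)

    # -- basic accessors -------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """Reference coordinates (n_atoms, 3), Å."""
        return self._coords

    @property
    def residue_keys(self) -> list:
        return list(self._residues)

    @property
    def heavy_mask(self) -> np.ndarray:
        return self._heavy

    def atom_index(self, atom_id: int) -> int:
        try:
            return self._id_index[atom_id]
        except KeyError:
            raise AnalysisError(f"atom_id {atom_id} not in structure") from None

    def atom_indices(self, atom_ids: Iterable[int]) -> np.ndarray:
        return np.asarray([self.atom_index(i) for i in atom_ids], dtype=int)

    def has_residue(self, key: ResidueKey) -> bool:
        return tuple(key) in self._residues

    def residue_atom_indices(self, key: ResidueKey, heavy_only: bool = True) -> np.ndarray:
        try:
            idx = self._residues[tuple(key)]
        except KeyError:
            raise AnalysisError(f"residue {format_residue_key(key)} not in structure") from None
        if heavy_only:
            idx = idx[self._heavy[idx]]
            if idx.size == 0:
                raise AnalysisError(
                    f"residue {format_residue_key(key)} has no heavy atoms"
                )
        return idx


@dataclass
class Trajectory:
    """Per-frame coordinates for one structure.

    ``coordinates`` has shape ``(n_frames, n_atoms, 3)`` in Å; the time of
    frame ``i`` is ``i * frame_interval`` ns (frames are 0-based).  ``box``,
    when present, holds orthorhombic box lengths in Å and switches all
    distance computations to minimum-image.
    """

    coordinates: np.ndarray
    frame_interval: float
    box: Optional[np.ndarray] = None

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise InputError("trajectory coordinates must have shape (n_frames, n_atoms, 3)")
        if self.coordinates.shape[0] < 1:
            raise InputError("trajectory must contain at least one frame")
        if not self.frame_interval > 0:
            raise InputError("frame_interval must be positive (ns per frame)")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]

    @property
    def run_length(self) -> float:
        """Total simulated time in ns (n_frames × frame_interval)."""
        return self.n_frames * self.frame_interval

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval


class Species(str, Enum):
    O2 = "O2"
    NO = "NO"
    OTHER = "other"


#: residue-name dialect for diatomic gases: O2 ships as residue ``OXY`` with
#: atoms O1/O2, NO as residue ``NO`` with atoms N/O.
DEFAULT_GAS_NAMING: Mapping[str, Species] = {"OXY": Species.O2, "NO": Species.NO}

_SPECIES_ELEMENTS = {
    Species.O2: sorted(["O", "O"]),
    Species.NO: sorted(["N", "O"]),
}


@dataclass(frozen=True)
class LigandInstance:
    """A single gas molecule: label like ``OXY_701``, species, two atom ids."""

    label: str
    species: Species
    atom_ids: tuple

    def atom_indices(self, structure: Structure) -> np.ndarray:
        return structure.atom_indices(self.atom_ids)


@dataclass
class ReferenceAtoms:
    """Atom ids of the catalytic iron and, optionally, the substrate carbons
    C13/C15 of the sn-2 arachidonoyl chain plus the full substrate selection."""

    fe_atom_id: int
    c13_atom_id: Optional[int] = None
    c15_atom_id: Optional[int] = None
    substrate_atom_ids: Optional[tuple] = None

    def validate(self, structure: Structure) -> None:
        structure.atom_index(self.fe_atom_id)
        for aid in (self.c13_atom_id, self.c15_atom_id):
            if aid is not None:
                structure.atom_index(aid)
        if self.substrate_atom_ids:
            structure.atom_indices(self.substrate_atom_ids)


# ---------------------------------------------------------------------------
# structure I/O
# ---------------------------------------------------------------------------

def _load_pdb(path: Path) -> Structure:
    import gemmi

    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:
        raise InputError(f"cannot parse PDB file {path}: {exc}") from exc
    atoms = []
    if len(st) == 0:
        raise InputError(f"{path}: no models in PDB file")
    model = st[0]
    for chain in model:
        for res in chain:
            for at in res:
                atoms.append(
                    Atom(
                        atom_id=at.serial,
                        name=at.name,
                        element=at.element.name,
                        residue_number=res.seqid.num,
                        residue_name=res.name,
                        chain_id=chain.name,
                        position=np.array([at.pos.x, at.pos.y, at.pos.z]),
                    )
                )
    if not atoms:
        raise InputError(f"{path}: PDB file contains no atoms")
    return Structure(atoms, title=st.name or path.stem)


def _load_text_structure(path: Path) -> Structure:
    atoms = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 9:
                raise InputError(f"{path}:{lineno}: expected 9 fields, got {len(parts)}")
            try:
                atoms.append(
                    Atom(
                        atom_id=int(parts[0]),
                        name=parts[1],
                        element=parts[2],
                        chain_id=parts[3],
                        residue_number=int(parts[4]),
                        residue_name=parts[5],
                        position=np.array([float(p) for p in parts[6:9]]),
                    )
                )
            except ValueError as exc:
                raise InputError(f"{path}:{lineno}: malformed record: {exc}") from exc
    if not atoms:
        raise InputError(f"{path}: empty structure file")
    return Structure(atoms, title=path.stem)


def load_structure(path, format: Optional[str] = None) -> Structure:
    """Load a structure from PDB or the plain-text fixture format.

    ``format`` is ``"pdb"`` or ``"text"``; inferred from the suffix when
    omitted (``.pdb`` → PDB, anything else → text).
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"structure file not found: {path}")
    fmt = (format or ("pdb" if path.suffix.lower() == ".pdb" else "text")).lower()
    if fmt in ("pdb",):
        return _load_pdb(path)
    if fmt in ("text", "fixture", "fixture-text", "txt"):
        return _load_text_structure(path)
    raise InputError(f"unknown structure format {format!r}")


def write_structure(structure: Structure, path, format: Optional[str] = None) -> None:
    """Write a structure as PDB (via gemmi) or the plain-text fixture format."""
    path = Path(path)
    fmt = (format or ("pdb" if path.suffix.lower() == ".pdb" else "text")).lower()
    if fmt == "pdb":
        import gemmi

        st = gemmi.Structure()
        st.name = structure.title
        model = gemmi.Model("1")
        chains: dict[str, "gemmi.Chain"] = {}
        residues: dict[ResidueKey, "gemmi.Residue"] = {}
        for a in structure.atoms:
            ch = chains.get(a.chain_id)
            if ch is None:
                ch = gemmi.Chain(a.chain_id)
                chains[a.chain_id] = ch
            res = residues.get(a.residue_key)
            if res is None:
                res = gemmi.Residue()
                res.name = a.residue_name
                res.seqid = gemmi.SeqId(a.residue_number, " ")
                ch.add_residue(res)
                residues[a.residue_key] = ch[len(ch) - 1]
                res = residues[a.residue_key]
            at = gemmi.Atom()
            at.name = a.name
            at.element = gemmi.Element(a.element)
            at.serial = a.atom_id
            at.pos = gemmi.Position(*a.position)
            res.add_atom(at)
        for ch in chains.values():
            model.add_chain(ch)
        st.add_model(model)
        path.write_text(st.make_pdb_string())
    elif fmt in ("text", "fixture", "fixture-text", "txt"):
        with open(path, "w") as fh:
            for a in structure.atoms:
                fh.write(
                    f"{a.atom_id} {a.name} {a.element} {a.chain_id} "
                    f"{a.residue_number} {a.residue_name} "
                    f"{a.position[0]:.17g} {a.position[1]:.17g} {a.position[2]:.17g}\n"
                )
    else:
        raise InputError(f"unknown structure format {format!r}")


# ---------------------------------------------------------------------------
# trajectory I/O
# ---------------------------------------------------------------------------

def _load_text_trajectory(path: Path, structure: Structure) -> Trajectory:
    with open(path) as fh:
        header = fh.readline().split()
        if len(header) != 3:
            raise InputError(f"{path}:1: header must be 'n_atoms n_frames frame_interval_ns'")
        try:
            n_atoms, n_frames = int(header[0]), int(header[1])
            frame_interval = float(header[2])
        except ValueError as exc:
            raise InputError(f"{path}:1: malformed header: {exc}") from exc
        if n_atoms != structure.n_atoms:
            raise InputError(
                f"{path}: trajectory has {n_atoms} atoms but structure has {structure.n_atoms}"
            )
        if n_frames < 1:
            raise InputError(f"{path}: zero frames")
        coords = np.empty((n_frames, n_atoms, 3), dtype=float)
        order = {aid: i for i, aid in enumerate(a.atom_id for a in structure.atoms)}
        lineno = 1
        for f in range(n_frames):
            for _ in range(n_atoms):
                line = fh.readline()
                lineno += 1
                if not line:
                    raise InputError(f"{path}: truncated at frame {f} (line {lineno})")
                parts = line.split()
                if len(parts) != 4:
                    raise InputError(f"{path}:{lineno}: expected 'atom_id x y z'")
                try:
                    aid = int(parts[0])
                    coords[f, order[aid]] = [float(p) for p in parts[1:]]
                except (ValueError, KeyError) as exc:
                    raise InputError(f"{path}:{lineno}: bad record: {exc}") from exc
    return Trajectory(coords, frame_interval=frame_interval)


def _load_mda_trajectory(path: Path, structure: Structure, frame_interval) -> Trajectory:
    import warnings

    import MDAnalysis as mda

    if frame_interval is None:
        raise InputError("frame_interval (ns per frame) is required for DCD/XTC input")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe.empty(structure.n_atoms, trajectory=True)
        try:
            u.load_new(str(path))
        except (IOError, ValueError) as exc:
            raise InputError(f"cannot read trajectory {path}: {exc}") from exc
        frames = []
        box = None
        for ts in u.trajectory:
            frames.append(ts.positions.astype(float).copy())
            if ts.dimensions is not None and np.any(ts.dimensions[:3] > 0):
                box = np.asarray(ts.dimensions[:3], dtype=float)
    if not frames:
        raise InputError(f"{path}: zero frames")
    return Trajectory(np.stack(frames), frame_interval=float(frame_interval), box=box)


def load_trajectory(path, structure: Structure, frame_interval: Optional[float] = None,
                    format: Optional[str] = None) -> Trajectory:
    """Load a trajectory for ``structure``.

    Text fixtures carry their frame interval in the header; for DCD/XTC the
    interval must be given explicitly (it is never inferred).
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"trajectory file not found: {path}")
    fmt = format
    if fmt is None:
        suffix = path.suffix.lower()
        fmt = {"dcd": "dcd", "xtc": "xtc"}.get(suffix.lstrip("."), "text")
    fmt = fmt.lower()
    if fmt in ("dcd", "xtc"):
        traj = _load_mda_trajectory(path, structure, frame_interval)
    elif fmt in ("text", "fixture", "fixture-text", "txt"):
        traj = _load_text_trajectory(path, structure)
        if frame_interval is not None and not math.isclose(
            frame_interval, traj.frame_interval, rel_tol=1e-9
        ):
            raise InputError(
                f"{path}: header frame_interval {traj.frame_interval} ns "
                f"conflicts with requested {frame_interval} ns"
            )
    else:
        raise InputError(f"unknown trajectory format {format!r}")
    if traj.n_atoms != structure.n_atoms:
        raise InputError(
            f"{path}: trajectory atom count {traj.n_atoms} does not match "
            f"structure ({structure.n_atoms})"
        )
    return traj


def write_text_trajectory(traj: Trajectory, structure: Structure, path) -> None:
    """Write the plain-text fixture trajectory format (bit-exact round trip)."""
    with open(path, "w") as fh:
        fh.write(f"{traj.n_atoms} {traj.n_frames} {traj.frame_interval:.17g}\n")
        ids = [a.atom_id for a in structure.atoms]
        for f in range(traj.n_frames):
            frame = traj.coordinates[f]
            for aid, (x, y, z) in zip(ids, frame):
                fh.write(f"{aid} {x:.17g} {y:.17g} {z:.17g}\n")


def write_dcd_trajectory(traj: Trajectory, path) -> None:
    """Write a DCD trajectory (float32 coordinates, lossy for float64 data)."""
    import warnings

    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe.empty(traj.n_atoms, trajectory=True)
        if traj.box is not None:
            u.dimensions = [*traj.box, 90.0, 90.0, 90.0]
        with mda.Writer(str(path), traj.n_atoms) as w:
            for f in range(traj.n_frames):
                u.atoms.positions = traj.coordinates[f]
                w.write(u.atoms)


# ---------------------------------------------------------------------------
# selections
# ---------------------------------------------------------------------------

def find_ligands(structure: Structure,
                 naming_rules: Mapping[str, Species] = DEFAULT_GAS_NAMING) -> list:
    """Identify diatomic gas ligands from residue names.

    ``naming_rules`` maps residue name → species; each matching residue yields
    one :class:`LigandInstance` labelled ``"<resname>_<resnum>"``.  A matching
    residue whose atom count or element composition is inconsistent with its
    species is an error.
    """
    ligands = []
    for key in structure.residue_keys:
        chain, num, name = key
        species = naming_rules.get(name)
        if species is None:
            continue
        idx = structure.residue_atom_indices(key, heavy_only=False)
        atoms = [structure.atoms[i] for i in idx]
        if len(atoms) != 2:
            raise InputError(
                f"gas residue {format_residue_key(key)} has {len(atoms)} atoms, expected 2"
            )
        elements = sorted(a.element.upper().capitalize() for a in atoms)
        expected = _SPECIES_ELEMENTS.get(species)
        if expected is not None and elements != expected:
            raise InputError(
                f"gas residue {format_residue_key(key)}: elements {elements} "
                f"inconsistent with species {species.value}"
            )
        ligands.append(
            LigandInstance(
                label=f"{name}_{num}",
                species=species,
                atom_ids=tuple(a.atom_id for a in atoms),
            )
        )
    return ligands


def residues_within(structure: Structure, frame: np.ndarray, center_atom_id: int,
                    radius: float, box=None, heavy_only: bool = True) -> set:
    """Residue keys with ≥1 (heavy) atom within ``radius`` Å (inclusive) of the
    given atom in the given frame.  Minimum-image if ``box`` is set."""
    if not radius > 0:
        raise AnalysisError("radius must be positive")
    frame = np.asarray(frame, dtype=float)
    center = frame[structure.atom_index(center_atom_id)]
    d = pairwise_distances(center[None, :], frame, box=box)[0]
    mask = d <= radius
    if heavy_only:
        mask &= structure.heavy_mask
    keys = set()
    for i in np.nonzero(mask)[0]:
        keys.add(structure.atoms[i].residue_key)
    return keys


def region_displacement(struct_a: Structure, frame_a: np.ndarray,
                        struct_b: Structure, frame_b: np.ndarray,
                        region: Iterable, reference: Iterable):
    """Per-residue displacement of ``region`` between two conformations.

    Conformation B is rigidly superposed onto A using the heavy atoms of the
    ``reference`` residues (Kabsch); the table then reports, for each region
    residue, the mean displacement of its heavy atoms between A and the
    aligned B.  Returns ``(pandas.DataFrame, reference_rmsd)``.

    Both residue selections must resolve in both structures with identical
    atom counts per residue.
    """
    import pandas as pd

    region = [tuple(k) for k in region]
    reference = [tuple(k) for k in reference]

    def _gather(struct: Structure, frame: np.ndarray, keys):
        frame = np.asarray(frame, dtype=float)
        idx = np.concatenate([struct.residue_atom_indices(k) for k in keys])
        return frame[idx]

    ref_a = _gather(struct_a, frame_a, reference)
    ref_b = _gather(struct_b, frame_b, reference)
    if ref_a.shape != ref_b.shape:
        raise AnalysisError("reference selections differ in atom count between structures")
    transform, ref_rmsd = superpose(ref_b, ref_a)

    rows = []
    frame_a = np.asarray(frame_a, dtype=float)
    frame_b = np.asarray(frame_b, dtype=float)
    for key in region:
        ia = struct_a.residue_atom_indices(key)
        ib = struct_b.residue_atom_indices(key)
        if ia.size != ib.size:
            raise AnalysisError(
                f"region residue {format_residue_key(key)} differs in atom count"
            )
        moved = transform(frame_b[ib])
        disp = float(np.linalg.norm(moved - frame_a[ia], axis=1).mean())
        rows.append({"residue": format_residue_key(key), "displacement": disp})
    return pd.DataFrame(rows), ref_rmsd
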