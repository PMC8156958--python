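"""Synthetic trajectories with planted, machine-readable ground truth.

The generator is phenomenological, not physical MD: what the analyses need is
*known truth*, not realism.  It emits a bead model of a lipoxygenase-like
system — two surface entrances (E1, E3), two interior binding sites (S1, S2),
a catalytic pocket (CAT) holding an iron bead and a short substrate chain with
tagged C13/C15 carbons — plus diatomic gas ligands (rigid 1.2 Å bond) that
follow scripted plans:

* free segments are a reflecting-wall random walk kept ≥ 9 Å away from every
  protein/substrate atom, so no contact (3.5 Å) or proximity (7.5 Å) criterion
  can fire accidentally;
* planted segments pin the molecule's centre to a site anchor (2.5–2.8 Å from
  the nearest site bead, inside the 3.5 Å contact shell with margin to spare)
  or to a proximity anchor near C15, with isotropic positional jitter;
* transitions between segments are instantaneous (the walk teleports), which
  keeps every planted interval frame-exact.

Every planted dwell, entrance label, displacement event and competent-pose
frame is recorded in a :class:`GroundTruth` object and, through
:func:`write_fixture_bundle`, in plain-text fixture files.  The same seed
always reproduces the same bundle byte for byte.

Gas-mixture presets follow the simulated study conditions: O2:NO ratios of
1:1 (five of each), 1:3 and 3:1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .errors import InputError
from .model_io import (Atom, LigandInstance, ReferenceAtoms, Species, Structure,
                       Trajectory, write_structure, write_text_trajectory,
                       write_dcd_trajectory)
from .site_occupancy import SiteDefinition, save_site_catalog
from .catalogs import REFERENCE_SITE_RESIDUES, _ONE_TO_THREE, _res

__all__ = [
    "SystemGeometry",
    "Plant",
    "LigandPlan",
    "DwellModel",
    "SyntheticSystemSpec",
    "GroundTruth",
    "SyntheticSystem",
    "ratio_counts",
    "build_protein_model",
    "default_system_spec",
    "dwell_sampling_spec",
    "displacement_scenario_specs",
    "simulate_gas_trajectory",
    "write_fixture_bundle",
    "read_fixture_bundle",
]

GAS_BOND_LENGTH = 1.2  # Å, rigid diatomic


# ---------------------------------------------------------------------------
# geometry / protein model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SystemGeometry:
    """Bead-model layout; offsets are relative to the box centre, in Å."""

    box: tuple = (80.0, 80.0, 80.0)
    pocket_radius: float = 4.0       # CAT beads' distance from the iron
    site_ring_radius: float = 2.5    # bead ring radius of E1/E3/S1/S2
    min_site_separation: float = 8.0
    e1_offset: tuple = (0.0, 0.0, 30.0)
    e3_offset: tuple = (0.0, 24.0, 16.0)
    s1_offset: tuple = (0.0, 0.0, 15.0)
    s2_offset: tuple = (0.0, 15.0, 8.0)


# site -> residues of the shipped reference catalog used for the bead model
_MODEL_SITE_RESIDUES = {
    "E1": REFERENCE_SITE_RESIDUES["E1"][1],
    "E3": REFERENCE_SITE_RESIDUES["E3"][1],
    "S1": REFERENCE_SITE_RESIDUES["S1"][1],
    "S2": REFERENCE_SITE_RESIDUES["S2"][1],
    "CAT": REFERENCE_SITE_RESIDUES["CAT"][1],
}
_MODEL_SITE_ROLES = {"E1": "entrance", "E3": "entrance", "S1": "binding",
                     "S2": "binding", "CAT": "catalytic"}

# substrate sn-2 chain beads (name -> offset from centre); C13/C15 are the
# tagged carbons, C13 sits 6.15 Å from the iron, well inside the 7.5 Å shell
_SUBSTRATE_BEADS = {
    "C11": (-9.3, 0.4, 0.0),
    "C12": (-7.7, 0.9, 0.0),
    "C13": (-6.1, 0.8, 0.0),
    "C14": (-5.3, 0.4, 0.0),
    "C15": (-4.5, 0.0, 0.0),
    "C16": (-4.9, -0.9, 0.8),
    "C17": (-5.7, -1.4, 1.4),
    "C18": (-6.9, -1.7, 2.0),
}

#: during a substrate excursion C13 is shifted by this offset, putting it
#: ~9.3 Å from the iron (outside the competence shell)
_C13_EXCURSION_SHIFT = np.array([-3.5, 0.5, 0.0])


@dataclass
class ProteinModel:
    structure: Structure
    catalog: dict
    refs: ReferenceAtoms
    anchors: dict  # name -> centre-point (3,) for planted segments
    site_centroids: dict


def _ring(center: np.ndarray, radius: float, n: int) -> np.ndarray:
    ang = 2 * np.pi * np.arange(n) / n
    pts = np.stack([radius * np.cos(ang), radius * np.sin(ang), np.zeros(n)], axis=1)
    return center[None, :] + pts


def build_protein_model(geometry: SystemGeometry = SystemGeometry()) -> ProteinModel:
    """Build the static bead structure, its site catalog and reference atoms."""
    if geometry.pocket_radius <= 0:
        raise InputError("pocket_radius must be positive")
    if geometry.site_ring_radius <= 0:
        raise InputError("site_ring_radius must be positive")
    center = np.asarray(geometry.box, dtype=float) / 2.0
    atoms: list[Atom] = []
    next_id = 1
    site_positions: dict[str, np.ndarray] = {}

    def add_bead(name, element, resnum, resname, pos):
        nonlocal next_id
        atoms.append(Atom(next_id, name, element, resnum, resname, "A",
                          np.asarray(pos, dtype=float)))
        next_id += 1
        return next_id - 1

    ring_layouts = {
        "E1": np.asarray(geometry.e1_offset),
        "E3": np.asarray(geometry.e3_offset),
        "S1": np.asarray(geometry.s1_offset),
        "S2": np.asarray(geometry.s2_offset),
    }
    centroids = {}
    for site, offset in ring_layouts.items():
        codes = _MODEL_SITE_RESIDUES[site]
        pts = _ring(center + offset, geometry.site_ring_radius, len(codes))
        for code, pos in zip(codes, pts):
            add_bead("CA", "C", int(code[1:]), _ONE_TO_THREE[code[0]], pos)
        centroids[site] = center + offset
        site_positions[site] = pts

    # catalytic pocket: 4 beads around the iron, substrate chain on the -x side
    r = geometry.pocket_radius
    cat_offsets = [(r, 0, 0), (0, r, 0), (0, 0, r), (0, -r, 0)]
    cat_codes = _MODEL_SITE_RESIDUES["CAT"]
    cat_pts = []
    for code, off in zip(cat_codes, cat_offsets):
        pos = center + np.asarray(off, dtype=float)
        add_bead("CA", "C", int(code[1:]), _ONE_TO_THREE[code[0]], pos)
        cat_pts.append(pos)
    centroids["CAT"] = np.mean(cat_pts, axis=0)

    fe_id = add_bead("FE", "Fe", 700, "FE", center)
    substrate_ids = []
    c13_id = c15_id = None
    for name, off in _SUBSTRATE_BEADS.items():
        aid = add_bead(name, "C", 690, "SPE", center + np.asarray(off))
        substrate_ids.append(aid)
        if name == "C13":
            c13_id = aid
        elif name == "C15":
            c15_id = aid

    names = list(centroids)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            sep = float(np.linalg.norm(centroids[a] - centroids[b]))
            if sep < geometry.min_site_separation:
                raise InputError(
                    f"degenerate geometry: sites {a} and {b} overlap "
                    f"(centroid separation {sep:.2f} Å)"
                )

    catalog = {
        name: SiteDefinition(
            name=name, role=_MODEL_SITE_ROLES[name],
            residue_keys=frozenset(_res(c) for c in _MODEL_SITE_RESIDUES[name]),
        )
        for name in _MODEL_SITE_RESIDUES
    }
    anchors = {name: centroids[name].copy() for name in ("E1", "E3", "S1", "S2")}
    # CAT anchor: 2.6 Å outside the +x catalytic bead, 11 Å from C15 so a
    # CAT dwell never satisfies the 7.5 Å C15-proximity criterion
    anchors["CAT"] = center + np.array([r + 2.6, 0.0, 0.0])
    # C15 proximity anchor: 2.8 Å beyond the C15 bead, away from CAT beads
    anchors["C15"] = center + np.asarray(_SUBSTRATE_BEADS["C15"]) + np.array([-2.8, 0.0, 0.0])

    structure = Structure(atoms, title="synthetic gas-channel bead model")
    refs = ReferenceAtoms(fe_atom_id=fe_id, c13_atom_id=c13_id, c15_atom_id=c15_id,
                          substrate_atom_ids=tuple(substrate_ids))
    return ProteinModel(structure=structure, catalog=catalog, refs=refs,
                        anchors=anchors, site_centroids=centroids)


# ---------------------------------------------------------------------------
# plans and specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Plant:
    """One scripted segment: a site dwell (contact) or target proximity."""

    kind: str  # "site" | "proximity"
    name: str  # site name, or target name (only "C15" is wired)
    start_frame: int
    end_frame: int  # inclusive

    def __post_init__(self):
        if self.kind not in ("site", "proximity"):
            raise InputError(f"unknown plant kind {self.kind!r}")
        if self.start_frame > self.end_frame or self.start_frame < 0:
            raise InputError("plant frames out of order")


@dataclass(frozen=True)
class LigandPlan:
    species: Species
    plants: tuple = ()
    entrance: str = "none"  # planted entrance label, for ground truth


@dataclass(frozen=True)
class DwellModel:
    """Repeated random dwells in one site: exponential dwell and gap times.

    Each ligand is scripted with a *fixed* number of dwells (``n_dwells``), so
    the pooled dwell sample is i.i.d. exponential; planning dwells into a
    fixed time window instead would over-represent short dwells (ligands that
    draw short dwells fit more of them)."""

    site: str = "S1"
    mean_dwell: float = 10.0  # ns
    mean_gap: float = 2.0     # ns
    min_gap: float = 1.0      # ns; keeps distinct dwells beyond the merge gap
    n_dwells: int = 7         # dwells planted per ligand


@dataclass(frozen=True)
class SyntheticSystemSpec:
    """Full description of one synthetic run; ``seed`` is mandatory and is the
    only source of randomness."""

    seed: int
    geometry: SystemGeometry = SystemGeometry()
    n_o2: int = 5
    n_no: int = 5
    run_length: float = 150.0     # ns
    frame_interval: float = 0.1   # ns per frame
    jitter: float = 0.3           # Å, anchor jitter during planted segments
    step_sigma: float = 0.8       # Å per frame, free-walk step
    exclusion_radius: float = 9.0 # Å, free-walk clearance from the structure
    periodic: bool = False
    plans: Optional[tuple] = None            # tuple[LigandPlan]; scripted
    dwell_model: Optional[DwellModel] = None # random dwell cycling
    substrate_excursions: tuple = ()         # ((start_frame, end_frame), ...)
    planted_displacements: tuple = ()        # ((displaced, displacer, overlap_f, disp_f), ...)

    def __post_init__(self):
        if self.n_o2 < 0 or self.n_no < 0:
            raise InputError("ligand counts must be non-negative")
        n = self.run_length / self.frame_interval
        if abs(n - round(n)) > 1e-6:
            raise InputError("run_length must be an integer number of frames")

    @property
    def n_frames(self) -> int:
        return int(round(self.run_length / self.frame_interval))


def ratio_counts(preset: str, base: int = 5) -> tuple:
    """O2/NO counts for the mixture presets 1:1 (five of each), 1:3, 3:1."""
    ratios = {"1:1": (1, 1), "1:3": (1, 3), "3:1": (3, 1)}
    if preset not in ratios:
        raise InputError(f"unknown ratio preset {preset!r}")
    a, b = ratios[preset]
    return (base * a, base * b)


@dataclass
class GroundTruth:
    """Everything the generator planted, in frame units."""

    dwells: list = field(default_factory=list)        # (label, site, start, end)
    proximity: list = field(default_factory=list)     # (label, target, start, end)
    entrances: dict = field(default_factory=dict)     # label -> E1|E3|none
    displacements: list = field(default_factory=list) # (displaced, displacer, overlap_f, disp_f)
    competent_frames: dict = field(default_factory=dict)  # o2 label -> tuple of frames

    @property
    def n_competent_poses(self) -> int:
        return sum(len(v) for v in self.competent_frames.values())


@dataclass
class SyntheticSystem:
    spec: SyntheticSystemSpec
    structure: Structure
    trajectory: Trajectory
    catalog: dict
    refs: ReferenceAtoms
    ligands: list
    truth: GroundTruth
    anchors: dict


# ---------------------------------------------------------------------------
# spec builders
# ---------------------------------------------------------------------------

def _f(t_ns: float, fi: float) -> int:
    return int(round(t_ns / fi))


def default_system_spec(seed: int, ratio: str = "1:1") -> SyntheticSystemSpec:
    """The default showcase bundle: 150 ns at 0.1 ns/frame, gas mixture per
    ``ratio``, with planted entrance routes (E1 and E3), a 70 ns S1 dwell, a
    35 ns S2 dwell, and one scripted displacement at the C15 position —
    an O2 in the pocket from 43 ns, the NO arriving at 74 ns, the O2 leaving
    for good at 145 ns of the 150 ns run."""
    n_o2, n_no = ratio_counts(ratio)
    fi = 0.1
    plans = []

    def site(name, t0, t1):
        return Plant("site", name, _f(t0, fi), _f(t1, fi) - 1)

    def prox(t0, t1):
        return Plant("proximity", "C15", _f(t0, fi), _f(t1, fi) - 1)

    # O2 #1: E1 route with the long S1 dwell (70 ns) and a catalytic visit
    plans.append(LigandPlan(Species.O2, (site("E1", 10, 15), site("S1", 20, 90),
                                         site("CAT", 95, 120)), entrance="E1"))
    # O2 #2: E1 route, then the C15 pocket position from 43 ns until displaced
    # at 145 ns (the scripted competition narrative)
    plans.append(LigandPlan(Species.O2, (site("E1", 30, 35), site("CAT", 38, 42),
                                         prox(43, 145)), entrance="E1"))
    # O2 #3: a plain S2 visitor, never catalytic
    plans.append(LigandPlan(Species.O2, (site("S2", 100, 120),), entrance="none"))
    # NO #1: E3 route with the 35 ns S2 dwell and a catalytic visit
    plans.append(LigandPlan(Species.NO, (site("E3", 5, 10), site("S2", 15, 50),
                                         site("CAT", 55, 70)), entrance="E3"))
    # NO #2: E3 route, arrives near C15 at 74 ns and stays to the end
    plans.append(LigandPlan(Species.NO, (site("E3", 60, 65), site("CAT", 68, 72),
                                         prox(74, 150)), entrance="E3"))
    # NO #3: a plain S1 visitor
    plans.append(LigandPlan(Species.NO, (site("S1", 110, 125),), entrance="none"))
    # remaining ligands diffuse freely
    for _ in range(n_o2 - 3):
        plans.append(LigandPlan(Species.O2))
    for _ in range(n_no - 3):
        plans.append(LigandPlan(Species.NO))
    plans.sort(key=lambda p: 0 if p.species is Species.O2 else 1)
    displacement = (("OXY_702", "NO_802", _f(74, fi), _f(145, fi)),)
    return SyntheticSystemSpec(seed=seed, n_o2=n_o2, n_no=n_no, run_length=150.0,
                               frame_interval=fi, plans=tuple(plans),
                               planted_displacements=displacement)


def dwell_sampling_spec(seed: int, n_ligands: int = 80, mean_dwell: float = 10.0,
                        mean_gap: float = 2.0, run_length: float = 150.0,
                        frame_interval: float = 0.1,
                        site: str = "S1") -> SyntheticSystemSpec:
    """Spec for dwell-statistics recovery: every ligand cycles through
    exponential dwells (mean ``mean_dwell`` ns) in one site."""
    n_o2 = n_ligands // 2
    return SyntheticSystemSpec(
        seed=seed, n_o2=n_o2, n_no=n_ligands - n_o2,
        run_length=run_length, frame_interval=frame_interval,
        dwell_model=DwellModel(site=site, mean_dwell=mean_dwell, mean_gap=mean_gap),
    )


def displacement_scenario_specs(n_events: int, seed: int,
                                jitter: float = 0.3) -> list:
    """Specs planting ``n_events`` displacement events at the C15 position,
    ten per 150 ns run, using a rotating pool of two O2 and two NO ligands."""
    fi = 0.1
    per_run = 10
    n_runs = math.ceil(n_events / per_run)
    specs = []
    for r in range(n_runs):
        k_events = min(per_run, n_events - r * per_run)
        pool = ["OXY_701", "OXY_702", "NO_801", "NO_802"]
        plants: dict[str, list] = {label: [] for label in pool}
        planted = []
        for k in range(k_events):
            t0 = 2.0 + 14.0 * k
            a = pool[k % 4]
            b = pool[(k + 1) % 4]
            plants[a].append(Plant("proximity", "C15", _f(t0, fi), _f(t0 + 8, fi) - 1))
            plants[b].append(Plant("proximity", "C15", _f(t0 + 6, fi), _f(t0 + 10, fi) - 1))
            planted.append((a, b, _f(t0 + 6, fi), _f(t0 + 8, fi)))
        plans = (
            LigandPlan(Species.O2, tuple(plants["OXY_701"])),
            LigandPlan(Species.O2, tuple(plants["OXY_702"])),
            LigandPlan(Species.NO, tuple(plants["NO_801"])),
            LigandPlan(Species.NO, tuple(plants["NO_802"])),
        )
        specs.append(
            SyntheticSystemSpec(seed=seed + r, n_o2=2, n_no=2, run_length=150.0,
                                frame_interval=fi, jitter=jitter,
                                plans=plans, planted_displacements=tuple(planted))
        )
    return specs


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def _random_dwell_plans(spec: SyntheticSystemSpec, rng: np.random.Generator):
    """Generate fixed-count dwell plans from the spec's DwellModel.

    Every ligand draws exactly ``n_dwells`` exponential dwell lengths up
    front (an i.i.d. sample, free of the length bias that time-window
    planning would introduce).  If the drawn dwells plus their gaps exceed
    the run, gaps are first compressed to ``min_gap``; in the rare remaining
    overflow the ligand's trailing dwells are dropped."""
    dm = spec.dwell_model
    fi = spec.frame_interval
    n = spec.n_frames
    min_gap_frames = max(1, _f(dm.min_gap, fi))
    plans = []
    species_seq = [Species.O2] * spec.n_o2 + [Species.NO] * spec.n_no
    for sp in species_seq:
        dwell_frames = [max(1, int(round(rng.exponential(dm.mean_dwell) / fi)))
                        for _ in range(dm.n_dwells)]
        gap_frames = [min_gap_frames + _f(rng.exponential(dm.mean_gap), fi)
                      for _ in range(dm.n_dwells)]
        while dwell_frames and \
                sum(dwell_frames) + sum(min_gap_frames for _ in dwell_frames) > n - 2:
            dwell_frames.pop()
            gap_frames.pop()
        if sum(dwell_frames) + sum(gap_frames) > n - 2:
            gap_frames = [min_gap_frames] * len(dwell_frames)
        plants = []
        t_frame = 0
        for dw, gap in zip(dwell_frames, gap_frames):
            start = t_frame + gap
            end = start + dw - 1
            plants.append(Plant("site", dm.site, start, end))
            t_frame = end + 1
        plans.append(LigandPlan(sp, tuple(plants)))
    return tuple(plans)


def _validate_plans(plans, spec: SyntheticSystemSpec):
    if len(plans) != spec.n_o2 + spec.n_no:
        raise InputError("plan count does not match ligand counts")
    n_o2 = sum(1 for p in plans if p.species is Species.O2)
    if n_o2 != spec.n_o2:
        raise InputError("plan species do not match the spec's O2/NO counts")
    for plan in plans:
        last_end = -1
        for pl in sorted(plan.plants, key=lambda p: p.start_frame):
            if pl.start_frame <= last_end:
                raise InputError("infeasible script: overlapping plants for one ligand")
            if pl.end_frame >= spec.n_frames:
                raise InputError("plant extends beyond the trajectory")
            last_end = pl.end_frame


def _ligand_labels(plans) -> list:
    labels = []
    n_oxy = 0
    n_no = 0
    for plan in plans:
        if plan.species is Species.O2:
            n_oxy += 1
            labels.append(f"OXY_{700 + n_oxy}")
        else:
            n_no += 1
            labels.append(f"NO_{800 + n_no}")
    return labels


def _jitter_point(rng: np.random.Generator, radius: float) -> np.ndarray:
    if radius <= 0:
        return np.zeros(3)
    v = rng.normal(size=3)
    v /= np.linalg.norm(v)
    return v * radius * rng.random() ** (1.0 / 3.0)


def _random_orientation(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _free_point(rng, box, struct_coords, clearance):
    for _ in range(10000):
        p = rng.uniform(low=2.0, high=np.asarray(box) - 2.0)
        if np.min(np.linalg.norm(struct_coords - p, axis=1)) >= clearance:
            return p
    raise InputError("cannot place a free gas particle; box too crowded")


def simulate_gas_trajectory(spec: SyntheticSystemSpec, validate: bool = True) -> SyntheticSystem:
    """Generate the scripted trajectory and its ground truth.

    Identical specs (including the seed) produce bit-identical output.  With
    ``validate`` the planted script is spot-replayed against the emitted
    coordinates at generation time.
    """
    rng = np.random.default_rng(spec.seed)
    model = build_protein_model(spec.geometry)
    n_struct = model.structure.n_atoms
    n_frames = spec.n_frames
    fi = spec.frame_interval
    box = np.asarray(spec.geometry.box, dtype=float)

    if spec.plans is not None:
        plans = tuple(spec.plans)
    elif spec.dwell_model is not None:
        plans = _random_dwell_plans(spec, rng)
    else:
        plans = tuple(
            [LigandPlan(Species.O2)] * spec.n_o2 + [LigandPlan(Species.NO)] * spec.n_no
        )
    _validate_plans(plans, spec)
    labels = _ligand_labels(plans)

    # assemble the full structure: protein + substrate beads, then gas atoms
    atoms = list(model.structure.atoms)
    next_id = max(a.atom_id for a in atoms) + 1
    lig_atom_rows = []
    for label, plan in zip(labels, plans):
        resname, num = label.split("_")
        if plan.species is Species.O2:
            names_elems = (("O1", "O"), ("O2", "O"))
        else:
            names_elems = (("N", "N"), ("O", "O"))
        rows = []
        for name, elem in names_elems:
            atoms.append(Atom(next_id, name, elem, int(num), resname, "G",
                              np.zeros(3)))
            rows.append(len(atoms) - 1)
            next_id += 1
        lig_atom_rows.append(rows)

    struct_coords = model.structure.coords
    coords = np.empty((n_frames, len(atoms), 3), dtype=float)
    coords[:, :n_struct, :] = struct_coords[None, :, :]

    # substrate excursions move C13 out of the iron's competence shell
    c13_row = model.structure.atom_index(model.refs.c13_atom_id)
    excursion_mask = np.zeros(n_frames, dtype=bool)
    for s, e in spec.substrate_excursions:
        excursion_mask[s:e + 1] = True
    coords[excursion_mask, c13_row, :] += _C13_EXCURSION_SHIFT

    # per-ligand frame scripts: anchor name per frame, or None (free)
    truth = GroundTruth()
    for label, plan in zip(labels, plans):
        truth.entrances[label] = plan.entrance
        for pl in plan.plants:
            if pl.kind == "site":
                truth.dwells.append((label, pl.name, pl.start_frame, pl.end_frame))
            else:
                truth.proximity.append((label, pl.name, pl.start_frame, pl.end_frame))
    truth.displacements = list(spec.planted_displacements)

    # competent poses: O2 at the C15 anchor while C13 is inside the Fe shell
    for label, plan in zip(labels, plans):
        if plan.species is not Species.O2:
            continue
        frames = []
        for pl in plan.plants:
            if pl.kind == "proximity" and pl.name == "C15":
                fr = np.arange(pl.start_frame, pl.end_frame + 1)
                frames.extend(fr[~excursion_mask[fr]].tolist())
        if frames:
            truth.competent_frames[label] = tuple(sorted(frames))

    clearance = spec.exclusion_radius
    for (label, plan), rows in zip(zip(labels, plans), lig_atom_rows):
        anchor_by_frame: list = [None] * n_frames
        for pl in plan.plants:
            name = pl.name if pl.kind == "site" else pl.name  # anchor key
            for f in range(pl.start_frame, pl.end_frame + 1):
                anchor_by_frame[f] = name
        center = None
        for f in range(n_frames):
            a = anchor_by_frame[f]
            if a is not None:
                center = model.anchors[a] + _jitter_point(rng, spec.jitter)
                fresh = True
            else:
                if f == 0 or anchor_by_frame[f - 1] is not None or center is None:
                    center = _free_point(rng, box, struct_coords, clearance + 3.0)
                else:
                    step = rng.normal(scale=spec.step_sigma, size=3)
                    cand = center + step
                    if spec.periodic:
                        cand = np.mod(cand, box)
                    else:
                        cand = np.clip(cand, 1.0, box - 1.0)
                    if np.min(np.linalg.norm(struct_coords - cand, axis=1)) >= clearance:
                        center = cand
                    # else: rejected step, stay put
            u = _random_orientation(rng)
            half = 0.5 * GAS_BOND_LENGTH
            coords[f, rows[0]] = center + half * u
            coords[f, rows[1]] = center - half * u

    structure = Structure(
        [a if i < n_struct else Atom(a.atom_id, a.name, a.element, a.residue_number,
                                     a.residue_name, a.chain_id, coords[0, i].copy())
         for i, a in enumerate(atoms)],
        title=model.structure.title,
    )
    trajectory = Trajectory(coords, frame_interval=fi,
                            box=box if spec.periodic else None)
    ligands = [
        LigandInstance(label=label, species=plan.species,
                       atom_ids=tuple(atoms[r].atom_id for r in rows))
        for (label, plan), rows in zip(zip(labels, plans), lig_atom_rows)
    ]
    system = SyntheticSystem(spec=spec, structure=structure, trajectory=trajectory,
                             catalog=model.catalog, refs=model.refs,
                             ligands=ligands, truth=truth, anchors=model.anchors)
    if validate:
        _spot_check(system)
    return system


def _spot_check(system: SyntheticSystem) -> None:
    """Replay the script endpoints against the emitted coordinates."""
    from .geometry import min_distance

    struct = system.structure
    coords = system.trajectory.coordinates
    lig_rows = {l.label: l.atom_indices(struct) for l in system.ligands}
    for label, site, s, e in system.truth.dwells:
        site_idx = np.concatenate([
            struct.residue_atom_indices(k) for k in system.catalog[site].residue_keys
        ])
        for f in (s, e):
            d = min_distance(coords[f, lig_rows[label]], coords[f, site_idx])
            if d >= 3.5:
                raise InputError(
                    f"plant validation failed: {label} not in contact with {site} "
                    f"at frame {f} (min distance {d:.2f} Å)"
                )
    c15_row = struct.atom_index(system.refs.c15_atom_id)
    for label, target, s, e in system.truth.proximity:
        for f in (s, e):
            d = min_distance(coords[f, lig_rows[label]], coords[f, [c15_row]])
            if d > 7.5:
                raise InputError(
                    f"plant validation failed: {label} not within 7.5 Å of C15 "
                    f"at frame {f} (distance {d:.2f} Å)"
                )


# ---------------------------------------------------------------------------
# fixture bundle I/O
# ---------------------------------------------------------------------------

def write_fixture_bundle(system: SyntheticSystem, directory, dcd: bool = True) -> dict:
    """Write the bundle: structure (PDB + text), trajectory (text, optionally
    DCD), site catalog, reference atoms, ground-truth TSVs and a ready
    pipeline config.  Returns the path map."""
    import yaml

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "structure_pdb": directory / "structure.pdb",
        "structure_text": directory / "structure.txt",
        "trajectory_text": directory / "trajectory.txt",
        "sites": directory / "sites.yaml",
        "reference_atoms": directory / "reference_atoms.yaml",
        "spec": directory / "spec.yaml",
        "config": directory / "config.yaml",
        "truth_dwells": directory / "truth_dwells.tsv",
        "truth_proximity": directory / "truth_proximity.tsv",
        "truth_entrances": directory / "truth_entrances.tsv",
        "truth_displacements": directory / "truth_displacements.tsv",
        "truth_competent_frames": directory / "truth_competent_frames.tsv",
    }
    write_structure(system.structure, paths["structure_pdb"], format="pdb")
    write_structure(system.structure, paths["structure_text"], format="text")
    write_text_trajectory(system.trajectory, system.structure, paths["trajectory_text"])
    if dcd:
        paths["trajectory_dcd"] = directory / "trajectory.dcd"
        write_dcd_trajectory(system.trajectory, paths["trajectory_dcd"])
    save_site_catalog(system.catalog, paths["sites"])
    refs = system.refs
    with open(paths["reference_atoms"], "w") as fh:
        yaml.safe_dump(
            {
                "fe": refs.fe_atom_id,
                "c13": refs.c13_atom_id,
                "c15": refs.c15_atom_id,
                "substrate": list(refs.substrate_atom_ids or ()),
            },
            fh, sort_keys=True,
        )
    spec = system.spec
    with open(paths["spec"], "w") as fh:
        yaml.safe_dump(
            {
                "seed": spec.seed,
                "n_o2": spec.n_o2,
                "n_no": spec.n_no,
                "run_length_ns": spec.run_length,
                "frame_interval_ns": spec.frame_interval,
                "jitter_A": spec.jitter,
                "periodic": spec.periodic,
                "box_A": list(spec.geometry.box),
            },
            fh, sort_keys=True,
        )
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(
            {
                "structure": "structure.pdb",
                "trajectories": ["trajectory.txt"],
                "site_catalog": "sites.yaml",
                "reference_atoms": "reference_atoms.yaml",
                "frame_interval": spec.frame_interval,
                "output_dir": "analysis",
            },
            fh, sort_keys=True,
        )
    truth = system.truth
    with open(paths["truth_dwells"], "w") as fh:
        fh.write("ligand\tsite\tstart_frame\tend_frame\n")
        for row in truth.dwells:
            fh.write("\t".join(str(x) for x in row) + "\n")
    with open(paths["truth_proximity"], "w") as fh:
        fh.write("ligand\ttarget\tstart_frame\tend_frame\n")
        for row in truth.proximity:
            fh.write("\t".join(str(x) for x in row) + "\n")
    with open(paths["truth_entrances"], "w") as fh:
        fh.write("ligand\tentrance\n")
        for label in sorted(truth.entrances):
            fh.write(f"{label}\t{truth.entrances[label]}\n")
    with open(paths["truth_displacements"], "w") as fh:
        fh.write("displaced\tdisplacer\toverlap_frame\tdisplacement_frame\n")
        for row in truth.displacements:
            fh.write("\t".join(str(x) for x in row) + "\n")
    with open(paths["truth_competent_frames"], "w") as fh:
        fh.write("ligand\tframe\n")
        for label in sorted(truth.competent_frames):
            for f in truth.competent_frames[label]:
                fh.write(f"{label}\t{f}\n")
    return paths


def read_fixture_bundle(directory):
    """Load a written bundle back: (structure, trajectory, catalog, refs, truth)."""
    import yaml

    from .model_io import load_structure, load_trajectory
    from .site_occupancy import load_site_catalog

    directory = Path(directory)
    structure = load_structure(directory / "structure.txt", format="text")
    trajectory = load_trajectory(directory / "trajectory.txt", structure, format="text")
    catalog = load_site_catalog(directory / "sites.yaml")
    with open(directory / "reference_atoms.yaml") as fh:
        r = yaml.safe_load(fh)
    refs = ReferenceAtoms(fe_atom_id=r["fe"], c13_atom_id=r.get("c13"),
                          c15_atom_id=r.get("c15"),
                          substrate_atom_ids=tuple(r.get("substrate") or ()))
    truth = GroundTruth()
    with open(directory / "truth_dwells.tsv") as fh:
        next(fh)
        for line in fh:
            lab, site, s, e = line.split()
            truth.dwells.append((lab, site, int(s), int(e)))
    with open(directory / "truth_proximity.tsv") as fh:
        next(fh)
        for line in fh:
            lab, tgt, s, e = line.split()
            truth.proximity.append((lab, tgt, int(s), int(e)))
    with open(directory / "truth_entrances.tsv") as fh:
        next(fh)
        for line in fh:
            lab, ent = line.split()
            truth.entrances[lab] = ent
    with open(directory / "truth_displacements.tsv") as fh:
        next(fh)
        for line in fh:
            a, b, o, d = line.split()
            truth.displacements.append((a, b, int(o), int(d)))
    comp: dict[str, list] = {}
    with open(directory / "truth_competent_frames.tsv") as fh:
        next(fh)
        for line in fh:
            lab, f = line.split()
            comp.setdefault(lab, []).append(int(f))
    truth.competent_frames = {k: tuple(v) for k, v in comp.items()}
    return structure, trajectory, catalog, refs, truth
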