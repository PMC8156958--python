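"""Catalytically competent poses and substrate-coordination profiles.

Peroxidation of the esterified arachidonoyl chain requires a specific
geometry: an O2 molecule within 7.5 Å of the substrate carbon C15 while the
substrate carbon C13 is within 7.5 Å of the catalytic iron.  Both conditions
are strict (<).  A *pose* is one (frame, O2 instance) pair satisfying both;
several O2 molecules in one frame count as several poses.

The coordination profile reports, over a frame selection (by default the
competent-pose frames), the probability that each candidate residue contacts
the substrate — the number of contact frames divided by the number of
selected frames.  Candidates may span chains, so residues of a partner
protein appear in the same profile as the enzyme's own.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import AnalysisError
from .contact_analysis import _min_dist_per_frame, contact_probability
from .model_io import LigandInstance, ReferenceAtoms, Species, Structure, Trajectory

__all__ = [
    "CompetentPose",
    "CoordinationProfile",
    "competent_poses",
    "competent_frames",
    "coordination_profile",
]

DEFAULT_POSE_THRESHOLD = 7.5  # Å, strict <
DEFAULT_REPORT_THRESHOLD = 0.70


@dataclass(frozen=True)
class CompetentPose:
    frame_index: int
    o2_label: str
    d_o2_c15: float
    d_c13_fe: float


@dataclass
class CoordinationProfile:
    probabilities: dict  # residue key -> probability in [0, 1]
    n_selected_frames: int
    source: str  # "competent-pose frames" | "custom selection"
    highlighted: tuple = ()  # residues at/above the report threshold


def competent_poses(traj: Trajectory, structure: Structure, refs: ReferenceAtoms,
                    ligands: Sequence[LigandInstance],
                    threshold: float = DEFAULT_POSE_THRESHOLD) -> list:
    """All (frame, O2) poses with d(O2, C15) < threshold and d(C13, Fe) < threshold.

    ``ligands`` may contain any species; only O2 instances are considered, and
    at least one must be present.  O2-to-C15 distance uses the nearer of the
    molecule's two atoms.
    """
    if refs.c13_atom_id is None or refs.c15_atom_id is None:
        raise AnalysisError("competent_poses requires C13 and C15 reference atoms")
    refs.validate(structure)
    o2 = [l for l in ligands if l.species is Species.O2]
    if not o2:
        raise AnalysisError("competent_poses requires at least one O2 instance")
    fe_idx = np.asarray([structure.atom_index(refs.fe_atom_id)])
    c13_idx = np.asarray([structure.atom_index(refs.c13_atom_id)])
    c15_idx = np.asarray([structure.atom_index(refs.c15_atom_id)])
    d_c13_fe = _min_dist_per_frame(traj.coordinates, c13_idx, fe_idx, box=traj.box)
    poses = []
    for lig in o2:
        l_idx = lig.atom_indices(structure)
        d_o2_c15 = _min_dist_per_frame(traj.coordinates, l_idx, c15_idx, box=traj.box)
        ok = (d_o2_c15 < threshold) & (d_c13_fe < threshold)
        for f in np.flatnonzero(ok):
            poses.append(
                CompetentPose(int(f), lig.label, float(d_o2_c15[f]), float(d_c13_fe[f]))
            )
    poses.sort(key=lambda p: (p.frame_index, p.o2_label))
    return poses


def competent_frames(poses: Sequence[CompetentPose]) -> list:
    """Sorted unique frame indices covered by a pose list."""
    return sorted({p.frame_index for p in poses})


def coordination_profile(traj: Trajectory, structure: Structure,
                         selected_frames: Sequence[int],
                         substrate_atom_ids: Sequence[int],
                         candidate_residues: Sequence,
                         cutoff: float = 3.5,
                         report_threshold: float = DEFAULT_REPORT_THRESHOLD,
                         source: str = "custom selection") -> CoordinationProfile:
    """Substrate-contact probability per candidate residue over a frame
    selection.  Residues with probability ≥ ``report_threshold`` are flagged
    in ``highlighted``."""
    probs = contact_probability(traj, structure, selected_frames,
                                substrate_atom_ids, candidate_residues, cutoff=cutoff)
    highlighted = tuple(sorted(
        (k for k, p in probs.items() if p >= report_threshold),
        key=lambda k: (k[0], k[1]),
    ))
    return CoordinationProfile(
        probabilities=probs,
        n_selected_frames=len(list(selected_frames)),
        source=source,
        highlighted=highlighted,
    )
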