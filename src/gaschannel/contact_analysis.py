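"""Ligand–residue contact timelines, residence times and contact probabilities.

A contact is geometric: any heavy-atom pair between the ligand and a residue
at distance strictly below the cutoff (default 3.5 Å).  Residence is measured
in ns as (number of contact frames) × frame interval.  The frequent-contact
filter keeps residues whose cumulative contact time reaches a threshold
(default 2.5 ns, boundary inclusive).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .errors import AnalysisError
from .geometry import pairwise_distances
from .model_io import LigandInstance, ResidueKey, Structure, Trajectory

__all__ = [
    "ContactTimeline",
    "ContactSummary",
    "contact_matrix",
    "contact_timeline",
    "cumulative_contact_time",
    "summarize_contacts",
    "frequent_contact_residues",
    "contact_probability",
]

DEFAULT_CONTACT_CUTOFF = 3.5  # Å, strict <
DEFAULT_FREQUENT_THRESHOLD = 2.5  # ns, inclusive >=


@dataclass
class ContactTimeline:
    """Boolean per-frame contact series between one ligand and one residue."""

    ligand_label: str
    residue_key: ResidueKey
    contact: np.ndarray  # bool, length n_frames
    frame_interval: float
    min_distance: Optional[np.ndarray] = None  # Å per frame

    @property
    def n_frames(self) -> int:
        return len(self.contact)


@dataclass
class ContactSummary:
    """Residence-time aggregate for one residue, possibly across runs.

    ``cumulative_time`` is the largest per-run cumulative contact time (so it
    is always bounded by one run length); ``per_run`` holds every run's
    cumulative time; ``n_runs_observed`` counts runs in which the residue
    reached the frequent-contact threshold used during summarisation.
    """

    residue_key: ResidueKey
    cumulative_time: float
    n_runs_observed: int
    per_run: tuple = ()


def _min_dist_per_frame(coords: np.ndarray, a_idx: np.ndarray, b_idx: np.ndarray,
                        box=None) -> np.ndarray:
    """Min over atom pairs of distances, per frame: coords (F, N, 3) -> (F,)."""
    a = coords[:, a_idx, :]  # (F, na, 3)
    b = coords[:, b_idx, :]  # (F, nb, 3)
    diff = a[:, :, None, :] - b[:, None, :, :]
    if box is not None:
        bx = np.asarray(box, dtype=float)
        diff = diff - bx * np.round(diff / bx)
    d = np.sqrt((diff ** 2).sum(axis=-1))
    return d.reshape(d.shape[0], -1).min(axis=1)


def contact_matrix(structure: Structure, frame: np.ndarray, ligand: LigandInstance,
                   residues: Sequence[ResidueKey],
                   cutoff: float = DEFAULT_CONTACT_CUTOFF,
                   box=None, heavy_only: bool = True) -> np.ndarray:
    """Boolean vector over ``residues``: True iff any ligand-atom/residue-atom
    pair is at distance strictly < ``cutoff`` in this frame."""
    if not cutoff > 0:
        raise AnalysisError("cutoff must be positive")
    residues = list(residues)
    if not residues:
        raise AnalysisError("empty residue selection")
    frame = np.asarray(frame, dtype=float)
    lig = frame[ligand.atom_indices(structure)]
    out = np.empty(len(residues), dtype=bool)
    for j, key in enumerate(residues):
        idx = structure.residue_atom_indices(key, heavy_only=heavy_only)
        d = pairwise_distances(lig, frame[idx], box=box)
        out[j] = bool(d.min() < cutoff)
    return out


def contact_timeline(traj: Trajectory, structure: Structure, ligand: LigandInstance,
                     residues: Sequence[ResidueKey],
                     cutoff: float = DEFAULT_CONTACT_CUTOFF,
                     heavy_only: bool = True,
                     keep_distances: bool = False) -> list:
    """One :class:`ContactTimeline` per residue over the whole trajectory."""
    if not cutoff > 0:
        raise AnalysisError("cutoff must be positive")
    residues = list(residues)
    if not residues:
        raise AnalysisError("empty residue selection")
    lig_idx = ligand.atom_indices(structure)
    timelines = []
    for key in residues:
        res_idx = structure.residue_atom_indices(key, heavy_only=heavy_only)
        dmin = _min_dist_per_frame(traj.coordinates, lig_idx, res_idx, box=traj.box)
        timelines.append(
            ContactTimeline(
                ligand_label=ligand.label,
                residue_key=tuple(key),
                contact=dmin < cutoff,
                frame_interval=traj.frame_interval,
                min_distance=dmin if keep_distances else None,
            )
        )
    return timelines


def cumulative_contact_time(timeline: ContactTimeline,
                            frame_interval: Optional[float] = None) -> float:
    """Total contact time in ns: contact-frame count × frame interval."""
    fi = timeline.frame_interval if frame_interval is None else frame_interval
    return float(np.count_nonzero(timeline.contact)) * fi


def summarize_contacts(runs: Sequence[Sequence[ContactTimeline]],
                       threshold: float = DEFAULT_FREQUENT_THRESHOLD) -> list:
    """Aggregate per-residue residence over independent runs.

    ``runs`` is a list of runs, each a list of timelines (one per residue; a
    residue may appear in any subset of runs).  Runs are independent inputs
    and are never concatenated: ``n_runs_observed`` counts the runs in which
    the residue's cumulative contact time reached ``threshold``.
    """
    per_res: dict[ResidueKey, list] = {}
    for run in runs:
        seen: dict[ResidueKey, float] = {}
        for tl in run:
            seen[tl.residue_key] = seen.get(tl.residue_key, 0.0) + cumulative_contact_time(tl)
        for key, t in seen.items():
            per_res.setdefault(key, []).append(t)
    summaries = []
    for key, times in per_res.items():
        summaries.append(
            ContactSummary(
                residue_key=key,
                cumulative_time=max(times),
                n_runs_observed=sum(1 for t in times if t >= threshold),
                per_run=tuple(times),
            )
        )
    summaries.sort(key=lambda s: (-s.cumulative_time, s.residue_key[1]))
    return summaries


def frequent_contact_residues(summaries: Iterable[ContactSummary],
                              threshold: float = DEFAULT_FREQUENT_THRESHOLD) -> list:
    """Residues whose cumulative contact time is ≥ ``threshold`` ns (boundary
    inclusive), sorted by descending time, ties by residue number ascending."""
    if threshold < 0:
        raise AnalysisError("threshold must be non-negative")
    kept = [s for s in summaries if s.cumulative_time >= threshold]
    kept.sort(key=lambda s: (-s.cumulative_time, s.residue_key[1]))
    return [s.residue_key for s in kept]


def contact_probability(traj: Trajectory, structure: Structure,
                        selected_frames: Sequence[int],
                        subject_atom_ids: Sequence[int],
                        residues: Sequence[ResidueKey],
                        cutoff: float = DEFAULT_CONTACT_CUTOFF,
                        heavy_only: bool = True) -> dict:
    """Per-residue contact probability over a frame selection.

    probability(residue) = (#selected frames in contact with the subject
    atoms) / (#selected frames).  Candidate residues may span chains.
    """
    frames = np.asarray(list(selected_frames), dtype=int)
    if frames.size == 0:
        raise AnalysisError("selected_frames must be non-empty")
    residues = list(residues)
    if not residues:
        raise AnalysisError("empty residue selection")
    subj_idx = structure.atom_indices(subject_atom_ids)
    coords = traj.coordinates[frames]
    probs = {}
    for key in residues:
        res_idx = structure.residue_atom_indices(key, heavy_only=heavy_only)
        dmin = _min_dist_per_frame(coords, subj_idx, res_idx, box=traj.box)
        probs[tuple(key)] = float(np.count_nonzero(dmin < cutoff)) / frames.size
    return probs
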