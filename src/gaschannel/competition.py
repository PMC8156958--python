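"""Two-species competition near a target atom.

The central object is a :class:`ProximitySeries`: per-frame distance of a
ligand to a target atom (for a diatomic, the nearer of its two atoms — the
same nearest-atom semantics the contact analysis uses), thresholded into a
boolean ``within`` series.

A *displacement event* (A displaced by B) is an operational, purely geometric
formalisation of one species evicting the other:

1. A is continuously within the threshold for at least ``min_pre_dwell`` ns
   (the incumbent actually resided there);
2. B *enters* the threshold during A's dwell or within ``max_entry_gap`` ns
   of its end (overlap, not mere succession);
3. A then leaves and stays out for at least ``min_post_absence`` ns (or until
   the run ends) while B is still within at A's exit.

The three windows are configurable; the defaults (5 ns pre-dwell, 1 ns entry
gap, 5 ns post-absence) are loose enough that a dwell of tens of ns ended by
a terminal departure counts, and tight enough that simple succession does
not.  Reports label the definition as operational.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .errors import AnalysisError
from .contact_analysis import _min_dist_per_frame
from .model_io import LigandInstance, Structure, Trajectory

__all__ = [
    "ProximitySeries",
    "DisplacementEvent",
    "proximity_series",
    "colocalization_fraction",
    "detect_displacements",
]

DEFAULT_MIN_PRE_DWELL = 5.0  # ns
DEFAULT_MAX_ENTRY_GAP = 1.0  # ns
DEFAULT_MIN_POST_ABSENCE = 5.0  # ns


@dataclass
class ProximitySeries:
    """Distance of one ligand to a target atom, per frame, plus a boolean
    ``within`` series at the stated threshold (inclusive ≤)."""

    ligand_label: str
    target: str
    threshold: float
    distance: np.ndarray
    within: np.ndarray
    frame_interval: float

    @property
    def n_frames(self) -> int:
        return len(self.distance)


@dataclass
class DisplacementEvent:
    displaced: str
    displacer: str
    overlap_start: float  # ns; displacer's entry into the threshold
    displacement_time: float  # ns; first frame with the incumbent absent
    parameters: tuple = ()  # (threshold Å, min_pre_dwell ns, min_post_absence ns)

    def __post_init__(self):
        if self.displaced == self.displacer:
            raise AnalysisError("displaced and displacer must differ")
        if self.overlap_start > self.displacement_time:
            raise AnalysisError("overlap must start before the displacement")


def proximity_series(traj: Trajectory, structure: Structure, ligand: LigandInstance,
                     target_atom_id: int, threshold: float,
                     target_name: Optional[str] = None) -> ProximitySeries:
    """Per-frame nearest-atom distance of ``ligand`` to the target atom."""
    if not threshold > 0:
        raise AnalysisError("threshold must be positive")
    t_idx = np.asarray([structure.atom_index(target_atom_id)])
    l_idx = ligand.atom_indices(structure)
    d = _min_dist_per_frame(traj.coordinates, l_idx, t_idx, box=traj.box)
    return ProximitySeries(
        ligand_label=ligand.label,
        target=target_name or structure.atoms[t_idx[0]].name,
        threshold=float(threshold),
        distance=d,
        within=d <= threshold,
        frame_interval=traj.frame_interval,
    )


def colocalization_fraction(series_a: ProximitySeries, series_b: ProximitySeries) -> float:
    """Fraction of frames in which both ligands are within the threshold."""
    if series_a.n_frames != series_b.n_frames:
        raise AnalysisError("proximity series differ in length")
    if series_a.target != series_b.target or series_a.threshold != series_b.threshold:
        raise AnalysisError("proximity series differ in target or threshold")
    both = np.logical_and(series_a.within, series_b.within)
    return float(np.count_nonzero(both)) / series_a.n_frames


def _runs(mask: np.ndarray):
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([idx[0]], idx[breaks + 1]))
    ends = np.concatenate((idx[breaks], [idx[-1]]))
    return list(zip(starts.tolist(), ends.tolist()))


def detect_displacements(series: Sequence[ProximitySeries],
                         min_pre_dwell: float = DEFAULT_MIN_PRE_DWELL,
                         max_entry_gap: float = DEFAULT_MAX_ENTRY_GAP,
                         min_post_absence: float = DEFAULT_MIN_POST_ABSENCE) -> list:
    """Detect displacement events among proximity series sharing one target.

    Returns events time-ordered by ``displacement_time``.  The rule is
    anti-symmetric by construction: it requires the displaced ligand to leave
    while the displacer stays, so one frame window can never yield the event
    in both directions.
    """
    series = list(series)
    if len(series) < 2:
        return []
    ref = series[0]
    for s in series[1:]:
        if s.target != ref.target or s.threshold != ref.threshold \
                or s.n_frames != ref.n_frames or s.frame_interval != ref.frame_interval:
            raise AnalysisError("inconsistent proximity-series metadata")
    fi = ref.frame_interval
    n = ref.n_frames
    eps = 1e-9
    gap_frames = int(np.floor(max_entry_gap / fi + eps))
    events = []
    for a in series:
        a_runs = _runs(a.within)
        for b in series:
            if b is a:
                continue
            b_within = b.within
            # entry frames: transitions out -> in
            entries = np.flatnonzero(b_within & ~np.concatenate(([True], b_within[:-1])))
            for s0, e0 in a_runs:
                if (e0 - s0 + 1) * fi + eps < min_pre_dwell:
                    continue
                if e0 >= n - 1:
                    continue  # incumbent never exits within the run
                window_entries = entries[(entries >= s0) & (entries <= e0 + gap_frames)]
                if window_entries.size == 0:
                    continue
                if not b_within[e0 + 1]:
                    continue  # displacer not present at the incumbent's exit
                # incumbent must stay out >= min_post_absence (or to run end)
                out = ~a.within[e0 + 1:]
                first_back = np.argmin(out) if not out.all() else out.size
                if out.size and not out[0]:
                    continue
                if first_back * fi + eps < min_post_absence:
                    continue
                events.append(
                    DisplacementEvent(
                        displaced=a.ligand_label,
                        displacer=b.ligand_label,
                        overlap_start=float(window_entries[0]) * fi,
                        displacement_time=float(e0 + 1) * fi,
                        parameters=(ref.threshold, min_pre_dwell, min_post_absence),
                    )
                )
    events.sort(key=lambda ev: (ev.displacement_time, ev.displaced, ev.displacer))
    return events
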