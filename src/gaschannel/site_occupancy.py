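"""Named sites, occupancy intervals, binding-site qualification, path traces
and entrance assignment.

A *site* is a named residue set with a role (entrance, binding, catalytic or
cluster).  A ligand occupies a site in a frame when it contacts at least
``min_residues`` of the site's residues; occupied runs separated by gaps of at
most ``merge_gap`` ns are merged into one interval, so single-frame thermal
flicker does not fragment a dwell.

Binding-site qualification follows a residence criterion: a site qualifies
when its total occupancy reaches a configurable fraction of the run length
(default 0.20, under which both a 70 ns and a 35 ns total residence in a
150 ns run qualify).

Entrance assignment: the portal credited with a ligand's entry is the
entrance whose first visit most recently precedes the ligand's first
catalytic-site visit — the last portal crossed before arrival.  A ligand that
never reaches the catalytic site gets the call ``none``; two entrances whose
first visits fall within one frame of each other give ``ambiguous``, as does
a catalytic visit with no preceding entrance visit (the portal cannot be
determined).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from .errors import AnalysisError, InputError
from .contact_analysis import ContactTimeline, contact_timeline
from .model_io import (LigandInstance, ResidueKey, Structure, Trajectory,
                       format_residue_key, parse_residue_key)

__all__ = [
    "SiteDefinition",
    "OccupancyInterval",
    "Visit",
    "PathTrace",
    "EntranceCall",
    "site_occupancy",
    "qualify_binding_site",
    "trace_path",
    "assign_entrance",
    "load_site_catalog",
    "save_site_catalog",
]

SITE_ROLES = ("entrance", "binding", "catalytic", "cluster")
DEFAULT_MIN_RESIDUES = 1
DEFAULT_MERGE_GAP = 0.5  # ns
DEFAULT_QUALIFICATION_FRACTION = 0.20


@dataclass(frozen=True)
class SiteDefinition:
    name: str
    role: str
    residue_keys: frozenset

    def __post_init__(self):
        if self.role not in SITE_ROLES:
            raise InputError(f"site {self.name!r}: unknown role {self.role!r}")
        if not self.residue_keys:
            raise InputError(f"site {self.name!r}: empty residue set")


@dataclass
class OccupancyInterval:
    """A contiguous dwell of one ligand in one site; frames inclusive."""

    ligand_label: str
    site_name: str
    start_frame: int
    end_frame: int
    frame_interval: float

    def __post_init__(self):
        if self.start_frame > self.end_frame:
            raise AnalysisError("interval start after end")

    @property
    def duration(self) -> float:
        """Dwell duration in ns: (end − start + 1) × frame interval."""
        return (self.end_frame - self.start_frame + 1) * self.frame_interval

    @property
    def start_time(self) -> float:
        return self.start_frame * self.frame_interval

    @property
    def end_time(self) -> float:
        return self.end_frame * self.frame_interval


@dataclass
class Visit:
    site_name: str
    start_frame: int
    end_frame: int
    entry_time: float
    exit_time: float
    co_visit: bool = False  # overlaps a visit to another site in time


@dataclass
class PathTrace:
    ligand_label: str
    visits: list  # of Visit, time-ordered


@dataclass
class EntranceCall:
    ligand_label: str
    call: str  # "E1" | "E3" | ... | "ambiguous" | "none"
    first_entrance_time: Optional[float] = None
    first_catalytic_time: Optional[float] = None


# ---------------------------------------------------------------------------


def _bool_runs(mask: np.ndarray):
    """Maximal runs of True as (start, end) inclusive frame pairs."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([idx[0]], idx[breaks + 1]))
    ends = np.concatenate((idx[breaks], [idx[-1]]))
    return list(zip(starts.tolist(), ends.tolist()))


def site_occupancy(timelines: Mapping[ResidueKey, ContactTimeline] | Sequence[ContactTimeline],
                   site: SiteDefinition,
                   min_residues: int = DEFAULT_MIN_RESIDUES,
                   merge_gap: float = DEFAULT_MERGE_GAP,
                   ligand_label: Optional[str] = None) -> list:
    """Occupancy intervals of one ligand in one site.

    ``timelines`` must cover every residue of the site (mapping residue key →
    timeline, or a list of timelines).  A frame counts as occupied when the
    ligand contacts ≥ ``min_residues`` site residues; occupied runs separated
    by gaps ≤ ``merge_gap`` ns are merged.
    """
    if min_residues < 1:
        raise AnalysisError("min_residues must be >= 1")
    if isinstance(timelines, Mapping):
        by_key = {tuple(k): v for k, v in timelines.items()}
    else:
        by_key = {tl.residue_key: tl for tl in timelines}
    rows = []
    for key in site.residue_keys:
        if tuple(key) not in by_key:
            raise AnalysisError(
                f"site {site.name}: missing timeline for residue {format_residue_key(key)}"
            )
        rows.append(by_key[tuple(key)])
    fi = rows[0].frame_interval
    label = ligand_label if ligand_label is not None else rows[0].ligand_label
    counts = np.sum([tl.contact for tl in rows], axis=0)
    occupied = counts >= min_residues
    runs = _bool_runs(occupied)
    if not runs:
        return []
    gap_frames = int(np.floor(merge_gap / fi + 1e-9))
    merged = [list(runs[0])]
    for s, e in runs[1:]:
        if s - merged[-1][1] - 1 <= gap_frames:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    return [
        OccupancyInterval(label, site.name, s, e, fi) for s, e in merged
    ]


def qualify_binding_site(intervals: Sequence[OccupancyInterval], run_length: float,
                         min_fraction: float = DEFAULT_QUALIFICATION_FRACTION) -> dict:
    """Residence-based binding-site qualification.

    Qualified iff total occupancy ≥ ``min_fraction`` × ``run_length``; totals
    are reported either way.
    """
    if not run_length > 0:
        raise AnalysisError("run_length must be positive")
    total = sum(iv.duration for iv in intervals)
    longest = max((iv.duration for iv in intervals), default=0.0)
    for iv in intervals:
        if iv.end_time + iv.frame_interval > run_length + 1e-9:
            raise AnalysisError("occupancy interval exceeds run length")
    return {
        "qualified": bool(total >= min_fraction * run_length - 1e-12),
        "total_occupancy": float(total),
        "longest": float(longest),
    }


def trace_path(traj: Trajectory, structure: Structure, ligand: LigandInstance,
               catalog: Mapping[str, SiteDefinition],
               cutoff: float = 3.5,
               min_residues: int = DEFAULT_MIN_RESIDUES,
               merge_gap: float = DEFAULT_MERGE_GAP) -> PathTrace:
    """Time-ordered site visits of one ligand across a whole site catalog.

    Frames in which the ligand satisfies the occupancy criterion for several
    sites at once yield one visit per site, flagged as co-visits.
    """
    if not catalog:
        raise AnalysisError("site catalog is empty")
    visits = []
    for name in sorted(catalog):
        site = catalog[name]
        tls = contact_timeline(traj, structure, ligand, sorted(site.residue_keys),
                               cutoff=cutoff)
        for iv in site_occupancy(tls, site, min_residues=min_residues,
                                 merge_gap=merge_gap, ligand_label=ligand.label):
            visits.append(
                Visit(site_name=site.name, start_frame=iv.start_frame,
                      end_frame=iv.end_frame, entry_time=iv.start_time,
                      exit_time=iv.end_time)
            )
    visits.sort(key=lambda v: (v.start_frame, v.site_name))
    for i, v in enumerate(visits):
        for w in visits:
            if w is not v and w.start_frame <= v.end_frame and v.start_frame <= w.end_frame:
                v.co_visit = True
                break
    return PathTrace(ligand_label=ligand.label, visits=visits)


def assign_entrance(trace: PathTrace,
                    entrance_names: Sequence[str] = ("E1", "E3"),
                    catalytic_name: str = "CAT") -> EntranceCall:
    """Credit a ligand's catalytic-site arrival to an entrance.

    The call is the entrance whose first visit most recently precedes the
    first catalytic visit; ``none`` when the catalytic site is never visited;
    ``ambiguous`` when the two best candidates' first visits fall within one
    frame of each other, or when no entrance visit precedes the catalytic
    visit.
    """
    names = {v.site_name for v in trace.visits}
    first = {}
    for v in trace.visits:
        if v.site_name not in first:
            first[v.site_name] = v
    cat = first.get(catalytic_name)
    if cat is None:
        return EntranceCall(trace.ligand_label, "none")
    cat_time = cat.entry_time
    candidates = []
    for name in entrance_names:
        v = first.get(name)
        if v is not None and v.start_frame <= cat.start_frame:
            candidates.append(v)
    if not candidates:
        return EntranceCall(trace.ligand_label, "ambiguous",
                            first_catalytic_time=cat_time)
    candidates.sort(key=lambda v: -v.start_frame)
    best = candidates[0]
    if len(candidates) > 1 and abs(candidates[1].start_frame - best.start_frame) <= 1:
        return EntranceCall(trace.ligand_label, "ambiguous",
                            first_entrance_time=best.entry_time,
                            first_catalytic_time=cat_time)
    return EntranceCall(trace.ligand_label, best.site_name,
                        first_entrance_time=best.entry_time,
                        first_catalytic_time=cat_time)


# ---------------------------------------------------------------------------
# catalog I/O (YAML: {sites: {NAME: {role: ..., residues: ["A:154:TYR", ...]}}})
# ---------------------------------------------------------------------------

def load_site_catalog(path) -> dict:
    import yaml

    try:
        with open(path) as fh:
            data = yaml.safe_load(fh)
    except FileNotFoundError:
        raise InputError(f"site catalog not found: {path}") from None
    except yaml.YAMLError as exc:
        raise InputError(f"malformed site catalog {path}: {exc}") from exc
    if not isinstance(data, dict) or "sites" not in data:
        raise InputError(f"site catalog {path} lacks a 'sites' mapping")
    catalog = {}
    for name, entry in data["sites"].items():
        keys = frozenset(parse_residue_key(r) for r in entry["residues"])
        catalog[name] = SiteDefinition(name=name, role=entry["role"], residue_keys=keys)
    return catalog


def save_site_catalog(catalog: Mapping[str, SiteDefinition], path) -> None:
    import yaml

    data = {
        "sites": {
            name: {
                "role": site.role,
                "residues": sorted(format_residue_key(k) for k in site.residue_keys),
            }
            for name, site in sorted(catalog.items())
        }
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)
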