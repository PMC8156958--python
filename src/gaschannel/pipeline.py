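"""End-to-end analysis pipeline: contacts → sites → paths/entrances →
competition → poses → profiles, with TSV/JSON reporting.

A :class:`RunConfig` names the inputs (structure, one or more trajectory
runs, site catalog, reference atoms) and carries every analysis threshold.
``run_pipeline`` executes the stages in order, writes one TSV per result
table, a machine-readable ``summary.json`` and a ``run.log`` that echoes every
parameter actually used.  Output is deterministic: identical inputs (and
seed, for synthetic workflows) give byte-identical files.

The displacement-event definition is operational (pre-dwell / entry-gap /
post-absence windows); the summary labels it as such.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .errors import GasChannelError, InputError, StageError
from . import contact_analysis as ca
from . import competition as comp
from . import pose_competence as pc
from .site_occupancy import (OccupancyInterval, assign_entrance,
                             load_site_catalog, qualify_binding_site,
                             site_occupancy, trace_path)
from .model_io import (ReferenceAtoms, Species, Structure, Trajectory,
                       find_ligands, format_residue_key, load_structure,
                       load_trajectory, residues_within)

__all__ = ["RunConfig", "DEFAULT_PARAMETERS", "run_pipeline", "compare_runs",
           "load_config"]

DEFAULT_PARAMETERS = {
    "contact_cutoff": 3.5,          # Å, strict <
    "frequent_threshold": 2.5,      # ns, inclusive >=
    "pose_threshold": 7.5,          # Å, strict <
    "sape_proximity": 7.0,          # Å, inclusive <=
    "fe_shell": 20.0,               # Å, inclusive <=
    "qualification_fraction": 0.20,
    "min_residues": 1,
    "merge_gap": 0.5,               # ns
    "displacement_min_pre_dwell": 5.0,   # ns
    "displacement_max_entry_gap": 1.0,   # ns
    "displacement_min_post_absence": 5.0,  # ns
    "report_threshold": 0.70,
}


@dataclass
class RunConfig:
    structure: str
    trajectories: list
    site_catalog: str
    output_dir: str
    reference_atoms: Optional[str] = None
    frame_interval: Optional[float] = None
    parameters: dict = field(default_factory=dict)
    seed: Optional[int] = None
    make_plots: bool = False
    base_dir: Path = Path(".")

    def __post_init__(self):
        merged = dict(DEFAULT_PARAMETERS)
        merged.update(self.parameters)
        for key, value in merged.items():
            if key != "min_residues" and isinstance(value, (int, float)) and value <= 0:
                raise InputError(f"parameter {key} must be positive")
        self.parameters = merged

    def resolve(self, path: str) -> Path:
        p = Path(path)
        return p if p.is_absolute() else self.base_dir / p


def load_config(path) -> RunConfig:
    """Read a YAML run configuration; relative paths resolve against the
    config file's directory."""
    import yaml

    path = Path(path)
    if not path.exists():
        raise InputError(f"config file not found: {path}")
    with open(path) as fh:
        try:
            data = yaml.safe_load(fh) or {}
        except yaml.YAMLError as exc:
            raise InputError(f"malformed config {path}: {exc}") from exc
    try:
        cfg = RunConfig(
            structure=data["structure"],
            trajectories=list(data["trajectories"]),
            site_catalog=data["site_catalog"],
            output_dir=data.get("output_dir", "analysis"),
            reference_atoms=data.get("reference_atoms"),
            frame_interval=data.get("frame_interval"),
            parameters=data.get("parameters", {}),
            seed=data.get("seed"),
            make_plots=bool(data.get("make_plots", False)),
            base_dir=path.parent,
        )
    except KeyError as exc:
        raise InputError(f"config {path}: missing required key {exc}") from exc
    return cfg


def _load_reference_atoms(path) -> ReferenceAtoms:
    import yaml

    with open(path) as fh:
        r = yaml.safe_load(fh)
    return ReferenceAtoms(
        fe_atom_id=r["fe"], c13_atom_id=r.get("c13"), c15_atom_id=r.get("c15"),
        substrate_atom_ids=tuple(r.get("substrate") or ()) or None,
    )


def _round(x, nd=6):
    if isinstance(x, float):
        return round(x, nd)
    if isinstance(x, dict):
        return {k: _round(v, nd) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_round(v, nd) for v in x]
    return x


def _write_tsv(path: Path, header: list, rows: list) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(c) for c in row) + "\n")


def _analyze_run(structure: Structure, traj: Trajectory, catalog, refs,
                 params: dict, run_name: str, out_dir: Path, make_plots: bool):
    ligands = find_ligands(structure)
    cutoff = params["contact_cutoff"]

    # --- contacts over the iron shell ----------------------------------
    shell_keys = None
    timelines_by_ligand = {}
    if refs is not None:
        shell = residues_within(structure, traj.coordinates[0], refs.fe_atom_id,
                                params["fe_shell"], box=traj.box)
        gas_names = {"OXY", "NO"}
        shell_keys = sorted(k for k in shell if k[2] not in gas_names)
    site_keys = sorted({k for s in catalog.values() for k in s.residue_keys})
    contact_keys = sorted(set(site_keys) | set(shell_keys or []))
    for lig in ligands:
        timelines_by_ligand[lig.label] = ca.contact_timeline(
            traj, structure, lig, contact_keys, cutoff=cutoff)
    summaries = ca.summarize_contacts(
        [tls for tls in timelines_by_ligand.values()],
        threshold=params["frequent_threshold"])
    frequent = ca.frequent_contact_residues(summaries, params["frequent_threshold"])

    # --- site occupancy, qualification, paths, entrances ----------------
    occupancy_rows = []
    site_totals: dict[str, dict] = {}
    entrance_calls = {}
    run_length = traj.run_length
    for lig in ligands:
        by_key = {tl.residue_key: tl for tl in timelines_by_ligand[lig.label]}
        for name in sorted(catalog):
            site = catalog[name]
            intervals = site_occupancy(
                by_key, site, min_residues=params["min_residues"],
                merge_gap=params["merge_gap"], ligand_label=lig.label)
            for iv in intervals:
                occupancy_rows.append(
                    [lig.label, name, iv.start_frame, iv.end_frame,
                     f"{iv.duration:.4f}"])
                site_totals.setdefault(name, {"total": 0.0, "by_species": {}})
                site_totals[name]["total"] += iv.duration
                sp = lig.species.value
                site_totals[name]["by_species"][sp] = (
                    site_totals[name]["by_species"].get(sp, 0.0) + iv.duration)
        trace = trace_path(traj, structure, lig, catalog, cutoff=cutoff,
                              min_residues=params["min_residues"],
                              merge_gap=params["merge_gap"])
        call = assign_entrance(trace)
        entrance_calls[lig.label] = call.call
    qualification = {
        name: qualify_binding_site(
            [OccupancyInterval("*", name, 0,
                                  int(round(tot["total"] / traj.frame_interval)) - 1,
                                  traj.frame_interval)]
            if tot["total"] > 0 else [],
            run_length, params["qualification_fraction"])
        for name, tot in sorted(site_totals.items())
    }

    # --- competition near C15 (or the iron when no substrate) ----------
    events = []
    colocalization = {}
    target_id = None
    if refs is not None:
        target_id = refs.c15_atom_id if refs.c15_atom_id is not None else refs.fe_atom_id
    if target_id is not None:
        series = [
            comp.proximity_series(traj, structure, lig, target_id,
                                  params["pose_threshold"], target_name="C15")
            for lig in ligands
        ]
        events = comp.detect_displacements(
            series,
            min_pre_dwell=params["displacement_min_pre_dwell"],
            max_entry_gap=params["displacement_max_entry_gap"],
            min_post_absence=params["displacement_min_post_absence"])
        by_label = {s.ligand_label: s for s in series}
        for a in sorted(by_label):
            for b in sorted(by_label):
                if a < b:
                    colocalization[f"{a}|{b}"] = comp.colocalization_fraction(
                        by_label[a], by_label[b])

    # --- substrate-proximity occupancy (7 Å from any substrate atom) ----
    substrate_proximity = {}
    if refs is not None and refs.substrate_atom_ids:
        sub_idx = structure.atom_indices(refs.substrate_atom_ids)
        for lig in ligands:
            dmin = ca._min_dist_per_frame(traj.coordinates,
                                          lig.atom_indices(structure), sub_idx,
                                          box=traj.box)
            substrate_proximity[lig.label] = float(
                np.count_nonzero(dmin <= params["sape_proximity"])) / traj.n_frames

    # --- competent poses and coordination profile -----------------------
    poses = []
    profile = None
    if refs is not None and refs.c13_atom_id is not None and refs.c15_atom_id is not None \
            and any(l.species is Species.O2 for l in ligands):
        poses = pc.competent_poses(traj, structure, refs, ligands,
                                   threshold=params["pose_threshold"])
        frames = pc.competent_frames(poses)
        if frames and refs.substrate_atom_ids:
            profile = pc.coordination_profile(
                traj, structure, frames, refs.substrate_atom_ids,
                contact_keys, cutoff=cutoff,
                report_threshold=params["report_threshold"],
                source="competent-pose frames")

    # --- write tables ----------------------------------------------------
    prefix = out_dir / run_name
    _write_tsv(prefix.with_suffix(".contacts.tsv"),
               ["residue", "cumulative_time_ns", "n_runs_observed"],
               [[format_residue_key(s.residue_key), f"{s.cumulative_time:.4f}",
                 s.n_runs_observed] for s in summaries])
    _write_tsv(prefix.with_suffix(".occupancy.tsv"),
               ["ligand", "site", "start_frame", "end_frame", "duration_ns"],
               occupancy_rows)
    _write_tsv(prefix.with_suffix(".entrances.tsv"), ["ligand", "entrance"],
               [[lab, entrance_calls[lab]] for lab in sorted(entrance_calls)])
    _write_tsv(prefix.with_suffix(".displacements.tsv"),
               ["displaced", "displacer", "overlap_start_ns", "displacement_ns",
                "definition"],
               [[ev.displaced, ev.displacer, f"{ev.overlap_start:.4f}",
                 f"{ev.displacement_time:.4f}", "operational"] for ev in events])
    _write_tsv(prefix.with_suffix(".poses.tsv"),
               ["frame", "o2", "d_o2_c15_A", "d_c13_fe_A"],
               [[p.frame_index, p.o2_label, f"{p.d_o2_c15:.4f}",
                 f"{p.d_c13_fe:.4f}"] for p in poses])
    if profile is not None:
        _write_tsv(prefix.with_suffix(".coordination.tsv"),
                   ["residue", "probability"],
                   [[format_residue_key(k), f"{v:.6f}"]
                    for k, v in sorted(profile.probabilities.items())])
    if make_plots:
        from . import plotting

        plotting.contact_chronogram(
            {lab: tls for lab, tls in timelines_by_ligand.items()},
            prefix.with_suffix(".chronogram.png"))
        if profile is not None:
            plotting.coordination_bars(profile, prefix.with_suffix(".coordination.png"))

    return {
        "ligands": {l.label: l.species.value for l in ligands},
        "run_length_ns": run_length,
        "frequent_contact_residues": [format_residue_key(k) for k in frequent],
        "entrance_calls": entrance_calls,
        "sites": {
            name: {
                "qualified": qualification[name]["qualified"],
                "total_occupancy_ns": qualification[name]["total_occupancy"],
                "longest_ns": qualification[name]["longest"],
                "by_species_ns": site_totals.get(name, {}).get("by_species", {}),
            }
            for name in sorted(site_totals)
        },
        "catalytic_access": {
            sp.value: sum(
                1 for l in ligands
                if l.species is sp and entrance_calls[l.label] not in ("none",)
            )
            for sp in (Species.O2, Species.NO)
        },
        "displacement_events": [
            {"displaced": ev.displaced, "displacer": ev.displacer,
             "overlap_start_ns": ev.overlap_start,
             "displacement_ns": ev.displacement_time,
             "definition": "operational"}
            for ev in events
        ],
        "colocalization": colocalization,
        "substrate_proximity_fraction": substrate_proximity,
        "pose_count": len(poses),
        "coordination_highlighted": (
            [format_residue_key(k) for k in profile.highlighted] if profile else []
        ),
    }


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage on every trajectory; returns (and writes) the summary."""
    out_dir = config.resolve(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    params = config.parameters

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except GasChannelError as exc:
            if isinstance(exc, StageError):
                raise
            raise StageError(name, exc) from exc

    structure = stage("load-structure", load_structure, config.resolve(config.structure))
    catalog = stage("load-sites", load_site_catalog, config.resolve(config.site_catalog))
    refs = None
    if config.reference_atoms:
        refs = stage("load-reference-atoms", _load_reference_atoms,
                     config.resolve(config.reference_atoms))
        refs.validate(structure)
    # keep only sites that resolve in this structure (the reference catalog
    # may name residues a reduced model does not carry)
    catalog = {
        name: site for name, site in catalog.items()
        if all(structure.has_residue(k) for k in site.residue_keys)
    }
    if not catalog:
        raise StageError("load-sites", InputError("no catalog site resolves in structure"))

    summary = {"parameters": _round(dict(sorted(params.items()))),
               "seed": config.seed, "runs": {}}
    for i, tpath in enumerate(config.trajectories):
        run_name = f"run{i + 1}"
        traj = stage("load-trajectory", load_trajectory, config.resolve(tpath),
                     structure, config.frame_interval)
        summary["runs"][run_name] = stage(
            "analyze", _analyze_run, structure, traj, catalog, refs, params,
            run_name, out_dir, config.make_plots)
    summary["aggregate"] = {
        "pose_count_total": sum(r["pose_count"] for r in summary["runs"].values()),
        "displacement_event_total": sum(
            len(r["displacement_events"]) for r in summary["runs"].values()),
    }
    summary = _round(summary)

    with open(out_dir / "run.log", "w") as fh:
        for key in sorted(params):
            fh.write(f"parameter\t{key}\t{params[key]}\n")
        fh.write(f"input\tstructure\t{config.structure}\n")
        for t in config.trajectories:
            fh.write(f"input\ttrajectory\t{t}\n")
        fh.write(f"input\tsite_catalog\t{config.site_catalog}\n")
        if config.reference_atoms:
            fh.write(f"input\treference_atoms\t{config.reference_atoms}\n")
        if config.seed is not None:
            fh.write(f"input\tseed\t{config.seed}\n")
    with open(out_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary


def compare_runs(summary_a: dict, summary_b: dict):
    """Side-by-side differences of two pipeline summaries (e.g. a ±partner
    contrast): per-site occupancy, per-species catalytic access and
    co-localization.  Summaries must share the same parameter block."""
    import pandas as pd

    if summary_a.get("parameters") != summary_b.get("parameters"):
        raise InputError("summaries were produced with different parameters")

    def collect(summary):
        sites: dict[str, float] = {}
        access: dict[str, int] = {}
        coloc = []
        for run in summary["runs"].values():
            for name, s in run["sites"].items():
                sites[name] = sites.get(name, 0.0) + s["total_occupancy_ns"]
            for sp, n in run["catalytic_access"].items():
                access[sp] = access.get(sp, 0) + n
            coloc.extend(run["colocalization"].values())
        mean_coloc = float(np.mean(coloc)) if coloc else 0.0
        return sites, access, mean_coloc

    sites_a, access_a, col_a = collect(summary_a)
    sites_b, access_b, col_b = collect(summary_b)
    rows = []
    for name in sorted(set(sites_a) | set(sites_b)):
        a, b = sites_a.get(name, 0.0), sites_b.get(name, 0.0)
        rows.append({"quantity": f"site_occupancy_ns:{name}", "a": a, "b": b,
                     "difference": a - b})
    for sp in sorted(set(access_a) | set(access_b)):
        a, b = access_a.get(sp, 0), access_b.get(sp, 0)
        rows.append({"quantity": f"catalytic_access:{sp}", "a": a, "b": b,
                     "difference": a - b})
    rows.append({"quantity": "mean_colocalization", "a": col_a, "b": col_b,
                 "difference": col_a - col_b})
    return pd.DataFrame(rows)
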