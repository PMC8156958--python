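"""Headless-safe figures: contact chronograms and coordination bar charts."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .model_io import format_residue_key

__all__ = ["contact_chronogram", "coordination_bars"]


def contact_chronogram(timelines_by_ligand: dict, path) -> None:
    """Residue-vs-time contact raster, one panel per ligand.

    Only residues with at least one contact are drawn, ordered by residue
    number, so the panel reads like a ligand's itinerary through the protein.
    """
    ligands = sorted(timelines_by_ligand)
    fig, axes = plt.subplots(len(ligands), 1, squeeze=False,
                             figsize=(8, 2.2 * len(ligands)), sharex=True)
    for ax, label in zip(axes[:, 0], ligands):
        tls = [tl for tl in timelines_by_ligand[label] if tl.contact.any()]
        tls.sort(key=lambda tl: tl.residue_key[1])
        for row, tl in enumerate(tls):
            t = np.flatnonzero(tl.contact) * tl.frame_interval
            ax.plot(t, np.full_like(t, row, dtype=float), "|", ms=4, color="k")
        ax.set_yticks(range(len(tls)))
        ax.set_yticklabels([format_residue_key(tl.residue_key) for tl in tls],
                           fontsize=6)
        ax.set_title(label, fontsize=8)
    axes[-1, 0].set_xlabel("time (ns)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def coordination_bars(profile, path) -> None:
    """Bar chart of substrate-coordination probabilities per residue."""
    items = sorted(profile.probabilities.items(), key=lambda kv: -kv[1])
    labels = [format_residue_key(k) for k, _ in items]
    values = [v for _, v in items]
    fig, ax = plt.subplots(figsize=(max(4, 0.3 * len(items)), 3))
    ax.bar(range(len(items)), values, color="steelblue")
    ax.set_xticks(range(len(items)))
    ax.set_xticklabels(labels, rotation=90, fontsize=6)
    ax.set_ylabel("contact probability")
    ax.set_ylim(0, 1)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
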