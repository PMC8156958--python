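"""Reference site catalog for human 15-lipoxygenase-2 (15LOX-2).

The catalog names the surface entrances, interior binding sites and catalytic
site of 15LOX-2 as residue sets on chain A of the 4NRE structure:

* ``E1`` — surface entrance near the Y154–P159 loop, the main access point of
  O2 and NO to the tunnel leading to the catalytic site.
* ``E3`` — alternative surface entrance near S573/P595/A599, with S430 and
  V603 near the surface.
* ``S0`` — the first-recognition site; described only as transient occupancy
  of the E1 region, so it maps to the E1 residue set with role "binding"
  (an approximation, flagged here rather than asserted).
* ``S1``, ``S2`` — interior binding sites that arrest gas ligands en route to
  the catalytic pocket.
* ``CAT`` — the iron-coordinating residues H373, H378, H553 and the
  C-terminal I676.
* ``CLUSTER1``–``CLUSTER3`` — hydrophobic clusters that stage the ligands
  between entrances and the pocket.
* ``WIDE`` — a wide-entrance short tunnel lined by conserved residues; it is
  shipped for completeness but no gas ligand selected it.
"""

from __future__ import annotations

from .site_occupancy import SiteDefinition

__all__ = ["REFERENCE_SITE_RESIDUES", "reference_site_catalog"]

_ONE_TO_THREE = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
    "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
    "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
    "W": "TRP", "Y": "TYR",
}


def _res(code: str, chain: str = "A"):
    return (chain, int(code[1:]), _ONE_TO_THREE[code[0]])


REFERENCE_SITE_RESIDUES = {
    "E1": ("entrance", ["Y154", "N155", "G157", "W158", "I421", "I435", "F438", "S439"]),
    "E3": ("entrance", ["S573", "P595", "A599", "S430", "V603"]),
    "S0": ("binding", ["Y154", "N155", "G157", "W158", "I421", "I435", "F438", "S439"]),
    "S1": ("binding", ["N413", "A416", "R417", "L374", "L379"]),
    "S2": ("binding", ["I433", "T431", "V427", "F365", "E369"]),
    "CAT": ("catalytic", ["H373", "H378", "H553", "I676"]),
    "CLUSTER1": ("cluster", ["I216", "I604", "F561", "C564", "A565"]),
    "CLUSTER2": ("cluster", ["L607", "L610", "L420", "V426", "V427"]),
    "CLUSTER3": ("cluster", ["L246", "E364", "F365", "H368", "E369", "L570"]),
    "WIDE": ("cluster", ["L610", "Q560", "H373", "H553", "I676", "E613", "S557"]),
}


def reference_site_catalog(chain: str = "A") -> dict:
    """The shipped 15LOX-2 site catalog as {name: SiteDefinition}."""
    catalog = {}
    for name, (role, residues) in REFERENCE_SITE_RESIDUES.items():
        catalog[name] = SiteDefinition(
            name=name,
            role=role,
            residue_keys=frozenset(_res(r, chain) for r in residues),
        )
    return catalog
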