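"""Monoisotopic mass arithmetic for phosphatidylethanolamine (PE) species.

Supports the lipidomics bookkeeping around arachidonoyl-PE oxidation and
nitrosylation: building molecular formulas for PE(sn1/sn2) species with
hydroperoxy (+O2), hydroxy (+O) or nitroso modifications, computing their
monoisotopic masses and the deprotonated [M−H]⁻ m/z observed in negative-mode
electrospray.

The nitroso adduct is modelled as the coupling of the carbon-centered lipid
radical with the NO radical: net +N +O −H relative to the parent PE.

Atomic masses are the IUPAC/CODATA monoisotopic values for the principal
isotope; the proton mass already accounts for the electron, so
[M−H]⁻ = M − 1.00727646 Da exactly.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass
from typing import Mapping

from .errors import InputError

__all__ = [
    "MolecularFormula",
    "LipidSpec",
    "MODIFICATIONS",
    "monoisotopic_mass",
    "pe_species_formula",
    "mz_deprotonated",
    "parse_species",
]

#: monoisotopic atomic masses (Da) of the principal isotopes
MONOISOTOPIC = {
    "H": 1.00782503207,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "P": 30.97376163,
    "S": 31.97207100,
    "Na": 22.9897692809,
    "K": 38.96370668,
    "Fe": 55.9349375,
}

PROTON_MASS = 1.007276466879  # Da


class MolecularFormula(Mapping):
    """Immutable element → count mapping with formula arithmetic."""

    def __init__(self, counts: Mapping[str, int] | None = None, **kwargs: int):
        merged = Counter()
        for source in (counts or {}, kwargs):
            for el, n in source.items():
                if el not in MONOISOTOPIC:
                    raise InputError(f"unknown element {el!r}")
                merged[el] += int(n)
        for el, n in merged.items():
            if n < 0:
                raise InputError(f"negative count for element {el}")
        self._counts = {el: n for el, n in merged.items() if n > 0}

    def __getitem__(self, el):
        return self._counts[el]

    def __iter__(self):
        return iter(self._counts)

    def __len__(self):
        return len(self._counts)

    def __add__(self, other: "MolecularFormula") -> "MolecularFormula":
        c = Counter(self._counts)
        c.update(other._counts)
        return MolecularFormula(c)

    def add(self, **deltas: int) -> "MolecularFormula":
        """Return a new formula with element counts shifted by ``deltas``
        (negative deltas allowed as long as no count goes below zero)."""
        c = Counter(self._counts)
        for el, n in deltas.items():
            c[el] += n
        return MolecularFormula(c)

    def __eq__(self, other):
        return isinstance(other, MolecularFormula) and self._counts == other._counts

    def __hash__(self):
        return hash(frozenset(self._counts.items()))

    def __repr__(self):
        return f"MolecularFormula({self.hill()})"

    def hill(self) -> str:
        """Hill-notation formula string, e.g. ``C43H78NO8P``."""
        parts = []
        rest = dict(self._counts)
        for el in ("C", "H"):
            n = rest.pop(el, 0)
            if n:
                parts.append(el + (str(n) if n > 1 else ""))
        for el in sorted(rest):
            n = rest[el]
            parts.append(el + (str(n) if n > 1 else ""))
        return "".join(parts)


def monoisotopic_mass(formula: MolecularFormula | Mapping[str, int]) -> float:
    """Monoisotopic mass in Da: Σ count × principal-isotope atomic mass."""
    if not isinstance(formula, MolecularFormula):
        formula = MolecularFormula(formula)
    return sum(MONOISOTOPIC[el] * n for el, n in formula.items())


def mz_deprotonated(formula: MolecularFormula | Mapping[str, int]) -> float:
    """[M−H]⁻ m/z: monoisotopic mass minus one proton mass."""
    if not isinstance(formula, MolecularFormula):
        formula = MolecularFormula(formula)
    if formula.get("H", 0) < 1:
        raise InputError("cannot deprotonate a formula without hydrogen")
    return monoisotopic_mass(formula) - PROTON_MASS


#: modification → formula delta relative to the parent PE
MODIFICATIONS = {
    "none": {},
    "hydroperoxy": {"O": 2},
    "hydroxy": {"O": 1},
    "nitroso": {"N": 1, "O": 1, "H": -1},
}

# free glycerophosphoethanolamine backbone; PE = backbone + 2 fatty acids − 2 H2O
_GPE_BACKBONE = {"C": 5, "H": 14, "N": 1, "O": 6, "P": 1}


@dataclass(frozen=True)
class LipidSpec:
    """A PE species: two acyl chains as (carbons, double bonds) plus an
    optional modification ('none', 'hydroperoxy', 'hydroxy' or 'nitroso')."""

    sn1: tuple
    sn2: tuple
    modification: str = "none"

    def __post_init__(self):
        if self.modification not in MODIFICATIONS:
            raise InputError(f"unknown modification {self.modification!r}")
        for chain in (self.sn1, self.sn2):
            c, d = chain
            if c <= 0 or d < 0:
                raise InputError(f"invalid acyl chain {chain}")
            if d > (c - 2) // 2:
                raise InputError(
                    f"acyl chain {c}:{d} infeasible: at most {(c - 2) // 2} "
                    f"methylene-interrupted double bonds fit {c} carbons"
                )


def _fatty_acid(carbons: int, double_bonds: int) -> MolecularFormula:
    # CnH(2n-2d)O2
    return MolecularFormula({"C": carbons, "H": 2 * carbons - 2 * double_bonds, "O": 2})


def pe_species_formula(spec: LipidSpec) -> MolecularFormula:
    """Molecular formula of the (modified) PE species.

    Constructive bookkeeping: glycerophosphoethanolamine backbone plus both
    acyls, minus two waters for the ester bonds, plus the modification delta.
    """
    f = MolecularFormula(_GPE_BACKBONE)
    f = f + _fatty_acid(*spec.sn1) + _fatty_acid(*spec.sn2)
    f = f.add(H=-4, O=-2)  # two ester condensations
    delta = MODIFICATIONS[spec.modification]
    if delta:
        f = f.add(**delta)
    return f


_SPECIES_RE = re.compile(
    r"^PE\((\d+):(\d+)/(\d+):(\d+)\)(?:\+(NO|OOH|OH))?$"
)
_MOD_BY_SUFFIX = {None: "none", "NO": "nitroso", "OOH": "hydroperoxy", "OH": "hydroxy"}


def parse_species(text: str) -> LipidSpec:
    """Parse a species string like ``"PE(18:0/20:4)+NO"`` into a LipidSpec."""
    m = _SPECIES_RE.match(text.strip())
    if not m:
        raise InputError(
            f"cannot parse species {text!r}; expected e.g. 'PE(18:0/20:4)' "
            f"optionally followed by +NO, +OOH or +OH"
        )
    c1, d1, c2, d2, suffix = m.groups()
    return LipidSpec(
        sn1=(int(c1), int(d1)),
        sn2=(int(c2), int(d2)),
        modification=_MOD_BY_SUFFIX[suffix],
    )
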