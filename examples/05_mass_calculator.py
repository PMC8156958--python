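"""Monoisotopic masses of arachidonoyl-PE species and their derivatives.

Computes formulas and deprotonated [M-H]- m/z values for the stearoyl- and
oleoyl-arachidonoyl PE species, their hydroperoxy products and their nitroso
(NO-radical) adducts.
"""

from gaschannel import (monoisotopic_mass, mz_deprotonated, parse_species,
                        pe_species_formula)

for name in ("PE(18:0/20:4)", "PE(18:0/20:4)+OOH", "PE(18:0/20:4)+NO",
             "PE(18:1/20:4)+NO"):
    f = pe_species_formula(parse_species(name))
    print(f"{name:20s} {f.hill():16s} M {monoisotopic_mass(f):9.4f} Da   "
          f"[M-H]- {mz_deprotonated(f):9.4f}")

sa = pe_species_formula(parse_species("PE(18:0/20:4)+NO"))
oa = pe_species_formula(parse_species("PE(18:1/20:4)+NO"))
print(f"\nSA-vs-OA nitroso species gap: "
      f"{mz_deprotonated(sa) - mz_deprotonated(oa):.4f} (one H2, as expected "
      f"for an 18:0 vs 18:1 sn-1 chain)")
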