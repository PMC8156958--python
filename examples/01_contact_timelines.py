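"""Contact timelines and residence times of gas ligands near binding sites.

Generates the default synthetic system, computes per-residue contact
timelines (strict 3.5 Å heavy-atom criterion) for one O2 molecule, and ranks
residues by cumulative contact time with the 2.5 ns frequent-contact filter.
"""

from gaschannel import (contact_timeline, cumulative_contact_time,
                        frequent_contact_residues, format_residue_key,
                        summarize_contacts)
from gaschannel.synthetic import default_system_spec, simulate_gas_trajectory

system = simulate_gas_trajectory(default_system_spec(seed=1))
ligand = next(l for l in system.ligands if l.label == "OXY_701")
residues = sorted({k for s in system.catalog.values() for k in s.residue_keys})

timelines = contact_timeline(system.trajectory, system.structure, ligand, residues)
summaries = summarize_contacts([timelines])
frequent = frequent_contact_residues(summaries, threshold=2.5)

print(f"ligand {ligand.label}: residues with >= 2.5 ns cumulative contact")
for key in frequent:
    t = next(s.cumulative_time for s in summaries if s.residue_key == key)
    print(f"  {format_residue_key(key):16s} {t:6.1f} ns")
print("Each line is a residue this O2 molecule touched (any heavy-atom pair")
print("closer than 3.5 Å) for at least 2.5 ns of the 150 ns run; the long")
print("times are the planted S1 dwell (70 ns) and catalytic-site visit.")
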