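"""Two-species competition at the C15 position of the substrate.

Builds per-ligand proximity series to the substrate carbon C15 (7.5 Å
threshold), measures O2/NO co-localization, and detects displacement events:
one species holding the position for >= 5 ns, the other entering during the
overlap, the incumbent then leaving for >= 5 ns while the challenger stays.
"""

from gaschannel import (colocalization_fraction, detect_displacements,
                        proximity_series)
from gaschannel.synthetic import default_system_spec, simulate_gas_trajectory

system = simulate_gas_trajectory(default_system_spec(seed=1))
series = {
    lig.label: proximity_series(system.trajectory, system.structure, lig,
                                system.refs.c15_atom_id, threshold=7.5,
                                target_name="C15")
    for lig in system.ligands
}

frac = colocalization_fraction(series["OXY_702"], series["NO_802"])
print(f"OXY_702 / NO_802 co-localization near C15: {frac:.3f}")
print("(fraction of frames with both molecules inside the 7.5 Å shell)\n")

for ev in detect_displacements(list(series.values())):
    print(f"{ev.displacer} displaced {ev.displaced}: overlap began at "
          f"{ev.overlap_start:.1f} ns, {ev.displaced} left for good at "
          f"{ev.displacement_time:.1f} ns")
print("\nThe scripted scenario plants an O2 at the C15 position from 43 ns,")
print("an NO arriving at 74 ns, and the O2's final departure at 145 ns of")
print("the 150 ns run — the detector recovers exactly that one event.")
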