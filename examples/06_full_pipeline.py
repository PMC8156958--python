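"""The whole pipeline in one call: generate a fixture bundle, analyse it,
and print the machine-readable summary highlights.

The same workflow is available from the shell:

    gaschannel synth-generate --seed 1 --out bundle/
    gaschannel analyze bundle/config.yaml
"""

import tempfile
from pathlib import Path

from gaschannel import load_config, run_pipeline
from gaschannel.synthetic import (default_system_spec, simulate_gas_trajectory,
                                  write_fixture_bundle)

with tempfile.TemporaryDirectory() as tmp:
    system = simulate_gas_trajectory(default_system_spec(seed=1))
    write_fixture_bundle(system, tmp, dcd=False)
    summary = run_pipeline(load_config(Path(tmp) / "config.yaml"))

run = summary["runs"]["run1"]
print("entrance calls:   ", run["entrance_calls"])
print("qualified sites:  ", [n for n, s in run["sites"].items() if s["qualified"]])
print("catalytic access: ", run["catalytic_access"])
print("displacements:    ", [(e["displacer"], "displaced", e["displaced"],
                              f"at {e['displacement_ns']:.0f} ns")
                             for e in run["displacement_events"]])
print("competent poses:  ", run["pose_count"])
print("\nEvery number above is checked against the generator's planted ground")
print("truth in the test suite; the summary and all TSV outputs are written")
print("to the bundle's analysis/ directory and are byte-reproducible.")
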