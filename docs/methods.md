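# Methods

## Scope and data model

All analyses operate on a `Structure` (an ordered atom table; residues keyed
by `(chain, residue_number, residue_name)`) and a `Trajectory` (per-frame
coordinates in Å at a fixed frame interval in ns).  Frames are 0-based and
the time of frame *i* is *i* × interval; the frame interval is a required
input for binary trajectories and is never inferred from file headers, since
DCD/XTC time metadata is unreliable across MD engines.  The plain-text
fixture formats carry it explicitly and round-trip float64 coordinates
bit-exactly (17 significant digits).

Distances are Euclidean; with an orthorhombic periodic box they use the
minimum-image convention componentwise.  The synthetic generator defaults to
a non-periodic reflecting box so that distance semantics in tests are
unambiguous; a periodic variant exists to exercise the minimum-image paths.

Contacts and distance shells consider heavy atoms only (hydrogens and
deuteriums excluded).  Gas-contact statistics are dominated by heavy-atom
packing and hydrogen placement is force-field dependent; the behaviour is a
switch (`heavy_only`) on every operation that uses it.

## Contact criterion and residence times

A ligand–residue contact in a frame means *some* ligand-heavy-atom /
residue-heavy-atom pair is at distance **strictly less than** the cutoff
(default 3.5 Å).  The strict inequality is deliberate and pinned by tests;
the other geometric criteria differ:

| criterion | default | boundary |
|---|---|---|
| atomic contact | 3.5 Å | strict < |
| frequent-contact filter | 2.5 ns | inclusive ≥ |
| iron residue shell | 20 Å | inclusive ≤ |
| substrate proximity | 7 Å | inclusive ≤ |
| C15/Fe pose competence | 7.5 Å | strict < |
| proximity-series threshold | stated per analysis | inclusive ≤ |

Cumulative contact time is (number of contact frames) × frame interval, so
occupied plus unoccupied time always equals the run length exactly — a
conservation law the test suite asserts on every timeline.

Cross-run aggregation never concatenates runs: each run contributes its own
cumulative time, a residue's headline `cumulative_time` is its largest
per-run value (hence always bounded by one run length), and
`n_runs_observed` counts the runs in which the residue reached the
frequent-contact threshold.

## Sites, occupancy and entrances

A site is a named residue set with a role (entrance / binding / catalytic /
cluster).  The shipped reference catalog for 15LOX-2 names E1, E3, S0, S1,
S2, CAT, three hydrophobic clusters and a wide-entrance tunnel on chain A of
the 4NRE structure.  S0 is described in the source material only as transient
occupancy of the E1 region; the catalog therefore maps S0 to the E1 residue
set with role "binding" and flags this as an approximation.

A ligand occupies a site in a frame when it contacts at least `min_residues`
site residues (default 1: a single-residue graze still marks presence);
occupied runs separated by gaps of at most `merge_gap` ns (default 0.5) are
merged, so one-frame thermal flicker does not fragment a dwell.  Both knobs
are exposed; raising `min_residues` can only shrink intervals (a monotone
property under test).

**Binding-site qualification.**  No explicit residence criterion accompanies
the published site definitions, so the package adopts one: a site qualifies
when its total occupancy reaches `qualification_fraction` × run length
(default 0.20).  Both reported reference residences — about 70 ns and about
35 ns in 150 ns runs — clear this bar with margin; the fraction is
configurable.

**Entrance assignment.**  The entrance credited with a catalytic arrival is
the one whose *first* visit most recently precedes the ligand's first
catalytic-site visit — physically, the last portal crossed on the way in.
A ligand that never reaches the catalytic site is called `none`; when the two
best candidates' first visits fall within one frame of each other, or when a
catalytic visit has no preceding entrance visit at all, the call is
`ambiguous` rather than a guess.

## Competition and displacement events

Proximity of a diatomic to a target atom uses the nearer of its two atoms
(consistent with the contact semantics; never the centroid).  Co-localization
of two ligands is the fraction of frames with both inside the threshold.

The source narrative describes displacement qualitatively; this package
formalises it with three windows, all configurable:

1. **pre-dwell** — the incumbent is continuously within the threshold for at
   least `min_pre_dwell` ns (default 5): it actually resided there;
2. **overlap** — the challenger *enters* the threshold during the incumbent's
   dwell or within `max_entry_gap` ns (default 1) of its end: succession
   without overlap is not displacement;
3. **post-absence** — the incumbent stays out for at least
   `min_post_absence` ns (default 5, or to the end of the run) while the
   challenger is still within at the moment of exit.

The defaults are loose enough that a multi-ten-ns dwell ended by a terminal
departure is detected and tight enough that independent successive visits are
not.  The rule is anti-symmetric by construction (the displaced ligand must
leave while the displacer stays), which the suite checks on random series.
All reports label the definition as operational.

## Competent poses and coordination profiles

A catalytically competent pose is one `(frame, O₂ instance)` pair with the O₂
within 7.5 Å of the substrate carbon C15 **and** the substrate carbon C13
within 7.5 Å of the catalytic iron, both strict.  Several O₂ molecules
satisfying the geometry in the same frame count as several poses; pose counts
are reported per run plus a separate aggregate, since either convention is
defensible and this one is at least explicit.  C13/C15/Fe are identified by
configured atom ids, never by name-guessing in arbitrary PDB dialects.

Coordination profiles divide, per candidate residue, the number of
substrate-contact frames by the number of selected frames; the default frame
selection is the competent-pose frames (coordination at the geometry that
matters for peroxidation), and candidates may span chains so partner-protein
residues appear alongside the enzyme's own.  Residues at or above
`report_threshold` (default 0.70) are flagged.

## The synthetic generator

The generator is phenomenological — a scripted, biased random walk — not
physical MD.  Its purpose is *known truth*: every analysis stage is accepted
against events the generator planted, which realism would destroy.

Geometry: an 80 Å cube containing a bead model (one CA bead per residue) of
two surface entrances, two interior binding sites and a catalytic pocket with
an iron bead and an eight-bead substrate chain carrying tagged C13/C15
carbons (C13 sits 6.15 Å from the iron).  Bead residues reuse the reference
catalog's residue numbering so the shipped site definitions resolve directly.
Site centroids are at least 8 Å apart (verified at build time; closer
layouts are rejected as degenerate).

Gas ligands are rigid diatomics (1.2 Å bond, random orientation per frame) in
the O₂:NO mixture presets 1:1 (five of each), 1:3 and 3:1.  Each ligand
follows a plan of *plants* — site dwells (centre pinned 2.5–2.8 Å from a site
bead, inside the contact shell with ≥ 0.6 Å margin after jitter and bond
half-length) and C15-proximity segments — separated by free segments: a
reflecting-wall Gaussian walk (σ = 0.8 Å/frame) rejected within 9 Å of any
structure atom, so free ligands can never fire a 3.5 Å or 7.5 Å criterion
accidentally and planted intervals are frame-exact.  Transitions between
segments are instantaneous teleports; the generator trades kinematic realism
for exact ground truth.  Positional jitter during plants defaults to 0.3 Å
(0.5 Å in the noise-robustness scenario).

The default showcase spec (150 ns at 0.1 ns/frame — the frame interval is a
package choice, as durations are specified in ns throughout) plants: an E1
route with a 70 ns S1 dwell and a catalytic visit; an E3 route with a 35 ns
S2 dwell and a catalytic visit; plain S1/S2 visitors; free diffusers; and the
scripted pocket competition (O₂ at the C15 position from 43 ns, NO• arriving
at 74 ns, O₂ departing at 145 ns).  A substrate-excursion option moves C13
out of the iron's 7.5 Å shell to exercise the second pose condition.

The dwell-statistics spec plants a *fixed number* of exponential dwells per
ligand (7 each for 80 ligands, mean 10 ns, gaps ≥ 1 ns) rather than filling a
time window, because window-filling over-represents short dwells (ligands
that draw short dwells fit more of them) and biases the pooled mean low by
several percent.  With the fixed-count design the pooled sample is i.i.d. and
the recovered mean is an unbiased estimate, tested to within 10 %.

The displacement-robustness scenario plants events in batches of ten per
150 ns run over a rotating four-ligand pool, with window spacings chosen so
each planted event is the only rule-satisfying window in its neighbourhood.

Determinism: a single `numpy` generator seeded from the spec drives all
randomness in a fixed iteration order; identical spec + seed reproduces the
fixture bundle byte for byte (asserted in tests, DCD included).

**What the generator does not emulate** — and hence what passing tests do
not show about real data: no force fields, solvent, thermodynamics or
realistic kinetics; bead-level rather than atomic side-chain geometry; no
genuinely ambiguous marginal geometries (distances sit well inside or outside
every threshold by construction).  The tests establish that the *measurement
machinery* is exact; they cannot establish that real trajectories contain
such clean events.

## Pipeline and reporting

`run_pipeline` executes contacts → site occupancy/qualification → path
traces/entrance calls → competition/displacement → poses/profiles for each
trajectory run, writing one TSV per table, a sorted-key `summary.json`
(floats rounded to 6 decimals) and a `run.log` echoing every parameter used
— an audit property the tests verify by parsing the log.  Output is
byte-reproducible from config + inputs.  Stage failures abort with the stage
name (CLI exit code 3; input errors exit 2).  Catalog sites naming residues
absent from the structure are dropped for that run, so the full reference
catalog can drive a reduced model.  `compare_runs` contrasts two summaries
(per-site occupancy, per-species catalytic access, co-localization) and
refuses summaries produced under different parameter blocks.

## Mass calculator

Formulas are built constructively: glycerophosphoethanolamine backbone
(C₅H₁₄NO₆P) + two fatty acyls (CₙH₂ₙ₋₂dO₂) − 2 H₂O for the ester bonds,
plus modification deltas — hydroperoxy +O₂, hydroxy +O, nitroso +NO −H.  The
nitroso adduct models the coupling of the carbon-centered lipid radical with
the NO• radical, hence the net −H relative to the parent PE.  An acyl chain
declaring more than ⌊(c−2)/2⌋ double bonds is rejected as infeasible
(methylene-interrupted geometry).  Monoisotopic masses use principal-isotope
IUPAC/CODATA values; [M−H]⁻ subtracts the proton mass (1.007276 Da), which
already accounts for the electron.  Reported precision is 4 decimals;
comparisons in tests use absolute tolerances.

Observed m/z values from real spectra can differ from these theoretical
values by instrument calibration (tens of ppm); the calculator provides
theory, not peak assignment.

## Numerical choices and limitations

- Tie-breaks: ranked residue outputs sort by descending time, then residue
  number ascending; events sort by time, then labels.  All outputs are
  deterministically ordered.
- Boundary arithmetic on durations uses a 10⁻⁹ epsilon so that, e.g., a
  5.0 ns absence at 0.1 ns/frame satisfies a ≥ 5 ns window exactly.
- Problem sizes in tests (≤ 1500 frames, ≤ 200 atoms, ≤ 100 planted events)
  keep the full suite around ten seconds while exercising every code path;
  all kernels are vectorised over frames and scale linearly in
  frames × atoms.
- The package measures geometry only: no energetics, no reaction chemistry,
  no tunnel-shape computation (sites are residue sets, not probe-swept
  cavities), and no inference about causality of a displacement beyond the
  operational windows.
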