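# Methods

## Scope and shape

plasmidcad is a *compiler and ledger*, not a designer: primer design, melting
temperature optimization and assembly-strategy selection are the job of the
upstream CAD/design tool whose tabular output this package consumes. The
package owns everything downstream of the design: stoichiometry, plate
logistics, QC calling, redo planning and campaign bookkeeping.

## Expected assemblies

A construct is an ordered list of PCR fragments whose termini carry homology
arms. Arms are counted **inside** fragment length (a PCR product physically
contains them), so the assembled size is Σ lengths − Σ junction overlaps,
with *n* junctions for an *n*-fragment circular plasmid and *n* − 1 for a
linear product. Sequence merging emits each shared overlap once and demands
an exact match of at least the campaign homology minimum (default 60 bp) at
every junction, including the circular wrap; a mismatch is an error naming
the offending fragment pair, never a silent best-effort join. Sequences are
normalized (uppercase, whitespace stripped) on ingest.

## Demand and thermocycling

Fragment demand is ⌈uses / capacity⌉ replicate PCRs, where `capacity`
(default 4) is how many assembly reactions one PCR product can feed. This is
a configuration value, deliberately not hard-coded: it is the single knob
linking combinatorial usage to bench effort.

Reactions are grouped into thermocycler blocks by 1-D clustering on annealing
temperature: greedy span-limited grouping on the sorted temperatures (default
span 2 °C). When the greedy result exceeds the block budget, the smallest
feasible span is found by bisection over the pairwise temperature gaps, which
is optimal for contiguous partitions of 1-D data. A group runs at its coolest
member's temperature (permissive for every member) with extension time
⌈max product size / polymerase rate⌉ at a default rate of 1000 bp per 30 s.
Annealing temperatures default to the cooler primer's nearest-neighbor Tm
(Biopython's `MeltingTemp.Tm_NN`) when the design does not supply conditions.

## Mix stoichiometry

Equimolar dosing uses the average double-stranded DNA molecular weight
MW(L) = 617.96·L + 36.04 g/mol, stated explicitly so results are
reproducible bit for bit. The volume delivering *m* fmol of an *L*-bp
fragment at *c* ng/µL is *m*·MW(L)·10⁻⁶/*c* µL, rounded **up** to the
acoustic droplet quantum (default 25 nL; 2.5 nL supported) so a mix never
under-delivers moles; equivolume fills round **down** to avoid overflow, with
the remainder as water. If equimolar doses exceed the target total volume the
compiler errors rather than silently rescaling — rescaling would change the
moles delivered, which is the one thing the mode promises. Vector excess is
an explicit ratio (default 1.0, true equimolar).

## Plates, volumes, and validation

All addressing accepts `A1`/`A01` and emits unpadded; fill order defaults to
row-major and is configurable because 8-channel heads favor column-major.
96→384 stamping uses the standard interleaved quadrant convention
(row₃₈₄ = 2·row₉₆ + ⌊q/2⌋, col₃₈₄ = 2·col₉₆ + q mod 2). Every picklist is
simulated against plate state before anything is reported as executable:
validation precedes mutation, failures are all-or-nothing per picklist, and a
source may never be drawn below its labware's dead volume. Dead volumes and
capacities are configuration with documented defaults (acoustic source
2.5 µL, PCR plate 5 µL, deep-well 10 µL), not vendor gospel.

Pooled PCR consolidation (all passing replicates of a fragment into one
well) runs on 2 mL deep-well plates, and downstream bead-purification /
digestion worklists take per-sample volumes so pooled wells carry
proportionally more material forward. High-use fragments therefore stock
enough purified material for all their assembly draws — the same reason the
demand plan made replicates in the first place.

## QC calling and redo rounds

A capillary-electrophoresis peak table is parsed through a column mapping
(instrument export formats vary), alignment-marker sizes are stripped by a
configured list, and unparseable rows are collected and reported rather than
dropped. A reaction passes when some peak has relative size error ≤ τ
(default 0.10) and concentration ≥ 1 ng/µL; the matched peak minimizes
relative error with ties broken toward higher concentration, making calls
deterministic. An empty lane is its own verdict. Passing is monotone in τ by
construction.

Fragments are *verified* once any replicate passes in any round; reactions
that fail keep reappearing — conditions copied verbatim, or ±2 °C
alternating under the gradient strategy — until the round budget (default 6)
is exhausted, after which the fragment is *exhausted*, never silently
dropped. Feasibility is the pure monotone function: a construct is feasible
iff every fragment is verified.

## Campaign tracking

The build state is a forward-only ledger: colonies must belong to plated
constructs, verdicts to registered colonies, and every mutation re-validates
provenance. Colony registration caps at the configured picks per construct
(default 3) with a warning on excess rows — picker files in practice
occasionally contain more picks than requested, and that is data, not an
error. A construct is *verified* when some colony has full reference
coverage and zero mutations (both thresholds configurable). Consolidation
cherry-picks exactly one qualifying colony per verified construct — the
lowest (plate, well-index) qualifier, a deterministic and idempotent rule —
onto ⌈n/96⌉ archive plates, and lists verified constructs that lack a
qualifying colony instead of skipping them. State snapshots are versioned
JSON: desk-scale, diff-able, no database.

## The synthetic campaign generator

The generator emulates a large combinatorial build as a chain of independent
Bernoulli stages per entity, with default probabilities taken from empirical
per-stage survival rates of a published ~900-construct campaign: PCR pass
0.88, yeast assembly growth 0.66, *E. coli* transformation 0.70, colony-PCR
pass 0.41, full sequencing coverage 0.76, zero mutations 0.65. Successful
PCRs emit a peak at the expected size times 1 + ε with ε ~ N(0, σ), σ = 0.03
by default; failures emit a grossly wrong-sized product or an empty lane.
With τ = 0.10 the false-fail probability is the Gaussian tail
2·Φ̄(τ/σ) ≈ 8.6×10⁻⁴, verified by simulation.

Designs use a shared inter-bin junction model: consecutive bins exchange a
fixed 60-bp linker, so every full-factorial combination of parts has exact
overlaps by construction — as docking-domain libraries do physically. The
default design is a 3-bin 2×3×4 factorial (24 circular constructs,
fragments 1–3 kb); the acceptance script scales to a 4-bin 2×5×5×4 design
(200 constructs). These sizes are the package's chosen test conditions: they
exercise replicate demand, multi-plate layouts and every funnel stage while
staying desk-sized.

What the simulator does **not** model, and hence what passing tests do not
show about real campaigns: correlated failures (shared templates, GC-rich
parts failing in every replicate — the main reason real fragment attrition
persists across redo rounds), polymerase error spectra, yeast recombination
infidelity, smears and primer-dimers in electropherograms, and colony-count
variation (exactly three picks per growing construct). Because failures are
independent, six redo rounds nearly always rescue every fragment, so the
simulated funnel is more generous upstream than a real campaign with
persistent hard-to-amplify fragments.

## Numerical and degenerate-input choices

Volumes are compared with a 10⁻⁹ µL slack to keep quantized arithmetic
exact; droplet quantization uses round-half-away ceilings on a 10⁻⁹-rounded
ratio so exact multiples stay exact. Empty designs, empty registries, empty
redo sets and zero-construct exports are all legal and produce header-only
artifacts. Seeds drive a single `numpy` generator per simulation; identical
seeds give byte-identical design bundles and identical campaign states.
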