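# Methods

## The model

The bundled lymph-node net is a place/transition net with 49 places, 65
transitions and 149 arcs.  Places are named `SPECIES[_SPECIES...]
[_QUALIFIER]_COMPARTMENT` (complexes list all constituents; the qualifier
`G1` marks a replication-phase intermediate and `D` degraded material
awaiting clearance); transitions are named
`PROCESS_SPECIES..._COMPARTMENT[_COMPARTMENT]` with the process codes
influx/outflux (IN/OUT), translocation (TRA), encounter/separation
(ENC/SEP), differentiation (DIF), replication phases (G1/M), regeneration
(REG) and antibody release (REL).  The complete vocabulary ships as
`data/vocabulary.yaml`; `vocab.parse_node_id` decomposes every identifier
and the model self-check asserts that all 114 ids parse.

The encoded biology, compartment by compartment: antigen (`AG`) invades
the tissue through the input transition `IN_AG_TIS`; subcapsular-sinus
macrophages capture it (`ENC_M_with_AG_SCS`), carry it to the T zone and
hand it to antigen-presenting cells, which activate T cells; an activated,
antigen-bearing T cell recruits a naive B cell and the conjugate moves to
the light zone, where separation leaves an activated B cell carrying the
antigen (`B1_AG_LZ`).  Follicular dendritic cells strip and display the
antigen, macrophages collect and degrade it.  Activated B cells shuttle
between light and dark zone, replicate in the dark zone through the pure
two-step mitosis motif (`G1_B1_DZ` then `M_B1_DZ`, whose output arc has
weight two), and are also eliminated there by macrophages that engulf two
cells at once (the weight-two input arc of `ENC_M_with_B1_DZ`).  Exit from
the germinal center runs through differentiation to plasma cells — either
directly or helped by a germinal-center T cell — migration via T zone and
medulla to the blood and tissue, where plasma cells cycle between a
resting and an antibody-loaded state (`REG_B2_TIS` / `REL_AB_TIS`).
Antibody opsonizes antigen and the complex is destroyed by tissue
macrophages, leaving separate antigen and antibody debris that exit
through dedicated outflux transitions.  Memory B cells form in the
medulla, replicate there (second weight-two arc), and re-enter the
circulation as plasma cells.  There are exactly two input and six output
transitions; death and elimination happen only at the borders, never as a
silent internal sink.

### Provenance of the encoding

The net was reconstructed from the published narrative description,
figure captions and abbreviation tables of the underlying study; the
full reaction listing of the original model was not available.  The reconstruction was
accepted only when it reproduced *every* printed summary quantity
simultaneously: node/arc counts, border and weight-two arc counts, the
structural predicates (pure, connected, not ordinary, not conserved, not
strongly connected), 25 transition invariants with 13 trivial members and
non-trivial lengths spanning exactly 5–28 (the 28-transition activation
pathway and the 8-transition antibody module included), 4 place
invariants, the 49/57/141 PBOPN with ten place invariants and the
antibody place as the only uncovered one, and a conservative
antibody-deleted reduction with twelve place invariants.  Transition and
place names printed in the text are used verbatim; names of transient
complexes and debris places are this package's own.  Consequences of this
reconstruction for the Manatee-invariant layer are discussed below.

## Algorithms and numerical choices

**Invariants.**  Minimal semi-positive invariants are computed by
Farkas/Fourier–Motzkin elimination on `[Aᵀ | I]` with exact Python
integers — no floating point anywhere — with gcd normalisation and
support-minimality pruning after every elimination step, and a
configurable cap on intermediate rows (default 2,000,000) that raises
rather than thrashes.  Output order is deterministic (lexicographic by
sorted support).  The engine is cross-checked against an independent
brute-force oracle that enumerates all coefficient vectors up to bound 8
on nets of up to 7×7 nodes; since the oracle cannot see invariants with
coefficients above its bound, comparisons restrict the engine output to
the same box.

**Manatee invariants.**  A TI is token-neutral but need not be
schedulable from the empty marking.  Because no transition sequence can
ever place tokens on a conserved pool that starts empty (the zero-marking
property of place invariants), feasibility is judged from a marking that
seeds the PI-covered pool places with ample tokens and leaves everything
else empty.  Realizability of a summed Parikh vector is decided by a
structural startability fixpoint (fast rejection), a greedy scheduler
(fast acceptance) and an exact memoised depth-first search for the
remainder.  Combinations of up to four distinct TIs (multiplicity one)
are enumerated, and the MI set is the union over all seed TIs of the
inclusion-minimal feasible combinations containing that seed.  An MI is
*pure* when its induced subnet, taken as a net of its own, admits no
place invariant — impure MIs conserve something internally and therefore
depend on pre-existing tokens.

The published account reports 66 MIs (7 of them single TIs, lengths up
to 37, 3 pure, 14 antibody-producing, 30 antigen-eliminating without
antibody) but specifies neither the construction's exact minimality
criterion (that lives in an external reference) nor the complete
listing of the combinations.  On the reconstructed net this implementation finds 80 MIs
(14 single, lengths 2–41, 2 pure, 8 antibody-producing).  The deviation
is reported as measured; it traces to reconstruction choices such as
which movement shuttles are reversible pairs (each pool-species shuttle
is feasible alone and becomes a trivial MI) and the coupling of both the
antibody and the antigen-destruction routes to both influx transitions.

**Knockout.**  Knocking a transition removes every MI through it; a
target place is affected when no surviving MI contains a transition
producing onto it.  Production means a token gain on the place, not mere
adjacency.  Of the published 5×3 example matrix, 12 of 15 cells
reproduce, including both compensation rows (knocking either replication
alone has no effect) and the antibody-release row.  The three deviating
cells all concern the antibody/influx coupling described above.

**Simulation.**  One transition per step, chosen uniformly at random
among enabled, non-disabled transitions; input transitions compete on
equal footing, which yields the linear antigen accumulation of the
empty-marking scenario.  All reactions share one notional time scale; the
dynamics come from the combinatorial structure alone.  Runs are
reproducible from a single integer seed (`numpy.random.default_rng`);
enabled-set maintenance is incremental, so a 100,000-step run takes about
a second.  Markings save and load as flat `place<TAB>count` text files and
replay bit-identically.

The four standard scenarios: A — empty start, 10,000 steps; B — 100
tokens on antigen and on each conserved pool (`AG_TIS`, `M_TIS`,
`APC_TZ`, `T_BL`, `DC_GC`), 10,000 steps; C — continue from an adapted
marking with antigen influx disabled, 10,000 steps; D — as C after 20,000
adaptation steps, run for 100,000 steps.  Long runs record only tracked
places at a configurable stride (`record_every`) and keep the full
marking at the end.

In scenario C the memory pool (about 20 cells after adaptation) performs
a near-critical random walk — G1/M replication against
re-differentiation — so its extinction time is broad: about a third of
seeds lose all memory within 10,000 steps, the rest later.  The published
figure shows a single representative run; an ensemble statement of
"memory usually lost within 10,000 steps" does not hold at this
reconstruction's mixing rate, and the acceptance suite reports the
measured fraction rather than asserting the single-run anecdote.

## Synthetic benchmark nets

`synthetic` generates the structural motifs the model is built from, at
sizes where expectations are closed-form: token-conserving rings,
border-to-border chains (one through-flow TI, no PI), a two-species
binding/release pair (two PIs sharing the complex place), the pure G1/M
replication motif, and seed-deterministic random bipartite nets for the
oracle comparison.  These deliberately do not emulate realistic degree
distributions or rates; they exercise the engines' correctness, not the
biology.

## Known limitations

* The net is a reconstruction; identifiers and counts printed in the
  source narrative are reproduced exactly, but individual reactions not
  named there (complex intermediates, debris routing, escort of B cells
  by T cells into the follicle) are this package's own modelling choices.
* Boundedness, liveness and reachability are out of scope; the structural
  report exposes only what invariants imply (e.g. PI coverage as a
  sufficient boundedness condition on the covered places).
* The Manatee construction follows the definition given with the model
  (feasibility-oriented TI combination, minimal per seed) and not the
  unpublished reference implementation; its counts are reported, not
  calibrated.
* Timed, colored, stochastic-rate and hierarchical extensions are
  out of scope, as is fitting kinetic data.
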