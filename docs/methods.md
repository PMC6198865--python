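# Methods

This note records the modelling and engineering decisions behind the
package, in the order a maintainer is likely to meet them.

## The event grammar and the object model

An `<eventsRec>` block is a regular sequence `transferBack* terminal`, where
the terminal is one of `speciation | duplication | branchingOut |
bifurcationOut` (bifurcating: the clade has exactly two children) or
`leaf | loss` (lineage-ending: no children).  The model enforces this at
construction: `Event` checks attribute legality (`speciesLocation` is
mandatory on located events and forbidden on `transferBack` /
`bifurcationOut`; `destinationSpecies` only on `transferBack`; `geneName`
only on `leaf`; `timeSlice` a non-negative integer), `EventSequence` checks
the regular structure, `GeneNode` checks that the child count equals the
terminal's arity.  Confidence values are deliberately unconstrained reals —
support conventions differ between producers — with a validator *warning*
outside [0, 1].

Trees are strictly binary.  Every event's semantics is binary or
lineage-ending; a polytomy has no defined event, so clades with a child
count other than 0 or 2 are rejected.  Sibling order is preserved on read
and write but carries no meaning: all structural comparisons
(`gene_trees_equal`, `documents_equal`) are invariant under swapping
siblings.  Node identity is by object, not by name (gene names need not be
unique — simulated and reconciled trees reuse `LOST`).

Each type also has an `unchecked` constructor that bypasses validation.
This is how the lenient reader and the validator's own tests materialize
malformed documents; user code should never need it.

Lineages in unsampled/extinct species map to the identity-based `UNSAMPLED`
sentinel rather than any reserved name string, so collision with user
species names is impossible by construction.

## Reading and writing

The reader (lxml) matches local tag names, so documents with or without a
namespace on the root parse identically.  Strict mode turns every deviation
into an error; lenient mode downgrades the recoverable ones — unknown
phyloXML clade children (kept verbatim as opaque blobs and re-emitted on
write), nameless geography areas (placeholder name), `rooted="false"` — to
warnings.  Grammar violations (missing/extra terminal events, arity
mismatches, more than one species tree, zero gene trees) are errors in both
modes because no faithful in-memory object exists for them.

The writer emits UTF-8, two-space indentation, `rooted="true"` on every
phylogeny, and a fixed attribute order (`speciesLocation` /
`destinationSpecies`, then `confidence`, `timeSlice`, `geneName`).  Floats
are written with Python's shortest round-trip repr.  Together this makes
serialization a pure function of the document: equal documents give
byte-identical files, and write–read–write is byte-stable.

Plain Newick/NHX input goes through dendropy with `preserve_underscores`
(species/gene naming conventions depend on underscores) and with leaf taxa
suppressed (gene trees legitimately repeat the `LOST` label).  A quirk worth
recording: a comment trailing the root label is attached by dendropy to the
`Tree` object, not the seed node, and is merged back into the root here.

## Validation

Level 1 re-derives the grammar checks from scratch (codes `E_NO_TERMINAL`,
`E_EARLY_TERMINAL`, `E_MULTI_TERMINAL`, `E_ARITY`, `E_ATTR`, `E_DOC`), so it
also classifies objects built through `unchecked` constructors.

Level 2 checks the reconciliation against the species tree.  The format
itself fixes only local tag grammar, so the cross-node rules are derived
from the events' meaning; all rules that an interoperable reader might not
share are strict-mode only, and lenient mode keeps just species-name
resolution (`E_SPECIES_UNKNOWN`) and timeSlice monotonicity
(`W_TIMESLICE`).  The *starting species* of a branch is the destination of
its leading `transferBack` if it has one, else the species of its terminal
event (`UNSAMPLED` for `bifurcationOut`).  Strict rules:

* `E_SPECIATION_CHILDREN` — a speciation at *s* must send its children into
  the two distinct child species of *s*;
* `E_DUP_CHILDREN` — a duplication's children both start in *s*;
* `E_BRANCHINGOUT_CHILDREN` — exactly one child remains in *s*, the other
  is an emigrant (leading `transferBack` or terminal `bifurcationOut`).  A
  resident `loss` child is legal (transfer whose donor copy later died);
  strict mode permits loss only on the resident side;
* `E_BIFOUT_CHILDREN` — both children of a `bifurcationOut` are emigrants;
* `E_ORPHAN_TRANSFERBACK` — a reception requires a donor-side branching
  event in the parent.  A *root* beginning with `transferBack` is only a
  warning (`W_ROOT_TRANSFERBACK`): the family's origin may simply lie
  outside the sampled tree;
* `E_TRANSFER_SELF` — within a chain of `transferBack`s, successive
  destinations must differ (each is a genuine species change, applied in
  listed order);
* `E_TRANSFERBACK_TERMINUS` — after a chain, the terminal event must take
  place in the last destination, and `bifurcationOut` cannot follow a
  re-entry.  This rule is not in the obvious per-tag reading of the format;
  it was added when the independent lineage-threading oracle (see below)
  rejected sequences like `[transferBack(A), bifurcationOut]` that the
  per-tag rules accepted.  The two implementations now agree exhaustively
  on small instances.

`W_TIMESLICE` warns when timeSlice ranks decrease along any root-to-leaf
path, with rank 0 oldest.  Dated-subdivision conventions vary between
tools, which is why this is a warning and why no check is made against real
branch lengths.

The test suite contains an independent oracle (`tests/oracles.py`) that
decides legality by recursively threading the lineage's location (a sampled
species or the unsampled compartment) through every event sequence — a
different decomposition of the same semantics.  Validator and oracle are
compared exhaustively over all event assignments (with up to one
`transferBack` prefix per node) of 1- and 3-node gene trees on a 3-species
tree, and on thousands of sampled 5–7-node assignments over a 4-leaf
species tree.  Full exhaustion at 7 gene nodes × 4 species leaves would be
~10^14 assignments and is not attempted; the enumerated layer plus the
sampled layer covers every rule interaction the enumeration space contains.

## LCA duplication–loss reconciliation

Classical most-parsimonious reconciliation without transfers: each gene
node g gets M(g), the LCA in the species tree of its descendant species;
g is a duplication iff M(g) equals a child's mapping, else a speciation.
Explicit `LOST` leaves are inserted along the species path between M(g) and
M(c) for each child c — starting below M(g) for a speciation (the child
enters a child branch of M(g)) and at M(g) itself for a duplication (the
copy starts inside the branch).  Each inserted node is a speciation at the
path species with the loss in the off-path child.  This charges d−1 losses
per speciation child and d losses per duplication child (d = species-tree
edges from M(g) to M(c)), which is the standard minimal DL count; the
package's cost is verified against an exhaustive minimization over all
feasible assignments on 500 random instances.

The output is a complete document (species tree included) and passes strict
validation by construction.  Reconciliation is deterministic: identical
inputs give byte-identical XML.  Unnamed interior species nodes are
auto-named `S1, S2, …` in preorder so that every `speciesLocation` is
addressable.

## The DTL simulator

The simulator exists to generate unboundedly many *valid* documents that
exercise every tag, including the two-step transfer representation.  One
gene lineage enters at the top of the root branch (or at the root node if
the root has no branch length) and evolves with exponential waiting times
at total rate `dup + transfer + loss` per unit branch length; rates are
homogeneous across branches.  Species trees must be binary, ultrametric
(tolerance 1e-9) with strictly positive branch lengths; node times count
back from the contemporaneous leaves.

Transfers route through a single undated unsampled compartment: the
emigrant copy of a `branchingOut` dwells outside for an exponential
(transfer-rate) time capped at the time remaining, then re-enters a branch
chosen uniformly among those alive at the re-entry time, excluding the
donor for a direct re-entry.  With probability `unsampled_bifurcation_prob`
the emigrant first bifurcates outside (`bifurcationOut`) and both daughters
re-enter independently (one nesting level by default;
`allow_nested_bifurcation` lifts the cap).  On a single-branch species tree
no recipient can exist, so a drawn transfer is a no-op rather than an
unrepresentable one-child event.  What this compartment does *not* emulate:
an explicit extinct-species tree with its own birth–death dynamics, rate
heterogeneity, replacement transfers — so passing tests say nothing about
the realism of transfer time distributions, only about format validity and
the bookkeeping of donor/recipient pairing.

`timeSlice` is emitted (toggleable) as the rank, 0 = oldest, of the
inter-speciation time interval containing the event; because event times
are non-increasing along every gene path, slices are non-decreasing and the
validator's monotonicity warning is exercised but never triggered by
simulator output.

Defaults (`dup = transfer = loss = 0.1`, `unsampled_bifurcation_prob =
0.1`, survival conditioning on) are mild enough that a three-species tree
yields mostly tree-like families with occasional transfers.  Closure
checks instead draw all three rates uniformly from [0, 0.7] and the
bifurcation probability from [0, 1], which produces dense multi-event
families.  All randomness flows through one `random.Random(seed)` stream
with a fixed recursion order, so equal seeds give byte-identical files.
Survival conditioning redraws up to 100,000 times before failing loudly.

The pure-duplication limit is checked analytically: on a single branch of
length T, leaf count is a Yule process with mean e^{δT}; 10,000 replicates
must sit within 3 Monte-Carlo standard errors.

## Rendering

The layout is deliberately simple and fully deterministic.  Time runs left
to right; each species occupies a horizontal tube whose x-extent comes from
its topological depth (leaf tubes extend to the right margin) and whose
height grows with the number of gene nodes mapped to it (one lane per
node, assigned in document order).  Tube y-intervals are allocated
disjointly with the parent corridor placed between its children, giving the
nested-tube look.  Gene anchors always lie inside their species' tube;
events in unsampled lineages are drawn in a reserved band above the tubes;
transfer segments are the only routes that cross tube borders, and they
cross the donor border exactly once.

Glyphs: square = duplication, cross = loss, diamond = transfer departure,
triangle = transfer arrival (the conventions of reconciled-tree figures);
circle for speciation, a four-point star for `bifurcationOut` and a small
dot for extant leaves are this library's own choices, made restylable via
one CSS class per event type (`event-speciation`, …) and stable element
ids.  Exactly one glyph element is emitted per event, so the SVG census
equals `count_events` by construction — and is re-counted in tests rather
than assumed.

## Interchange formats

The NHX dialect puts one comment per node: `Ev` (semicolon-separated tag
names, verbatim to avoid clashing with other tools' one-letter codes), `S`
(terminal species), `D` (transferBack destinations in order), `T` / `C`
(per-event timeSlices / confidences, empty slot = absent), `G` (leaf gene
name), `B` (node support).  This is lossless for everything except
geography annotations, which only exist in the XML format.  Plain-Newick
export keeps topology, names and branch lengths only.

`combine` requires all *present* species trees to be structurally equal
(absence is "unspecified", not "different") and reports the first divergent
node on conflict; gene-name spaces are not required to be disjoint.
`extract` selects by 0-based index in the API and 1-based index on the
command line.

## Problem sizes and numerical choices

Default test/acceptance scales: 10 canonical documents; 31,040 enumerated +
8,000 sampled assignments for the oracle comparison; 500 random LCA
instances (gene trees ≤ 9 nodes, species trees ≤ 4 leaves); 1,000 simulated
datasets for closure; 10,000 pure-birth replicates; 100 rendered documents.
These sizes keep the whole suite and the acceptance script in the
seconds-to-a-minute range while leaving each statistical check
well-powered.  Float equality in structural comparison uses a 1e-9 relative
tolerance; ultrametricity uses the same; species identity is exact,
case-sensitive string match.

## Known limitations

* No dialect converters for specific tools' Newick/NHX flavours, and no
  schema-file (XSD/RelaxNG) validation — the validator is native rule code.
* Dated consistency is checked only ordinally (timeSlice ranks), never
  against branch lengths.
* The LCA module is duplication–loss only; transfer-bearing documents come
  from the simulator or external producers.
* Multifurcations, ILS, gene conversion and transfer-with-replacement are
  outside the event vocabulary and rejected.
* The renderer draws every family of a document into one SVG; very large
  documents produce tall images rather than paginated ones.
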