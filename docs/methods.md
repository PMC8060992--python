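# Methods

## The model

metnav treats a metabolic network as an indexed set of metabolites and an
indexed set of reactions; a reaction has a left and a right participant
list (with stoichiometric coefficients), a direction, and curator
annotations (EC number, enzymes, genes, pathways, a spontaneous flag).
Stoichiometry is stored and round-tripped but deliberately plays no role in
neighborhood computation: precursor/successor status is defined purely by
side membership, which keeps the definition faithful and the result
independent of coefficient conventions.

Direction has four values. `LEFT_TO_RIGHT` and `RIGHT_TO_LEFT` admit one
*effective orientation* each; `REVERSIBLE` and `UNSPECIFIED` admit both.
The two bidirectional-acting values are kept distinct because a database
may record genuinely unknown directionality rather than known
reversibility; SBML import can never produce `UNSPECIFIED` (the SBML
`reversible` attribute is boolean) — only native files, or SBML written by
this package (which records the original value in notes), can.

### Neighborhoods

For focal *M*, the precursors are all non-ubiquitous *P ≠ M* with some
reaction carrying *P* on an effective reactant side and *M* on the matching
product side; successors are symmetric. Consequences of the definition:

- a reversible-only link places the neighbor in both lists;
- a reaction with *M* on both effective sides never makes *M* its own
  neighbor (self-edges are display noise and name no distinct role);
- the currency omission applies **only** to neighbor lists. Side-metabolite
  listings, the candidate panel, and direct neighborhood queries of a
  currency metabolite all work normally. Likewise, the reactions linking
  two *path* members are computed directly from the reaction set
  (`linking_reactions`), not through neighbor lists, so a path legitimately
  starting at a currency metabolite still supports reaction selection and
  count display.

The default currency set, used only when the input carrier has no explicit
flags (plain SBML), is {water, H2O, H, H+, proton, phosphate, Pi} matched
case-insensitively against ids and names; it is fully overridable per
network (`Network.set_ubiquitous`, `--ubiquitous-file`, or the `ubiquitous`
key of the TOML config). The native format carries explicit per-metabolite
flags instead.

Entries are sorted by display name then id — an arbitrary but deterministic
order. Neighborhoods are cached per focal metabolite; the cache is
invalidated when reactions are added or the ubiquitous set changes, and the
test suite asserts cached == uncached.

### Connection classes

A focal–neighbor connection on a given side is classified
`MULTIPLE` > `SPONTANEOUS` > `BIDIRECTIONAL` > `UNIDIRECTIONAL`, evaluated
in that order. Multiplicity is the only property of the reaction *set*
rather than of a single reaction, so it dominates; spontaneity is rarer and
more informative than reversibility, so it outranks it. The class is a
total function of the linking-reaction multiset.

### The path state machine

A path is a non-empty list of steps; each non-terminal step stores its
metabolite, the selected successor reaction, and the orientation in which
that reaction is used. Adding neighbor *N* at anchor step *i*:

- successor at the last step / precursor at the first step → pure
  extension, history untouched;
- successor at any other anchor → steps after the anchor are discarded and
  *N* appended; precursor at any other anchor → steps before the anchor are
  discarded and *N* prepended. The displaced path is pushed onto the
  history (most recent first). The side chosen by the caller decides which
  portion is discarded, preserving the clicked connection.
- **Degenerate case**: a "replacement" that rebuilds the identical path
  (re-adding the same neighbor via the same reaction) is a no-op — neither
  the path nor the history changes. This keeps the history free of
  duplicates of the current path while preserving "every genuine
  replacement grows history by exactly one".

Tie-breaks: when several reactions link a pair and none is specified, the
lexicographically smallest reaction id is selected; when a reversible
reaction admits both orientations for the same (reactant, product)
assignment, the forward orientation is tried first. Both rules exist purely
for determinism. Restoring a history entry *swaps* it with the current path
rather than copying, so restore is an involution and memory stays bounded.
Cycles are allowed — a metabolite may recur in a path — because forbidding
them would block legal biochemistry (futile cycles, regenerating loops).

Paths are validated structurally (`validate_path`): every adjacent pair
must be linked by its recorded reaction in its recorded orientation, and
the terminal step must carry no successor reaction. The API forces the
caller to state the side when a reversible link makes a neighbor both
precursor and successor; guessing would be silently wrong half the time.

### Links and rendering

The link string (`LINKFORMAT.md`) percent-encodes every id with no safe
characters, so the structural separators cannot collide with id content;
the per-step orientation is encoded explicitly rather than re-derived, so
decoding is exact even when both orientations would fit. History is
intentionally not part of the link — a link reproduces the *displayed*
path.

Rendering (`RENDERING.md`) draws the path top-to-bottom; each element
carries a stable anchor id, identical in grammar across the text and SVG
backends because both consume the same element stream. Only ordering and
element presence are contractual; layout metrics are not. Connection-class
colors/letters are this package's documented legend — the original display
convention this mirrors is not published, so no palette is guessed.
Structures are rendered as SMILES text; graphical depiction is deliberately
out of scope of the rendering contract.

## The synthetic generator

`FixtureSpec` defaults describe the test-bed conditions used throughout:
200 metabolites, 500 reactions, 30% reversible, 5% spontaneous, 5%
currency metabolites, 1–3 participants per side, all driven by a single
`random.Random(seed)` (same spec ⇒ byte-identical serialization). Sides
are sampled jointly without replacement, so a reaction's two sides are
disjoint. Spontaneous reactions carry no enzyme, gene, or EC annotation,
matching their biochemical meaning. 30%/5% reversibility and spontaneity
are round figures in the range seen in curated bacterial reaction sets; the
200/500 scale keeps a full brute-force cross-check of every metabolite of
100 networks comfortably fast while being dense enough (mean degree ≈ 10)
to exercise multi-reaction links, dual membership, and replacement.

What the generator does **not** emulate: the heavy-tailed degree
distribution of real currency metabolites (its currency molecules are
random, not hubs), compartments, mass balance, and realistic coefficient
patterns. Passing tests therefore demonstrate the correctness of the graph
semantics and state machine under controlled conditions, not performance or
curation quality on a genome-scale reconstruction — though nothing in the
code depends on the generator's statistics.

## Interfaces and formats

SBML L3V1 core is the lossy-but-standard carrier: EC/enzyme/gene/pathway/
spontaneous annotations, SMILES, `UNSPECIFIED`/`RIGHT_TO_LEFT` directions,
and ids that are not valid SBML SIds are recorded in XHTML notes as a JSON
payload and restored on load; a document from another tool simply has no
such notes and gets the boolean direction mapping plus name-based currency
detection. The native JSON format is the lossless carrier and the schema in
`schemas/` is its contract. Identifier comparison is case-sensitive
exact-match everywhere; compartmentalized instances of a compound are
distinct metabolites (merging is data preparation, not this library's
job).

## Known limitations

- No automatic path search: exploration is strictly user-driven by design.
- Neighbor lists are "complete minus the configured currency set"; no
  atom-mapping or flux-based filtering of spurious currency links.
- The SBML notes payload is this package's own convention; other tools will
  ignore it (by design it degrades to plain valid SBML core).
- The candidate panel and diagrams emit text; hyperlinking into external
  databases is out of scope.
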