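# Methods

## The model

An experimental protocol is represented as a **workflow embedded within a
document**.  The document layer (`DocumentMetadata`) carries what a reader
needs to archive, find and cite the protocol: title, authors (with optional
quality-control roles such as *chief scientist* or *statistical reviewer*),
a protocol identifier (DOI or internal code), application, provenance,
objective, advantages/limitations, version, and the declared materials —
specimens, reagents, kits, equipment, and recipes.  The workflow layer
(`Workflow`) carries what an executor needs: an ordered list of laboratory
procedures, each with experimental inputs and outputs, and each composed of
subprocedures (instruction steps) with participants, quantitative measures
and alert messages (*caution*, *hint*, *pause point*, *troubleshooting*).

Key representation decisions:

- **Single stored ordering relation.**  Order among sibling procedures or
  steps is stored only as `preceded_by` (one optional predecessor); the
  inverse *precedes* is derived on demand and never stored or emitted, so the
  two duals can never disagree.  Where links are absent, document order is
  authoritative — protocol narratives frequently leave order implicit — and
  when links define only a partial order, ties are broken by document order
  and an `AmbiguityWarning` is recorded.
- **Reagent vs. kit vs. equipment is an authoring choice.**  Published
  protocols routinely conflate the three under "Reagents" while practitioners
  read them as distinct; the model therefore never infers the category from
  the name.
- **Recipes are text; recipe executions are processes.**  A recipe (how to
  prepare a buffer, how to clean equipment) lives in the document layer as a
  textual entity; the act of carrying it out is a workflow procedure of kind
  `recipe_execution`.
- **Procedure containers.**  A protocol that is only a flat list of steps is
  wrapped in one auto-generated `container` procedure, so flat and grouped
  protocols share a single representation (`wrap_flat_steps`).
- **Derived materials.**  Antibodies, cell lines and plasmids may carry a
  derivation annotation: the source organism (emitted as a *derives from*
  link) and the role the material plays (emitted as a *has role* link).
- **Containment is exactly-one.**  A subprocedure belongs to exactly one
  procedure (tree-shaped workflows); merged protocols duplicate steps rather
  than share them.  Loops and conditionals are out of scope.

### Validation

`validate_structure` reports, never throws, and never mutates.  Structural
breaks are errors: empty titles/ids, duplicate ids, dangling or cyclic
precedence links, an empty workflow, a catalog number without a
manufacturer.  Reporting-quality gaps are warnings (missing catalog numbers,
missing version), because published protocols routinely omit them and a
warning is actionable while an error would make most real protocols
unrepresentable.

### Ordering and IO chaining

`linearize_subprocedures` runs a stable topological sort (Kahn's algorithm
with the ready set drained in document order), so its output is the unique
consistent permutation when links form a chain and a deterministic,
input-order-stable completion otherwise.  Cycles raise `CycleError`.

`resolve_io_chain` links every procedure input that is not a declared
document-level material to the **nearest earlier** procedure whose outputs
contain a name-matching flow item.  Matching is case-insensitive and
whitespace-normalized, with no fuzzy matching: deterministic and testable,
at the price of missing paraphrased hand-offs (future work).  Unmatched
inputs are returned as warnings, not errors, because authors legitimately
omit chains.

## Interchange format

One protocol per YAML 1.2 file (`.spd.yaml`) with top-level `id`,
`visibility`, `document:` and `workflow:` sections.  Unknown keys are hard
errors so round-trips can never silently drop data.  Writing is
deterministic (stable key order and list order, empty optionals omitted,
UTF-8 throughout), and `parse ∘ write` is the identity; `write ∘ parse` is
idempotent after one pass.

## RDF mapping

The term registry mints **label-faithful IRIs** (`…sp#has-experimental-input`
for the label "has experimental input") under configurable namespaces for
the prefixes `sp`, `iao`, `ro`, `bfo`, `obi`, `chebi`, `ncbitaxon`, `nci`,
`siro` and the mock-data prefix `ld`.  Published ontologies use opaque
numeric fragments; since the artifact must run self-contained, it mints its
own IRIs and lets deployers re-point namespaces via an overrides map.

Slug rule (shared by vocabulary terms and data IRIs): lowercase, runs of
non-alphanumeric characters collapse to a single hyphen, outer hyphens
stripped.  Two distinct local ids that slug identically within one protocol
raise `SlugCollisionError`.  Data IRIs are
`base + kind + "/" + protocol-slug + "/" + local-slug`; blank nodes are never
used, so graphs are diffable and queries stable.

### Emission rules (triples per model element)

| element | triples |
|---|---|
| protocol base | 6 — document type, internal identifier, visibility, link to execution node, execution type, title |
| optional scalar (identifier, application, provenance, objective, version) | +1 each |
| advantage / limitation | +1 each |
| author | 4 (+1 identifier, +1 per role) |
| specimen | 3 (+1 each: organism, organism CURIE type, anatomical part; +1 per attribute; +6 derivation) |
| reagent | 3 (+1 each: manufacturer, catalog number, CURIE type; +6 derivation) |
| kit | 3 (+1 manufacturer, +1 catalog) |
| equipment | 4 (+1 manufacturer, +1 catalog) |
| recipe | 4 |
| undeclared flow item (distinct name) | 2 (+1 CURIE type) |
| input / output occurrence | +1 link (set semantics: a repeated name is one link) |
| procedure | 5 (+1 preceded-by) |
| subprocedure | 5 (+1 preceded-by) |
| participant | 3 (+2 with measure) |
| alert | 3 |

`count_expected_triples` re-derives the total by walking the object model
with no RDF machinery; conservation (`len(graph) ==` the count) is asserted
over the fixture and every fuzzed protocol.

Literal conventions: narrative text carries a language tag (default `en`,
configurable); names, identifiers and category tokens are plain strings;
measures are `xsd:decimal` with the unit as a separate literal; list
positions (which make author/procedure/step order recoverable from a set of
triples) are `xsd:integer`.  Flow items whose name matches a declared
material link to the material's node; the canonical form drops an
`external_ref` on such items because the declaration is authoritative.
The paper-level *has catalog number* relation is emitted as a direct literal
triple to keep instance graphs lean.

`from_rdf` inverts the mapping and returns the **canonical** protocol
(unordered collections sorted, positions honoured for ordered ones);
`from_rdf ∘ to_rdf = canonicalize`.  Unknown triples are ignored with an
`UnknownTripleWarning`; an untyped procedure raises `MissingTypeError`; a
subprocedure node not linked to any procedure raises `OrphanStepError`.

Canonical Turtle sorts subjects by IRI, predicates by IRI and objects by
lexical form, with the prefix header generated from the registry — output is
byte-identical for equal graphs, which makes determinism directly testable.
Deterministic query row order is obtained by sorting result rows after
evaluation (equivalent to appending an ORDER BY over all projected
variables, without rewriting the query text).

## SIRO cards

The SIRO (Sample–Instrument–Reagent–Objective) card is the minimal common
information shared across protocols, analogous to PICO in evidence-based
medicine.  Extraction rules:

- samples ← declared specimens; instruments ← declared equipment **and
  kits** (kit retrieval questions are instrument-shaped); reagents ←
  declared reagents; objective ← the document's stated purpose field only.
  Narrative mining of a scattered objective is out of scope — authors must
  state it.
- Workflow participants that match no declaration are routed by lexicon
  lookup, so the card stays truthful when authors under-declare; a
  participant the lexicon cannot place is skipped rather than guessed into a
  slot.
- Category classification uses a lexicon seeded with the exemplar terms of
  the published category table (whole organisms, anatomical parts,
  biomolecules, body fluids; five instrument classes; chemical compounds,
  solutions/buffers, culture media).  Lookup is normalized,
  slot-respecting, total (`unclassified` when absent) and deterministic;
  extension is config-file based, with no external vocabulary download.

`export_siro_rdf` reuses the same document-layer predicates as the full
mapping plus `siro:` typing and category literals, so SIRO-level competency
queries run unchanged over full and SIRO-only graphs, while step-, alert-
and recipe-level queries return zero rows *by construction* — the graph
simply contains no such nodes.  The privacy invariant (export literals
disjoint from the protocol's step/alert/recipe text) is asserted for the
fixture and fuzzed private protocols, and `run_siro_only_audit` records both
what stays answerable and what is suppressed.

## Competency queries

The suite formalizes the questions quoted with the model: protocols by
sample, reagents with manufacturers, caution steps, protocols by author,
author+sample conjunction, common reagents across two protocols, plus the
linked-data variants.  Federated SPARQL against public endpoints is replaced
by **local mock graphs** with the same join shape — taxon→order membership
(a rodent-order entry is planted so the "samples from the Rodent order"
query shape is exercised), reagent→vendor offers, reagent→applications and
reagent→disease hazards — shipped as small synthetic Turtle files.  The
same query logic runs desk-scale with no network; only the data source is
mocked, not the join.

## Synthetic-protocol generator

`synthesize_protocol(SynthConfig)` emulates the shape of real protocols at
the scale of the running example: by default 3 procedures of 3–6 steps,
materials drawn from fixed pools of realistic names (TRIzol, chloroform,
forceps, RNeasy kit, …; organisms from the lexicon so taxon joins are
testable), a 0.2 per-step alert probability, and a 0.5 probability that
consecutive procedures hand an intermediate material from one to the next
with exactly matching names.  Output is deterministic per seed, always
passes structural validation, and is emitted in canonical order.

What the generator does **not** emulate: free-text step narrative (step
texts are templates), under-specified or paraphrased IO hand-offs, loops and
conditionals, and authorship metadata variety.  Passing tests therefore
demonstrate the correctness of the representation, serialization and query
machinery — not the ability to parse real narrative protocols, which is
explicitly out of scope.

## Problem sizes and numerical choices

Round-trip suites run the fixture plus 200 seeded synthetic protocols;
privacy audits 20 private protocols; ordering checks enumerate all
permutations up to length 7 (5040), the practical ceiling for the
brute-force oracle.  Measures are compared as decimals serialized from
their shortest repr; there is no floating-point tolerance anywhere because
every comparison in the pipeline is exact (strings, counts, sets).

## Known limitations

- Steps 5–20 of the running example's extraction procedure are not printed
  in the public summary of the source protocol; the fixture ships
  counts-faithful numbered placeholders (`step-05`…`step-20`) whose text
  marks them as unprinted, so tests can rely on the structure but not on
  their wording.
- The reagent–manufacturer pairing in the fixture (TRIzol→Invitrogen, the
  rest→Sigma-Aldrich) and the equipment categories are the package's own
  assignment; the source table prints only the name lists.
- CURIE locals are kept verbatim in minted IRIs and must therefore be
  IRI-safe.
- The document node and the protocol-execution node are distinct linked
  individuals (document layer vs. workflow layer); deployments aligning
  with a published OWL rendering may need to revisit this split.
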