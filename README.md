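# smartprotocols

Structured representation of experimental protocols for research-data
management: an in-memory **document + workflow** model with structural
validation, a plain-text interchange format, a lossless **RDF vocabulary
mapping** with deterministic Turtle output, **SIRO**
(Sample–Instrument–Reagent–Objective) minimal-information cards with
privacy-preserving export, and a **SPARQL competency-question suite**.

It is written for the people who curate, publish or search laboratory
protocols — data stewards at journals and repositories, lab information
managers, and ontology engineers — and for anyone who needs protocols to be
*born semantic*: readable as documents by humans and processable as
workflows by machines.

## The model in brief

A protocol `P = (D, W, v)` couples a document layer `D` (title, authors,
identifiers, declared specimens/reagents/kits/equipment, recipes) with a
workflow layer `W`: an ordered list of laboratory procedures
`W = ⟨p₁ … pₙ⟩`, each `pᵢ` holding subprocedures (instruction steps with
participants, measures and caution/hint/pause-point/troubleshooting
alerts), experimental inputs and outputs, and an optional *is-preceded-by*
link.  `v ∈ {public, siro_only}` is the visibility flag.

Three derived structures do the analytical work:

- **Linearization** — a stable topological sort of the *is-preceded-by*
  links (ties broken by document order, cycles rejected) yields the
  execution order of steps.
- **IO chaining** — each undeclared procedure input is resolved to the
  nearest earlier procedure producing a name-matching output, recovering the
  material flow (e.g. *tumor tissue → homogenized tissue → RNA*).
- **SIRO projection** — the card `(S, I, R, O)` of declared samples,
  instruments (equipment + kits), reagents and the stated objective,
  categorized by a seeded lexicon, which can be published while the step
  text stays private.

The RDF mapping emits one typed, minted IRI per entity (no blank nodes),
only the *is-preceded-by* direction of the ordering duals, and is invertible:
`from_rdf(to_rdf(P))` equals `P` up to canonical ordering, with the graph
size equal to an independently computed triple count.

## Worked example

The built-in fixture is the three-procedure TRIzol protocol *"Extraction of
total RNA from fresh/frozen tissue (FT)"*:

```python
>>> from smartprotocols import (running_example, validate_structure,
...                             resolve_io_chain, to_rdf,
...                             count_expected_triples, extract_siro)
>>> p = running_example()
>>> [(proc.id, len(proc.subprocedures)) for proc in p.workflow.procedures]
[('lab procedure 1', 3), ('lab procedure 2', 3), ('lab procedure 3', 20)]
>>> validate_structure(p).is_valid()
True
>>> resolve_io_chain(p).links
[IOLink(producer='lab procedure 1', item='homogenized tissue', consumer='lab procedure 3')]
>>> g = to_rdf(p)
>>> (len(g), count_expected_triples(p))
(289, 289)
>>> [name for name, _cat in extract_siro(p).reagents]
['Chloroform', 'Ethyl alcohol', 'Isopropyl alcohol', 'TRIzol']
```

Reading: the protocol has 3 procedures (overview, equipment cleaning, RNA
extraction) with 3, 3 and 20 steps; exactly one inter-procedure material
hand-off (homogenized tissue from procedure 1 into procedure 3); its RDF
graph has 289 triples, matching the independent counting oracle; and its
SIRO card lists the four declared reagents.

The same flows are available from the shell:

```bash
smartproto validate src/smartprotocols/data/running_example.spd.yaml
smartproto rdf src/smartprotocols/data/running_example.spd.yaml -o rna.ttl
smartproto query rna.ttl --id protocols-by-sample --param "sample_name=tumor tissue"
smartproto siro src/smartprotocols/data/running_example.spd.yaml
smartproto synth --seed 42 -o synthetic.spd.yaml
```

The query prints one row — the fixture's IRI and title — because exactly one
protocol in the dataset uses tumor tissue as a sample.  Federated
linked-data questions (taxon orders, vendors, hazards) run against shipped
synthetic mock graphs with the same join shape; `smartproto query --list`
shows the whole suite.

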