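"""Term registry, IRI minting, emission/counting conservation, round-trips
and canonical serialization."""

import random

import pytest
from rdflib import Graph, URIRef
from rdflib.namespace import RDF

from smartprotocols import model as m
from smartprotocols.authoring import (
    SynthConfig,
    parse_protocol_doc,
    synthesize_protocol,
)
from smartprotocols.errors import (
    DuplicateLabelError,
    MissingTypeError,
    OrphanStepError,
    SlugCollisionError,
    UnknownPrefixError,
    UnknownTripleWarning,
    UnregisteredTermError,
)
from smartprotocols.model import canonicalize
from smartprotocols.rdf import (
    DEFAULT_PREFIXES,
    VOCABULARY,
    build_term_registry,
    count_expected_triples,
    from_rdf,
    mint_iri,
    parse_rdf_text,
    serialize_ntriples,
    serialize_turtle,
    to_rdf,
)

MINIMAL = """\
id: mini
document:
  title: A minimal protocol
workflow:
  procedures:
    - id: p1
      label: only procedure
      steps:
        - id: s1
          text: do the one thing
"""


class TestRegistry:
    def test_lookup_returns_object_property(self, registry):
        term = registry.lookup("sp", "has experimental input")
        assert term.kind == "object_property"
        assert str(term.iri).startswith(DEFAULT_PREFIXES["sp"])
        assert str(term.iri).endswith("has-experimental-input")

    def test_double_registration_rejected(self, registry):
        with pytest.raises(DuplicateLabelError):
            registry.register("sp", "has experimental input", "object_property")

    def test_unknown_prefix_rejected(self, registry):
        with pytest.raises(UnknownPrefixError):
            registry.register("zzz", "whatever", "class")
        with pytest.raises(UnknownPrefixError):
            build_term_registry(overrides={"zzz": "https://x/"})

    def test_unregistered_term_lookup(self, registry):
        with pytest.raises(UnregisteredTermError):
            registry.lookup("sp", "no such label")

    def test_closure_every_vocabulary_term_resolves(self, registry):
        # exhaustive scan of the rule table against the registry
        for prefix, label, kind in VOCABULARY:
            assert registry.lookup(prefix, label).kind == kind

    def test_override_remaps_namespace(self):
        reg = build_term_registry(overrides={"sp": "https://example.org/sp#"})
        assert str(reg.term("sp", "has output")) == \
            "https://example.org/sp#has-output"

    def test_curie_roundtrip(self, registry):
        iri = registry.expand_curie("chebi:RNA")
        assert registry.compact(iri) == "chebi:RNA"


class TestMintIri:
    def test_slug_rule(self):
        iri = mint_iri("procedure", "rna-ft", "lab procedure 1")
        assert str(iri).endswith("/procedure/rna-ft/lab-procedure-1")

    def test_collision_detected(self):
        seen = {}
        mint_iri("step", "p", "Step 1.A", minted=seen)
        with pytest.raises(SlugCollisionError):
            mint_iri("step", "p", "step 1 a", minted=seen)

    def test_injectivity_on_distinct_slugs(self):
        rng = random.Random(0)
        locals_ = {f"item {rng.randrange(10 ** 9)} v{i}" for i in range(1000)}
        iris = {str(mint_iri("x", "p", loc)) for loc in locals_}
        assert len(iris) == len(locals_)


class TestToRdf:
    def test_running_example_io_edges(self, fixture_protocol, registry):
        g = to_rdf(fixture_protocol, registry)
        sp = lambda label: registry.term("sp", label)  # noqa: E731
        proc3 = URIRef("https://w3id.org/smart-protocols/data/procedure/"
                       "rna-extraction-ft/lab-procedure-3")
        inputs = list(g.objects(proc3, sp("has experimental input")))
        assert len(inputs) == 1
        assert (inputs[0], sp("material name"), None) in g
        assert str(next(g.objects(inputs[0], sp("material name")))) == \
            "homogenized tissue"
        outputs = list(g.objects(proc3, sp("has output")))
        assert len(outputs) == 1
        # the RNA output node is additionally typed by its chebi reference
        assert registry.expand_curie("chebi:RNA") in set(
            g.objects(outputs[0], RDF.type))

    def test_minimal_protocol_triple_count_is_exactly_the_rule_sum(self):
        # base document block (6) + one procedure (5) + one step (5)
        p = parse_protocol_doc(MINIMAL)
        g = to_rdf(p)
        assert len(g) == count_expected_triples(p) == 16

    def test_reagent_with_manufacturer_and_catalog_adds_two_triples(self):
        p = parse_protocol_doc(MINIMAL)
        base = count_expected_triples(p)
        p.document.reagents.append(m.Reagent(name="TRIzol"))
        assert count_expected_triples(p) == base + 3
        p.document.reagents[0].manufacturer = "Invitrogen"
        p.document.reagents[0].catalog_number = "15596026"
        assert count_expected_triples(p) == base + 5
        assert len(to_rdf(p)) == base + 5

    def test_counting_oracle_matches_graph_size(self, fixture_protocol):
        assert len(to_rdf(fixture_protocol)) == \
            count_expected_triples(fixture_protocol)

    @pytest.mark.parametrize("seed", range(50))
    def test_counting_oracle_on_synthesized_protocols(self, seed):
        p = synthesize_protocol(SynthConfig(seed=seed))
        assert len(to_rdf(p)) == count_expected_triples(p)

    def test_only_is_preceded_by_is_emitted(self, fixture_protocol, registry):
        g = to_rdf(fixture_protocol, registry)
        assert set(g.subject_objects(registry.term("bfo", "is preceded by")))
        assert not set(g.subject_objects(registry.term("bfo", "precedes")))

    def test_vocabulary_closure_of_emitted_iris(self, fixture_protocol, registry):
        g = to_rdf(fixture_protocol, registry)
        known = {str(t.iri) for t in registry.terms()}
        known |= {str(RDF.type), "http://www.w3.org/2000/01/rdf-schema#label"}
        for _s, pred, _o in g:
            assert str(pred) in known
        namespaces = tuple(registry.prefixes.values()) + (
            "https://w3id.org/smart-protocols/data/",)
        for s, _p, o in g:
            for node in (s, o):
                if isinstance(node, URIRef):
                    assert str(node).startswith(namespaces)

    def test_determinism_identical_protocols_identical_graphs(self, synth):
        a, b = synth(seed=9), synth(seed=9)
        assert set(to_rdf(a)) == set(to_rdf(b))

    def test_derived_material_emits_organism_and_role(self, registry):
        p = parse_protocol_doc(MINIMAL)
        p.document.reagents.append(m.Reagent(
            name="anti-tubulin antibody",
            derived=m.DerivedMaterial(derives_from_organism="Mus musculus",
                                      role="primary antibody")))
        g = to_rdf(p, registry)
        derives = list(g.subject_objects(registry.term("ro", "derives from")))
        assert len(derives) == 1
        org = derives[0][1]
        assert str(next(g.objects(org, registry.term("sp", "organism name")))) \
            == "Mus musculus"
        roles = list(g.subject_objects(registry.term("obi", "has role")))
        assert len(roles) == 1


class TestFromRdf:
    def test_roundtrip_running_example(self, fixture_protocol, registry):
        g = to_rdf(fixture_protocol, registry)
        back = from_rdf(g, registry)
        assert back == canonicalize(fixture_protocol)
        assert len(back.workflow.procedures) == 3

    def test_roundtrip_minimal(self, registry):
        p = parse_protocol_doc(MINIMAL)
        assert from_rdf(to_rdf(p, registry), registry) == canonicalize(p)

    @pytest.mark.parametrize("seed", range(50))
    def test_roundtrip_synthesized(self, seed, registry):
        p = synthesize_protocol(SynthConfig(seed=seed))
        assert from_rdf(to_rdf(p, registry), registry) == canonicalize(p)

    def test_unknown_triples_ignored_with_warning(self, registry):
        p = parse_protocol_doc(MINIMAL)
        g = to_rdf(p, registry)
        g.add((URIRef("https://elsewhere.example/x"),
               URIRef("https://elsewhere.example/pred"),
               URIRef("https://elsewhere.example/y")))
        with pytest.warns(UnknownTripleWarning):
            back = from_rdf(g, registry)
        assert back == canonicalize(p)

    def test_missing_protocol_type_raises(self, registry):
        with pytest.raises(MissingTypeError):
            from_rdf(Graph(), registry)

    def test_orphan_step_raises(self, registry):
        p = parse_protocol_doc(MINIMAL)
        g = to_rdf(p, registry)
        g.add((URIRef("https://w3id.org/smart-protocols/data/step/mini/ghost"),
               RDF.type, registry.term("sp", "laboratory subprocedure")))
        with pytest.raises(OrphanStepError):
            from_rdf(g, registry)


class TestSerialization:
    def test_canonical_turtle_is_byte_identical(self, fixture_protocol, registry):
        g = to_rdf(fixture_protocol, registry)
        assert serialize_turtle(g, registry) == serialize_turtle(g, registry)
        # and identical for an independently emitted graph
        g2 = to_rdf(fixture_protocol, registry)
        assert serialize_turtle(g, registry) == serialize_turtle(g2, registry)

    def test_turtle_subjects_sorted(self, fixture_protocol, registry):
        text = serialize_turtle(to_rdf(fixture_protocol, registry), registry)
        g = parse_rdf_text(text)
        assert set(g) == set(to_rdf(fixture_protocol, registry))

    def test_ntriples_roundtrip(self, fixture_protocol, registry):
        g = to_rdf(fixture_protocol, registry)
        text = serialize_ntriples(g)
        assert text == serialize_ntriples(g)
        assert set(parse_rdf_text(text, format="nt")) == set(g)
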