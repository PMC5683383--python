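"""Local competency-question suite over protocol RDF graphs.

The questions an annotated protocol corpus must answer — which protocols use
a given sample, which reagents (and manufacturers) a protocol uses, which
steps carry cautions, what two protocols have in common — are formalized as
SPARQL SELECT queries.  The published federated variants (DBpedia taxon
orders, PubChem vendors, ChEBI applications, SNOMED hazards) are replaced by
local mock linked-data graphs with the same join shape, so the identical
query logic is exercised desk-scale with no network.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

from rdflib import Graph, Literal

from .errors import MissingMockError
from .rdf import TermRegistry, build_term_registry

MOCK_NAMES = ("taxa", "vendors", "reagent_applications", "hazards")


@dataclass
class CompetencyQuery:
    id: str
    description: str
    query_text: str  # SPARQL 1.1 SELECT; parameters bound as SPARQL variables
    requires_mock: list[str] = field(default_factory=list)
    params: list[str] = field(default_factory=list)


@dataclass
class MockLinkedGraph:
    """A local stand-in for one external linked-data source."""

    name: str
    triples: Graph


_SUITE: list[tuple[str, str, list[str], list[str], str]] = [
    (
        "protocols-by-sample",
        "Which protocols use a given material (e.g. tumor tissue) as a sample?",
        [], ["sample_name"],
        """
        SELECT ?protocol ?title WHERE {
          ?protocol sp:has-specimen ?s .
          ?s sp:specimen-name ?sample_name .
          ?protocol sp:title-of-the-protocol ?title .
        }
        """,
    ),
    (
        "reagents-with-manufacturer",
        "Retrieve the reagents and the corresponding manufacturer information "
        "for a specific protocol.",
        [], ["protocol_id"],
        """
        SELECT ?reagent_name ?manufacturer WHERE {
          ?protocol sp:identifier ?protocol_id ;
                    sp:has-reagent ?r .
          ?r sp:reagent-name ?reagent_name .
          OPTIONAL { ?r sp:manufacturer-name ?manufacturer }
        }
        """,
    ),
    (
        "caution-steps",
        "Retrieve the steps that have CAUTIONS as alert messages from a named "
        "protocol.",
        [], ["protocol_id"],
        """
        SELECT ?step_id ?text WHERE {
          ?protocol sp:identifier ?protocol_id ;
                    iao:is-about ?exec .
          ?exec sp:has-procedure ?proc .
          ?proc sp:has-subprocedure ?step .
          ?step sp:has-alert-message ?alert .
          ?alert a sp:caution .
          ?step sp:identifier ?step_id ;
                sp:instruction-text ?text .
        }
        """,
    ),
    (
        "protocols-by-author",
        "Retrieve the protocols authored by a given person.",
        [], ["author_name"],
        """
        SELECT ?protocol ?title WHERE {
          ?protocol sp:has-author ?a .
          ?a sp:author-name ?author_name .
          ?protocol sp:title-of-the-protocol ?title .
        }
        """,
    ),
    (
        "protocols-by-author-and-sample",
        "Retrieve the protocols by a given author that use a given sample.",
        [], ["author_name", "sample_name"],
        """
        SELECT ?protocol ?title WHERE {
          ?protocol sp:has-author ?a .
          ?a sp:author-name ?author_name .
          ?protocol sp:has-specimen ?s .
          ?s sp:specimen-name ?sample_name .
          ?protocol sp:title-of-the-protocol ?title .
        }
        """,
    ),
    (
        "common-reagents",
        "Retrieve the common reagents across two protocols.",
        [], ["protocol_a", "protocol_b"],
        """
        SELECT ?reagent_name WHERE {
          ?pa sp:identifier ?protocol_a ; sp:has-reagent ?ra .
          ?ra sp:reagent-name ?reagent_name .
          ?pb sp:identifier ?protocol_b ; sp:has-reagent ?rb .
          ?rb sp:reagent-name ?reagent_name .
        }
        """,
    ),
    (
        "protocols-by-sample-order",
        "Retrieve the protocols with samples that belong to a taxonomic order "
        "(e.g. Rodentia), with information about each organism.",
        ["taxa"], ["order_name"],
        """
        SELECT ?protocol ?title ?organism ?abstract WHERE {
          ?protocol sp:has-specimen ?s .
          ?s sp:from-organism ?organism .
          ?taxon ld:scientific-name ?organism ;
                 ld:order-name ?order_name .
          OPTIONAL { ?taxon ld:abstract ?abstract }
          ?protocol sp:title-of-the-protocol ?title .
        }
        """,
    ),
    (
        "reagent-vendors",
        "Retrieve all the reagents along with the web sites to buy them and "
        "the vendors registered for every reagent.",
        ["vendors"], [],
        """
        SELECT ?reagent_name ?vendor ?website WHERE {
          ?protocol sp:has-reagent ?r .
          ?r sp:reagent-name ?reagent_name .
          ?offer ld:reagent-name ?reagent_name ;
                 ld:vendor-name ?vendor .
          OPTIONAL { ?offer ld:website ?website }
        }
        """,
    ),
    (
        "protocols-by-reagent-with-application",
        "Retrieve the protocols in which a reagent (e.g. Bromophenol blue) is "
        "used, together with the applications of that reagent.",
        ["reagent_applications"], ["reagent_name"],
        """
        SELECT ?protocol ?title ?application WHERE {
          ?protocol sp:has-reagent ?r .
          ?r sp:reagent-name ?reagent_name .
          ?app ld:reagent-name ?reagent_name ;
               ld:application ?application .
          ?protocol sp:title-of-the-protocol ?title .
        }
        """,
    ),
    (
        "diseases-by-reagent",
        "Retrieve all the diseases caused by the reagents in a specific "
        "protocol.",
        ["hazards"], ["protocol_id"],
        """
        SELECT ?reagent_name ?disease WHERE {
          ?protocol sp:identifier ?protocol_id ;
                    sp:has-reagent ?r .
          ?r sp:reagent-name ?reagent_name .
          ?h ld:reagent-name ?reagent_name ;
             ld:causes-disease ?disease .
        }
        """,
    ),
    (
        "steps-of-protocol",
        "Retrieve every subprocedure (step) of a specific protocol.",
        [], ["protocol_id"],
        """
        SELECT ?step_id ?text WHERE {
          ?protocol sp:identifier ?protocol_id ;
                    iao:is-about ?exec .
          ?exec sp:has-procedure ?proc .
          ?proc sp:has-subprocedure ?step .
          ?step sp:identifier ?step_id ;
                sp:instruction-text ?text .
        }
        """,
    ),
    (
        "recipes-of-protocol",
        "Retrieve every recipe (name and body) of a specific protocol.",
        [], ["protocol_id"],
        """
        SELECT ?recipe_name ?recipe_text WHERE {
          ?protocol sp:identifier ?protocol_id ;
                    sp:has-recipe ?recipe .
          ?recipe sp:recipe-name ?recipe_name ;
                  sp:recipe-text ?recipe_text .
        }
        """,
    ),
]

# step- and recipe-level question ids: these must return nothing on a
# SIRO-only export
STEP_LEVEL_QUERIES = ("caution-steps", "steps-of-protocol",
                      "recipes-of-protocol")
SIRO_LEVEL_QUERIES = ("protocols-by-sample", "reagents-with-manufacturer",
                      "protocols-by-author")


def load_competency_suite(
    registry: TermRegistry | None = None,
) -> list[CompetencyQuery]:
    """The built-in competency-question suite, prefix header taken from the
    term registry so overridden namespaces propagate into the queries."""
    registry = registry or build_term_registry()
    header = registry.sparql_prefix_header()
    return [
        CompetencyQuery(id=qid, description=desc, query_text=header + text,
                        requires_mock=list(mocks), params=list(params))
        for qid, desc, mocks, params, text in _SUITE
    ]


def get_query(query_id: str,
              registry: TermRegistry | None = None) -> CompetencyQuery:
    for q in load_competency_suite(registry):
        if q.id == query_id:
            return q
    raise KeyError(f"no competency query with id {query_id!r}")


def load_mock_graph(name: str) -> MockLinkedGraph:
    """Load one shipped mock linked-data graph by name."""
    if name not in MOCK_NAMES:
        raise MissingMockError(f"unknown mock graph {name!r}")
    text = (importlib.resources.files("smartprotocols")
            / "data" / "mocks" / f"{name}.ttl").read_text(encoding="utf-8")
    g = Graph(bind_namespaces="none")
    g.parse(data=text, format="turtle")
    return MockLinkedGraph(name=name, triples=g)


def load_all_mocks() -> list[MockLinkedGraph]:
    return [load_mock_graph(name) for name in MOCK_NAMES]


def run_query(
    graph: Graph,
    query: CompetencyQuery,
    mocks: list[MockLinkedGraph] = (),
    params: dict[str, str] | None = None,
) -> list[tuple]:
    """Evaluate ``query`` over the union of ``graph`` and its required mocks.

    Parameters are bound as plain-literal SPARQL variables.  Rows come back
    as tuples of python values in a deterministic (sorted) order — graphs are
    sets, so evaluation order must not leak into results.
    """
    provided = {mg.name: mg for mg in mocks}
    union = Graph(bind_namespaces="none")
    for t in graph:
        union.add(t)
    for name in query.requires_mock:
        if name not in provided:
            raise MissingMockError(
                f"query {query.id!r} requires mock graph {name!r}")
        for t in provided[name].triples:
            union.add(t)
    bindings = {k: Literal(v) for k, v in (params or {}).items()}
    result = union.query(query.query_text, initBindings=bindings)
    rows = [tuple(None if v is None else v.toPython() for v in row)
            for row in result]
    return sorted(rows, key=lambda r: tuple("" if v is None else str(v)
                                            for v in r))


@dataclass
class SIROAuditReport:
    """Outcome of auditing a SIRO-only export: what stays answerable and
    what is suppressed."""

    answerable: dict[str, int] = field(default_factory=dict)
    suppressed: dict[str, int] = field(default_factory=dict)

    def is_privacy_preserving(self) -> bool:
        return all(n == 0 for n in self.suppressed.values())


def run_siro_only_audit(graph: Graph,
                        registry: TermRegistry | None = None) -> SIROAuditReport:
    """Audit a SIRO export: SIRO-level queries (sample/reagent/author) must
    return rows where the card has content, while step- and recipe-level
    queries must return zero rows.  Queries run unparameterized so the audit
    covers every binding present in the graph."""
    registry = registry or build_term_registry()
    report = SIROAuditReport()
    for qid in SIRO_LEVEL_QUERIES:
        query = get_query(qid, registry)
        report.answerable[qid] = len(run_query(graph, query))
    for qid in STEP_LEVEL_QUERIES:
        query = get_query(qid, registry)
        report.suppressed[qid] = len(run_query(graph, query))
    return report


__all__ = [
    "MOCK_NAMES", "SIRO_LEVEL_QUERIES", "STEP_LEVEL_QUERIES",
    "CompetencyQuery", "MockLinkedGraph", "SIROAuditReport",
    "get_query", "load_all_mocks", "load_competency_suite", "load_mock_graph",
    "run_query", "run_siro_only_audit",
]
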