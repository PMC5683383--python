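"""Term registry and lossless Protocol <-> RDF conversion.

The registry mints label-faithful IRIs (``sp:has-experimental-input`` for the
label "has experimental input") under configurable namespaces instead of
hard-coding any published ontology's opaque identifiers; an overrides map can
re-point namespaces later.  Blank nodes are never used — every entity gets a
minted IRI so graphs are diffable and queries stable.  Precedence is emitted
as *is preceded by* only; the inverse *precedes* is registered but never
written, so a graph can never carry inconsistent duals.

The per-rule triple contributions implemented by :func:`to_rdf` are documented
in ``docs/methods.md``; :func:`count_expected_triples` re-derives the total by
walking the object model without touching any RDF machinery, and serves as an
independent conservation check on the emitter.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

from rdflib import Graph, Literal, Namespace, URIRef
from rdflib.namespace import NamespaceManager, RDF, RDFS, XSD

from . import model as m
from .errors import (
    DuplicateLabelError,
    InvalidProtocolError,
    MissingTypeError,
    OrphanStepError,
    SlugCollisionError,
    UnknownPrefixError,
    UnregisteredTermError,
    UnknownTripleWarning,
)

DEFAULT_DATA_BASE = "https://w3id.org/smart-protocols/data/"

DEFAULT_PREFIXES: dict[str, str] = {
    "sp": "https://w3id.org/smart-protocols/sp#",
    "iao": "https://w3id.org/smart-protocols/iao#",
    "ro": "https://w3id.org/smart-protocols/ro#",
    "bfo": "https://w3id.org/smart-protocols/bfo#",
    "obi": "https://w3id.org/smart-protocols/obi#",
    "chebi": "https://w3id.org/smart-protocols/chebi#",
    "ncbitaxon": "https://w3id.org/smart-protocols/ncbitaxon#",
    "nci": "https://w3id.org/smart-protocols/nci#",
    "siro": "https://w3id.org/smart-protocols/siro#",
    "ld": "https://w3id.org/smart-protocols/mock#",
}

_SLUG_RE = re.compile(r"[^a-z0-9]+")


def slugify(text: str) -> str:
    """Deterministic IRI-safe slug: lowercase, runs of any non-alphanumeric
    characters collapse to a single hyphen, outer hyphens stripped."""
    return _SLUG_RE.sub("-", text.casefold()).strip("-")


@dataclass(frozen=True)
class Term:
    prefix: str
    label: str
    kind: str  # "class" | "object_property" | "annotation"
    iri: URIRef


# (prefix, label, kind) for every vocabulary term any emission rule touches.
VOCABULARY: list[tuple[str, str, str]] = [
    # --- classes -----------------------------------------------------------
    ("sp", "experimental protocol", "class"),
    ("sp", "experimental protocol execution", "class"),
    ("sp", "laboratory procedure", "class"),
    ("sp", "laboratory subprocedure", "class"),
    ("sp", "recipe execution", "class"),
    ("sp", "procedure container", "class"),
    ("sp", "author", "class"),
    ("sp", "specimen", "class"),
    ("sp", "reagent", "class"),
    ("sp", "kit", "class"),
    ("sp", "equipment or supplies", "class"),
    ("sp", "recipe", "class"),
    ("sp", "participant", "class"),
    ("sp", "alert message", "class"),
    ("sp", "caution", "class"),
    ("sp", "hint", "class"),
    ("sp", "pause point", "class"),
    ("sp", "troubleshooting", "class"),
    ("sp", "catalog number", "class"),
    ("iao", "information content entity", "class"),
    ("iao", "document", "class"),
    ("iao", "document part", "class"),
    ("iao", "textual entity", "class"),
    ("bfo", "material entity", "class"),
    ("obi", "organism", "class"),
    ("obi", "role", "class"),
    ("siro", "siro record", "class"),
    ("siro", "sample", "class"),
    ("siro", "instrument", "class"),
    ("siro", "reagent", "class"),
    # --- object properties -------------------------------------------------
    ("sp", "has procedure", "object_property"),
    ("sp", "has subprocedure", "object_property"),
    ("sp", "has experimental input", "object_property"),
    ("sp", "has output", "object_property"),
    ("sp", "has author", "object_property"),
    ("sp", "has specimen", "object_property"),
    ("sp", "has reagent", "object_property"),
    ("sp", "has kit", "object_property"),
    ("sp", "has equipment", "object_property"),
    ("sp", "has recipe", "object_property"),
    ("sp", "has alert message", "object_property"),
    ("iao", "is about", "object_property"),
    ("ro", "part of", "object_property"),
    ("ro", "has part", "object_property"),
    ("ro", "derives from", "object_property"),
    ("ro", "has participant", "object_property"),
    ("bfo", "is preceded by", "object_property"),
    ("bfo", "precedes", "object_property"),  # registered, never emitted
    ("obi", "has role", "object_property"),
    # --- annotation / data terms -------------------------------------------
    ("sp", "identifier", "annotation"),
    ("sp", "visibility", "annotation"),
    ("sp", "position", "annotation"),
    ("sp", "title of the protocol", "annotation"),
    ("sp", "protocol identifier", "annotation"),
    ("sp", "application of the protocol", "annotation"),
    ("sp", "provenance of the protocol", "annotation"),
    ("sp", "purpose of the protocol", "annotation"),
    ("sp", "version", "annotation"),
    ("sp", "advantage", "annotation"),
    ("sp", "limitation", "annotation"),
    ("sp", "author name", "annotation"),
    ("sp", "author identifier", "annotation"),
    ("sp", "author role", "annotation"),
    ("sp", "specimen name", "annotation"),
    ("sp", "from organism", "annotation"),
    ("sp", "anatomical part", "annotation"),
    ("sp", "specimen attribute", "annotation"),
    ("sp", "reagent name", "annotation"),
    ("sp", "manufacturer name", "annotation"),
    ("sp", "has catalog number", "annotation"),
    ("sp", "kit name", "annotation"),
    ("sp", "equipment name", "annotation"),
    ("sp", "equipment category", "annotation"),
    ("sp", "recipe name", "annotation"),
    ("sp", "recipe text", "annotation"),
    ("sp", "material name", "annotation"),
    ("sp", "instruction text", "annotation"),
    ("sp", "participant name", "annotation"),
    ("sp", "measure value", "annotation"),
    ("sp", "measure unit", "annotation"),
    ("sp", "alert text", "annotation"),
    ("sp", "organism name", "annotation"),
    ("sp", "role name", "annotation"),
    ("siro", "category", "annotation"),
    # --- mock linked-data vocabulary ---------------------------------------
    ("ld", "scientific name", "annotation"),
    ("ld", "order name", "annotation"),
    ("ld", "abstract", "annotation"),
    ("ld", "reagent name", "annotation"),
    ("ld", "vendor name", "annotation"),
    ("ld", "website", "annotation"),
    ("ld", "application", "annotation"),
    ("ld", "causes disease", "annotation"),
]


class TermRegistry:
    """Prefix map plus (prefix, label) -> IRI entries for every vocabulary
    term the serializer emits."""

    def __init__(self, prefixes: dict[str, str] | None = None):
        self.prefixes: dict[str, str] = dict(prefixes or DEFAULT_PREFIXES)
        self._terms: dict[tuple[str, str], Term] = {}
        self._slugs: dict[tuple[str, str], str] = {}

    def register(self, prefix: str, label: str, kind: str) -> Term:
        if prefix not in self.prefixes:
            raise UnknownPrefixError(f"unknown prefix {prefix!r}")
        key = (prefix, label)
        if key in self._terms:
            raise DuplicateLabelError(
                f"term {label!r} already registered under prefix {prefix!r}")
        slug = slugify(label)
        slug_key = (prefix, slug)
        if slug_key in self._slugs:
            raise DuplicateLabelError(
                f"label {label!r} slugs to {slug!r}, already taken by "
                f"{self._slugs[slug_key]!r} under prefix {prefix!r}")
        term = Term(prefix, label, kind, URIRef(self.prefixes[prefix] + slug))
        self._terms[key] = term
        self._slugs[slug_key] = label
        return term

    def lookup(self, prefix: str, label: str) -> Term:
        try:
            return self._terms[(prefix, label)]
        except KeyError:
            raise UnregisteredTermError(
                f"term {prefix}:{label!r} is not registered") from None

    def term(self, prefix: str, label: str) -> URIRef:
        return self.lookup(prefix, label).iri

    def terms(self) -> list[Term]:
        return list(self._terms.values())

    def expand_curie(self, curie: str) -> URIRef:
        # the local part is kept verbatim (it must be IRI-safe) so that
        # compact(expand_curie(c)) == c and external refs round-trip exactly
        prefix, _, local = curie.partition(":")
        if not local or prefix not in self.prefixes:
            raise UnknownPrefixError(f"cannot expand CURIE {curie!r}")
        return URIRef(self.prefixes[prefix] + local)

    def compact(self, iri: URIRef) -> str | None:
        best: tuple[int, str] | None = None
        for prefix, ns in self.prefixes.items():
            if str(iri).startswith(ns) and (best is None or len(ns) > best[0]):
                best = (len(ns), prefix)
        if best is None:
            return None
        prefix = best[1]
        return f"{prefix}:{str(iri)[len(self.prefixes[prefix]):]}"

    def namespace_manager(self) -> NamespaceManager:
        g = Graph(bind_namespaces="none")
        for prefix, ns in sorted(self.prefixes.items()):
            g.bind(prefix, Namespace(ns))
        g.bind("rdf", RDF)
        g.bind("rdfs", RDFS)
        g.bind("xsd", XSD)
        return g.namespace_manager

    def sparql_prefix_header(self) -> str:
        lines = [f"PREFIX {p}: <{ns}>" for p, ns in sorted(self.prefixes.items())]
        lines.append(f"PREFIX rdf: <{RDF}>")
        lines.append(f"PREFIX rdfs: <{RDFS}>")
        return "\n".join(lines) + "\n"

    def check_closure(self) -> None:
        """Verify every vocabulary term any emission rule references resolves."""
        for prefix, label, _kind in VOCABULARY:
            self.lookup(prefix, label)


def build_term_registry(overrides: dict[str, str] | None = None) -> TermRegistry:
    """Build the default registry; ``overrides`` may only remap namespace IRIs."""
    prefixes = dict(DEFAULT_PREFIXES)
    if overrides:
        for prefix, ns in overrides.items():
            if prefix not in prefixes:
                raise UnknownPrefixError(
                    f"override for unknown prefix {prefix!r}")
            prefixes[prefix] = ns
    registry = TermRegistry(prefixes)
    for prefix, label, kind in VOCABULARY:
        registry.register(prefix, label, kind)
    registry.check_closure()
    return registry


# ---------------------------------------------------------------------------
# IRI minting
# ---------------------------------------------------------------------------

def mint_iri(
    kind: str,
    protocol_id: str,
    local_id: str,
    base: str = DEFAULT_DATA_BASE,
    minted: dict[tuple[str, str], str] | None = None,
) -> URIRef:
    """Mint a deterministic data IRI: ``base + kind + "/" + protocol-slug +
    "/" + local-slug``.

    When a ``minted`` map is supplied it is used to detect two distinct local
    ids slugging identically within one protocol (:class:`SlugCollisionError`).
    """
    if not protocol_id or not local_id:
        raise ValueError("protocol id and local id must be non-empty")
    local_slug = slugify(local_id)
    key = (kind, local_slug)
    if minted is not None:
        prior = minted.get(key)
        if prior is not None and prior != local_id:
            raise SlugCollisionError(
                f"{kind} ids {prior!r} and {local_id!r} both slug to "
                f"{local_slug!r} within protocol {protocol_id!r}")
        minted[key] = local_id
    return URIRef(f"{base}{kind}/{slugify(protocol_id)}/{local_slug}")


class IriMinter:
    """Stateful wrapper around :func:`mint_iri` for one protocol's graph."""

    def __init__(self, protocol_id: str, base: str = DEFAULT_DATA_BASE):
        self.protocol_id = protocol_id
        self.base = base
        self._minted: dict[tuple[str, str], str] = {}

    def mint(self, kind: str, local_id: str) -> URIRef:
        return mint_iri(kind, self.protocol_id, local_id, self.base, self._minted)


# ---------------------------------------------------------------------------
# Emission
# ---------------------------------------------------------------------------

_KIND_CLASS = {
    "procedure": "laboratory procedure",
    "recipe_execution": "recipe execution",
    "container": "procedure container",
}
_ALERT_CLASS = {
    "caution": "caution",
    "hint": "hint",
    "pause_point": "pause point",
    "troubleshooting": "troubleshooting",
    "generic_alert": "alert message",
}
_MATERIAL_RULES = (
    # (document field, node kind, link label, class label, name label)
    ("specimens", "specimen", "has specimen", "specimen", "specimen name"),
    ("reagents", "reagent", "has reagent", "reagent", "reagent name"),
    ("kits", "kit", "has kit", "kit", "kit name"),
    ("equipment", "equipment", "has equipment", "equipment or supplies",
     "equipment name"),
)


def _material_index(document: m.DocumentMetadata):
    """Normalized name -> (node kind, material) with declaration-order priority:
    specimens, then reagents, kits, equipment."""
    index: dict[str, tuple[str, object]] = {}
    for attr, kind, _link, _cls, _name in _MATERIAL_RULES:
        for mat in getattr(document, attr):
            index.setdefault(m.normalize_name(mat.name), (kind, mat))
    return index


def _undeclared_flows(protocol: m.Protocol):
    """Distinct undeclared flow-item names across the workflow, mapping
    normalized name -> (first-seen display name, first non-null external ref)."""
    declared = _material_index(protocol.document)
    flows: dict[str, list] = {}
    for proc in protocol.workflow.procedures:
        for item in list(proc.inputs) + list(proc.outputs):
            key = m.normalize_name(item.name)
            if key in declared:
                continue
            entry = flows.setdefault(key, [item.name, None])
            if entry[1] is None and item.external_ref:
                entry[1] = item.external_ref
    return flows


def to_rdf(
    protocol: m.Protocol,
    registry: TermRegistry | None = None,
    base: str = DEFAULT_DATA_BASE,
    language: str = "en",
) -> Graph:
    """Emit the RDF graph for a structurally valid protocol.

    Deterministic: identical protocols yield identical triple sets.  Narrative
    text carries the configured language tag; names, identifiers and category
    tokens are plain literals; measures are xsd:decimal; positions (which make
    author/procedure/step order recoverable) are xsd:integer.
    """
    report = m.validate_structure(protocol)
    if not report.is_valid():
        details = "; ".join(f"{i.code}: {i.message}" for i in report.errors)
        raise InvalidProtocolError(f"cannot emit RDF: {details}")
    registry = registry or build_term_registry()
    sp = lambda label: registry.term("sp", label)  # noqa: E731
    text = lambda s: Literal(s, lang=language)  # noqa: E731
    minter = IriMinter(protocol.id, base)
    g = Graph(bind_namespaces="none")

    doc = minter.mint("protocol", protocol.id)
    execution = minter.mint("execution", protocol.id)
    g.add((doc, RDF.type, sp("experimental protocol")))
    g.add((doc, sp("identifier"), Literal(protocol.id)))
    g.add((doc, sp("visibility"), Literal(protocol.visibility)))
    g.add((doc, registry.term("iao", "is about"), execution))
    g.add((execution, RDF.type, sp("experimental protocol execution")))
    meta = protocol.document
    g.add((doc, sp("title of the protocol"), text(meta.title)))
    for label, value, tagged in (
        ("protocol identifier", meta.protocol_identifier, False),
        ("application of the protocol", meta.application, True),
        ("provenance of the protocol", meta.provenance_statement, True),
        ("purpose of the protocol", meta.purpose_objective, True),
        ("version", meta.version, False),
    ):
        if value is not None:
            g.add((doc, sp(label), text(value) if tagged else Literal(value)))
    for adv in meta.advantages:
        g.add((doc, sp("advantage"), text(adv)))
    for lim in meta.limitations:
        g.add((doc, sp("limitation"), text(lim)))

    for i, author in enumerate(meta.authors):
        node = minter.mint("author", f"author {i + 1} {author.name}")
        g.add((doc, sp("has author"), node))
        g.add((node, RDF.type, sp("author")))
        g.add((node, sp("author name"), Literal(author.name)))
        g.add((node, sp("position"), Literal(i, datatype=XSD.integer)))
        if author.identifier is not None:
            g.add((node, sp("author identifier"), Literal(author.identifier)))
        for role in author.roles:
            g.add((node, sp("author role"), Literal(role)))

    material_nodes: dict[str, URIRef] = {}

    def _emit_derivation(node: URIRef, mat_name: str, derived: m.DerivedMaterial):
        org = minter.mint("organism", f"{mat_name} source organism")
        g.add((node, registry.term("ro", "derives from"), org))
        g.add((org, RDF.type, registry.term("obi", "organism")))
        g.add((org, sp("organism name"), Literal(derived.derives_from_organism)))
        role = minter.mint("role", f"{mat_name} role")
        g.add((node, registry.term("obi", "has role"), role))
        g.add((role, RDF.type, registry.term("obi", "role")))
        g.add((role, sp("role name"), Literal(derived.role)))

    used_material_locals: set[tuple[str, str]] = set()
    for attr, kind, link, cls, name_label in _MATERIAL_RULES:
        for seq, mat in enumerate(getattr(meta, attr)):
            # same name may legally recur with a different manufacturer;
            # give later occurrences a distinct, deterministic local id
            local = mat.name
            if (kind, slugify(local)) in used_material_locals:
                local = f"{mat.name} {seq + 1}"
            used_material_locals.add((kind, slugify(local)))
            node = minter.mint(kind, local)
            material_nodes.setdefault(m.normalize_name(mat.name), node)
            g.add((doc, sp(link), node))
            g.add((node, RDF.type, sp(cls)))
            g.add((node, sp(name_label), Literal(mat.name)))
            manufacturer = getattr(mat, "manufacturer", None)
            if manufacturer is not None:
                g.add((node, sp("manufacturer name"), Literal(manufacturer)))
            catalog = getattr(mat, "catalog_number", None)
            if catalog is not None:
                g.add((node, sp("has catalog number"), Literal(catalog)))
            if kind == "specimen":
                if mat.organism is not None:
                    g.add((node, sp("from organism"), Literal(mat.organism)))
                if mat.organism_ref is not None:
                    g.add((node, RDF.type, registry.expand_curie(mat.organism_ref)))
                if mat.anatomical_part is not None:
                    g.add((node, sp("anatomical part"), Literal(mat.anatomical_part)))
                for key, value in mat.attributes.items():
                    g.add((node, sp("specimen attribute"),
                           Literal(f"{key}={value}")))
            if kind == "reagent" and mat.external_ref is not None:
                g.add((node, RDF.type, registry.expand_curie(mat.external_ref)))
            if kind == "equipment":
                g.add((node, sp("equipment category"), Literal(mat.category)))
            derived = getattr(mat, "derived", None)
            if derived is not None:
                _emit_derivation(node, local, derived)

    for recipe in meta.recipes:
        node = minter.mint("recipe", recipe.name)
        g.add((doc, sp("has recipe"), node))
        g.add((node, RDF.type, sp("recipe")))
        g.add((node, sp("recipe name"), Literal(recipe.name)))
        g.add((node, sp("recipe text"), text(recipe.body_text)))

    flow_nodes: dict[str, URIRef] = {}
    for key, (display, ext) in _undeclared_flows(protocol).items():
        node = minter.mint("flow", display)
        flow_nodes[key] = node
        g.add((node, RDF.type, registry.term("bfo", "material entity")))
        g.add((node, sp("material name"), Literal(display)))
        if ext:
            g.add((node, RDF.type, registry.expand_curie(ext)))

    proc_nodes: dict[str, URIRef] = {}
    for proc in protocol.workflow.procedures:
        proc_nodes[proc.id] = minter.mint("procedure", proc.id)
    for i, proc in enumerate(protocol.workflow.procedures):
        node = proc_nodes[proc.id]
        g.add((execution, sp("has procedure"), node))
        g.add((node, RDF.type, sp(_KIND_CLASS[proc.kind])))
        g.add((node, sp("identifier"), Literal(proc.id)))
        g.add((node, sp("position"), Literal(i, datatype=XSD.integer)))
        g.add((node, RDFS.label, text(proc.label)))
        if proc.preceded_by is not None:
            g.add((node, registry.term("bfo", "is preceded by"),
                   proc_nodes[proc.preceded_by]))
        for link_label, items in (("has experimental input", proc.inputs),
                                  ("has output", proc.outputs)):
            for item in items:
                key = m.normalize_name(item.name)
                target = material_nodes.get(key) or flow_nodes[key]
                g.add((node, sp(link_label), target))
        step_nodes = {s.id: minter.mint("step", f"{proc.id} {s.id}")
                      for s in proc.subprocedures}
        for j, step in enumerate(proc.subprocedures):
            snode = step_nodes[step.id]
            g.add((node, sp("has subprocedure"), snode))
            g.add((snode, RDF.type, sp("laboratory subprocedure")))
            g.add((snode, sp("identifier"), Literal(step.id)))
            g.add((snode, sp("position"), Literal(j, datatype=XSD.integer)))
            g.add((snode, sp("instruction text"), text(step.text)))
            if step.preceded_by is not None:
                g.add((snode, registry.term("bfo", "is preceded by"),
                       step_nodes[step.preceded_by]))
            for q, part in enumerate(step.participants):
                pnode = minter.mint("participation",
                                    f"{proc.id} {step.id} p{q + 1} {part.name}")
                g.add((snode, registry.term("ro", "has participant"), pnode))
                g.add((pnode, RDF.type, sp("participant")))
                g.add((pnode, sp("participant name"), Literal(part.name)))
                if part.measure is not None:
                    g.add((pnode, sp("measure value"),
                           Literal(str(part.measure.value),
                                   datatype=XSD.decimal)))
                    g.add((pnode, sp("measure unit"),
                           Literal(part.measure.unit)))
            for k, alert in enumerate(step.alerts):
                anode = minter.mint("alert",
                                    f"{proc.id} {step.id} alert {k + 1}")
                g.add((snode, sp("has alert message"), anode))
                g.add((anode, RDF.type, sp(_ALERT_CLASS[alert.kind])))
                g.add((anode, sp("alert text"), text(alert.text)))
    return g


def count_expected_triples(protocol: m.Protocol) -> int:
    """Independent enumeration of the triples :func:`to_rdf` must produce,
    summing the documented per-rule contributions over the object model.

    Implemented without any RDF machinery so it can serve as an oracle for
    the emitter (conservation: graph size == this count).
    """
    meta = protocol.document
    n = 6  # document type/identifier/visibility, link to execution, its type, title
    n += sum(v is not None for v in (
        meta.protocol_identifier, meta.application, meta.provenance_statement,
        meta.purpose_objective, meta.version))
    n += len(meta.advantages) + len(meta.limitations)
    for author in meta.authors:
        n += 4 + (author.identifier is not None) + len(author.roles)
    for specimen in meta.specimens:
        n += 3
        n += sum(v is not None for v in (specimen.organism, specimen.organism_ref,
                                         specimen.anatomical_part))
        n += len(specimen.attributes)
        n += 6 * (specimen.derived is not None)
    for reagent in meta.reagents:
        n += 3
        n += sum(v is not None for v in (reagent.manufacturer,
                                         reagent.catalog_number,
                                         reagent.external_ref))
        n += 6 * (reagent.derived is not None)
    for kit in meta.kits:
        n += 3 + (kit.manufacturer is not None) + (kit.catalog_number is not None)
    for eq in meta.equipment:
        n += 4 + (eq.manufacturer is not None) + (eq.catalog_number is not None)
    n += 4 * len(meta.recipes)

    for _key, (_display, ext) in _undeclared_flows(protocol).items():
        n += 2 + (1 if ext else 0)
    for proc in protocol.workflow.procedures:
        n += 5 + (proc.preceded_by is not None)
        # graphs are sets: a name repeated within one direction is one link
        n += len({m.normalize_name(x.name) for x in proc.inputs})
        n += len({m.normalize_name(x.name) for x in proc.outputs})
        for step in proc.subprocedures:
            n += 5 + (step.preceded_by is not None)
            for part in step.participants:
                n += 3 + 2 * (part.measure is not None)
            n += 3 * len(step.alerts)
    return n


# ---------------------------------------------------------------------------
# Inverse mapping
# ---------------------------------------------------------------------------

def _one(graph: Graph, subject, predicate):
    for obj in graph.objects(subject, predicate):
        return obj
    return None


def _sorted_by_position(graph: Graph, registry: TermRegistry, nodes):
    pos = registry.term("sp", "position")
    return sorted(nodes, key=lambda n: int(_one(graph, n, pos) or 0))


def from_rdf(graph: Graph, registry: TermRegistry | None = None) -> m.Protocol:
    """Reconstruct a canonical :class:`Protocol` from a graph produced by
    :func:`to_rdf` (or conforming to its emission rules).

    Unknown extra triples are ignored with an :class:`UnknownTripleWarning`.
    Raises :class:`MissingTypeError` if no protocol-typed node exists and
    :class:`OrphanStepError` if a subprocedure node hangs off no procedure.
    """
    registry = registry or build_term_registry()
    sp = lambda label: registry.term("sp", label)  # noqa: E731

    docs = list(graph.subjects(RDF.type, sp("experimental protocol")))
    if not docs:
        raise MissingTypeError("graph contains no protocol-typed node")
    doc_node = sorted(docs)[0]

    def plain(node, label):
        v = _one(graph, node, sp(label))
        return str(v) if v is not None else None

    meta = m.DocumentMetadata(
        title=plain(doc_node, "title of the protocol") or "",
        protocol_identifier=plain(doc_node, "protocol identifier"),
        application=plain(doc_node, "application of the protocol"),
        provenance_statement=plain(doc_node, "provenance of the protocol"),
        purpose_objective=plain(doc_node, "purpose of the protocol"),
        version=plain(doc_node, "version"),
        advantages=sorted(str(v) for v in graph.objects(doc_node, sp("advantage"))),
        limitations=sorted(str(v) for v in graph.objects(doc_node, sp("limitation"))),
    )
    for node in _sorted_by_position(graph, registry,
                                    graph.objects(doc_node, sp("has author"))):
        meta.authors.append(m.Author(
            name=plain(node, "author name") or "",
            identifier=plain(node, "author identifier"),
            roles=sorted(str(v) for v in graph.objects(node, sp("author role"))),
        ))

    known_classes = {t.iri for t in registry.terms() if t.kind == "class"}

    def external_ref_of(node, own_classes) -> str | None:
        refs = []
        for cls in graph.objects(node, RDF.type):
            if cls in own_classes or cls in known_classes:
                continue
            curie = registry.compact(cls)
            if curie is not None:
                refs.append(curie)
        return sorted(refs)[0] if refs else None

    def derivation_of(node) -> m.DerivedMaterial | None:
        org = _one(graph, node, registry.term("ro", "derives from"))
        role = _one(graph, node, registry.term("obi", "has role"))
        if org is None and role is None:
            return None
        return m.DerivedMaterial(
            derives_from_organism=str(_one(graph, org, sp("organism name")) or "")
            if org is not None else "",
            role=str(_one(graph, role, sp("role name")) or "")
            if role is not None else "",
        )

    node_name: dict[URIRef, str] = {}

    for node in graph.objects(doc_node, sp("has specimen")):
        attrs = {}
        for lit in graph.objects(node, sp("specimen attribute")):
            key, _, value = str(lit).partition("=")
            attrs[key] = value
        specimen = m.Specimen(
            name=plain(node, "specimen name") or "",
            organism=plain(node, "from organism"),
            organism_ref=external_ref_of(node, {sp("specimen")}),
            anatomical_part=plain(node, "anatomical part"),
            attributes=dict(sorted(attrs.items())),
            derived=derivation_of(node),
        )
        meta.specimens.append(specimen)
        node_name[node] = specimen.name
    for node in graph.objects(doc_node, sp("has reagent")):
        reagent = m.Reagent(
            name=plain(node, "reagent name") or "",
            manufacturer=plain(node, "manufacturer name"),
            catalog_number=plain(node, "has catalog number"),
            external_ref=external_ref_of(node, {sp("reagent")}),
            derived=derivation_of(node),
        )
        meta.reagents.append(reagent)
        node_name[node] = reagent.name
    for node in graph.objects(doc_node, sp("has kit")):
        kit = m.Kit(
            name=plain(node, "kit name") or "",
            manufacturer=plain(node, "manufacturer name"),
            catalog_number=plain(node, "has catalog number"),
        )
        meta.kits.append(kit)
        node_name[node] = kit.name
    for node in graph.objects(doc_node, sp("has equipment")):
        eq = m.Equipment(
            name=plain(node, "equipment name") or "",
            category=plain(node, "equipment category") or "instrument",
            manufacturer=plain(node, "manufacturer name"),
            catalog_number=plain(node, "has catalog number"),
        )
        meta.equipment.append(eq)
        node_name[node] = eq.name
    for node in graph.objects(doc_node, sp("has recipe")):
        meta.recipes.append(m.RecipeRef(
            name=plain(node, "recipe name") or "",
            body_text=plain(node, "recipe text") or "",
        ))

    workflow = m.Workflow()
    execution = _one(graph, doc_node, registry.term("iao", "is about"))
    proc_nodes = []
    if execution is not None:
        proc_nodes = _sorted_by_position(
            graph, registry, graph.objects(execution, sp("has procedure")))
    class_kind = {sp(cls): kind for kind, cls in _KIND_CLASS.items()}
    alert_kind = {sp(cls): kind for kind, cls in _ALERT_CLASS.items()}
    node_id: dict[URIRef, str] = {}
    for node in proc_nodes:
        node_id[node] = plain(node, "identifier") or ""
    linked_steps: set[URIRef] = set()
    material_entity = registry.term("bfo", "material entity")

    def flow_item_of(node) -> m.FlowItem:
        if node in node_name:  # declared material node
            return m.FlowItem(name=node_name[node])
        return m.FlowItem(
            name=str(_one(graph, node, sp("material name")) or ""),
            external_ref=external_ref_of(node, {material_entity}),
        )

    preceded = registry.term("bfo", "is preceded by")
    for node in proc_nodes:
        kind = None
        for cls in graph.objects(node, RDF.type):
            if cls in class_kind:
                kind = class_kind[cls]
        if kind is None:
            raise MissingTypeError(
                f"procedure node {node} lacks a recognized type")
        pred_node = _one(graph, node, preceded)
        proc = m.LabProcedure(
            id=node_id[node],
            label=str(_one(graph, node, RDFS.label) or ""),
            kind=kind,
            preceded_by=node_id.get(pred_node) if pred_node is not None else None,
            inputs=sorted((flow_item_of(x) for x in
                           graph.objects(node, sp("has experimental input"))),
                          key=lambda it: (m.normalize_name(it.name),
                                          it.external_ref or "")),
            outputs=sorted((flow_item_of(x) for x in
                            graph.objects(node, sp("has output"))),
                           key=lambda it: (m.normalize_name(it.name),
                                           it.external_ref or "")),
        )
        step_nodes = _sorted_by_position(
            graph, registry, graph.objects(node, sp("has subprocedure")))
        step_id = {s: str(_one(graph, s, sp("identifier")) or "")
                   for s in step_nodes}
        for snode in step_nodes:
            linked_steps.add(snode)
            pred = _one(graph, snode, preceded)
            step = m.LabSubprocedure(
                id=step_id[snode],
                text=str(_one(graph, snode, sp("instruction text")) or ""),
                preceded_by=step_id.get(pred) if pred is not None else None,
            )
            for pnode in graph.objects(snode,
                                       registry.term("ro", "has participant")):
                value = _one(graph, pnode, sp("measure value"))
                unit = _one(graph, pnode, sp("measure unit"))
                step.participants.append(m.Participant(
                    name=str(_one(graph, pnode, sp("participant name")) or ""),
                    measure=m.Measure(value=float(value), unit=str(unit))
                    if value is not None else None,
                ))
            step.participants.sort(key=lambda q: m.normalize_name(q.name))
            for anode in graph.objects(snode, sp("has alert message")):
                akind = "generic_alert"
                for cls in graph.objects(anode, RDF.type):
                    if cls in alert_kind:
                        akind = alert_kind[cls]
                step.alerts.append(m.AlertMessage(
                    kind=akind,
                    text=str(_one(graph, anode, sp("alert text")) or ""),
                ))
            step.alerts.sort(key=lambda a: (a.kind, a.text))
            proc.subprocedures.append(step)
        workflow.procedures.append(proc)

    for snode in graph.subjects(RDF.type, sp("laboratory subprocedure")):
        if snode not in linked_steps:
            raise OrphanStepError(
                f"subprocedure node {snode} is not linked to any procedure")

    protocol = m.Protocol(
        id=plain(doc_node, "identifier") or "",
        document=meta,
        workflow=workflow,
        visibility=plain(doc_node, "visibility") or "public",
    )
    protocol = m.canonicalize(protocol)

    _warn_unknown_triples(graph, registry)
    return protocol


def _warn_unknown_triples(graph: Graph, registry: TermRegistry) -> None:
    known_predicates = {t.iri for t in registry.terms()
                        if t.kind in ("object_property", "annotation")}
    known_predicates |= {RDF.type, RDFS.label}
    unknown = [t for t in graph if t[1] not in known_predicates]
    if unknown:
        warnings.warn(
            f"ignored {len(unknown)} triple(s) with unrecognized predicates",
            UnknownTripleWarning,
            stacklevel=3,
        )


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def serialize_ntriples(graph: Graph) -> str:
    """Sorted, deterministic N-Triples."""
    lines = sorted(
        f"{s.n3()} {p.n3()} {o.n3()} ." for s, p, o in graph
    )
    return "\n".join(lines) + ("\n" if lines else "")


def serialize_turtle(graph: Graph, registry: TermRegistry | None = None) -> str:
    """Canonical Turtle: prefix header from the registry, subjects sorted by
    IRI, predicates by IRI, objects by lexical form; byte-identical for
    identical graphs."""
    registry = registry or build_term_registry()
    nm = registry.namespace_manager()
    out: list[str] = []
    for prefix, ns in sorted(registry.prefixes.items()):
        out.append(f"@prefix {prefix}: <{ns}> .")
    out.append(f"@prefix rdf: <{RDF}> .")
    out.append(f"@prefix rdfs: <{RDFS}> .")
    out.append(f"@prefix xsd: <{XSD}> .")
    out.append("")

    def okey(o):
        return (isinstance(o, Literal), str(o), getattr(o, "datatype", None) or "",
                getattr(o, "language", None) or "")

    triples = sorted(graph, key=lambda t: (str(t[0]), str(t[1]), okey(t[2])))
    current = None
    block: list[str] = []
    for s, p, o in triples:
        line = f"{p.n3(nm)} {o.n3(nm)}"
        if s != current:
            if block:
                out.append(" ;\n    ".join(block) + " .")
                out.append("")
            current = s
            block = [f"{s.n3(nm)} {line}"]
        else:
            block.append(line)
    if block:
        out.append(" ;\n    ".join(block) + " .")
    return "\n".join(out) + "\n"


def parse_rdf_text(text: str, format: str = "turtle") -> Graph:
    """Parse Turtle or N-Triples text into a graph."""
    g = Graph(bind_namespaces="none")
    g.parse(data=text, format=format)
    return g


__all__ = [
    "DEFAULT_DATA_BASE", "DEFAULT_PREFIXES", "VOCABULARY",
    "IriMinter", "Term", "TermRegistry",
    "build_term_registry", "count_expected_triples", "from_rdf", "mint_iri",
    "parse_rdf_text", "serialize_ntriples", "serialize_turtle", "slugify",
    "to_rdf",
]
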