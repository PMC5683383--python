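"""SIRO (Sample-Instrument-Reagent-Objective) minimal-information cards.

SIRO is the minimal common information shared across experimental protocols,
conceived in the same spirit as PICO in evidence-based medicine: enough to
frame and answer search questions without exposing the document's content.
A card carries the declared samples, instruments (equipment and kits) and
reagents, the stated objective, and bibliographic pass-through — and by
construction never any subprocedure text, alert text or recipe body, so a
laboratory can publish the card while keeping the protocol itself private.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import yaml
from rdflib import Graph, Literal
from rdflib.namespace import RDF, XSD

from . import model as m
from .errors import SchemaError
from .rdf import DEFAULT_DATA_BASE, IriMinter, TermRegistry, build_term_registry

SAMPLE_CATEGORIES = ("whole_organism", "anatomical_part", "biomolecule",
                     "body_fluid", "unclassified")
INSTRUMENT_CATEGORIES = ("high_throughput", "instrument", "glassware",
                         "standard_equipment", "consumable", "unclassified")
REAGENT_CATEGORIES = ("chemical_compound", "solution_buffer",
                      "cell_culture_medium", "unclassified")

_SLOT_CATEGORIES = {
    "sample": SAMPLE_CATEGORIES,
    "instrument": INSTRUMENT_CATEGORIES,
    "reagent": REAGENT_CATEGORIES,
}

# Seed lexicon: the exemplar terms of the published category table, one slot
# and category per normalized term.  Extension is config-file based; there is
# no external vocabulary download and no fuzzy matching.
_SEED_ENTRIES: list[tuple[str, str, str]] = [
    # sample / whole organism
    ("Arabidopsis thaliana", "sample", "whole_organism"),
    ("Oriza sativa", "sample", "whole_organism"),
    ("Oryza sativa", "sample", "whole_organism"),
    ("Mangifera indica", "sample", "whole_organism"),
    ("Mus musculus", "sample", "whole_organism"),
    ("Mouse-ear Cress", "sample", "whole_organism"),
    ("rice", "sample", "whole_organism"),
    ("mango", "sample", "whole_organism"),
    ("mouse", "sample", "whole_organism"),
    # sample / anatomical part
    ("leaf", "sample", "anatomical_part"),
    ("stem", "sample", "anatomical_part"),
    ("cells", "sample", "anatomical_part"),
    ("tissues", "sample", "anatomical_part"),
    ("membranes", "sample", "anatomical_part"),
    ("organs", "sample", "anatomical_part"),
    ("skeletal system", "sample", "anatomical_part"),
    ("muscular system", "sample", "anatomical_part"),
    ("nervous system", "sample", "anatomical_part"),
    ("reproductive system", "sample", "anatomical_part"),
    ("cardiovascular system", "sample", "anatomical_part"),
    # sample / biomolecules
    ("deoxyribonucleic acid", "sample", "biomolecule"),
    ("DNA", "sample", "biomolecule"),
    ("ribonucleic acid", "sample", "biomolecule"),
    ("RNA", "sample", "biomolecule"),
    ("enzymes", "sample", "biomolecule"),
    ("keratin", "sample", "biomolecule"),
    ("elastin", "sample", "biomolecule"),
    ("collagen", "sample", "biomolecule"),
    ("antibodies", "sample", "biomolecule"),
    ("hormones", "sample", "biomolecule"),
    # sample / body fluids
    ("blood serum", "sample", "body_fluid"),
    ("saliva", "sample", "body_fluid"),
    ("semen", "sample", "body_fluid"),
    ("amniotic fluid", "sample", "body_fluid"),
    ("cerebrospinal fluid", "sample", "body_fluid"),
    ("gastric acid", "sample", "body_fluid"),
    # instrument / high-throughput equipment
    ("Liquid Handling Platforms", "instrument", "high_throughput"),
    ("Real-Time PCR Detection System", "instrument", "high_throughput"),
    ("Microplate Reader", "instrument", "high_throughput"),
    # instrument / instruments
    ("goggles", "instrument", "instrument"),
    ("Bunsen burner", "instrument", "instrument"),
    ("spot plate", "instrument", "instrument"),
    ("pipet", "instrument", "instrument"),
    ("forceps", "instrument", "instrument"),
    ("test tube rack", "instrument", "instrument"),
    ("mortar and pestle", "instrument", "instrument"),
    # instrument / laboratory glassware
    ("beaker", "instrument", "glassware"),
    ("Erlenmeyer flask", "instrument", "glassware"),
    ("graduated cylinder", "instrument", "glassware"),
    ("volumetric flask", "instrument", "glassware"),
    # instrument / standard equipment
    ("balances", "instrument", "standard_equipment"),
    ("shakers", "instrument", "standard_equipment"),
    ("centrifuges", "instrument", "standard_equipment"),
    ("centrifuge", "instrument", "standard_equipment"),
    ("refrigerators", "instrument", "standard_equipment"),
    ("incubators", "instrument", "standard_equipment"),
    ("incubator", "instrument", "standard_equipment"),
    ("thermocyclers", "instrument", "standard_equipment"),
    ("fume hood", "instrument", "standard_equipment"),
    # instrument / consumables
    ("weighing dishes", "instrument", "consumable"),
    ("pipette tips", "instrument", "consumable"),
    ("gloves", "instrument", "consumable"),
    ("syringes", "instrument", "consumable"),
    ("petri dishes", "instrument", "consumable"),
    ("test tubes", "instrument", "consumable"),
    ("micro centrifuge tubes", "instrument", "consumable"),
    ("glass slides", "instrument", "consumable"),
    ("filter paper", "instrument", "consumable"),
    # reagent / chemical compound or substance
    ("glucose", "reagent", "chemical_compound"),
    ("ethanol", "reagent", "chemical_compound"),
    ("glycerol", "reagent", "chemical_compound"),
    ("chloroform", "reagent", "chemical_compound"),
    ("acetic acid", "reagent", "chemical_compound"),
    ("isopropyl alcohol", "reagent", "chemical_compound"),
    # reagent / solutions and buffers
    ("70% ethanol", "reagent", "solution_buffer"),
    ("10X PCR buffer", "reagent", "solution_buffer"),
    ("phenol:chloroform:isoamyl alcohol", "reagent", "solution_buffer"),
    # reagent / cell culture media
    ("nutrient media", "reagent", "cell_culture_medium"),
    ("minimal media", "reagent", "cell_culture_medium"),
    ("selective media", "reagent", "cell_culture_medium"),
    ("differential media", "reagent", "cell_culture_medium"),
]


class CategoryLexicon:
    """Normalized term -> (slot, category) lookup for material classification."""

    def __init__(self, entries: dict[str, tuple[str, str]] | None = None):
        self.entries: dict[str, tuple[str, str]] = dict(entries or {})

    def add(self, term: str, slot: str, category: str) -> None:
        if slot not in _SLOT_CATEGORIES:
            raise SchemaError(f"unknown SIRO slot {slot!r}", term)
        if category not in _SLOT_CATEGORIES[slot]:
            raise SchemaError(
                f"category {category!r} is not valid for slot {slot!r}", term)
        self.entries[m.normalize_name(term)] = (slot, category)

    def get(self, term: str) -> tuple[str, str] | None:
        return self.entries.get(m.normalize_name(term))

    def merge_file(self, path) -> None:
        """Extend the lexicon from a YAML config of ``term: slot/category``
        lines (or ``term: {slot: ..., category: ...}`` mappings)."""
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise SchemaError("lexicon config must be a mapping", str(path))
        for term, value in data.items():
            if isinstance(value, str):
                slot, _, category = value.partition("/")
            elif isinstance(value, dict):
                slot, category = value.get("slot", ""), value.get("category", "")
            else:
                raise SchemaError("lexicon entry must be 'slot/category' or a "
                                  "mapping", str(term))
            self.add(str(term), slot.strip(), category.strip())


def default_lexicon() -> CategoryLexicon:
    lex = CategoryLexicon()
    for term, slot, category in _SEED_ENTRIES:
        lex.add(term, slot, category)
    return lex


def classify_material(name: str, slot: str, lexicon: CategoryLexicon) -> str:
    """Total, deterministic category lookup; ``unclassified`` when the term is
    absent or recorded under a different slot (never guesses across slots)."""
    if slot not in _SLOT_CATEGORIES:
        raise SchemaError(f"unknown SIRO slot {slot!r}", name)
    hit = lexicon.get(name)
    if hit is None or hit[0] != slot:
        return "unclassified"
    return hit[1]


@dataclass
class SIROBiblio:
    title: str = ""
    authors: list[str] = field(default_factory=list)
    protocol_identifier: str | None = None


@dataclass
class SIROCard:
    """Minimal-information projection of one protocol.

    ``protocol_id`` is the internal linkage id; every (name, category) entry
    traces back to a declaration or a workflow participant of the source
    protocol, and no step, alert or recipe text ever enters the card.
    """

    protocol_id: str = ""
    samples: list[tuple[str, str]] = field(default_factory=list)
    instruments: list[tuple[str, str]] = field(default_factory=list)
    reagents: list[tuple[str, str]] = field(default_factory=list)
    objective: str = ""
    biblio: SIROBiblio = field(default_factory=SIROBiblio)

    def to_json(self) -> str:
        return json.dumps({
            "protocol_id": self.protocol_id,
            "samples": [{"name": n, "category": c} for n, c in self.samples],
            "instruments": [{"name": n, "category": c}
                            for n, c in self.instruments],
            "reagents": [{"name": n, "category": c} for n, c in self.reagents],
            "objective": self.objective,
            "biblio": {
                "title": self.biblio.title,
                "authors": list(self.biblio.authors),
                "protocol_identifier": self.biblio.protocol_identifier,
            },
        }, indent=2, ensure_ascii=False) + "\n"


def extract_siro(protocol: m.Protocol,
                 lexicon: CategoryLexicon | None = None) -> SIROCard:
    """Project a protocol onto its SIRO card.

    Samples come from declared specimens, instruments from declared equipment
    and kits, reagents from declared reagents.  Workflow participants that
    match no declaration are routed by lexicon lookup — the card stays
    truthful when authors under-declare — and silently skipped when the
    lexicon cannot place them (placing them would mean guessing a slot).
    The extraction is idempotent and independent of protocol visibility.
    """
    lexicon = lexicon or default_lexicon()
    slots: dict[str, dict[str, str]] = {"sample": {}, "instrument": {},
                                        "reagent": {}}

    def put(slot: str, name: str) -> None:
        key = m.normalize_name(name)
        if key and key not in slots[slot]:
            slots[slot][key] = name

    doc = protocol.document
    for specimen in doc.specimens:
        put("sample", specimen.name)
    for eq in doc.equipment:
        put("instrument", eq.name)
    for kit in doc.kits:
        put("instrument", kit.name)
    for reagent in doc.reagents:
        put("reagent", reagent.name)

    declared = m.declared_material_names(doc)
    for proc in protocol.workflow.procedures:
        for step in proc.subprocedures:
            for part in step.participants:
                if m.normalize_name(part.name) in declared:
                    continue
                hit = lexicon.get(part.name)
                if hit is not None:
                    put(hit[0], part.name)

    def entries(slot: str) -> list[tuple[str, str]]:
        return sorted(
            ((name, classify_material(name, slot, lexicon))
             for name in slots[slot].values()),
            key=lambda e: m.normalize_name(e[0]),
        )

    return SIROCard(
        protocol_id=protocol.id,
        samples=entries("sample"),
        instruments=entries("instrument"),
        reagents=entries("reagent"),
        objective=doc.purpose_objective or "",
        biblio=SIROBiblio(
            title=doc.title,
            authors=[a.name for a in doc.authors],
            protocol_identifier=doc.protocol_identifier,
        ),
    )


def export_siro_rdf(card: SIROCard,
                    registry: TermRegistry | None = None,
                    base: str = DEFAULT_DATA_BASE,
                    language: str = "en") -> Graph:
    """Emit the privacy-preserving RDF view of a card.

    The graph reuses the same document-layer predicates as the full mapping
    (specimen/reagent/equipment names, authors, title) so SIRO-level
    competency queries run unchanged, and additionally types every entry with
    its SIRO slot and category.  It contains no subprocedure, alert or recipe
    node, so step-level queries return nothing by construction.
    """
    registry = registry or build_term_registry()
    sp = lambda label: registry.term("sp", label)  # noqa: E731
    siro = lambda label: registry.term("siro", label)  # noqa: E731
    minter = IriMinter(card.protocol_id or "siro-card", base)
    g = Graph(bind_namespaces="none")

    doc = minter.mint("protocol", card.protocol_id or "siro-card")
    g.add((doc, RDF.type, sp("experimental protocol")))
    g.add((doc, RDF.type, siro("siro record")))
    if card.protocol_id:
        g.add((doc, sp("identifier"), Literal(card.protocol_id)))
    if card.biblio.title:
        g.add((doc, sp("title of the protocol"),
               Literal(card.biblio.title, lang=language)))
    if card.biblio.protocol_identifier:
        g.add((doc, sp("protocol identifier"),
               Literal(card.biblio.protocol_identifier)))
    for i, name in enumerate(card.biblio.authors):
        node = minter.mint("author", f"author {i + 1} {name}")
        g.add((doc, sp("has author"), node))
        g.add((node, RDF.type, sp("author")))
        g.add((node, sp("author name"), Literal(name)))
        g.add((node, sp("position"), Literal(i, datatype=XSD.integer)))
    if card.objective:
        g.add((doc, sp("purpose of the protocol"),
               Literal(card.objective, lang=language)))

    rules = (
        ("samples", "specimen", "has specimen", "specimen", "specimen name",
         "sample"),
        ("instruments", "equipment", "has equipment", "equipment or supplies",
         "equipment name", "instrument"),
        ("reagents", "reagent", "has reagent", "reagent", "reagent name",
         "reagent"),
    )
    for attr, kind, link, cls, name_label, siro_cls in rules:
        for name, category in getattr(card, attr):
            node = minter.mint(kind, name)
            g.add((doc, sp(link), node))
            g.add((node, RDF.type, sp(cls)))
            g.add((node, RDF.type, siro(siro_cls)))
            g.add((node, sp(name_label), Literal(name)))
            g.add((node, siro("category"), Literal(category)))
    return g


def private_text_set(protocol: m.Protocol) -> set[str]:
    """Every literal that must never leak into a SIRO export: subprocedure
    text, alert text and recipe bodies."""
    texts: set[str] = {r.body_text for r in protocol.document.recipes}
    for proc in protocol.workflow.procedures:
        for step in proc.subprocedures:
            texts.add(step.text)
            for alert in step.alerts:
                texts.add(alert.text)
    texts.discard("")
    return texts


__all__ = [
    "INSTRUMENT_CATEGORIES", "REAGENT_CATEGORIES", "SAMPLE_CATEGORIES",
    "CategoryLexicon", "SIROBiblio", "SIROCard",
    "classify_material", "default_lexicon", "export_siro_rdf", "extract_siro",
    "private_text_set",
]
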