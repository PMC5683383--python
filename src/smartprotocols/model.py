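"""In-memory data model for experimental protocols.

A protocol is conceptualized as a workflow embedded within a document: the
document layer carries reporting metadata (title, authors, identifiers,
declared materials, recipes), the workflow layer carries the executable
sequence of laboratory procedures and subprocedures, each with experimental
inputs/outputs, participants and alert messages.

Ordering between sibling workflow units is stored as a single optional
``preceded_by`` link (the inverse *precedes* is always derived, never stored,
so the two duals cannot disagree).  Where links are absent, document order is
authoritative.
"""

from __future__ import annotations

import copy
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Union

from .errors import (
    AmbiguityWarning,
    CycleError,
    DanglingPrecedenceError,
    EmptyStepsError,
)

VISIBILITIES = ("public", "siro_only")
PROCEDURE_KINDS = ("procedure", "recipe_execution", "container")
ALERT_KINDS = ("caution", "hint", "pause_point", "troubleshooting", "generic_alert")
EQUIPMENT_CATEGORIES = (
    "high_throughput",
    "instrument",
    "glassware",
    "standard_equipment",
    "consumable",
)
AUTHOR_ROLES = (
    "chief_scientist",
    "lab_scientist",
    "validator",
    "statistical_reviewer",
    "author",
)


def normalize_name(name: str) -> str:
    """Case-insensitive, whitespace-normalized form used for name matching."""
    return " ".join(name.split()).casefold()


@dataclass
class Measure:
    """A scalar quantity attached to a participant, e.g. 0.2 mL of chloroform."""

    value: float
    unit: str


@dataclass
class AlertMessage:
    """Step-level advisory note: caution, hint, pause point or troubleshooting."""

    kind: str
    text: str


@dataclass
class FlowItem:
    """A material flowing between procedures, e.g. "homogenized tissue".

    ``external_ref`` is an optional compact prefixed identifier (CURIE) tying
    the item to an external vocabulary, e.g. ``chebi:RNA``.
    """

    name: str
    external_ref: str | None = None


@dataclass
class Participant:
    """Reference from a subprocedure to a material taking part in the action."""

    name: str
    measure: Measure | None = None


@dataclass
class DerivedMaterial:
    """Derivation annotation for antibodies, cell lines and plasmids:
    the source organism and the role the material plays in the protocol."""

    derives_from_organism: str
    role: str


@dataclass
class Reagent:
    name: str
    manufacturer: str | None = None
    catalog_number: str | None = None
    external_ref: str | None = None
    derived: DerivedMaterial | None = None


@dataclass
class Equipment:
    name: str
    category: str = "instrument"
    manufacturer: str | None = None
    catalog_number: str | None = None


@dataclass
class Kit:
    """Gear consisting of a set of articles or tools for a specified purpose.

    Reagent-vs-kit-vs-equipment is an explicit authoring choice, never
    inferred: authors routinely list all three under "Reagents" while readers
    understand them as distinct categories.
    """

    name: str
    manufacturer: str | None = None
    catalog_number: str | None = None


@dataclass
class Specimen:
    name: str
    organism: str | None = None
    organism_ref: str | None = None
    anatomical_part: str | None = None
    attributes: dict[str, str] = field(default_factory=dict)
    derived: DerivedMaterial | None = None


@dataclass
class RecipeRef:
    """A recipe is a textual entity of the document layer (how to prepare a
    solution, clean equipment, ...); its *execution* is a workflow-layer
    procedure of kind ``recipe_execution``."""

    name: str
    body_text: str


@dataclass
class Author:
    name: str
    identifier: str | None = None
    roles: list[str] = field(default_factory=list)


@dataclass
class LabSubprocedure:
    """A single instruction step within a procedure."""

    id: str
    text: str
    participants: list[Participant] = field(default_factory=list)
    alerts: list[AlertMessage] = field(default_factory=list)
    preceded_by: str | None = None


@dataclass
class LabProcedure:
    """A grouped stage of a protocol, transforming inputs into outputs."""

    id: str
    label: str = ""
    kind: str = "procedure"
    inputs: list[FlowItem] = field(default_factory=list)
    outputs: list[FlowItem] = field(default_factory=list)
    subprocedures: list[LabSubprocedure] = field(default_factory=list)
    preceded_by: str | None = None


@dataclass
class Workflow:
    procedures: list[LabProcedure] = field(default_factory=list)


@dataclass
class DocumentMetadata:
    title: str = ""
    authors: list[Author] = field(default_factory=list)
    protocol_identifier: str | None = None
    application: str | None = None
    provenance_statement: str | None = None
    purpose_objective: str | None = None
    advantages: list[str] = field(default_factory=list)
    limitations: list[str] = field(default_factory=list)
    version: str | None = None
    specimens: list[Specimen] = field(default_factory=list)
    reagents: list[Reagent] = field(default_factory=list)
    kits: list[Kit] = field(default_factory=list)
    equipment: list[Equipment] = field(default_factory=list)
    recipes: list[RecipeRef] = field(default_factory=list)


@dataclass
class Protocol:
    """Root aggregate: document metadata + workflow + visibility flag."""

    id: str
    document: DocumentMetadata
    workflow: Workflow
    visibility: str = "public"


@dataclass
class Issue:
    severity: str  # "error" | "warning"
    code: str
    message: str
    location: str


@dataclass
class ValidationReport:
    issues: list[Issue] = field(default_factory=list)

    @property
    def errors(self) -> list[Issue]:
        return [i for i in self.issues if i.severity == "error"]

    @property
    def warnings(self) -> list[Issue]:
        return [i for i in self.issues if i.severity == "warning"]

    def is_valid(self) -> bool:
        return not self.errors


class IOLink(NamedTuple):
    producer: str
    item: str
    consumer: str


class ChainResult(NamedTuple):
    links: list[IOLink]
    unmatched: list[tuple[str, str]]  # (consumer procedure id, flow item name)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def linearize_subprocedures(procedure: LabProcedure) -> list[LabSubprocedure]:
    """Return the subprocedures of ``procedure`` in execution order.

    The order is a strict total order consistent with every ``preceded_by``
    link; where links leave the order under-determined, ties are broken by
    input (document) order and an :class:`AmbiguityWarning` is recorded.

    Raises
    ------
    CycleError
        if the precedence links contain a cycle.
    DanglingPrecedenceError
        if a link references a non-sibling id.
    """
    steps = procedure.subprocedures
    return _linearize(steps, f"procedure {procedure.id!r}")


def _linearize(steps: list, context: str) -> list:
    n = len(steps)
    if n <= 1:
        return list(steps)
    index = {s.id: i for i, s in enumerate(steps)}
    succ: dict[int, list[int]] = {i: [] for i in range(n)}
    indeg = [0] * n
    n_links = 0
    for i, s in enumerate(steps):
        if s.preceded_by is None:
            continue
        if s.preceded_by not in index:
            raise DanglingPrecedenceError(
                f"{context}: step {s.id!r} is preceded by unknown id {s.preceded_by!r}"
            )
        succ[index[s.preceded_by]].append(i)
        indeg[i] += 1
        n_links += 1

    # Kahn's algorithm; the ready set is always drained smallest-input-index
    # first, which makes the result stable with respect to input order.
    ready = sorted(i for i in range(n) if indeg[i] == 0)
    out: list[int] = []
    ambiguous = False
    while ready:
        if len(ready) > 1 and n_links > 0:
            ambiguous = True
        i = ready.pop(0)
        out.append(i)
        for j in succ[i]:
            indeg[j] -= 1
            if indeg[j] == 0:
                ready.append(j)
        ready.sort()
    if len(out) != n:
        cyclic = sorted(steps[i].id for i in range(n) if i not in out)
        raise CycleError(f"{context}: precedence cycle involving steps {cyclic}")
    if ambiguous:
        warnings.warn(
            f"{context}: precedence links define only a partial order; "
            "ties broken by input order",
            AmbiguityWarning,
            stacklevel=3,
        )
    return [steps[i] for i in out]


def declared_material_names(document: DocumentMetadata) -> set[str]:
    """Normalized names of every document-level declared material."""
    names: set[str] = set()
    for group in (document.specimens, document.reagents, document.kits,
                  document.equipment):
        for m in group:
            names.add(normalize_name(m.name))
    return names


def resolve_io_chain(
    workflow: Union[Workflow, Protocol],
    declared: Iterable[str] = (),
) -> ChainResult:
    """Chain procedure outputs to later procedure inputs by name.

    For every procedure input that is a flow item *not* declared as a
    document-level material, links it to the nearest earlier procedure whose
    outputs contain a name-matching flow item.  Matching is case-insensitive
    and whitespace-normalized; there is no fuzzy matching.  Inputs that match
    nothing are returned in the companion ``unmatched`` list — authors
    legitimately omit chains, so these are warnings, not errors.
    """
    if isinstance(workflow, Protocol):
        declared_set = declared_material_names(workflow.document)
        declared_set |= {normalize_name(d) for d in declared}
        workflow = workflow.workflow
    else:
        declared_set = {normalize_name(d) for d in declared}

    procedures = workflow.procedures
    links: list[IOLink] = []
    unmatched: list[tuple[str, str]] = []
    for ci, consumer in enumerate(procedures):
        for item in consumer.inputs:
            key = normalize_name(item.name)
            if key in declared_set:
                continue
            producer = None
            for pi in range(ci - 1, -1, -1):  # nearest earlier producer
                if any(normalize_name(o.name) == key
                       for o in procedures[pi].outputs):
                    producer = procedures[pi]
                    break
            if producer is None:
                unmatched.append((consumer.id, item.name))
            else:
                links.append(IOLink(producer.id, item.name, consumer.id))
    return ChainResult(links, unmatched)


def wrap_flat_steps(
    steps: list[LabSubprocedure],
    label: str | None = None,
    proc_id: str = "container-1",
) -> LabProcedure:
    """Wrap a flat list of steps into an auto-generated procedure container.

    Protocols that are only a long list of steps get a single container
    procedure so flat and grouped protocols share one representation.
    Linearization of the result reproduces the input order.
    """
    if not steps:
        raise EmptyStepsError("cannot build a procedure container from zero steps")
    if label is None:
        label = f"procedure container ({len(steps)} steps)"
    return LabProcedure(
        id=proc_id,
        label=label,
        kind="container",
        subprocedures=list(steps),
    )


def validate_structure(protocol: Protocol) -> ValidationReport:
    """Check every structural invariant of the model; never mutates, never throws.

    Structural breaks (duplicate ids, dangling or cyclic precedence, empty
    workflow, empty titles, a catalog number without a manufacturer) are
    errors; reporting-quality gaps (missing catalog number, missing version)
    are warnings, because published protocols routinely omit them.
    """
    issues: list[Issue] = []

    def err(code: str, message: str, location: str) -> None:
        issues.append(Issue("error", code, message, location))

    def warn(code: str, message: str, location: str) -> None:
        issues.append(Issue("warning", code, message, location))

    doc = protocol.document
    if not protocol.id or not protocol.id.strip():
        err("protocol.id.empty", "protocol id must be non-empty", "id")
    if protocol.visibility not in VISIBILITIES:
        err("protocol.visibility.invalid",
            f"visibility must be one of {VISIBILITIES}", "visibility")
    if not doc.title or not doc.title.strip():
        err("document.title.empty", "document title must be non-empty",
            "document.title")
    if doc.version is None:
        warn("document.version.missing", "protocol carries no version information",
             "document.version")

    for ai, author in enumerate(doc.authors):
        loc = f"document.authors[{ai}]"
        if not author.name.strip():
            err("author.name.empty", "author name must be non-empty", loc)
        for role in author.roles:
            if role not in AUTHOR_ROLES:
                err("author.role.invalid", f"unknown author role {role!r}", loc)

    seen_materials: set[tuple[str, str, str, str]] = set()
    material_groups = (
        ("specimens", doc.specimens),
        ("reagents", doc.reagents),
        ("kits", doc.kits),
        ("equipment", doc.equipment),
    )
    for group_name, group in material_groups:
        for mi, m in enumerate(group):
            loc = f"document.{group_name}[{mi}]"
            if not m.name.strip():
                err("material.name.empty", "material name must be non-empty", loc)
            manufacturer = getattr(m, "manufacturer", None)
            catalog = getattr(m, "catalog_number", None)
            if catalog is not None and manufacturer is None:
                err("material.catalog_without_manufacturer",
                    f"{m.name!r} has a catalog number but no manufacturer", loc)
            if group_name != "specimens" and catalog is None:
                warn("material.catalog_number.missing",
                     f"{m.name!r} has no catalog number", loc)
            key = (
                group_name,
                normalize_name(m.name),
                normalize_name(manufacturer or ""),
                normalize_name(catalog or ""),
            )
            if key in seen_materials:
                err("material.duplicate",
                    f"duplicate declaration of {m.name!r} in {group_name}", loc)
            seen_materials.add(key)
            if group_name == "equipment" and m.category not in EQUIPMENT_CATEGORIES:
                err("equipment.category.invalid",
                    f"unknown equipment category {m.category!r}", loc)
            derived = getattr(m, "derived", None)
            if derived is not None:
                if not derived.derives_from_organism.strip() or not derived.role.strip():
                    err("material.derived.incomplete",
                        "derivation annotation needs both organism and role", loc)
    for ri, r in enumerate(doc.recipes):
        if not r.name.strip():
            err("recipe.name.empty", "recipe name must be non-empty",
                f"document.recipes[{ri}]")

    wf = protocol.workflow
    if not wf.procedures:
        err("workflow.empty", "workflow must contain at least one procedure",
            "workflow")
    proc_ids: set[str] = set()
    for p in wf.procedures:
        if p.id in proc_ids:
            err("procedure.id.duplicate", f"duplicate procedure id {p.id!r}",
                f"workflow.procedures[{p.id}]")
        proc_ids.add(p.id)
    for pi, p in enumerate(wf.procedures):
        loc = f"workflow.procedures[{pi}]"
        if p.kind not in PROCEDURE_KINDS:
            err("procedure.kind.invalid", f"unknown procedure kind {p.kind!r}", loc)
        if p.preceded_by is not None and p.preceded_by not in proc_ids:
            err("order.dangling",
                f"procedure {p.id!r} preceded by unknown id {p.preceded_by!r}", loc)
        for io_name, items in (("inputs", p.inputs), ("outputs", p.outputs)):
            for item in items:
                if not item.name.strip():
                    err("flowitem.name.empty",
                        f"empty flow item name in {io_name}", f"{loc}.{io_name}")
        step_ids: set[str] = set()
        for s in p.subprocedures:
            if s.id in step_ids:
                err("subprocedure.id.duplicate",
                    f"duplicate subprocedure id {s.id!r} in procedure {p.id!r}", loc)
            step_ids.add(s.id)
        for si, s in enumerate(p.subprocedures):
            sloc = f"{loc}.subprocedures[{si}]"
            if not s.text or not s.text.strip():
                err("subprocedure.text.empty",
                    f"subprocedure {s.id!r} has empty instruction text", sloc)
            if s.preceded_by is not None and s.preceded_by not in step_ids:
                err("order.dangling",
                    f"subprocedure {s.id!r} preceded by unknown id "
                    f"{s.preceded_by!r}", sloc)
            for a in s.alerts:
                if a.kind not in ALERT_KINDS:
                    err("alert.kind.invalid", f"unknown alert kind {a.kind!r}", sloc)
                if not a.text.strip():
                    err("alert.text.empty", "alert text must be non-empty", sloc)
            for part in s.participants:
                if not part.name.strip():
                    err("participant.name.empty",
                        "participant name must be non-empty", sloc)
                if part.measure is not None:
                    if not math.isfinite(part.measure.value):
                        err("measure.value.not_finite",
                            "measure value must be finite", sloc)
                    if not part.measure.unit.strip():
                        err("measure.unit.missing",
                            "measure with a value needs a unit", sloc)
        # cycle detection among this procedure's steps (dangling already reported)
        if not any(s.preceded_by is not None and s.preceded_by not in step_ids
                   for s in p.subprocedures):
            _check_cycle(p.subprocedures, loc, err)

    # cycle detection among procedures
    if not any(p.preceded_by is not None and p.preceded_by not in proc_ids
               for p in wf.procedures):
        _check_cycle(wf.procedures, "workflow.procedures", err)

    return ValidationReport(issues)


def _check_cycle(units, location: str, err) -> None:
    index = {u.id: u for u in units}
    state: dict[str, int] = {}  # 0 visiting, 1 done
    for u in units:
        if u.id in state:
            continue
        chain = []
        cur: object = u
        while cur is not None and cur.id not in state:
            state[cur.id] = 0
            chain.append(cur.id)
            cur = index.get(cur.preceded_by) if cur.preceded_by else None
        if cur is not None and state.get(cur.id) == 0:
            err("order.cycle",
                f"precedence links form a cycle through {cur.id!r}", location)
            for cid in chain:
                state[cid] = 1
            return
        for cid in chain:
            state[cid] = 1


# ---------------------------------------------------------------------------
# Canonical form
# ---------------------------------------------------------------------------

def canonicalize(protocol: Protocol) -> Protocol:
    """Return a deep copy in canonical form.

    Author, procedure and subprocedure order is meaningful and preserved;
    unordered collections (declared materials, advantages/limitations,
    inputs/outputs, participants, alerts, roles, specimen attributes) are
    sorted so that structurally equal protocols compare equal regardless of
    authoring order.  Flow items whose name matches a declared material drop
    their external reference (the declaration is authoritative).
    """
    p = copy.deepcopy(protocol)
    doc = p.document
    doc.specimens.sort(key=lambda m: normalize_name(m.name))
    doc.reagents.sort(key=lambda m: (normalize_name(m.name), m.manufacturer or "",
                                     m.catalog_number or ""))
    doc.kits.sort(key=lambda m: (normalize_name(m.name), m.manufacturer or ""))
    doc.equipment.sort(key=lambda m: (normalize_name(m.name), m.category))
    doc.recipes.sort(key=lambda r: normalize_name(r.name))
    doc.advantages.sort()
    doc.limitations.sort()
    for a in doc.authors:
        a.roles.sort()
    for sp in doc.specimens:
        sp.attributes = dict(sorted(sp.attributes.items()))
    declared = declared_material_names(doc)
    for proc in p.workflow.procedures:
        for items in (proc.inputs, proc.outputs):
            for item in items:
                if normalize_name(item.name) in declared:
                    item.external_ref = None
            items.sort(key=lambda it: (normalize_name(it.name),
                                       it.external_ref or ""))
        for s in proc.subprocedures:
            s.participants.sort(key=lambda q: normalize_name(q.name))
            s.alerts.sort(key=lambda a: (a.kind, a.text))
    return p


__all__ = [
    "ALERT_KINDS", "AUTHOR_ROLES", "EQUIPMENT_CATEGORIES", "PROCEDURE_KINDS",
    "VISIBILITIES",
    "AlertMessage", "Author", "ChainResult", "DerivedMaterial",
    "DocumentMetadata", "Equipment", "FlowItem", "IOLink", "Issue", "Kit",
    "LabProcedure", "LabSubprocedure", "Measure", "Participant", "Protocol",
    "Reagent", "RecipeRef", "Specimen", "ValidationReport", "Workflow",
    "canonicalize", "declared_material_names", "linearize_subprocedures",
    "normalize_name", "resolve_io_chain", "validate_structure",
    "wrap_flat_steps",
]
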