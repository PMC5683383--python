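"""Reader/writer for the ``.spd.yaml`` interchange format, the built-in
running-example fixture, and the synthetic-protocol generator.

The interchange format is a YAML 1.2 document with three top-level sections,
``id``/``visibility``, ``document`` and ``workflow``.  Unknown keys are hard
errors, not silently ignored, so round-trips can never lose data.  Writing is
deterministic: stable key order, stable list order, empty optionals omitted.
"""

from __future__ import annotations

import importlib.resources
import random
from dataclasses import dataclass, field

import yaml

from . import model as m
from .errors import ConfigError, InvalidProtocolError, ProtocolSyntaxError, SchemaError

# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

_TOP_KEYS = {"id", "visibility", "document", "workflow"}
_DOC_KEYS = {
    "title", "authors", "protocol_identifier", "application", "provenance",
    "objective", "version", "advantages", "limitations", "specimens",
    "reagents", "kits", "equipment", "recipes",
}
_AUTHOR_KEYS = {"name", "identifier", "roles"}
_REAGENT_KEYS = {"name", "manufacturer", "catalog_number", "external_ref",
                 "derives_from"}
_EQUIPMENT_KEYS = {"name", "category", "manufacturer", "catalog_number"}
_KIT_KEYS = {"name", "manufacturer", "catalog_number"}
_SPECIMEN_KEYS = {"name", "organism", "organism_ref", "anatomical_part",
                  "attributes", "derives_from"}
_RECIPE_KEYS = {"name", "text"}
_PROC_KEYS = {"id", "label", "kind", "preceded_by", "inputs", "outputs", "steps"}
_STEP_KEYS = {"id", "text", "preceded_by", "participants", "alerts"}
_PART_KEYS = {"name", "measure"}
_MEASURE_KEYS = {"value", "unit"}
_ALERT_KEYS = {"kind", "text"}
_DERIVES_KEYS = {"organism", "role"}


def _require_map(node, path: str) -> dict:
    if not isinstance(node, dict):
        raise SchemaError(f"expected a mapping, got {type(node).__name__}", path)
    return node


def _require_list(node, path: str) -> list:
    if not isinstance(node, list):
        raise SchemaError(f"expected a list, got {type(node).__name__}", path)
    return node


def _require_str(node, path: str) -> str:
    if not isinstance(node, str):
        raise SchemaError(f"expected a string, got {type(node).__name__}", path)
    return node


def _check_keys(node: dict, allowed: set[str], path: str) -> None:
    unknown = set(node) - allowed
    if unknown:
        key = sorted(unknown)[0]
        raise SchemaError(f"unknown key {key!r}", f"{path}.{key}" if path else key)


def _opt_str(node: dict, key: str, path: str) -> str | None:
    if key not in node or node[key] is None:
        return None
    return _require_str(node[key], f"{path}.{key}")


def _str_list(node: dict, key: str, path: str) -> list[str]:
    if key not in node or node[key] is None:
        return []
    return [_require_str(v, f"{path}.{key}[{i}]")
            for i, v in enumerate(_require_list(node[key], f"{path}.{key}"))]


def _parse_derives(node, path: str) -> m.DerivedMaterial | None:
    if node is None:
        return None
    node = _require_map(node, path)
    _check_keys(node, _DERIVES_KEYS, path)
    return m.DerivedMaterial(
        derives_from_organism=_require_str(node.get("organism", ""), f"{path}.organism"),
        role=_require_str(node.get("role", ""), f"{path}.role"),
    )


def _parse_flow_item(node, path: str) -> m.FlowItem:
    if isinstance(node, str):
        return m.FlowItem(name=node)
    node = _require_map(node, path)
    _check_keys(node, {"name", "external_ref"}, path)
    return m.FlowItem(name=_require_str(node.get("name", ""), f"{path}.name"),
                      external_ref=_opt_str(node, "external_ref", path))


def parse_protocol_doc(text: str) -> m.Protocol:
    """Parse an interchange document into a :class:`Protocol`.

    Raises :class:`ProtocolSyntaxError` (with line/column) on malformed YAML
    and :class:`SchemaError` (naming the offending key/path) on schema
    violations.
    """
    try:
        root = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        mark = getattr(exc, "problem_mark", None)
        if mark is not None:
            raise ProtocolSyntaxError(str(getattr(exc, "problem", exc)),
                                      mark.line + 1, mark.column + 1) from exc
        raise ProtocolSyntaxError(str(exc)) from exc
    root = _require_map(root, "")
    _check_keys(root, _TOP_KEYS, "")
    for key in ("id", "document", "workflow"):
        if key not in root:
            raise SchemaError(f"missing required section {key!r}", key)

    pid = _require_str(root["id"], "id")
    visibility = root.get("visibility", "public")
    visibility = _require_str(visibility, "visibility")

    doc_node = _require_map(root["document"], "document")
    _check_keys(doc_node, _DOC_KEYS, "document")
    doc = m.DocumentMetadata(
        title=_require_str(doc_node.get("title", ""), "document.title"),
        protocol_identifier=_opt_str(doc_node, "protocol_identifier", "document"),
        application=_opt_str(doc_node, "application", "document"),
        provenance_statement=_opt_str(doc_node, "provenance", "document"),
        purpose_objective=_opt_str(doc_node, "objective", "document"),
        version=_opt_str(doc_node, "version", "document"),
        advantages=_str_list(doc_node, "advantages", "document"),
        limitations=_str_list(doc_node, "limitations", "document"),
    )
    for i, a in enumerate(_require_list(doc_node.get("authors", []) or [],
                                        "document.authors")):
        path = f"document.authors[{i}]"
        a = _require_map(a, path)
        _check_keys(a, _AUTHOR_KEYS, path)
        doc.authors.append(m.Author(
            name=_require_str(a.get("name", ""), f"{path}.name"),
            identifier=_opt_str(a, "identifier", path),
            roles=_str_list(a, "roles", path),
        ))
    for i, s in enumerate(_require_list(doc_node.get("specimens", []) or [],
                                        "document.specimens")):
        path = f"document.specimens[{i}]"
        s = _require_map(s, path)
        _check_keys(s, _SPECIMEN_KEYS, path)
        attrs = s.get("attributes") or {}
        attrs = _require_map(attrs, f"{path}.attributes") if attrs else {}
        doc.specimens.append(m.Specimen(
            name=_require_str(s.get("name", ""), f"{path}.name"),
            organism=_opt_str(s, "organism", path),
            organism_ref=_opt_str(s, "organism_ref", path),
            anatomical_part=_opt_str(s, "anatomical_part", path),
            attributes={str(k): str(v) for k, v in attrs.items()},
            derived=_parse_derives(s.get("derives_from"), f"{path}.derives_from"),
        ))
    for i, r in enumerate(_require_list(doc_node.get("reagents", []) or [],
                                        "document.reagents")):
        path = f"document.reagents[{i}]"
        r = _require_map(r, path)
        _check_keys(r, _REAGENT_KEYS, path)
        doc.reagents.append(m.Reagent(
            name=_require_str(r.get("name", ""), f"{path}.name"),
            manufacturer=_opt_str(r, "manufacturer", path),
            catalog_number=_opt_str(r, "catalog_number", path),
            external_ref=_opt_str(r, "external_ref", path),
            derived=_parse_derives(r.get("derives_from"), f"{path}.derives_from"),
        ))
    for i, k in enumerate(_require_list(doc_node.get("kits", []) or [],
                                        "document.kits")):
        path = f"document.kits[{i}]"
        k = _require_map(k, path)
        _check_keys(k, _KIT_KEYS, path)
        doc.kits.append(m.Kit(
            name=_require_str(k.get("name", ""), f"{path}.name"),
            manufacturer=_opt_str(k, "manufacturer", path),
            catalog_number=_opt_str(k, "catalog_number", path),
        ))
    for i, e in enumerate(_require_list(doc_node.get("equipment", []) or [],
                                        "document.equipment")):
        path = f"document.equipment[{i}]"
        e = _require_map(e, path)
        _check_keys(e, _EQUIPMENT_KEYS, path)
        doc.equipment.append(m.Equipment(
            name=_require_str(e.get("name", ""), f"{path}.name"),
            category=_require_str(e.get("category", "instrument"),
                                  f"{path}.category"),
            manufacturer=_opt_str(e, "manufacturer", path),
            catalog_number=_opt_str(e, "catalog_number", path),
        ))
    for i, r in enumerate(_require_list(doc_node.get("recipes", []) or [],
                                        "document.recipes")):
        path = f"document.recipes[{i}]"
        r = _require_map(r, path)
        _check_keys(r, _RECIPE_KEYS, path)
        doc.recipes.append(m.RecipeRef(
            name=_require_str(r.get("name", ""), f"{path}.name"),
            body_text=_require_str(r.get("text", ""), f"{path}.text"),
        ))

    wf_node = _require_map(root["workflow"], "workflow")
    _check_keys(wf_node, {"procedures"}, "workflow")
    workflow = m.Workflow()
    for i, p in enumerate(_require_list(wf_node.get("procedures", []) or [],
                                        "workflow.procedures")):
        path = f"workflow.procedures[{i}]"
        p = _require_map(p, path)
        _check_keys(p, _PROC_KEYS, path)
        proc = m.LabProcedure(
            id=_require_str(p.get("id", ""), f"{path}.id"),
            label=_require_str(p.get("label", ""), f"{path}.label")
            if p.get("label") is not None else "",
            kind=_require_str(p.get("kind", "procedure"), f"{path}.kind"),
            preceded_by=_opt_str(p, "preceded_by", path),
            inputs=[_parse_flow_item(x, f"{path}.inputs[{j}]")
                    for j, x in enumerate(_require_list(p.get("inputs", []) or [],
                                                        f"{path}.inputs"))],
            outputs=[_parse_flow_item(x, f"{path}.outputs[{j}]")
                     for j, x in enumerate(_require_list(p.get("outputs", []) or [],
                                                         f"{path}.outputs"))],
        )
        for j, s in enumerate(_require_list(p.get("steps", []) or [],
                                            f"{path}.steps")):
            spath = f"{path}.steps[{j}]"
            s = _require_map(s, spath)
            _check_keys(s, _STEP_KEYS, spath)
            step = m.LabSubprocedure(
                id=_require_str(s.get("id", ""), f"{spath}.id"),
                text=_require_str(s.get("text", ""), f"{spath}.text"),
                preceded_by=_opt_str(s, "preceded_by", spath),
            )
            for q, pt in enumerate(_require_list(s.get("participants", []) or [],
                                                 f"{spath}.participants")):
                ppath = f"{spath}.participants[{q}]"
                if isinstance(pt, str):
                    step.participants.append(m.Participant(name=pt))
                    continue
                pt = _require_map(pt, ppath)
                _check_keys(pt, _PART_KEYS, ppath)
                measure = None
                if pt.get("measure") is not None:
                    mnode = _require_map(pt["measure"], f"{ppath}.measure")
                    _check_keys(mnode, _MEASURE_KEYS, f"{ppath}.measure")
                    try:
                        value = float(mnode["value"])
                    except (KeyError, TypeError, ValueError):
                        raise SchemaError("measure value must be a number",
                                          f"{ppath}.measure.value") from None
                    measure = m.Measure(
                        value=value,
                        unit=_require_str(mnode.get("unit", ""),
                                          f"{ppath}.measure.unit"),
                    )
                step.participants.append(m.Participant(
                    name=_require_str(pt.get("name", ""), f"{ppath}.name"),
                    measure=measure,
                ))
            for q, al in enumerate(_require_list(s.get("alerts", []) or [],
                                                 f"{spath}.alerts")):
                apath = f"{spath}.alerts[{q}]"
                al = _require_map(al, apath)
                _check_keys(al, _ALERT_KEYS, apath)
                step.alerts.append(m.AlertMessage(
                    kind=_require_str(al.get("kind", ""), f"{apath}.kind"),
                    text=_require_str(al.get("text", ""), f"{apath}.text"),
                ))
            proc.subprocedures.append(step)
        workflow.procedures.append(proc)

    return m.Protocol(id=pid, document=doc, workflow=workflow,
                      visibility=visibility)


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------

def _prune(d: dict) -> dict:
    return {k: v for k, v in d.items()
            if v is not None and v != [] and v != {} and v != ""}


def _flow_out(item: m.FlowItem):
    if item.external_ref is None:
        return item.name
    return {"name": item.name, "external_ref": item.external_ref}


def _derives_out(d: m.DerivedMaterial | None):
    if d is None:
        return None
    return {"organism": d.derives_from_organism, "role": d.role}


def protocol_to_mapping(protocol: m.Protocol) -> dict:
    """The canonical plain-dict form of a protocol (stable key order,
    empty optionals omitted)."""
    doc = protocol.document
    doc_map = _prune({
        "title": doc.title,
        "authors": [_prune({"name": a.name, "identifier": a.identifier,
                            "roles": list(a.roles)}) for a in doc.authors],
        "protocol_identifier": doc.protocol_identifier,
        "application": doc.application,
        "provenance": doc.provenance_statement,
        "objective": doc.purpose_objective,
        "version": doc.version,
        "advantages": list(doc.advantages),
        "limitations": list(doc.limitations),
        "specimens": [_prune({
            "name": s.name, "organism": s.organism,
            "organism_ref": s.organism_ref,
            "anatomical_part": s.anatomical_part,
            "attributes": dict(s.attributes),
            "derives_from": _derives_out(s.derived),
        }) for s in doc.specimens],
        "reagents": [_prune({
            "name": r.name, "manufacturer": r.manufacturer,
            "catalog_number": r.catalog_number,
            "external_ref": r.external_ref,
            "derives_from": _derives_out(r.derived),
        }) for r in doc.reagents],
        "kits": [_prune({"name": k.name, "manufacturer": k.manufacturer,
                         "catalog_number": k.catalog_number})
                 for k in doc.kits],
        "equipment": [_prune({"name": e.name, "category": e.category,
                              "manufacturer": e.manufacturer,
                              "catalog_number": e.catalog_number})
                      for e in doc.equipment],
        "recipes": [{"name": r.name, "text": r.body_text} for r in doc.recipes],
    })
    procedures = []
    for p in protocol.workflow.procedures:
        steps = []
        for s in p.subprocedures:
            steps.append(_prune({
                "id": s.id,
                "text": s.text,
                "preceded_by": s.preceded_by,
                "participants": [
                    pt.name if pt.measure is None else
                    {"name": pt.name,
                     "measure": {"value": pt.measure.value,
                                 "unit": pt.measure.unit}}
                    for pt in s.participants
                ],
                "alerts": [{"kind": a.kind, "text": a.text} for a in s.alerts],
            }))
        procedures.append(_prune({
            "id": p.id,
            "label": p.label,
            "kind": p.kind if p.kind != "procedure" else None,
            "preceded_by": p.preceded_by,
            "inputs": [_flow_out(x) for x in p.inputs],
            "outputs": [_flow_out(x) for x in p.outputs],
            "steps": steps,
        }))
    return _prune({
        "id": protocol.id,
        "visibility": protocol.visibility if protocol.visibility != "public" else None,
        "document": doc_map,
        "workflow": {"procedures": procedures},
    })


def write_protocol_doc(protocol: m.Protocol) -> str:
    """Serialize a protocol to the interchange format.

    Output is deterministic (byte-identical for equal protocols) and is
    guaranteed to parse back.  Raises :class:`InvalidProtocolError` if the
    protocol has structural validation errors.
    """
    report = m.validate_structure(protocol)
    if not report.is_valid():
        details = "; ".join(f"{i.code}: {i.message}" for i in report.errors)
        raise InvalidProtocolError(f"protocol has structural errors: {details}")
    return yaml.safe_dump(
        protocol_to_mapping(protocol),
        sort_keys=False,
        allow_unicode=True,
        default_flow_style=False,
        width=100,
    )


# ---------------------------------------------------------------------------
# Running example
# ---------------------------------------------------------------------------

def running_example() -> m.Protocol:
    """The built-in fixture: *Extraction of total RNA from fresh/frozen
    tissue (FT)*, a three-procedure TRIzol RNA-extraction protocol.

    Procedure 3's steps 5-20 are not printed in the source protocol's public
    summary; they are counts-faithful numbered placeholders, not real text
    (see the methods note).
    """
    text = (importlib.resources.files("smartprotocols")
            / "data" / "running_example.spd.yaml").read_text(encoding="utf-8")
    return parse_protocol_doc(text)


# ---------------------------------------------------------------------------
# Synthetic-protocol generator
# ---------------------------------------------------------------------------

SPECIMEN_POOL: list[tuple[str, str | None, str | None]] = [
    # (name, organism, anatomical part)
    ("leaf tissue", "Arabidopsis thaliana", "leaf"),
    ("root tissue", "Oryza sativa", "stem"),
    ("liver tissue", "Mus musculus", "organs"),
    ("blood serum", "Mus musculus", None),
    ("tumor tissue", None, "tissues"),
    ("mango peel", "Mangifera indica", None),
]

REAGENT_POOL: list[tuple[str, str | None]] = [
    ("TRIzol", "Invitrogen"),
    ("Chloroform", "Sigma-Aldrich"),
    ("Ethanol", "Sigma-Aldrich"),
    ("Isopropyl alcohol", "Sigma-Aldrich"),
    ("Glucose", "Sigma-Aldrich"),
    ("Glycerol", "Merck"),
    ("Acetic acid", "Merck"),
    ("Bromophenol blue", "Sigma-Aldrich"),
    ("Sodium chloride", "Merck"),
    ("70% ethanol", None),
]

EQUIPMENT_POOL: list[tuple[str, str]] = [
    ("Forceps", "instrument"),
    ("Mortar and pestle", "instrument"),
    ("Beaker", "glassware"),
    ("Graduated cylinder", "glassware"),
    ("Centrifuge", "standard_equipment"),
    ("Incubator", "standard_equipment"),
    ("Microplate reader", "high_throughput"),
    ("Pipette tips", "consumable"),
]

KIT_POOL: list[tuple[str, str]] = [
    ("RNeasy Mini Kit", "Qiagen"),
    ("DNeasy Plant Kit", "Qiagen"),
    ("GeneJET PCR Purification Kit", "Thermo Fisher"),
]

ALERT_TEXTS = {
    "caution": "synthetic caution: handle this reagent in a fume hood.",
    "hint": "synthetic hint: pre-chill the rotor for better yield.",
    "pause_point": "synthetic pause point: the lysate can be stored overnight.",
    "troubleshooting": "synthetic troubleshooting: if the pellet is loose, respin.",
    "generic_alert": "synthetic alert: note the batch number before use.",
}


@dataclass
class SynthConfig:
    """Configuration for the synthetic-protocol generator.

    Defaults mirror the running example's shape: three procedures of a few
    steps each, sparse alerts, and a coin-flip chance that consecutive
    procedures pass an intermediate material from one to the next.
    """

    n_procedures: int = 3
    steps_min: int = 3
    steps_max: int = 6
    p_alert: float = 0.2
    p_chain: float = 0.5
    material_pool_sizes: dict[str, int] = field(default_factory=lambda: {
        "specimen": 1, "reagent": 4, "equipment": 3, "kit": 1,
    })
    seed: int = 0
    visibility: str = "public"

    def validate(self) -> None:
        if self.n_procedures < 1:
            raise ConfigError("n_procedures must be >= 1")
        if self.steps_min < 1 or self.steps_max < self.steps_min:
            raise ConfigError("steps range must be non-empty and >= 1")
        for p in (self.p_alert, self.p_chain):
            if not 0.0 <= p <= 1.0:
                raise ConfigError("probabilities must lie in [0, 1]")
        for cat, size in self.material_pool_sizes.items():
            if cat not in ("specimen", "reagent", "equipment", "kit"):
                raise ConfigError(f"unknown material category {cat!r}")
            if size < 0:
                raise ConfigError("pool sizes must be >= 0")
        if self.visibility not in m.VISIBILITIES:
            raise ConfigError(f"visibility must be one of {m.VISIBILITIES}")


def synthesize_protocol(config: SynthConfig) -> m.Protocol:
    """Generate a structurally valid, canonical protocol from ``config``.

    Deterministic for a fixed seed.  Materials are drawn from fixed named
    pools per category; when consecutive procedures are IO-chained the
    producer's output name exactly matches the consumer's input name.
    """
    config.validate()
    rng = random.Random(config.seed)
    sizes = {"specimen": 1, "reagent": 4, "equipment": 3, "kit": 1}
    sizes.update(config.material_pool_sizes)

    specimens = [
        m.Specimen(name=n, organism=org, anatomical_part=part)
        for n, org, part in sorted(
            rng.sample(SPECIMEN_POOL, min(sizes["specimen"], len(SPECIMEN_POOL))))
    ]
    reagents = [
        m.Reagent(name=n, manufacturer=mf,
                  catalog_number=f"cat-{rng.randrange(1000, 9999)}"
                  if mf is not None else None)
        for n, mf in sorted(
            rng.sample(REAGENT_POOL, min(sizes["reagent"], len(REAGENT_POOL))))
    ]
    equipment = [
        m.Equipment(name=n, category=cat)
        for n, cat in sorted(
            rng.sample(EQUIPMENT_POOL, min(sizes["equipment"], len(EQUIPMENT_POOL))))
    ]
    kits = [
        m.Kit(name=n, manufacturer=mf)
        for n, mf in sorted(
            rng.sample(KIT_POOL, min(sizes["kit"], len(KIT_POOL))))
    ]

    doc = m.DocumentMetadata(
        title=f"Synthetic protocol {config.seed}",
        authors=[m.Author(name="Synthetic Author A", roles=["chief_scientist"]),
                 m.Author(name="Synthetic Author B", roles=["lab_scientist"])],
        protocol_identifier=f"synth:{config.seed}",
        purpose_objective=(
            "Synthetic objective: extraction of nucleic acids from "
            f"{specimens[0].name if specimens else 'a sample'} "
            "for downstream analysis."),
        version="1.0",
        specimens=specimens,
        reagents=reagents,
        kits=kits,
        equipment=equipment,
    )

    workflow = m.Workflow()
    prev_output: str | None = None
    for i in range(1, config.n_procedures + 1):
        proc = m.LabProcedure(
            id=f"proc-{i}",
            label=f"Synthetic procedure {i}",
            preceded_by=f"proc-{i - 1}" if i > 1 else None,
        )
        if i == 1 and specimens:
            proc.inputs.append(m.FlowItem(name=specimens[0].name))
        if prev_output is not None:
            proc.inputs.append(m.FlowItem(name=prev_output))
            prev_output = None
        n_steps = rng.randint(config.steps_min, config.steps_max)
        explicit_chain = rng.random() < 0.5
        for j in range(1, n_steps + 1):
            step = m.LabSubprocedure(
                id=f"step-{i}.{j}",
                text=(f"Synthetic step {i}.{j}: process the sample and "
                      "continue to the next instruction."),
                preceded_by=f"step-{i}.{j - 1}" if explicit_chain and j > 1 else None,
            )
            if reagents and rng.random() < 0.6:
                reagent = rng.choice(reagents)
                step.participants.append(m.Participant(
                    name=reagent.name,
                    measure=m.Measure(value=round(rng.uniform(0.1, 5.0), 1),
                                      unit="mL"),
                ))
            if equipment and rng.random() < 0.4:
                step.participants.append(
                    m.Participant(name=rng.choice(equipment).name))
            step.participants.sort(key=lambda q: m.normalize_name(q.name))
            if rng.random() < config.p_alert:
                kind = rng.choice(m.ALERT_KINDS)
                step.alerts.append(m.AlertMessage(kind=kind,
                                                  text=ALERT_TEXTS[kind]))
            proc.subprocedures.append(step)
        if i < config.n_procedures and rng.random() < config.p_chain:
            prev_output = f"intermediate fraction {i}"
            proc.outputs.append(m.FlowItem(name=prev_output))
        if i == config.n_procedures:
            proc.outputs.append(m.FlowItem(name="purified nucleic acid"))
        proc.inputs.sort(key=lambda it: m.normalize_name(it.name))
        proc.outputs.sort(key=lambda it: m.normalize_name(it.name))
        workflow.procedures.append(proc)

    return m.Protocol(
        id=f"synth-{config.seed}",
        document=doc,
        workflow=workflow,
        visibility=config.visibility,
    )


__all__ = [
    "SynthConfig", "parse_protocol_doc", "protocol_to_mapping",
    "running_example", "synthesize_protocol", "write_protocol_doc",
    "SPECIMEN_POOL", "REAGENT_POOL", "EQUIPMENT_POOL", "KIT_POOL",
]
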