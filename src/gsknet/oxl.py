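"""Lossless XML exchange format and node-link JSON export.

The XML dialect ("OXL-style") carries the full meta-model plus every
concept and relation with typed attribute values, so that
``read_oxl(write_oxl(g))`` reproduces the graph exactly (same ids, same
content).  Element order is deterministic (concepts and relations by id,
set-valued fields sorted), so exports of equal graphs are byte-identical.

The JSON export is a plain node-link document ("nodes"/"edges" arrays)
for generic graph viewers; it is lossy by design (no attributes beyond
class, preferred name and relation type).
"""

from __future__ import annotations

import json
import re
from typing import Union

from lxml import etree

from .errors import ExportError, MetaModelError, ParseError
from .graph import Accession, Concept, GenomicLocation, KnowledgeGraph, Relation
from .metamodel import MetaModel

FORMAT_VERSION = "1.0"

_INT = re.compile(r"^-?\d+$")


def _num(text: str) -> Union[int, float]:
    return int(text) if _INT.match(text) else float(text)


def _value_to_xml(parent, tag: str, name: str, value: object,
                  kind: str) -> None:
    el = etree.SubElement(parent, tag, name=name, kind=kind)
    if kind == "location":
        if not isinstance(value, GenomicLocation):
            raise ExportError(
                f"attribute {name!r}: location kind requires a GenomicLocation,"
                f" got {type(value).__name__}"
            )
        el.set("chromosome", value.chromosome)
        el.set("begin", repr(value.begin))
        el.set("end", repr(value.end))
        el.set("unit", value.unit)
        if value.taxid is not None:
            el.set("taxid", value.taxid)
    elif kind in ("text", "sequence"):
        el.text = str(value)
    elif kind == "integer":
        el.text = str(int(value))
    elif kind == "decimal":
        el.text = repr(value)
    else:
        raise ExportError(f"attribute {name!r}: unserialisable kind {kind!r}")


def _value_from_xml(el) -> tuple[str, object]:
    name = el.get("name")
    kind = el.get("kind")
    if kind == "location":
        return name, GenomicLocation(
            el.get("chromosome"), _num(el.get("begin")), _num(el.get("end")),
            el.get("unit"), el.get("taxid"),
        )
    text = el.text or ""
    if kind == "integer":
        return name, int(text)
    if kind == "decimal":
        return name, _num(text)
    return name, text


def _attr_kind(meta: MetaModel, name: str) -> str:
    try:
        return meta.attribute_names[name].kind
    except KeyError:
        raise ExportError(f"attribute {name!r} not declared in the meta-model")


def _meta_to_xml(meta: MetaModel) -> etree._Element:
    root = etree.Element("metamodel")
    ccs = etree.SubElement(root, "conceptClasses")
    for c in sorted(meta.concept_classes.values(), key=lambda c: c.id):
        el = etree.SubElement(ccs, "conceptClass", id=c.id, label=c.label)
        if c.parent:
            el.set("parent", c.parent)
    rts = etree.SubElement(root, "relationTypes")
    for r in sorted(meta.relation_types.values(), key=lambda r: r.id):
        el = etree.SubElement(rts, "relationType", id=r.id, label=r.label)
        if r.parent:
            el.set("parent", r.parent)
        if r.symmetric:
            el.set("symmetric", "true")
    dss = etree.SubElement(root, "dataSources")
    for d in sorted(meta.data_sources.values(), key=lambda d: d.id):
        etree.SubElement(dss, "dataSource", id=d.id, label=d.label)
    ans = etree.SubElement(root, "attributeNames")
    for a in sorted(meta.attribute_names.values(), key=lambda a: a.id):
        etree.SubElement(ans, "attributeName", id=a.id, kind=a.kind)
    evs = etree.SubElement(root, "evidenceTypes")
    for e in sorted(meta.evidence_types.values(), key=lambda e: e.id):
        etree.SubElement(evs, "evidenceType", id=e.id, label=e.label)
    return root


def _meta_from_xml(root) -> MetaModel:
    meta = MetaModel()
    for el in root.findall("conceptClasses/conceptClass"):
        meta.add_concept_class(el.get("id"), el.get("label"), el.get("parent"))
    for el in root.findall("relationTypes/relationType"):
        meta.add_relation_type(el.get("id"), el.get("label"), el.get("parent"),
                               el.get("symmetric") == "true")
    for el in root.findall("dataSources/dataSource"):
        meta.add_data_source(el.get("id"), el.get("label"))
    for el in root.findall("attributeNames/attributeName"):
        meta.add_attribute_name(el.get("id"), el.get("kind"))
    for el in root.findall("evidenceTypes/evidenceType"):
        meta.add_evidence_type(el.get("id"), el.get("label"))
    meta.validate()
    return meta


def write_oxl(g: KnowledgeGraph, destination) -> None:
    """Serialise the graph as the package's XML exchange dialect.

    ``destination`` is a path or a binary file object.  Output is
    deterministic for equal graphs.
    """
    root = etree.Element("oxl", version=FORMAT_VERSION)
    root.append(_meta_to_xml(g.meta))
    concepts = etree.SubElement(root, "concepts")
    for cid in sorted(g.concepts):
        c = g.concepts[cid]
        el = etree.SubElement(concepts, "concept", id=str(cid),
                              **{"class": c.concept_class})
        for acc in sorted(c.accessions,
                          key=lambda a: (a.namespace, a.value, a.ambiguous)):
            a = etree.SubElement(el, "accession", namespace=acc.namespace,
                                 value=acc.value)
            if acc.ambiguous:
                a.set("ambiguous", "true")
        for name in sorted(c.names):
            n = etree.SubElement(el, "name")
            n.text = name
            if c.names[name]:
                n.set("preferred", "true")
        for key in sorted(c.attributes):
            _value_to_xml(el, "attribute", key, c.attributes[key],
                          _attr_kind(g.meta, key))
        for key, old in c.audit:
            _value_to_xml(el, "overwritten", key, old, _attr_kind(g.meta, key))
        for src in sorted(c.provenance):
            etree.SubElement(el, "provenance", source=src)
        for ev in sorted(c.evidence):
            etree.SubElement(el, "evidence", type=ev)
    relations = etree.SubElement(root, "relations")
    for rid in sorted(g.relations):
        r = g.relations[rid]
        el = etree.SubElement(relations, "relation", id=str(rid),
                              **{"from": str(r.source), "to": str(r.target),
                                 "type": r.relation_type})
        for key in sorted(r.attributes):
            _value_to_xml(el, "attribute", key, r.attributes[key],
                          _attr_kind(g.meta, key))
        for src in sorted(r.provenance):
            etree.SubElement(el, "provenance", source=src)
        for ev in sorted(r.evidence):
            etree.SubElement(el, "evidence", type=ev)
    data = etree.tostring(root, pretty_print=True, xml_declaration=True,
                          encoding="UTF-8")
    if hasattr(destination, "write"):
        destination.write(data)
    else:
        with open(destination, "wb") as fh:
            fh.write(data)


def read_oxl(source) -> KnowledgeGraph:
    """Parse an exchange document back into a knowledge graph.

    Raises :class:`ParseError` on malformed XML (with line context) and
    :class:`MetaModelError` when elements reference vocabulary entries
    not declared in the document's meta-model section.
    """
    try:
        tree = etree.parse(source)
    except (etree.XMLSyntaxError, OSError) as exc:
        raise ParseError(f"not a readable exchange document: {exc}") from exc
    root = tree.getroot()
    if root.tag != "oxl":
        raise ParseError(f"unexpected root element {root.tag!r}")
    meta_el = root.find("metamodel")
    if meta_el is None:
        raise ParseError("missing metamodel section")
    meta = _meta_from_xml(meta_el)
    g = KnowledgeGraph(meta)
    for el in root.findall("concepts/concept"):
        cid = int(el.get("id"))
        cls = el.get("class")
        if cls not in meta.concept_classes:
            raise MetaModelError(
                f"concept {cid}: undeclared concept class {cls!r}"
            )
        c = Concept(cid, cls)
        for a in el.findall("accession"):
            acc = Accession(a.get("namespace"), a.get("value"),
                            a.get("ambiguous") == "true")
            c.accessions.add(acc)
            g.accession_index.setdefault(acc.key, set()).add(cid)
        for n in el.findall("name"):
            c.names[n.text] = n.get("preferred") == "true"
            g.name_index.setdefault(n.text.lower(), set()).add(cid)
        for a in el.findall("attribute"):
            key, value = _value_from_xml(a)
            if key not in meta.attribute_names:
                raise MetaModelError(f"concept {cid}: undeclared attribute {key!r}")
            c.attributes[key] = value
        for a in el.findall("overwritten"):
            key, value = _value_from_xml(a)
            c.audit.append((key, value))
        for p in el.findall("provenance"):
            c.provenance.add(p.get("source"))
        for e in el.findall("evidence"):
            c.evidence.add(e.get("type"))
        g.concepts[cid] = c
        g._incident[cid] = set()
        g._next_concept_id = max(g._next_concept_id, cid + 1)
    for el in root.findall("relations/relation"):
        rid = int(el.get("id"))
        rtype = el.get("type")
        if rtype not in meta.relation_types:
            raise MetaModelError(
                f"relation {rid}: undeclared relation type {rtype!r}"
            )
        src, dst = int(el.get("from")), int(el.get("to"))
        for endpoint in (src, dst):
            if endpoint not in g.concepts:
                raise ParseError(f"relation {rid}: dangling endpoint {endpoint}")
        r = Relation(rid, src, dst, rtype)
        for a in el.findall("attribute"):
            key, value = _value_from_xml(a)
            r.attributes[key] = value
        for p in el.findall("provenance"):
            r.provenance.add(p.get("source"))
        for e in el.findall("evidence"):
            r.evidence.add(e.get("type"))
        g.relations[rid] = r
        g._relation_key[g._canonical_key(src, dst, rtype)] = rid
        g._incident[src].add(rid)
        g._incident[dst].add(rid)
        g._next_relation_id = max(g._next_relation_id, rid + 1)
    return g


def to_node_link(g: KnowledgeGraph) -> dict:
    """Node-link dict: nodes carry id/class/preferred name, edges carry
    endpoints and relation type."""
    return {
        "nodes": [
            {
                "id": cid,
                "class": g.concepts[cid].concept_class,
                "name": g.concepts[cid].preferred_name,
            }
            for cid in sorted(g.concepts)
        ],
        "edges": [
            {
                "id": rid,
                "source": g.relations[rid].source,
                "target": g.relations[rid].target,
                "type": g.relations[rid].relation_type,
            }
            for rid in sorted(g.relations)
        ],
    }


def write_json(g: KnowledgeGraph, destination) -> None:
    """Write the node-link JSON export for generic graph viewers."""
    doc = json.dumps(to_node_link(g), indent=2, sort_keys=True)
    if hasattr(destination, "write"):
        destination.write(doc)
    else:
        with open(destination, "wt", encoding="utf-8") as fh:
            fh.write(doc)
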