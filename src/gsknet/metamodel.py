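"""Controlled vocabulary (meta-model) for typed knowledge graphs.

Every concept and relation in a :class:`~gsknet.graph.KnowledgeGraph` is
typed against a :class:`MetaModel`: a set of concept classes, relation
types, data sources, attribute names and evidence types.  Concept classes
and relation types may form ``is-a`` hierarchies (single parent, acyclic).
A default vocabulary covering the standard crop/reference network schema
ships with the package and is loaded by :meth:`MetaModel.default`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Optional

import yaml

from .errors import MetaModelError

#: Allowed value kinds for attribute names.
VALUE_KINDS = frozenset({"text", "integer", "decimal", "location", "sequence"})


@dataclass(frozen=True)
class ConceptClass:
    id: str
    label: str
    parent: Optional[str] = None


@dataclass(frozen=True)
class RelationType:
    id: str
    label: str
    parent: Optional[str] = None
    symmetric: bool = False


@dataclass(frozen=True)
class DataSource:
    id: str
    label: str


@dataclass(frozen=True)
class AttributeName:
    id: str
    kind: str


@dataclass(frozen=True)
class EvidenceType:
    id: str
    label: str


@dataclass
class MetaModel:
    """The controlled vocabulary a knowledge graph is typed against."""

    concept_classes: dict[str, ConceptClass] = field(default_factory=dict)
    relation_types: dict[str, RelationType] = field(default_factory=dict)
    data_sources: dict[str, DataSource] = field(default_factory=dict)
    attribute_names: dict[str, AttributeName] = field(default_factory=dict)
    evidence_types: dict[str, EvidenceType] = field(default_factory=dict)

    # -- construction -----------------------------------------------------

    @classmethod
    def default(cls) -> "MetaModel":
        """The packaged default vocabulary."""
        text = (
            resources.files("gsknet").joinpath("data/metamodel.yaml").read_text()
        )
        return cls.from_yaml(text)

    @classmethod
    def from_yaml(cls, text: str) -> "MetaModel":
        doc = yaml.safe_load(text) or {}
        meta = cls()
        for entry in doc.get("concept_classes", []):
            meta.add_concept_class(
                entry["id"], entry.get("label", entry["id"]), entry.get("parent")
            )
        for entry in doc.get("relation_types", []):
            meta.add_relation_type(
                entry["id"],
                entry.get("label", entry["id"]),
                entry.get("parent"),
                bool(entry.get("symmetric", False)),
            )
        for entry in doc.get("data_sources", []):
            meta.add_data_source(entry["id"], entry.get("label", entry["id"]))
        for entry in doc.get("attribute_names", []):
            meta.add_attribute_name(entry["id"], entry["kind"])
        for entry in doc.get("evidence_types", []):
            meta.add_evidence_type(entry["id"], entry.get("label", entry["id"]))
        meta.validate()
        return meta

    def to_yaml(self) -> str:
        doc = {
            "concept_classes": [
                {"id": c.id, "label": c.label, **({"parent": c.parent} if c.parent else {})}
                for c in self.concept_classes.values()
            ],
            "relation_types": [
                {
                    "id": r.id,
                    "label": r.label,
                    **({"parent": r.parent} if r.parent else {}),
                    **({"symmetric": True} if r.symmetric else {}),
                }
                for r in self.relation_types.values()
            ],
            "data_sources": [
                {"id": d.id, "label": d.label} for d in self.data_sources.values()
            ],
            "attribute_names": [
                {"id": a.id, "kind": a.kind} for a in self.attribute_names.values()
            ],
            "evidence_types": [
                {"id": e.id, "label": e.label} for e in self.evidence_types.values()
            ],
        }
        return yaml.safe_dump(doc, sort_keys=False)

    # -- mutation ---------------------------------------------------------

    def add_concept_class(self, id: str, label: str, parent: str | None = None) -> None:
        if id in self.concept_classes:
            raise MetaModelError(f"duplicate concept class id {id!r}")
        self.concept_classes[id] = ConceptClass(id, label, parent)

    def add_relation_type(
        self, id: str, label: str, parent: str | None = None, symmetric: bool = False
    ) -> None:
        if id in self.relation_types:
            raise MetaModelError(f"duplicate relation type id {id!r}")
        self.relation_types[id] = RelationType(id, label, parent, symmetric)

    def add_data_source(self, id: str, label: str | None = None) -> None:
        if id in self.data_sources:
            raise MetaModelError(f"duplicate data source id {id!r}")
        self.data_sources[id] = DataSource(id, label or id)

    def add_attribute_name(self, id: str, kind: str) -> None:
        if id in self.attribute_names:
            raise MetaModelError(f"duplicate attribute name id {id!r}")
        if kind not in VALUE_KINDS:
            raise MetaModelError(
                f"attribute {id!r}: unknown value kind {kind!r} "
                f"(expected one of {sorted(VALUE_KINDS)})"
            )
        self.attribute_names[id] = AttributeName(id, kind)

    def add_evidence_type(self, id: str, label: str | None = None) -> None:
        if id in self.evidence_types:
            raise MetaModelError(f"duplicate evidence type id {id!r}")
        self.evidence_types[id] = EvidenceType(id, label or id)

    def ensure_data_source(self, id: str, label: str | None = None) -> str:
        """Register *id* as a data source if not already known; return it."""
        if id not in self.data_sources:
            self.data_sources[id] = DataSource(id, label or id)
        return id

    def ensure_evidence(self, id: str, label: str | None = None) -> str:
        """Register *id* as an evidence type if not already known (used for
        GAF evidence codes outside the default vocabulary)."""
        if id not in self.evidence_types:
            self.evidence_types[id] = EvidenceType(id, label or id)
        return id

    # -- validation -------------------------------------------------------

    def validate(self) -> None:
        """Check referential integrity and hierarchy acyclicity.

        Raises :class:`MetaModelError` listing every offending entry.
        """
        problems: list[str] = []
        for cc in self.concept_classes.values():
            if cc.parent is not None and cc.parent not in self.concept_classes:
                problems.append(
                    f"concept class {cc.id!r}: unknown parent {cc.parent!r}"
                )
        for rt in self.relation_types.values():
            if rt.parent is not None and rt.parent not in self.relation_types:
                problems.append(
                    f"relation type {rt.id!r}: unknown parent {rt.parent!r}"
                )
        problems += self._cycles("concept class", self.concept_classes)
        problems += self._cycles("relation type", self.relation_types)
        if problems:
            raise MetaModelError("; ".join(problems))

    @staticmethod
    def _cycles(kind: str, entries) -> list[str]:
        problems = []
        for start in entries:
            seen = {start}
            cur = entries[start].parent
            while cur is not None and cur in entries:
                if cur in seen:
                    problems.append(f"{kind} hierarchy cycle involving {start!r}")
                    break
                seen.add(cur)
                cur = entries[cur].parent
        return problems

    # -- queries ----------------------------------------------------------

    def is_symmetric(self, relation_type: str) -> bool:
        return self.relation_types[relation_type].symmetric

    def ancestors(self, concept_class: str) -> list[str]:
        """Concept-class ancestry from *concept_class* up to the root."""
        out = []
        cur = self.concept_classes[concept_class].parent
        while cur is not None:
            out.append(cur)
            cur = self.concept_classes[cur].parent
        return out
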