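"""Typed labelled directed multigraph of concepts and relations.

The in-memory data model: concepts (nodes) and relations (edges) are both
typed against a :class:`~gsknet.metamodel.MetaModel`, carry free-form
attributes, and record their provenance (contributing data sources) and
evidence.  Two behaviours distinguish this container from a plain graph
library:

* **upsert merging** — adding a concept whose non-ambiguous accession is
  already held by a concept of the same class enriches that concept
  instead of creating a duplicate (entity resolution within one parsed
  dataset);
* **relation deduplication** — a second relation with the same
  (source, target, type) triple merges into the first; symmetric types
  (``equal``, ``ortholog``, ...) treat (a, b) and (b, a) as the same edge.

Parallel edges between the same pair of concepts are allowed as long as
their relation types differ.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Optional, Sequence, Union

from .errors import GraphError, MetaModelError
from .metamodel import MetaModel

#: Map units accepted for genomic locations.
MAP_UNITS = frozenset({"bp", "cM"})


@dataclass(frozen=True)
class Accession:
    """A namespaced identifier; the merge key of entity resolution.

    ``ambiguous`` accessions are carried as annotation but never drive
    merging (neither at upsert time nor in accession-based mapping).
    """

    namespace: str
    value: str
    ambiguous: bool = False

    def __post_init__(self):
        if not self.value:
            raise ValueError("accession value must be non-empty")

    @property
    def key(self) -> tuple[str, str]:
        return (self.namespace, self.value)


@dataclass(frozen=True)
class GenomicLocation:
    """Chromosome interval on a physical (bp) or genetic (cM) map.

    Coordinates are 1-based with inclusive ends (GFF3 convention); a
    point position has ``begin == end``.  Locations are only comparable
    when chromosome, unit and taxid all agree.
    """

    chromosome: str
    begin: float
    end: float
    unit: str = "bp"
    taxid: Optional[str] = None

    def __post_init__(self):
        if self.end < self.begin:
            raise ValueError(
                f"location end {self.end} precedes begin {self.begin}"
            )

    def comparable(self, other: "GenomicLocation") -> bool:
        """True when both locations live on the same map."""
        return (
            self.chromosome == other.chromosome
            and self.unit == other.unit
            and self.taxid == other.taxid
        )

    def overlaps(self, other: "GenomicLocation") -> bool:
        """Closed-interval intersection on the same map."""
        return self.comparable(other) and not (
            self.end < other.begin or other.end < self.begin
        )


@dataclass
class Concept:
    id: int
    concept_class: str
    accessions: set[Accession] = field(default_factory=set)
    #: name -> preferred flag; at most one name is preferred
    names: dict[str, bool] = field(default_factory=dict)
    attributes: dict[str, object] = field(default_factory=dict)
    provenance: set[str] = field(default_factory=set)
    evidence: set[str] = field(default_factory=set)
    #: overwritten attribute values retained for auditability:
    #: (attribute name, superseded value)
    audit: list[tuple[str, object]] = field(default_factory=list)

    @property
    def preferred_name(self) -> Optional[str]:
        for name, pref in self.names.items():
            if pref:
                return name
        return next(iter(sorted(self.names)), None)

    def signature(self) -> tuple:
        """Identity-free content fingerprint (for isomorphism checks)."""
        return (
            self.concept_class,
            frozenset(self.accessions),
            frozenset(self.names.items()),
            frozenset((k, _hashable(v)) for k, v in self.attributes.items()),
            frozenset(self.provenance),
            frozenset(self.evidence),
        )


def _hashable(value: object) -> object:
    if isinstance(value, list):
        return tuple(value)
    return value


@dataclass
class Relation:
    id: int
    source: int
    target: int
    relation_type: str
    attributes: dict[str, object] = field(default_factory=dict)
    provenance: set[str] = field(default_factory=set)
    evidence: set[str] = field(default_factory=set)


@dataclass
class Metagraph:
    """Schema-level summary: instance counts per concept class and per
    (source class, relation type, target class) triple."""

    nodes: dict[str, int] = field(default_factory=dict)
    edges: dict[tuple[str, str, str], int] = field(default_factory=dict)

    @property
    def total_concepts(self) -> int:
        return sum(self.nodes.values())

    @property
    def total_relations(self) -> int:
        return sum(self.edges.values())


AccessionLike = Union[Accession, tuple]
NameLike = Union[str, tuple]


def _as_accession(acc: AccessionLike) -> Accession:
    if isinstance(acc, Accession):
        return acc
    return Accession(*acc)


def _as_name(name: NameLike) -> tuple[str, bool]:
    if isinstance(name, str):
        return name, False
    n, pref = name
    return n, bool(pref)


class KnowledgeGraph:
    """Typed labelled directed multigraph bound to a meta-model."""

    def __init__(self, meta: Optional[MetaModel] = None):
        if meta is None:
            meta = MetaModel.default()
        meta.validate()
        self.meta = meta
        self.concepts: dict[int, Concept] = {}
        self.relations: dict[int, Relation] = {}
        self._next_concept_id = 1
        self._next_relation_id = 1
        # (namespace, value) -> set of concept ids holding that accession
        self.accession_index: dict[tuple[str, str], set[int]] = {}
        # lowercased name -> set of concept ids
        self.name_index: dict[str, set[int]] = {}
        # canonical (source, target, type) -> relation id
        self._relation_key: dict[tuple[int, int, str], int] = {}
        # concept id -> incident relation ids
        self._incident: dict[int, set[int]] = {}

    # -- basic queries ----------------------------------------------------

    def __len__(self) -> int:
        return len(self.concepts)

    @property
    def num_relations(self) -> int:
        return len(self.relations)

    def concepts_of_class(self, concept_class: str) -> Iterator[Concept]:
        for c in self.concepts.values():
            if c.concept_class == concept_class:
                yield c

    def find_by_accession(
        self, value: str, namespace: Optional[str] = None
    ) -> list[Concept]:
        ids: set[int] = set()
        if namespace is not None:
            ids = set(self.accession_index.get((namespace, value), ()))
        else:
            for (ns, val), cids in self.accession_index.items():
                if val == value:
                    ids |= cids
        return [self.concepts[i] for i in sorted(ids)]

    def find_by_name(self, name: str) -> list[Concept]:
        ids = self.name_index.get(name.lower(), set())
        return [self.concepts[i] for i in sorted(ids)]

    def relations_of(self, concept_id: int) -> list[Relation]:
        return [self.relations[r] for r in sorted(self._incident.get(concept_id, ()))]

    # -- validation helpers ----------------------------------------------

    def _check_class(self, concept_class: str) -> None:
        if concept_class not in self.meta.concept_classes:
            raise MetaModelError(f"unknown concept class {concept_class!r}")

    def _check_attributes(self, attributes: Mapping[str, object]) -> None:
        for key in attributes:
            if key not in self.meta.attribute_names:
                raise MetaModelError(f"unknown attribute name {key!r}")

    def _check_source(self, source: str) -> None:
        if source not in self.meta.data_sources:
            raise MetaModelError(f"unknown data source {source!r}")

    def _check_evidence(self, evidence: Iterable[str]) -> None:
        for ev in evidence:
            if ev not in self.meta.evidence_types:
                raise MetaModelError(f"unknown evidence type {ev!r}")

    # -- concept upsert ---------------------------------------------------

    def upsert_concept(
        self,
        concept_class: str,
        accessions: Iterable[AccessionLike] = (),
        names: Iterable[NameLike] = (),
        attributes: Optional[Mapping[str, object]] = None,
        source: str = "INTEGRATOR",
        evidence: Iterable[str] = ("IMPD",),
        merge: bool = True,
    ) -> int:
        """Insert a concept, merging on shared non-ambiguous accessions.

        If any non-ambiguous accession is already held (non-ambiguously)
        by an existing concept of the same class, that concept is enriched
        — union of accessions, names, attributes, provenance and evidence
        — and its id returned.  When several existing concepts match, all
        are folded into the lowest-id one so that no two concepts of the
        same class ever share a non-ambiguous accession.  With
        ``merge=False`` a new concept is always created.
        """
        self._check_class(concept_class)
        attributes = dict(attributes or {})
        self._check_attributes(attributes)
        self._check_source(source)
        evidence = set(evidence)
        self._check_evidence(evidence)
        accs = {_as_accession(a) for a in accessions}
        named = [_as_name(n) for n in names]

        target: Optional[Concept] = None
        if merge:
            candidates: set[int] = set()
            for acc in accs:
                if acc.ambiguous:
                    continue
                for cid in self.accession_index.get(acc.key, ()):
                    other = self.concepts[cid]
                    if other.concept_class != concept_class:
                        continue
                    if Accession(acc.namespace, acc.value) in other.accessions:
                        candidates.add(cid)
            if candidates:
                rep = min(candidates)
                for cid in sorted(candidates - {rep}):
                    self._absorb(rep, cid)
                target = self.concepts[rep]

        if target is None:
            target = Concept(self._next_concept_id, concept_class)
            self._next_concept_id += 1
            self.concepts[target.id] = target
            self._incident[target.id] = set()

        self._enrich_concept(target, accs, named, attributes, {source}, evidence)
        return target.id

    def _enrich_concept(
        self,
        concept: Concept,
        accessions: set[Accession],
        names: Sequence[tuple[str, bool]],
        attributes: Mapping[str, object],
        provenance: set[str],
        evidence: set[str],
    ) -> None:
        for acc in accessions:
            concept.accessions.add(acc)
            self.accession_index.setdefault(acc.key, set()).add(concept.id)
        has_pref = any(concept.names.values())
        for name, pref in names:
            if pref and not has_pref:
                # demote any identical non-preferred entry
                concept.names[name] = True
                has_pref = True
            else:
                concept.names.setdefault(name, False)
            self.name_index.setdefault(name.lower(), set()).add(concept.id)
        for key, value in attributes.items():
            if key in concept.attributes and concept.attributes[key] != value:
                concept.audit.append((key, concept.attributes[key]))
            concept.attributes[key] = value
        concept.provenance |= provenance
        concept.evidence |= evidence

    def _absorb(self, rep_id: int, other_id: int) -> None:
        """Fold concept *other_id* into *rep_id*, rewiring relations."""
        rep = self.concepts[rep_id]
        other = self.concepts[other_id]
        # detach other's relations first
        moved = [self.relations[r] for r in sorted(self._incident[other_id])]
        for rel in moved:
            self._drop_relation(rel.id)
        # merge content
        self._enrich_concept(
            rep,
            set(other.accessions),
            sorted(other.names.items()),
            other.attributes,
            set(other.provenance),
            set(other.evidence),
        )
        rep.audit.extend(other.audit)
        # deindex and delete other
        for acc in other.accessions:
            ids = self.accession_index.get(acc.key)
            if ids is not None:
                ids.discard(other_id)
                if not ids:
                    del self.accession_index[acc.key]
        for name in other.names:
            ids = self.name_index.get(name.lower())
            if ids is not None:
                ids.discard(other_id)
                if not ids:
                    del self.name_index[name.lower()]
        del self.concepts[other_id]
        del self._incident[other_id]
        # re-attach relations at the representative
        for rel in moved:
            src = rep_id if rel.source == other_id else rel.source
            dst = rep_id if rel.target == other_id else rel.target
            self._put_relation(
                src, dst, rel.relation_type, rel.attributes,
                rel.provenance, rel.evidence, prefer_id=rel.id,
            )

    # -- relations --------------------------------------------------------

    def _canonical_key(self, source: int, target: int, rtype: str) -> tuple:
        if self.meta.is_symmetric(rtype) and target < source:
            return (target, source, rtype)
        return (source, target, rtype)

    def add_relation(
        self,
        source: int,
        target: int,
        relation_type: str,
        attributes: Optional[Mapping[str, object]] = None,
        data_source: str = "INTEGRATOR",
        evidence: Iterable[str] = ("IMPD",),
    ) -> int:
        """Add (or merge into) the relation (source, target, type).

        Duplicate triples merge attributes, provenance and evidence; for
        symmetric relation types the endpoint order is irrelevant.
        """
        if relation_type not in self.meta.relation_types:
            raise MetaModelError(f"unknown relation type {relation_type!r}")
        attributes = dict(attributes or {})
        self._check_attributes(attributes)
        self._check_source(data_source)
        evidence = set(evidence)
        self._check_evidence(evidence)
        for endpoint in (source, target):
            if endpoint not in self.concepts:
                raise GraphError(f"relation endpoint {endpoint} does not exist")
        return self._put_relation(
            source, target, relation_type, attributes, {data_source}, evidence
        )

    def _put_relation(
        self,
        source: int,
        target: int,
        rtype: str,
        attributes: Mapping[str, object],
        provenance: set[str],
        evidence: set[str],
        prefer_id: Optional[int] = None,
    ) -> int:
        key = self._canonical_key(source, target, rtype)
        rid = self._relation_key.get(key)
        if rid is not None:
            rel = self.relations[rid]
            for k, v in attributes.items():
                rel.attributes.setdefault(k, v)
            rel.provenance |= provenance
            rel.evidence |= evidence
            return rid
        rid = prefer_id if prefer_id is not None and prefer_id not in self.relations \
            else self._next_relation_id
        if rid >= self._next_relation_id:
            self._next_relation_id = rid + 1
        rel = Relation(rid, key[0], key[1], rtype, dict(attributes),
                       set(provenance), set(evidence))
        self.relations[rid] = rel
        self._relation_key[key] = rid
        self._incident[rel.source].add(rid)
        self._incident[rel.target].add(rid)
        return rid

    def _drop_relation(self, relation_id: int) -> None:
        rel = self.relations.pop(relation_id)
        key = self._canonical_key(rel.source, rel.target, rel.relation_type)
        self._relation_key.pop(key, None)
        self._incident[rel.source].discard(relation_id)
        self._incident[rel.target].discard(relation_id)

    # -- whole-graph operations ------------------------------------------

    def add_graph(self, other: "KnowledgeGraph") -> dict[int, int]:
        """Copy every concept and relation of *other* into this graph.

        No accession merging takes place — interconnecting independently
        parsed networks is the job of the mapping + collapsing operators.
        Returns the old-id -> new-id concept mapping.
        """
        # adopt vocabulary extensions registered by the other graph's parsers
        for cc in other.meta.concept_classes.values():
            if cc.id not in self.meta.concept_classes:
                self.meta.concept_classes[cc.id] = cc
        for rt in other.meta.relation_types.values():
            if rt.id not in self.meta.relation_types:
                self.meta.relation_types[rt.id] = rt
        for ds in other.meta.data_sources.values():
            if ds.id not in self.meta.data_sources:
                self.meta.data_sources[ds.id] = ds
        for an in other.meta.attribute_names.values():
            if an.id not in self.meta.attribute_names:
                self.meta.attribute_names[an.id] = an
        for ev in other.meta.evidence_types.values():
            if ev.id not in self.meta.evidence_types:
                self.meta.evidence_types[ev.id] = ev
        mapping: dict[int, int] = {}
        for cid in sorted(other.concepts):
            c = other.concepts[cid]
            new = Concept(self._next_concept_id, c.concept_class,
                          set(c.accessions), dict(c.names), dict(c.attributes),
                          set(c.provenance), set(c.evidence), list(c.audit))
            self._next_concept_id += 1
            self.concepts[new.id] = new
            self._incident[new.id] = set()
            for acc in new.accessions:
                self.accession_index.setdefault(acc.key, set()).add(new.id)
            for name in new.names:
                self.name_index.setdefault(name.lower(), set()).add(new.id)
            mapping[cid] = new.id
        for rid in sorted(other.relations):
            r = other.relations[rid]
            self._put_relation(
                mapping[r.source], mapping[r.target], r.relation_type,
                dict(r.attributes), set(r.provenance), set(r.evidence),
            )
        return mapping

    def metagraph(self) -> Metagraph:
        """Schema-level summary with instance counts; only classes and
        (class, type, class) triples with at least one instance appear."""
        nodes = Counter(c.concept_class for c in self.concepts.values())
        edges = Counter(
            (
                self.concepts[r.source].concept_class,
                r.relation_type,
                self.concepts[r.target].concept_class,
            )
            for r in self.relations.values()
        )
        return Metagraph(dict(nodes), dict(edges))

    # -- equality ---------------------------------------------------------

    def equal_content(self, other: "KnowledgeGraph") -> bool:
        """Id-wise structural equality (concepts, relations, attributes)."""
        if set(self.concepts) != set(other.concepts):
            return False
        for cid, c in self.concepts.items():
            o = other.concepts[cid]
            if (c.concept_class, c.accessions, c.names, c.attributes,
                    c.provenance, c.evidence) != (
                    o.concept_class, o.accessions, o.names, o.attributes,
                    o.provenance, o.evidence):
                return False
        if set(self.relations) != set(other.relations):
            return False
        for rid, r in self.relations.items():
            o = other.relations[rid]
            if (r.source, r.target, r.relation_type, r.attributes,
                    r.provenance, r.evidence) != (
                    o.source, o.target, o.relation_type, o.attributes,
                    o.provenance, o.evidence):
                return False
        return True


def new_graph(meta: Optional[MetaModel] = None) -> KnowledgeGraph:
    """Create an empty knowledge graph bound to *meta* (default vocabulary
    when omitted).  Raises :class:`MetaModelError` if *meta* is invalid."""
    return KnowledgeGraph(meta)


def concept_locations(concept: Concept) -> list[GenomicLocation]:
    """All genomic locations carried by a concept's attributes.

    A concept may hold several locations on different maps (e.g. a
    physical bp interval from the genome annotation plus a genetic cM
    position from a mapping population).
    """
    return [v for v in concept.attributes.values()
            if isinstance(v, GenomicLocation)]
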