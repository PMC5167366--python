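"""Knowledge mining over the integrated graph.

Three query primitives support candidate-gene discovery:

* :func:`neighborhood` — the induced subgraph within a bounded number of
  hops of a seed set, optionally restricted to allowed concept classes
  and relation types;
* :func:`shortest_path` — a minimum-length evidence path between two
  concepts (undirected view by default, since evidence chains routinely
  cross relation directions), with a deterministic tie-break;
* :func:`evidence_network` — the union of all instances of a set of
  meta-path templates anchored at a gene, reproducing the classic
  gene-evidence network (Trait-QTL-Gene, Gene-Protein-Domain-GO,
  ortholog phenotypes and publications, text-mined trait links).
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .errors import GraphError
from .graph import KnowledgeGraph, Relation


@dataclass
class TraversalFilter:
    """Constraints on graph traversal."""

    concept_classes: Optional[set[str]] = None  #: None = all classes
    relation_types: Optional[set[str]] = None   #: None = all types
    max_depth: int = 1
    direction: str = "both"  #: forward | reverse | both

    def __post_init__(self):
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")
        if self.direction not in ("forward", "reverse", "both"):
            raise ValueError(f"unknown direction {self.direction!r}")

    def allows_class(self, concept_class: str) -> bool:
        return self.concept_classes is None or concept_class in self.concept_classes

    def allows_type(self, relation_type: str) -> bool:
        return self.relation_types is None or relation_type in self.relation_types


@dataclass
class EvidencePath:
    """Alternating concept/relation chain, starting and ending on
    concepts; ``length`` is the number of relations."""

    concepts: list[int]
    relations: list[int]

    @property
    def length(self) -> int:
        return len(self.relations)


def _neighbours(
    g: KnowledgeGraph, cid: int, filt: TraversalFilter
) -> list[tuple[int, Relation]]:
    """(neighbour id, relation) pairs leaving *cid* under the filter."""
    out = []
    for rel in g.relations_of(cid):
        if not filt.allows_type(rel.relation_type):
            continue
        if rel.source == cid and filt.direction in ("forward", "both"):
            out.append((rel.target, rel))
        if rel.target == cid and filt.direction in ("reverse", "both"):
            out.append((rel.source, rel))
        # symmetric storage means a relation may be traversable either way
    return out


def _check_seeds(g: KnowledgeGraph, seeds: Iterable[int]) -> list[int]:
    out = []
    for s in seeds:
        if s not in g.concepts:
            raise GraphError(f"unknown seed concept {s}")
        out.append(s)
    return out


def _subgraph(g: KnowledgeGraph, concept_ids: set[int],
              filt: Optional[TraversalFilter] = None) -> KnowledgeGraph:
    """Induced subgraph on *concept_ids*, keeping original ids."""
    sub = KnowledgeGraph(g.meta)
    for cid in sorted(concept_ids):
        c = g.concepts[cid]
        sub.concepts[cid] = c
        sub._incident[cid] = set()
        for acc in c.accessions:
            sub.accession_index.setdefault(acc.key, set()).add(cid)
        for name in c.names:
            sub.name_index.setdefault(name.lower(), set()).add(cid)
        sub._next_concept_id = max(sub._next_concept_id, cid + 1)
    for rid in sorted(g.relations):
        r = g.relations[rid]
        if r.source in concept_ids and r.target in concept_ids:
            if filt is not None and not filt.allows_type(r.relation_type):
                continue
            sub.relations[rid] = r
            key = sub._canonical_key(r.source, r.target, r.relation_type)
            sub._relation_key[key] = rid
            sub._incident[r.source].add(rid)
            sub._incident[r.target].add(rid)
            sub._next_relation_id = max(sub._next_relation_id, rid + 1)
    return sub


def neighborhood(
    g: KnowledgeGraph, seeds: Iterable[int], filt: TraversalFilter
) -> KnowledgeGraph:
    """Induced subgraph of everything reachable from the seeds within
    ``filt.max_depth`` hops through allowed classes and relation types.

    Seeds are always included, even when their class is not allowed.
    """
    seeds = _check_seeds(g, seeds)
    visited: set[int] = set(seeds)
    frontier = deque((s, 0) for s in sorted(seeds))
    while frontier:
        cid, depth = frontier.popleft()
        if depth >= filt.max_depth:
            continue
        for nid, _rel in _neighbours(g, cid, filt):
            if nid in visited:
                continue
            if not filt.allows_class(g.concepts[nid].concept_class):
                continue
            visited.add(nid)
            frontier.append((nid, depth + 1))
    return _subgraph(g, visited, filt)


def shortest_path(
    g: KnowledgeGraph, a: int, b: int, filt: Optional[TraversalFilter] = None
) -> Optional[EvidencePath]:
    """Minimum-length path between two concepts under the filter.

    Ties are broken deterministically: among all shortest paths the one
    with the lexicographically smallest concept-id sequence is returned,
    and on each hop the smallest-id qualifying relation is used.  Returns
    ``None`` when the concepts are disconnected; a == b yields a
    zero-length path.
    """
    if filt is None:
        filt = TraversalFilter(max_depth=len(g.concepts) + 1, direction="both")
    _check_seeds(g, [a, b])
    if a == b:
        return EvidencePath([a], [])

    def passable(cid: int) -> bool:
        return cid in (a, b) or filt.allows_class(g.concepts[cid].concept_class)

    # BFS distances from b, then greedy reconstruction from a choosing the
    # smallest-id neighbour that decreases the distance: yields the
    # lexicographically smallest shortest concept sequence.
    dist: dict[int, int] = {b: 0}
    q = deque([b])
    while q:
        cid = q.popleft()
        if dist[cid] >= filt.max_depth:
            continue
        for nid, _rel in _neighbours(g, cid, filt):
            if nid not in dist and passable(nid):
                dist[nid] = dist[cid] + 1
                q.append(nid)
    if a not in dist:
        return None
    concepts = [a]
    relations: list[int] = []
    cur = a
    while cur != b:
        want = dist[cur] - 1
        best: Optional[tuple[int, int]] = None  # (neighbour, relation id)
        for nid, rel in _neighbours(g, cur, filt):
            if dist.get(nid) == want and passable(nid):
                if best is None or (nid, rel.id) < best:
                    best = (nid, rel.id)
        assert best is not None
        concepts.append(best[0])
        relations.append(best[1])
        cur = best[0]
    return EvidencePath(concepts, relations)


# ---------------------------------------------------------------------------
# gene-evidence networks via meta-path templates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MetaPathStep:
    """One hop of a meta-path: follow a relation of ``relation_type`` (in
    either direction) to a concept whose class is in ``target_classes``
    (None = any class)."""

    relation_type: str
    target_classes: Optional[frozenset[str]] = None

    def admits(self, concept_class: str) -> bool:
        return self.target_classes is None or concept_class in self.target_classes


def _step(rtype: str, *classes: str) -> MetaPathStep:
    return MetaPathStep(rtype, frozenset(classes) if classes else None)


#: Default templates anchored at a Gene; partial instances count, so a
#: gene with only an encodes edge still yields Gene + Protein.
DEFAULT_META_PATHS: tuple[tuple[MetaPathStep, ...], ...] = (
    # genetics: co-located QTL and the traits they control
    (_step("colocated", "QTL"), _step("control", "Trait")),
    # annotation: protein, its domains, and domain-linked GO terms
    (_step("encodes", "Protein"), _step("has_domain", "ProtDomain"),
     _step("cross_reference", "BioProc", "MolFunc", "CelComp")),
    # protein-level GO annotation
    (_step("encodes", "Protein"),
     _step("participates_in", "BioProc")),
    (_step("encodes", "Protein"), _step("has_function", "MolFunc")),
    (_step("encodes", "Protein"), _step("located_in", "CelComp")),
    # homology: orthologs, their phenotypes and literature
    (_step("encodes", "Protein"), _step("ortholog", "Protein"),
     _step("has_observed_phenotype", "Phenotype")),
    (_step("encodes", "Protein"), _step("ortholog", "Protein"),
     _step("published_in", "Publication")),
    (_step("encodes", "Protein"), _step("has_similar_sequence", "Protein"),
     _step("has_observed_phenotype", "Phenotype")),
    # variation
    (_step("in_proximity", "SNP"),),
    # text-mined trait links
    (_step("cooccurs_with", "TO"),),
)


def evidence_network(
    g: KnowledgeGraph,
    gene: int,
    meta_paths: Sequence[Sequence[MetaPathStep]] = DEFAULT_META_PATHS,
) -> KnowledgeGraph:
    """Union of all (partial) instances of the meta-path templates
    anchored at *gene*: the gene-evidence subgraph.

    Every prefix of a template instance is included, so the result is a
    connected subgraph containing the anchor even when no template
    matches completely.
    """
    anchor = g.concepts.get(gene)
    if anchor is None:
        raise GraphError(f"unknown concept {gene}")
    if anchor.concept_class != "Gene":
        raise GraphError(f"concept {gene} is {anchor.concept_class}, not Gene")
    keep_concepts: set[int] = {gene}
    keep_relations: set[int] = set()

    def walk(cid: int, steps: Sequence[MetaPathStep], seen: frozenset[int]) -> None:
        if not steps:
            return
        step, rest = steps[0], steps[1:]
        for rel in g.relations_of(cid):
            if rel.relation_type != step.relation_type:
                continue
            nid = rel.target if rel.source == cid else rel.source
            if nid in seen:
                continue
            if not step.admits(g.concepts[nid].concept_class):
                continue
            keep_concepts.add(nid)
            keep_relations.add(rel.id)
            walk(nid, rest, seen | {nid})

    for template in meta_paths:
        walk(gene, tuple(template), frozenset([gene]))

    sub = _subgraph(g, keep_concepts)
    # restrict to the relations actually on template instances
    for rid in sorted(set(sub.relations) - keep_relations):
        sub._drop_relation(rid)
    return sub
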