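"""Mapping and collapsing operators that interconnect parsed networks.

Independently parsed networks (genes/proteins, ontologies, annotation,
genetics, homology, literature) are merged into one graph by first
creating ``equal`` relations between equivalent concepts — shared
accessions, shared names, or similar sequences — and then collapsing all
equal-connected components into single representative concepts with
unioned content and summarised provenance.  Additional operators create
cross-type evidence links: gene/QTL co-location, SNP/gene proximity and
protein-domain-to-GO cross references.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Optional

from .align import smith_waterman
from .errors import CollapseError, MetaModelError
from .graph import (
    Accession,
    Concept,
    GenomicLocation,
    KnowledgeGraph,
    MAP_UNITS,
    concept_locations,
)

log = logging.getLogger("gsknet.integrate")

_WS = re.compile(r"\s+")


# ---------------------------------------------------------------------------
# accession- and name-based mapping
# ---------------------------------------------------------------------------

def accession_map(
    g: KnowledgeGraph,
    classes: Optional[Iterable[str]] = None,
    namespaces: Optional[Iterable[str]] = None,
) -> int:
    """Create ``equal`` relations between same-class concepts sharing a
    non-ambiguous accession.

    ``classes`` / ``namespaces`` restrict which concept classes and
    accession namespaces participate (``None`` = all).  Returns the
    number of equal relations added (pairs already linked count zero).
    """
    classes = set(classes) if classes is not None else None
    namespaces = set(namespaces) if namespaces is not None else None
    added = 0
    before = g.num_relations
    for (ns, value), cids in sorted(g.accession_index.items()):
        if namespaces is not None and ns not in namespaces:
            continue
        if len(cids) < 2:
            continue
        plain = Accession(ns, value)
        holders = [
            cid for cid in sorted(cids)
            if plain in g.concepts[cid].accessions
            and (classes is None or g.concepts[cid].concept_class in classes)
        ]
        for a, b in combinations(holders, 2):
            if g.concepts[a].concept_class != g.concepts[b].concept_class:
                continue
            g.add_relation(a, b, "equal", data_source="INTEGRATOR",
                           evidence=("ACC",))
    added = g.num_relations - before
    return added


def normalise_name(name: str) -> str:
    """Case-folded, whitespace-collapsed form used by name mapping."""
    return _WS.sub(" ", name.strip()).casefold()


def name_map(
    g: KnowledgeGraph,
    classes: Optional[Iterable[str]] = None,
    min_len: int = 3,
) -> int:
    """Create ``equal`` relations between same-class concepts sharing a
    normalised name or synonym; names shorter than ``min_len`` never
    match (short symbols are too promiscuous)."""
    classes = set(classes) if classes is not None else None
    buckets: dict[tuple[str, str], set[int]] = {}
    for c in g.concepts.values():
        if classes is not None and c.concept_class not in classes:
            continue
        for name in c.names:
            norm = normalise_name(name)
            if len(norm) < min_len:
                continue
            buckets.setdefault((c.concept_class, norm), set()).add(c.id)
    before = g.num_relations
    for (_, _), cids in sorted(buckets.items()):
        for a, b in combinations(sorted(cids), 2):
            g.add_relation(a, b, "equal", data_source="INTEGRATOR",
                           evidence=("NAM",))
    return g.num_relations - before


# ---------------------------------------------------------------------------
# sequence-similarity mapping (Smith-Waterman, top-k per query)
# ---------------------------------------------------------------------------

def sequence_map(
    g: KnowledgeGraph,
    query_class: str = "Protein",
    subject_class: str = "Protein",
    top_k: int = 10,
    min_score: int = 50,
    query_taxid: Optional[str] = None,
    subject_taxid: Optional[str] = None,
    relation_type: str = "has_similar_sequence",
    sequence_attribute: str = "AA",
) -> int:
    """Link concepts with similar sequences by local alignment.

    Each query sequence is aligned (Smith-Waterman, affine gaps, BLOSUM62)
    against every subject; for each query at most ``top_k`` subjects with
    score >= ``min_score`` are linked by ``relation_type`` relations
    carrying Score and Identity attributes.  Self-hits are excluded.
    ``query_taxid`` / ``subject_taxid`` restrict the two sides by their
    TAXID attribute (e.g. crop queries against reference subjects).
    Returns the number of relations added.
    """

    def pool(cls: str, taxid: Optional[str]) -> list[Concept]:
        out = []
        for c in sorted(g.concepts_of_class(cls), key=lambda c: c.id):
            if taxid is not None and c.attributes.get("TAXID") != taxid:
                continue
            out.append(c)
        return out

    queries = pool(query_class, query_taxid)
    subjects = pool(subject_class, subject_taxid)
    before = g.num_relations
    for q in queries:
        seq = q.attributes.get(sequence_attribute)
        if not seq:
            log.warning("sequence_map: concept %d has no %s attribute; skipped",
                        q.id, sequence_attribute)
            continue
        hits = []
        for s in subjects:
            if s.id == q.id:
                continue
            sseq = s.attributes.get(sequence_attribute)
            if not sseq:
                continue
            aln = smith_waterman(seq, sseq)
            if aln.score >= min_score:
                hits.append((-aln.score, s.id, aln))
        hits.sort()
        for _, sid, aln in hits[:top_k]:
            g.add_relation(
                q.id, sid, relation_type,
                attributes={"Score": aln.score,
                            "Identity": round(aln.identity, 4)},
                data_source="INTEGRATOR", evidence=("SSA",),
            )
    return g.num_relations - before


# ---------------------------------------------------------------------------
# location-based mapping
# ---------------------------------------------------------------------------

def _checked_locations(c: Concept) -> list[GenomicLocation]:
    locs = concept_locations(c)
    for loc in locs:
        if loc.unit not in MAP_UNITS:
            raise MetaModelError(
                f"concept {c.id}: location with unknown map unit {loc.unit!r}"
            )
    return locs


def colocation_map(
    g: KnowledgeGraph,
    subject_class: str = "Gene",
    region_class: str = "QTL",
    relation_type: str = "colocated",
) -> int:
    """Link subject concepts (genes) to region concepts (QTL) whose
    genomic intervals overlap on the same map.

    Overlap is closed-interval intersection and requires identical
    (chromosome, unit, taxid) — physical (bp) and genetic (cM) positions
    never match each other.  Relations are directed subject -> region.
    Returns the number of relations added.
    """
    regions = [(c, _checked_locations(c))
               for c in sorted(g.concepts_of_class(region_class),
                               key=lambda c: c.id)]
    before = g.num_relations
    for subj in sorted(g.concepts_of_class(subject_class), key=lambda c: c.id):
        slocs = _checked_locations(subj)
        if not slocs:
            continue
        for region, rlocs in regions:
            if any(a.overlaps(b) for a in slocs for b in rlocs):
                g.add_relation(subj.id, region.id, relation_type,
                               data_source="INTEGRATOR", evidence=("COLOC",))
    return g.num_relations - before


def proximity_map(
    g: KnowledgeGraph,
    subject_class: str = "SNP",
    target_class: str = "Gene",
    window: float = 0,
) -> int:
    """Link point features (SNPs) to genes whose interval, extended by
    ``window`` map units on both sides, contains the point.

    The subject's position is the begin of its location (point locations
    have begin == end).  Same-map rule as :func:`colocation_map`.
    Relations are directed subject -> target (``in_proximity``).
    """
    targets = [(c, _checked_locations(c))
               for c in sorted(g.concepts_of_class(target_class),
                               key=lambda c: c.id)]
    before = g.num_relations
    for subj in sorted(g.concepts_of_class(subject_class), key=lambda c: c.id):
        for ploc in _checked_locations(subj):
            pos = ploc.begin
            for target, tlocs in targets:
                for tloc in tlocs:
                    if (ploc.comparable(tloc)
                            and tloc.begin - window <= pos <= tloc.end + window):
                        g.add_relation(subj.id, target.id, "in_proximity",
                                       data_source="INTEGRATOR",
                                       evidence=("PROX",))
                        break
    return g.num_relations - before


# ---------------------------------------------------------------------------
# external2go cross references
# ---------------------------------------------------------------------------

_X2GO_LINE = re.compile(
    r"^(?P<db>[A-Za-z0-9_.]+):(?P<acc>\S+)\s+.*>\s*GO:.*;\s*(?P<go>GO:\d{7})\s*$"
)


@dataclass
class External2GoReport:
    relations_added: int
    unmatched_lines: int
    malformed_lines: int


def external2go_map(g: KnowledgeGraph, mapping_source) -> External2GoReport:
    """Create ``cross_reference`` relations from an external2go mapping
    file (e.g. interpro2go) between Protein Domain concepts and GO term
    concepts already present in the graph.

    Lines look like ``InterPro:IPR003657 WRKY domain > GO:DNA binding ;
    GO:0003677``.  Lines whose domain or GO end is absent from the graph
    are counted as unmatched; malformed lines are warned about and
    skipped.
    """
    if hasattr(mapping_source, "read"):
        lines = mapping_source.read().splitlines()
    else:
        with open(mapping_source, "rt", encoding="utf-8") as fh:
            lines = fh.read().splitlines()
    added = unmatched = malformed = 0
    for lineno, line in enumerate(lines, 1):
        line = line.strip()
        if not line or line.startswith("!"):
            continue
        m = _X2GO_LINE.match(line)
        if m is None:
            malformed += 1
            log.warning("external2go: malformed line %d skipped: %s",
                        lineno, line[:80])
            continue
        db = m.group("db").upper()
        domain_ids = {
            c.id for c in g.find_by_accession(m.group("acc"), namespace=db)
            if c.concept_class == "ProtDomain"
        }
        go_ids = {
            c.id for c in g.find_by_accession(m.group("go"), namespace="GO")
        }
        if not domain_ids or not go_ids:
            unmatched += 1
            continue
        for d in sorted(domain_ids):
            for t in sorted(go_ids):
                before = g.num_relations
                g.add_relation(d, t, "cross_reference",
                               data_source="INTEGRATOR", evidence=("X2GO",))
                added += g.num_relations - before
    return External2GoReport(added, unmatched, malformed)


# ---------------------------------------------------------------------------
# collapsing equal-connected components
# ---------------------------------------------------------------------------

@dataclass
class CollapseReport:
    merged_groups: int        #: equal-components with >= 2 concepts collapsed
    concepts_removed: int
    relations_removed: int    #: equal relations dropped + duplicates merged
    rejected_components: int  #: cross-class components left untouched


def collapse_equal(g: KnowledgeGraph) -> CollapseReport:
    """Collapse every connected component of the ``equal``-relation
    subgraph into a single representative concept.

    The representative is the lowest concept id of the component; its
    accessions, names, attributes, provenance and evidence become unions
    over the component, all non-equal relations are rewired to it
    (duplicates merged), and the equal relations are removed.  A
    component mixing concept classes is rejected — reported, left
    unmerged, its equal relations removed.  Idempotent.
    """
    # union-find over equal edges
    parent: dict[int, int] = {}

    def find(x: int) -> int:
        while parent.get(x, x) != x:
            parent[x] = parent.get(parent[x], parent[x])
            x = parent[x]
        return x

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            if rb < ra:
                ra, rb = rb, ra
            parent[rb] = ra

    equal_rel_ids = [rid for rid, r in g.relations.items()
                     if r.relation_type == "equal"]
    for rid in equal_rel_ids:
        r = g.relations[rid]
        union(r.source, r.target)

    components: dict[int, list[int]] = {}
    for cid in list(parent) + [r for rid in equal_rel_ids
                               for r in (g.relations[rid].source,
                                         g.relations[rid].target)]:
        components.setdefault(find(cid), []).append(cid)
    for root in components:
        members = sorted(set(components[root]) | {root})
        components[root] = members

    concepts_before = len(g)
    relations_before = g.num_relations
    # drop equal relations first so they are not rewired
    for rid in equal_rel_ids:
        if rid in g.relations:
            g._drop_relation(rid)

    merged = rejected = 0
    for root in sorted(components):
        members = components[root]
        if len(members) < 2:
            continue
        classes = {g.concepts[m].concept_class for m in members}
        if len(classes) > 1:
            rejected += 1
            log.warning(
                "collapse_equal: component %s mixes classes %s; left unmerged",
                members, sorted(classes),
            )
            continue
        rep = members[0]
        for other in members[1:]:
            g._absorb(rep, other)
        merged += 1
    return CollapseReport(
        merged_groups=merged,
        concepts_removed=concepts_before - len(g),
        relations_removed=relations_before - g.num_relations,
        rejected_components=rejected,
    )
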