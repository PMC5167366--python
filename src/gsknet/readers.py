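"""Parsers turning standard-format files into independent typed networks.

Each parser reads one dataset (GFF3 + protein FASTA, OBO ontologies, GAF
annotation, declarative tabular imports, Medline-style publication
records, a minimal UniProt tabular dialect) and returns a fresh
:class:`~gsknet.graph.KnowledgeGraph` populated against the default
vocabulary.  Within one parse, concepts sharing a non-ambiguous
accession merge automatically; interconnecting the resulting networks is
left to the mapping/collapsing operators.

All readers accept plain or gzip-compressed files.
"""

from __future__ import annotations

import gzip
import io
import logging
from dataclasses import dataclass, field
from typing import Optional, Union

import gffutils
import obonet
import pandas as pd
from Bio import SeqIO
from lxml import etree

from .errors import ParseError, TableSpecError
from .graph import GenomicLocation, KnowledgeGraph
from .metamodel import MetaModel

log = logging.getLogger("gsknet.readers")

#: GO namespace -> concept class
GO_NAMESPACE_CLASS = {
    "biological_process": "BioProc",
    "molecular_function": "MolFunc",
    "cellular_component": "CelComp",
}

#: GAF aspect code -> (relation type, GO concept class)
GAF_ASPECT = {
    "P": ("participates_in", "BioProc"),
    "F": ("has_function", "MolFunc"),
    "C": ("located_in", "CelComp"),
}

GAF_OBJECT_TYPE_CLASS = {"gene": "Gene", "protein": "Protein"}


def open_text(source) -> io.TextIOBase:
    """Open a path (plain or .gz) or pass through a text file object."""
    if hasattr(source, "read"):
        return source
    path = str(source)
    if path.endswith(".gz"):
        return gzip.open(path, "rt", encoding="utf-8")
    return open(path, "rt", encoding="utf-8")


def _read_all(source) -> str:
    fh = open_text(source)
    try:
        return fh.read()
    finally:
        if fh is not source:
            fh.close()


# ---------------------------------------------------------------------------
# FASTA-GFF3: the Gene-Protein network
# ---------------------------------------------------------------------------

def parse_fasta_gff3(gff3_source, fasta_source, taxid: str) -> KnowledgeGraph:
    """Build the Gene-Protein ``encodes`` network from genome annotation.

    One Gene concept per ``gene`` feature (chromosome/begin/end/strand
    attributes plus a bp :class:`GenomicLocation`), one Protein concept
    per protein FASTA record whose id matches an mRNA of the annotation,
    and an ``encodes`` relation for each gene -> protein pair.  Every
    concept is stamped with *taxid*.  FASTA records without a matching
    mRNA become orphan Protein concepts (warned).  GFF3 feature types
    other than gene/mRNA/CDS are ignored with a counted warning.
    """
    text = _read_all(gff3_source)
    for lineno, line in enumerate(text.splitlines(), 1):
        if not line or line.startswith("#"):
            continue
        if len(line.split("\t")) != 9:
            raise ParseError(f"GFF3 line {lineno}: expected 9 tab-separated "
                             f"columns: {line[:60]!r}")
    db = gffutils.create_db(
        text, ":memory:", from_string=True, merge_strategy="create_unique",
        keep_order=True,
    )

    g = KnowledgeGraph(MetaModel.default())
    ignored: dict[str, int] = {}
    for ft in db.featuretypes():
        if ft not in ("gene", "mRNA", "CDS"):
            ignored[ft] = len(list(db.features_of_type(ft)))
    if ignored:
        log.warning("parse_fasta_gff3: ignored feature types %s", ignored)

    sequences = {}
    fh = open_text(fasta_source)
    try:
        for rec in SeqIO.parse(fh, "fasta"):
            sequences[rec.id] = str(rec.seq)
    finally:
        if fh is not fasta_source:
            fh.close()

    transcript_to_gene: dict[str, int] = {}
    for gene in db.features_of_type("gene", order_by="start"):
        names = []
        if "Name" in gene.attributes:
            names.append((gene.attributes["Name"][0], True))
        gid = g.upsert_concept(
            "Gene",
            accessions=[("ENSEMBL", gene.id)],
            names=names,
            attributes={
                "Chromosome": gene.seqid,
                "BEGIN": gene.start,
                "END": gene.end,
                "Strand": gene.strand or ".",
                "TAXID": taxid,
                "Location": GenomicLocation(gene.seqid, gene.start, gene.end,
                                            "bp", taxid),
            },
            source="ENSEMBL",
        )
        for mrna in db.children(gene, featuretype="mRNA", order_by="start"):
            transcript_to_gene[mrna.id] = gid

    for seq_id in sequences:
        pid = g.upsert_concept(
            "Protein",
            accessions=[("ENSEMBL", seq_id)],
            attributes={"AA": sequences[seq_id], "TAXID": taxid},
            source="ENSEMBL",
        )
        gid = transcript_to_gene.get(seq_id)
        if gid is None:
            log.warning("parse_fasta_gff3: FASTA id %r has no GFF3 mRNA; "
                        "orphan Protein created", seq_id)
            continue
        g.add_relation(gid, pid, "encodes", data_source="ENSEMBL")
    return g


# ---------------------------------------------------------------------------
# OBO ontologies
# ---------------------------------------------------------------------------

def _obo_synonyms(data: dict) -> list[str]:
    out = []
    for syn in data.get("synonym", []):
        if syn.startswith('"'):
            end = syn.find('"', 1)
            if end > 0:
                out.append(syn[1:end])
    return out


def parse_obo(source, concept_class: Optional[str] = None) -> KnowledgeGraph:
    """Parse an OBO ontology into one concept per non-obsolete term.

    For GO (``concept_class=None``) the term namespace selects the class
    (BioProc / MolFunc / CelComp); otherwise every term gets
    *concept_class* (e.g. ``TO`` for the Trait Ontology).  ``is_a``,
    ``part_of`` and ``regulates`` relations are created between terms;
    relations whose target is not a term stanza are skipped with a
    warning.
    """
    fh = open_text(source)
    try:
        onto = obonet.read_obo(fh)
    finally:
        if fh is not source:
            fh.close()

    g = KnowledgeGraph(MetaModel.default())
    term_ids: dict[str, int] = {}
    for node in sorted(onto.nodes):
        data = onto.nodes[node]
        if "name" not in data:
            continue  # referenced but not defined in this file
        if concept_class is None:
            cls = GO_NAMESPACE_CLASS.get(data.get("namespace"))
            if cls is None:
                log.warning("parse_obo: term %s has no recognised namespace; "
                            "skipped", node)
                continue
        else:
            cls = concept_class
        namespace = node.split(":", 1)[0] if ":" in node else cls
        g.meta.ensure_data_source(namespace)
        names = [(data["name"], True)]
        names += [(s, False) for s in _obo_synonyms(data)]
        term_ids[node] = g.upsert_concept(
            cls, accessions=[(namespace, node)], names=names,
            source=namespace,
        )
    for u, v, key in sorted(onto.edges(keys=True)):
        if key not in ("is_a", "part_of", "regulates"):
            continue
        if u not in term_ids or v not in term_ids:
            log.warning("parse_obo: %s %s %s has a dangling end; skipped",
                        u, key, v)
            continue
        src = u.split(":", 1)[0] if ":" in u else "GO"
        g.add_relation(term_ids[u], term_ids[v], key, data_source=src)
    return g


# ---------------------------------------------------------------------------
# GAF gene/protein annotation
# ---------------------------------------------------------------------------

def parse_gaf(source) -> KnowledgeGraph:
    """Parse GAF 2.x annotation rows into entity -> GO-term relations.

    DB object type selects the entity class (gene -> Gene, protein ->
    Protein; anything else is rejected).  The aspect selects the relation
    type (P -> participates_in, F -> has_function, C -> located_in) and
    the GO stub's class.  Rows qualified with NOT are skipped; the GAF
    evidence code becomes the relation's evidence.
    """
    g = KnowledgeGraph(MetaModel.default())
    fh = open_text(source)
    try:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("!"):
                continue
            cols = line.split("\t")
            if len(cols) < 13:
                raise ParseError(f"GAF line {lineno}: expected >= 13 columns")
            (db, obj_id, symbol, qualifier, go_id, _ref, ev_code, _with,
             aspect, obj_name, synonyms, obj_type) = cols[:12]
            taxon = cols[12] if len(cols) > 12 else ""
            if "NOT" in qualifier.split("|"):
                continue
            cls = GAF_OBJECT_TYPE_CLASS.get(obj_type.lower())
            if cls is None:
                raise ParseError(
                    f"GAF line {lineno}: unmapped DB object type {obj_type!r}"
                )
            if aspect not in GAF_ASPECT:
                raise ParseError(f"GAF line {lineno}: unknown aspect {aspect!r}")
            rel_type, go_class = GAF_ASPECT[aspect]
            ns = g.meta.ensure_data_source(db.upper())
            names = [(symbol, True)] if symbol else []
            names += [(s, False) for s in synonyms.split("|") if s]
            attrs = {}
            if taxon.startswith("taxon:"):
                attrs["TAXID"] = taxon.split(":", 1)[1]
            eid = g.upsert_concept(cls, accessions=[(ns, obj_id)],
                                   names=names, attributes=attrs, source="GOA")
            tid = g.upsert_concept(go_class, accessions=[("GO", go_id)],
                                   source="GOA")
            g.add_relation(eid, tid, rel_type, data_source="GOA",
                           evidence=(g.meta.ensure_evidence(ev_code),))
    finally:
        if fh is not source:
            fh.close()
    return g


# ---------------------------------------------------------------------------
# declarative tabular imports
# ---------------------------------------------------------------------------

Binding = Union[str, dict]


def _resolve(binding: Optional[Binding], row: pd.Series) -> Optional[str]:
    """A binding is a column name, {"column": name} or {"const": value}."""
    if binding is None:
        return None
    if isinstance(binding, dict):
        if "const" in binding:
            return str(binding["const"])
        binding = binding["column"]
    if binding not in row.index:
        raise TableSpecError(f"bound column {binding!r} missing from table")
    value = row[binding]
    return None if value == "" else str(value)


@dataclass
class LocationSpec:
    """Assemble a :class:`GenomicLocation` attribute from columns."""

    chromosome: Binding
    begin: Binding
    end: Optional[Binding] = None  #: defaults to begin (point feature)
    unit: Binding = "bp"
    taxid: Optional[Binding] = None
    attribute: str = "Location"

    @classmethod
    def from_dict(cls, d: dict) -> "LocationSpec":
        return cls(
            chromosome=d["chromosome"], begin=d["begin"], end=d.get("end"),
            unit=d.get("unit", {"const": "bp"}),
            taxid=d.get("taxid"), attribute=d.get("attribute", "Location"),
        )


@dataclass
class SlotSpec:
    """How one concept (subject or object) is built from a table row."""

    concept_class: str
    #: (namespace, column binding) pairs
    accessions: list[tuple[str, Binding]] = field(default_factory=list)
    #: (column binding, preferred flag) pairs
    names: list[tuple[Binding, bool]] = field(default_factory=list)
    #: column binding -> attribute name
    attributes: dict[str, str] = field(default_factory=dict)
    locations: list[LocationSpec] = field(default_factory=list)

    @classmethod
    def from_dict(cls, d: dict) -> "SlotSpec":
        return cls(
            concept_class=d["class"],
            accessions=[(a["namespace"], a.get("column", a))
                        for a in d.get("accessions", [])],
            names=[(n["column"], bool(n.get("preferred", False)))
                   for n in d.get("names", [])],
            attributes=dict(d.get("attributes", {})),
            locations=[LocationSpec.from_dict(l)
                       for l in d.get("locations", [])],
        )


@dataclass
class TableSpec:
    """Declarative mapping of a TSV file onto concepts and relations.

    The subject slot is mandatory; an object slot plus a relation
    binding turn each row into a subject-relation-object triple (e.g.
    Gene ``has_variance`` SNP).  Within the parse, repeated accessions
    merge into one concept, so tables naturally de-duplicate.
    """

    subject: SlotSpec
    object: Optional[SlotSpec] = None
    relation: Optional[str] = None  #: relation type, subject -> object
    relation_reversed: bool = False
    source_id: str = "INTEGRATOR"
    evidence: str = "IMPD"
    taxid: Optional[str] = None

    def __post_init__(self):
        if self.relation is not None and self.object is None:
            raise TableSpecError("relation declared but no object slot bound")

    @classmethod
    def from_dict(cls, d: dict) -> "TableSpec":
        rel = d.get("relation")
        return cls(
            subject=SlotSpec.from_dict(d["subject"]),
            object=SlotSpec.from_dict(d["object"]) if d.get("object") else None,
            relation=rel.get("type") if rel else None,
            relation_reversed=bool(rel.get("reversed", False)) if rel else False,
            source_id=d.get("source_id", "INTEGRATOR"),
            evidence=d.get("evidence", "IMPD"),
            taxid=str(d["taxid"]) if d.get("taxid") is not None else None,
        )


def _coerce(g: KnowledgeGraph, attr: str, value: str):
    kind = g.meta.attribute_names[attr].kind
    if kind == "integer":
        return int(value)
    if kind == "decimal":
        return float(value)
    return value


def _build_slot(g: KnowledgeGraph, slot: SlotSpec, row: pd.Series,
                spec: TableSpec) -> Optional[int]:
    accessions = []
    for namespace, binding in slot.accessions:
        value = _resolve(binding, row)
        if value is None:
            return None  # empty accession cell: caller skips the row
        g.meta.ensure_data_source(namespace)
        accessions.append((namespace, value))
    names = []
    for binding, preferred in slot.names:
        value = _resolve(binding, row)
        if value is not None:
            names.append((value, preferred))
    attributes: dict[str, object] = {}
    for binding, attr in slot.attributes.items():
        value = _resolve(binding, row)
        if value is not None:
            attributes[attr] = _coerce(g, attr, value)
    for loc in slot.locations:
        chrom = _resolve(loc.chromosome, row)
        begin = _resolve(loc.begin, row)
        if chrom is None or begin is None:
            continue
        end = _resolve(loc.end, row) if loc.end is not None else begin
        unit = _resolve(loc.unit, row) or "bp"
        taxid = _resolve(loc.taxid, row) if loc.taxid is not None else spec.taxid
        attributes[loc.attribute] = GenomicLocation(
            chrom, float(begin), float(end), unit, taxid,
        )
    if spec.taxid is not None:
        attributes.setdefault("TAXID", spec.taxid)
    g.meta.ensure_data_source(spec.source_id)
    return g.upsert_concept(
        slot.concept_class, accessions=accessions, names=names,
        attributes=attributes, source=spec.source_id,
        evidence=(g.meta.ensure_evidence(spec.evidence),),
    )


def parse_tabular(source, spec: TableSpec) -> KnowledgeGraph:
    """Apply a :class:`TableSpec` to a header-bearing TSV file.

    Each data row yields the bound subject (and object + relation, when
    declared).  Rows with an empty accession cell are skipped with a
    warning.
    """
    fh = open_text(source)
    try:
        table = pd.read_csv(fh, sep="\t", dtype=str, keep_default_na=False)
    finally:
        if fh is not source:
            fh.close()
    g = KnowledgeGraph(MetaModel.default())
    for idx, row in table.iterrows():
        sid = _build_slot(g, spec.subject, row, spec)
        if sid is None:
            log.warning("parse_tabular: row %d has an empty subject "
                        "accession; skipped", idx + 1)
            continue
        if spec.object is not None:
            oid = _build_slot(g, spec.object, row, spec)
            if oid is None:
                log.warning("parse_tabular: row %d has an empty object "
                            "accession; skipped", idx + 1)
                continue
            if spec.relation is not None:
                a, b = (oid, sid) if spec.relation_reversed else (sid, oid)
                g.add_relation(a, b, spec.relation,
                               data_source=spec.source_id,
                               evidence=(spec.evidence,))
    return g


# ---------------------------------------------------------------------------
# publications (minimal Medline XML or 3-column TSV)
# ---------------------------------------------------------------------------

def parse_publications(source) -> KnowledgeGraph:
    """Publication concepts from Medline-like XML or a pmid/title/abstract
    TSV.  Duplicate PMIDs merge; empty abstracts leave the attribute
    absent."""
    text = _read_all(source)
    g = KnowledgeGraph(MetaModel.default())
    if text.lstrip().startswith("<"):
        try:
            root = etree.fromstring(text.encode("utf-8"))
        except etree.XMLSyntaxError as exc:
            raise ParseError(f"malformed publication XML: {exc}") from exc
        for art in root.iter("PubmedArticle"):
            pmid = art.findtext(".//PMID")
            if not pmid:
                raise ParseError("publication record without PMID")
            title = art.findtext(".//ArticleTitle") or ""
            abstract = " ".join(
                t.text for t in art.findall(".//AbstractText") if t.text
            )
            _add_publication(g, pmid.strip(), title, abstract)
    else:
        table = pd.read_csv(io.StringIO(text), sep="\t", dtype=str,
                            keep_default_na=False)
        for _, row in table.iterrows():
            _add_publication(g, row["pmid"], row.get("title", ""),
                             row.get("abstract", ""))
    return g


def _add_publication(g: KnowledgeGraph, pmid: str, title: str,
                     abstract: str) -> int:
    attrs: dict[str, object] = {}
    if title:
        attrs["Title"] = title
    if abstract:
        attrs["Abstract"] = abstract
    return g.upsert_concept(
        "Publication", accessions=[("PMID", pmid)], attributes=attrs,
        source="PMID",
    )


# ---------------------------------------------------------------------------
# minimal UniProt tabular dialect
# ---------------------------------------------------------------------------

def parse_uniprot_min(source) -> KnowledgeGraph:
    """Reviewed-protein records from a simplified tabular dialect.

    Columns: ``accession  name  taxid  sequence  go_terms  pmids
    phenotype``.  ``go_terms`` is a semicolon list of ``aspect:GO:nnnnnnn``
    entries (aspect P/F/C selecting the relation type, mirroring GAF);
    ``pmids`` a semicolon list.  A non-empty phenotype text becomes a
    Phenotype concept linked by ``has_observed_phenotype``.
    """
    fh = open_text(source)
    try:
        table = pd.read_csv(fh, sep="\t", dtype=str, keep_default_na=False)
    finally:
        if fh is not source:
            fh.close()
    g = KnowledgeGraph(MetaModel.default())
    for idx, row in table.iterrows():
        attrs: dict[str, object] = {"TAXID": row["taxid"]}
        if row.get("sequence"):
            attrs["AA"] = row["sequence"]
        pid = g.upsert_concept(
            "Protein", accessions=[("UNIPROT", row["accession"])],
            names=[(row["name"], True)] if row.get("name") else [],
            attributes=attrs, source="UNIPROT",
        )
        for entry in filter(None, (row.get("go_terms") or "").split(";")):
            entry = entry.strip()
            aspect, _, go_id = entry.partition(":")
            if aspect not in GAF_ASPECT or not go_id.startswith("GO:"):
                log.warning("parse_uniprot_min: row %d: malformed GO entry "
                            "%r skipped", idx + 1, entry)
                continue
            rel_type, go_class = GAF_ASPECT[aspect]
            tid = g.upsert_concept(go_class, accessions=[("GO", go_id)],
                                   source="UNIPROT")
            g.add_relation(pid, tid, rel_type, data_source="UNIPROT")
        for pmid in filter(None, (row.get("pmids") or "").split(";")):
            pub = g.upsert_concept("Publication",
                                   accessions=[("PMID", pmid.strip())],
                                   source="UNIPROT")
            g.add_relation(pid, pub, "published_in", data_source="UNIPROT")
        phenotype = (row.get("phenotype") or "").strip()
        if phenotype:
            phen = g.upsert_concept(
                "Phenotype", names=[(phenotype, True)],
                attributes={"Description": phenotype}, source="UNIPROT",
            )
            g.add_relation(pid, phen, "has_observed_phenotype",
                           data_source="UNIPROT")
    return g
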